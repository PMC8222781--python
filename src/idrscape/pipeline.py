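"""End-to-end pipeline: ingest -> score -> segment -> compose -> classify -> compare.

A run is described by one :class:`RunConfig` (typically a YAML file) that
names either real input files (FASTA + track/propensity/annotation TSVs +
membership lists) or a synthetic cohort spec — never both.  Every stage
writes TSV tables into the output directory and the run ends with a JSON
manifest recording the configuration hash and per-table row counts, so a
run can be reproduced exactly from its manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as sio
from .composition import idr_composition_report
from .llps import LLPSThresholds, fraction_positive, membership_fraction
from .scoring import ScorerKind, ScorerSpec, score_disorder
from .segmentation import (
    SegmentationParams,
    cohort_idr_summary,
    profiles_table,
    segment_idrs,
    segments_table,
)
from .stats import stats_report, summarize_groups
from .synthetic import CohortSpec, GroupParams, generate_cohort

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    out_dir: str = "results/run"
    fasta: str | None = None
    tracks: str | None = None
    propensities: str | None = None
    annotations: str | None = None
    membership_lists: list[str] = field(default_factory=list)
    synthetic: CohortSpec | None = None
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    thresholds: LLPSThresholds = field(default_factory=LLPSThresholds)
    scorer_window: int = 21
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        real = any([self.fasta, self.tracks, self.propensities, self.annotations])
        if real and self.synthetic is not None:
            raise ValueError("config must name real inputs or a synthetic spec, not both")
        if not real and self.synthetic is None:
            raise ValueError("config names neither real inputs nor a synthetic spec")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kwargs = dict(raw)
        if "synthetic" in kwargs and kwargs["synthetic"] is not None:
            syn = dict(kwargs["synthetic"])
            if "group_params" in syn:
                syn["group_params"] = {
                    g: GroupParams(**p) for g, p in syn["group_params"].items()
                }
            kwargs["synthetic"] = CohortSpec(**syn)
        if "segmentation" in kwargs:
            kwargs["segmentation"] = SegmentationParams(**kwargs["segmentation"])
        if "thresholds" in kwargs:
            kwargs["thresholds"] = LLPSThresholds(**kwargs["thresholds"])
        return cls(**kwargs)

    def config_dict(self) -> dict:
        d: dict = {
            "out_dir": self.out_dir,
            "segmentation": vars(self.segmentation) | {},
            "thresholds": vars(self.thresholds) | {},
            "scorer_window": self.scorer_window,
            "alpha": self.alpha,
            "seed": self.seed,
        }
        if self.synthetic is not None:
            syn = {
                k: v for k, v in vars(self.synthetic).items() if k != "group_params"
            }
            syn["group_params"] = {
                g: vars(p) | {} for g, p in self.synthetic.group_params.items()
            }
            d["synthetic"] = syn
        else:
            d["inputs"] = {
                "fasta": self.fasta,
                "tracks": self.tracks,
                "propensities": self.propensities,
                "annotations": self.annotations,
                "membership_lists": list(self.membership_lists),
            }
        return d


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns the run manifest."""
    stage_times: dict[str, float] = {}
    tables: dict[str, pd.DataFrame] = {}

    def timed(name):
        class _T:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()
                logger.info("stage %s: start", name)
                return self_inner

            def __exit__(self_inner, *exc):
                stage_times[name] = round(time.perf_counter() - self_inner.t0, 3)
                logger.info("stage %s: %.2fs", name, stage_times[name])

        return _T()

    # --- ingest / simulate -------------------------------------------------
    with timed("ingest"):
        if config.synthetic is not None:
            cohort = generate_cohort(config.synthetic)
            records = cohort.records
            tracks = {t.protein_id: t for t in cohort.tracks}
            propensities = cohort.propensities
            groups = dict(cohort.groups)
            membership_lists: list[sio.MembershipList] = []
        else:
            records = sio.read_fasta(config.fasta)
            if config.annotations:
                records = sio.annotate(records, sio.read_annotations(config.annotations))
            groups = {
                r.id: r.group_label for r in records if r.group_label is not None
            }
            tracks = {}
            if config.tracks:
                tracks = {
                    t.protein_id: t
                    for t in sio.read_score_tracks(config.tracks, records)
                }
            propensities = (
                sio.read_propensities(config.propensities)
                if config.propensities else []
            )
            membership_lists = [
                sio.read_membership_list(p) for p in config.membership_lists
            ]

    # --- score -------------------------------------------------------------
    with timed("score"):
        spec = (
            ScorerSpec(kind=ScorerKind.external_track)
            if tracks
            else ScorerSpec(window=config.scorer_window)
        )
        all_tracks = [
            score_disorder(r, spec, external_tracks=tracks) for r in records
        ]

    # --- segment -----------------------------------------------------------
    with timed("segment"):
        profiles = [segment_idrs(t, config.segmentation) for t in all_tracks]
        tables["idr_segments"] = segments_table(profiles)
        tables["idr_profiles"] = profiles_table(profiles)

    # --- content summary ---------------------------------------------------
    with timed("content_summary"):
        if groups:
            summary = cohort_idr_summary(
                all_tracks, groups, config.segmentation,
                content_threshold_pct=config.thresholds.idr_content_min_pct,
            )
            rows = []
            for g, s in sorted(summary.items()):
                row = {
                    "group": g, "n": s.n,
                    "mean_content_pct": round(s.mean_content, 4),
                    "sd_content_pct": round(s.sd_content, 4),
                    "median_content_pct": round(s.median_content, 4),
                    "q1_content_pct": round(s.q1_content, 4),
                    "q3_content_pct": round(s.q3_content, 4),
                    "frac_content_ge_threshold": round(s.frac_content_ge_threshold, 4),
                }
                for ml, frac in sorted(s.frac_with_idr.items()):
                    row[f"frac_with_idr_{ml}"] = round(frac, 4)
                rows.append(row)
            tables["group_idr_summary"] = pd.DataFrame(rows)

    # --- composition -------------------------------------------------------
    with timed("composition"):
        rec_by_id = {r.id: r for r in records}
        glabels = groups or {r.id: "all" for r in records}
        report = idr_composition_report(profiles, rec_by_id, glabels)
        tables.update(report.tables())

    # --- LLPS classification -----------------------------------------------
    with timed("llps"):
        if propensities and groups:
            tables["llps_fraction_positive"] = fraction_positive(
                propensities, groups, config.thresholds
            )
        if membership_lists and groups:
            tables["llps_membership"] = membership_fraction(groups, membership_lists)

    # --- group statistics --------------------------------------------------
    with timed("group_stats"):
        if groups:
            contents: dict[str, list[float]] = {}
            prof_by_id = {p.protein_id: p for p in profiles}
            for pid, g in groups.items():
                g = g.value if isinstance(g, sio.GroupLabel) else str(g)
                contents.setdefault(g, []).append(prof_by_id[pid].idr_content_pct)
            eligible = {g: v for g, v in contents.items() if len(v) >= 2}
            if len(eligible) >= 2:
                tables["idr_content_stats"] = stats_report(eligible, alpha=config.alpha)
            box = summarize_groups(
                contents, threshold=config.thresholds.idr_content_min_pct
            )
            tables["idr_content_boxplot"] = pd.DataFrame(
                [
                    {
                        "group": b.group, "n": b.n, "mean": round(b.mean, 4),
                        "sd": round(b.sd, 4), "median": round(b.median, 4),
                        "q1": round(b.q1, 4), "q3": round(b.q3, 4),
                        "fraction_above_threshold": b.fraction_above_threshold,
                    }
                    for b in box
                ]
            )

    # --- write -------------------------------------------------------------
    with timed("write"):
        cfg = config.config_dict()
        manifest = sio.write_results(tables, config.out_dir, config=cfg)
        manifest["config_hash"] = _config_hash(cfg)
        manifest["stage_times_s"] = stage_times
        with open(Path(config.out_dir) / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
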