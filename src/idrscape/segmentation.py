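"""Segmentation of per-residue disorder tracks into IDRs.

An IDR is operationalized as a maximal stretch of at least ``min_len``
residues whose disorder score is >= ``threshold``, tolerating internal
sub-threshold runs ("gaps") of at most ``max_gap`` residues.  Segments
always begin and end on above-threshold residues — a tolerated gap never
dangles at an edge.  Each accepted segment carries the count of its
exceptional (sub-threshold) residues and a confidence score

    confidence = 1 - n_exceptional / length,

which is 1 exactly when the segment has no internal exceptional residue
and decreases for each one; confidence is reported, never used to filter.

Algorithm: mark residues >= threshold, take maximal above-threshold runs,
merge consecutive runs whenever the gap between them is <= max_gap
(transitively, left to right; merge eligibility depends only on gap
lengths, so the result is independent of scan direction), then keep merged
segments of length >= min_len.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import GroupLabel, ProteinRecord, ScoreTrack


@dataclass(frozen=True)
class SegmentationParams:
    threshold: float = 0.5
    min_len: int = 30
    max_gap: int = 10

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold < 1.0:
            raise ValueError(f"threshold must be in (0,1), got {self.threshold}")
        if self.min_len < 1:
            raise ValueError("min_len must be positive")
        if self.max_gap < 0:
            raise ValueError("max_gap must be non-negative")
        if self.min_len <= self.max_gap:
            raise ValueError("min_len must exceed max_gap")


@dataclass(frozen=True)
class IDRSegment:
    """One predicted IDR; coordinates are 1-based inclusive."""

    protein_id: str
    start: int
    end: int
    n_exceptional: int
    confidence: float

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass(frozen=True)
class IDRProfile:
    """All IDRs of one protein plus its disordered-residue content (%)."""

    protein_id: str
    protein_length: int
    segments: tuple[IDRSegment, ...] = field(default_factory=tuple)

    @property
    def idr_content_pct(self) -> float:
        return 100.0 * sum(s.length for s in self.segments) / self.protein_length


def _above_runs(above: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True, as 0-based half-open (start, stop) pairs."""
    runs = []
    n = len(above)
    i = 0
    while i < n:
        if above[i]:
            j = i
            while j < n and above[j]:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def segment_idrs(track: ScoreTrack, params: SegmentationParams) -> IDRProfile:
    """Segment one disorder track into IDRs (see module docstring)."""
    scores = np.asarray(track.scores, dtype=float)
    above = scores >= params.threshold
    runs = _above_runs(above)

    merged: list[tuple[int, int]] = []
    for start, stop in runs:
        if merged and start - merged[-1][1] <= params.max_gap:
            merged[-1] = (merged[-1][0], stop)
        else:
            merged.append((start, stop))

    segments = []
    for start, stop in merged:
        length = stop - start
        if length < params.min_len:
            continue
        n_exc = int((~above[start:stop]).sum())
        segments.append(
            IDRSegment(
                protein_id=track.protein_id,
                start=start + 1,
                end=stop,
                n_exceptional=n_exc,
                confidence=1.0 - n_exc / length,
            )
        )
    return IDRProfile(
        protein_id=track.protein_id,
        protein_length=len(scores),
        segments=tuple(segments),
    )


def has_idr(profile: IDRProfile, min_len: int) -> bool:
    """True iff the profile contains a segment of at least ``min_len`` residues."""
    return any(s.length >= min_len for s in profile.segments)


@dataclass(frozen=True)
class CohortGroupIDRSummary:
    """Per-group IDR prevalence and content statistics."""

    group: str
    n: int
    frac_with_idr: dict[int, float]  # min_len -> fraction of proteins
    mean_content: float
    sd_content: float
    median_content: float
    q1_content: float
    q3_content: float
    frac_content_ge_threshold: float
    content_threshold_pct: float


def cohort_idr_summary(
    tracks: list[ScoreTrack],
    groups: dict[str, GroupLabel | str],
    params: SegmentationParams = SegmentationParams(),
    min_len_variants: tuple[int, ...] = (20, 30, 40),
    content_threshold_pct: float = 25.0,
) -> dict[str, CohortGroupIDRSummary]:
    """Summarize IDR prevalence and content per protein group.

    IDR content uses ``params`` (default: the 30-residue definition);
    the fraction of proteins with at least one IDR is evaluated at each
    ``min_len_variants`` value by re-segmenting with that minimum length.
    Quartiles use linear interpolation between order statistics; SD uses
    the n-1 denominator (a single-protein group gets SD 0).
    """
    by_group: dict[str, list[ScoreTrack]] = {}
    for t in tracks:
        if t.protein_id not in groups:
            raise ValueError(f"protein {t.protein_id!r} has no group annotation")
        g = groups[t.protein_id]
        g = g.value if isinstance(g, GroupLabel) else str(g)
        by_group.setdefault(g, []).append(t)

    out: dict[str, CohortGroupIDRSummary] = {}
    for g, g_tracks in by_group.items():
        if not g_tracks:
            raise ValueError(f"group {g!r} is empty")
        contents = np.array(
            [segment_idrs(t, params).idr_content_pct for t in g_tracks]
        )
        frac_with = {}
        for ml in min_len_variants:
            p = SegmentationParams(
                threshold=params.threshold, min_len=ml, max_gap=params.max_gap
            )
            frac_with[ml] = float(
                np.mean([bool(segment_idrs(t, p).segments) for t in g_tracks])
            )
        sd = float(np.std(contents, ddof=1)) if len(contents) > 1 else 0.0
        q1, med, q3 = (
            float(np.quantile(contents, q, method="linear"))
            for q in (0.25, 0.5, 0.75)
        )
        out[g] = CohortGroupIDRSummary(
            group=g,
            n=len(g_tracks),
            frac_with_idr=frac_with,
            mean_content=float(np.mean(contents)),
            sd_content=sd,
            median_content=med,
            q1_content=q1,
            q3_content=q3,
            frac_content_ge_threshold=float(
                np.mean(contents >= content_threshold_pct)
            ),
            content_threshold_pct=content_threshold_pct,
        )
    return out


def segments_table(profiles: list[IDRProfile]) -> pd.DataFrame:
    rows = [
        (s.protein_id, s.start, s.end, s.length, s.n_exceptional,
         round(s.confidence, 6))
        for p in profiles
        for s in p.segments
    ]
    return pd.DataFrame(
        rows,
        columns=["protein_id", "start", "end", "length", "n_exceptional",
                 "confidence"],
    )


def profiles_table(profiles: list[IDRProfile]) -> pd.DataFrame:
    rows = [
        (p.protein_id, len(p.segments), round(p.idr_content_pct, 4))
        for p in profiles
    ]
    return pd.DataFrame(rows, columns=["protein_id", "n_segments", "idr_content_pct"])
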