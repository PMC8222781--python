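"""Synthetic interactome generator with known ground truth.

Emulates the statistical structure the analysis assumes: modular proteins
built from alternating folded-like and IDR blocks; IDR blocks with biased
low-complexity composition (Reader-like G/S/R/P-rich vs Enzyme-like
E/K/R/S-rich); disorder tracks that sit high (0.8) over planted IDRs and
low (0.2) elsewhere plus clipped Gaussian noise; and per-protein LLPS
propensity scores drawn so that configured fractions of each group exceed
the classification thresholds.

Default cohort conditions (group sizes 113 Readers / 93 Enzymes, IDR
content targets 48 +/- 25% vs 17 +/- 14% vs 29 +/- 26%, LLPS-positive
fractions 67/59% vs 31/17% vs 30/21%) mirror the reported characteristics
of the R-loop interactome subgroups, so that pipeline outputs on the
default cohort are directly comparable to those reference values.

Everything is reproducible: an identical CohortSpec (including seed)
yields byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .io import (
    STANDARD_AA,
    GroupLabel,
    PropensityMethod,
    PropensityRecord,
    ProteinRecord,
    ScoreTrack,
)

# Average amino-acid frequencies of well-folded globular proteins
# (approximate proteome background), used for folded-like blocks.
_FOLDED_FREQS = {
    "A": 8.25, "R": 5.53, "N": 4.06, "D": 5.45, "C": 1.38, "Q": 3.93,
    "E": 6.72, "G": 7.07, "H": 2.27, "I": 5.91, "L": 9.65, "K": 5.80,
    "M": 2.41, "F": 3.86, "P": 4.74, "S": 6.64, "T": 5.35, "W": 1.10,
    "Y": 2.92, "V": 6.86,
}


def _normalize(freqs: dict[str, float]) -> dict[str, float]:
    total = sum(freqs.values())
    return {aa: v / total for aa, v in freqs.items()}


def folded_composition() -> dict[str, float]:
    return _normalize(_FOLDED_FREQS)


def biased_composition(bias: dict[str, float]) -> dict[str, float]:
    """A composition placing the stated mass on ``bias`` residues and
    spreading the remainder uniformly over the other standard residues."""
    mass = sum(bias.values())
    if not 0.0 < mass < 1.0 + 1e-9:
        raise ValueError(f"bias mass {mass} must lie in (0, 1]")
    rest = [aa for aa in STANDARD_AA if aa not in bias]
    out = dict(bias)
    for aa in rest:
        out[aa] = (1.0 - mass) / len(rest)
    return _normalize(out)


#: Reader-like IDR composition: G/S/R/P carry 80% of the mass.
READER_IDR_BIAS = biased_composition({"G": 0.22, "S": 0.20, "R": 0.20, "P": 0.18})
#: Enzyme-like IDR composition: E/K/R/S carry 76% of the mass.
ENZYME_IDR_BIAS = biased_composition({"E": 0.22, "K": 0.20, "R": 0.18, "S": 0.16})
#: Combined-interactome IDR composition: midway blend of the two biases.
COMBINED_IDR_BIAS = _normalize(
    {aa: 0.5 * (READER_IDR_BIAS[aa] + ENZYME_IDR_BIAS[aa]) for aa in STANDARD_AA}
)


@dataclass(frozen=True)
class BlockSpec:
    """One building block of a modular protein."""

    kind: str  # "folded" | "idr"
    length: int
    composition: dict[str, float]
    track_mean: float | None = None  # defaults: folded 0.2, idr 0.8
    track_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("folded", "idr"):
            raise ValueError(f"unknown block kind {self.kind!r}")
        if self.length < 1:
            raise ValueError("block length must be positive")
        if abs(sum(self.composition.values()) - 1.0) > 1e-9:
            raise ValueError("block composition must sum to 1")
        if not set(self.composition) <= set(STANDARD_AA):
            raise ValueError("block composition over non-standard residues")

    @property
    def mean(self) -> float:
        if self.track_mean is not None:
            return self.track_mean
        return 0.8 if self.kind == "idr" else 0.2


@dataclass(frozen=True)
class GroupParams:
    """Per-group ground-truth targets for cohort generation."""

    idr_bias: dict[str, float]
    content_mean: float  # target IDR content, percent
    content_sd: float
    frac_catgranule_pos: float  # P(score >= 1.0)
    frac_pscore_pos: float  # P(score >= 2.5)
    domain_tags: tuple[str, ...] = ()


DEFAULT_GROUP_PARAMS: dict[str, GroupParams] = {
    "reader": GroupParams(
        idr_bias=READER_IDR_BIAS, content_mean=48.0, content_sd=25.0,
        frac_catgranule_pos=0.67, frac_pscore_pos=0.59,
        domain_tags=("KH", "RRM"),
    ),
    "enzyme": GroupParams(
        idr_bias=ENZYME_IDR_BIAS, content_mean=17.0, content_sd=14.0,
        frac_catgranule_pos=0.31, frac_pscore_pos=0.17,
        domain_tags=("helicase", "hydrolase"),
    ),
    "combined_only": GroupParams(
        idr_bias=COMBINED_IDR_BIAS, content_mean=29.0, content_sd=26.0,
        frac_catgranule_pos=0.30, frac_pscore_pos=0.21,
    ),
}


@dataclass(frozen=True)
class CohortSpec:
    n_readers: int = 113
    n_enzymes: int = 93
    n_combined_only: int = 0
    group_params: dict[str, GroupParams] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_PARAMS)
    )
    noise_sd: float = 0.05
    motif: str | None = None  # optional literal k-mer planted in IDR blocks
    motif_density: float = 0.0  # fraction of IDR residues covered by motif copies
    seed: int = 0


@dataclass
class CohortData:
    records: list[ProteinRecord]
    tracks: list[ScoreTrack]
    propensities: list[PropensityRecord]
    groups: dict[str, GroupLabel]
    ground_truth: dict[str, dict]


def generate_protein(
    blocks: list[BlockSpec], seed: int | np.random.Generator
) -> tuple[ProteinRecord, list[tuple[int, int]]]:
    """Concatenate blocks into one protein; residues are drawn i.i.d. from
    each block's composition.  Returns the record and the planted IDR
    intervals (1-based inclusive; adjacent IDR blocks merge into one)."""
    if not blocks:
        raise ValueError("blocks must be non-empty")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    seq_parts: list[str] = []
    intervals: list[tuple[int, int]] = []
    pos = 0
    for b in blocks:
        aas = sorted(b.composition)
        probs = np.array([b.composition[aa] for aa in aas])
        probs = probs / probs.sum()
        part = "".join(rng.choice(list(aas), size=b.length, p=probs))
        seq_parts.append(part)
        if b.kind == "idr":
            start, end = pos + 1, pos + b.length
            if intervals and intervals[-1][1] == start - 1:
                intervals[-1] = (intervals[-1][0], end)
            else:
                intervals.append((start, end))
        pos += b.length
    record = ProteinRecord(id="synthetic", sequence="".join(seq_parts))
    return record, intervals


def _plant_motif(
    seq: str, intervals: list[tuple[int, int]], motif: str, density: float,
    rng: np.random.Generator,
) -> str:
    """Overwrite random in-IDR positions with copies of ``motif`` until
    roughly ``density`` of IDR residues are motif residues."""
    chars = list(seq)
    m = len(motif)
    for start, end in intervals:
        length = end - start + 1
        if length < m:
            continue
        n_copies = int(round(density * length / m))
        starts = rng.choice(np.arange(start - 1, end - m + 1), size=n_copies)
        for s in sorted(starts):
            chars[s : s + m] = motif
    return "".join(chars)


def generate_score_track(
    record: ProteinRecord,
    ground_truth: list[tuple[int, int]],
    noise_sd: float,
    seed: int | np.random.Generator,
    idr_mean: float = 0.8,
    folded_mean: float = 0.2,
) -> ScoreTrack:
    """Piecewise-constant disorder track at the block means, plus clipped
    Gaussian noise of SD ``noise_sd``."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    means = np.full(len(record), folded_mean)
    for start, end in ground_truth:
        means[start - 1 : end] = idr_mean
    if noise_sd > 0:
        means = means + rng.normal(0.0, noise_sd, size=len(record))
    scores = np.clip(means, 0.0, 1.0)
    return ScoreTrack(
        protein_id=record.id,
        scores=tuple(float(x) for x in scores),
        mode="synthetic",
    )


def _architecture(
    length: int, target_content_pct: float, rng: np.random.Generator,
    idr_bias: dict[str, float],
) -> list[BlockSpec]:
    """Alternating folded/IDR blocks realizing the target IDR content."""
    folded = folded_composition()
    total_idr = int(round(target_content_pct / 100.0 * length))
    if total_idr < 20:
        return [BlockSpec("folded", length, folded)]
    total_folded = length - total_idr
    # two IDR blocks only when both they and the three folded spacers stay long
    n_idr = 2 if (total_idr >= 160 and total_folded >= 120) else 1
    if n_idr == 1:
        if total_folded == 0:
            return [BlockSpec("idr", total_idr, idr_bias)]
        left = int(rng.integers(0, total_folded + 1))
        right = total_folded - left
        blocks = []
        if left:
            blocks.append(BlockSpec("folded", left, folded))
        blocks.append(BlockSpec("idr", total_idr, idr_bias))
        if right:
            blocks.append(BlockSpec("folded", right, folded))
        return blocks
    idr_a = int(rng.integers(40, total_idr - 40 + 1))
    idr_b = total_idr - idr_a
    # keep the internal spacer >= 30 so planted IDRs stay separable
    spacer = int(rng.integers(30, max(31, total_folded - 1)))
    spacer = min(spacer, total_folded)
    left = int(rng.integers(0, total_folded - spacer + 1))
    right = total_folded - spacer - left
    blocks = []
    if left:
        blocks.append(BlockSpec("folded", left, folded))
    blocks.append(BlockSpec("idr", idr_a, idr_bias))
    blocks.append(BlockSpec("folded", spacer, folded))
    blocks.append(BlockSpec("idr", idr_b, idr_bias))
    if right:
        blocks.append(BlockSpec("folded", right, folded))
    return blocks


def _propensity_mu(threshold: float, sd: float, frac_positive: float) -> float:
    """Mean of a normal with given SD so that P(X >= threshold) = frac."""
    frac = min(max(frac_positive, 1e-6), 1 - 1e-6)
    return threshold - sd * sps.norm.ppf(1.0 - frac)


def generate_cohort(spec: CohortSpec) -> CohortData:
    """Generate a full annotated cohort with ground truth.

    Per-protein randomness is drawn from independent child streams of the
    cohort seed, so the cohort is reproducible as a whole.
    """
    ss = np.random.SeedSequence(spec.seed)
    rng = np.random.default_rng(ss)
    sizes = {
        "reader": spec.n_readers,
        "enzyme": spec.n_enzymes,
        "combined_only": spec.n_combined_only,
    }
    records: list[ProteinRecord] = []
    tracks: list[ScoreTrack] = []
    propensities: list[PropensityRecord] = []
    groups: dict[str, GroupLabel] = {}
    ground_truth: dict[str, dict] = {}

    cat_sd, ps_sd = 0.75, 1.5
    for group, n in sizes.items():
        gp = spec.group_params[group]
        mu_cat = _propensity_mu(1.0, cat_sd, gp.frac_catgranule_pos)
        mu_ps = _propensity_mu(2.5, ps_sd, gp.frac_pscore_pos)
        for i in range(n):
            pid = f"{group}_{i:04d}"
            length = int(np.clip(rng.lognormal(math.log(450.0), 0.35), 150, 2500))
            target = float(np.clip(rng.normal(gp.content_mean, gp.content_sd), 0.0, 95.0))
            blocks = _architecture(length, target, rng, gp.idr_bias)
            rec, intervals = generate_protein(blocks, rng)
            seq = rec.sequence
            if spec.motif and spec.motif_density > 0:
                seq = _plant_motif(seq, intervals, spec.motif, spec.motif_density, rng)
            tags = (
                frozenset([str(rng.choice(list(gp.domain_tags)))])
                if gp.domain_tags else frozenset()
            )
            rec = ProteinRecord(
                id=pid, sequence=seq, description=f"synthetic {group} protein",
                group_label=GroupLabel(group), domain_tags=tags,
            )
            records.append(rec)
            tracks.append(
                generate_score_track(rec, intervals, spec.noise_sd, rng)
            )
            propensities.append(
                PropensityRecord(pid, PropensityMethod.catgranule,
                                 float(rng.normal(mu_cat, cat_sd)))
            )
            propensities.append(
                PropensityRecord(pid, PropensityMethod.pscore,
                                 float(rng.normal(mu_ps, ps_sd)))
            )
            groups[pid] = GroupLabel(group)
            ground_truth[pid] = {
                "group": group,
                "intervals": intervals,
                "target_content_pct": 100.0 * sum(e - s + 1 for s, e in intervals) / length,
                "requested_content_pct": target,
            }
    return CohortData(
        records=records, tracks=tracks, propensities=propensities,
        groups=groups, ground_truth=ground_truth,
    )
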