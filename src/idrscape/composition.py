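"""Composition analytics over IDRs and arbitrary sub-regions.

Covers single-residue, dipeptide and tripeptide spectra (overlapping
windows, stride 1, never crossing region boundaries), a six-group reduced
amino-acid alphabet based on shared physico-chemical character, residue-set
shares for worked examples (e.g. the Arg/Gly share of an RGG box), and
reproducible top-k-mer rankings (ties broken lexicographically).

Reduced alphabet groups:
  1 aromatic (Y, W, F); 2 positively charged (R, K, H); 3 polar uncharged
  (N, Q); 4 negatively charged (D, E); 5 small/flexible (G, S, P, A, T, C);
  6 hydrophobic (I, L, V, M).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from .io import STANDARD_AA, GroupLabel, ProteinRecord
from .segmentation import IDRProfile

#: Default six-group reduced alphabet (residue -> group digit "1".."6").
DEFAULT_REDUCED_ALPHABET: dict[str, str] = {
    **{aa: "1" for aa in "YWF"},
    **{aa: "2" for aa in "RKH"},
    **{aa: "3" for aa in "NQ"},
    **{aa: "4" for aa in "DE"},
    **{aa: "5" for aa in "GSPATC"},
    **{aa: "6" for aa in "ILVM"},
}

AROMATIC_SET = frozenset("HFYW")


def validate_reduced_alphabet(mapping: dict[str, str]) -> None:
    """A reduced alphabet must partition exactly the 20 standard residues."""
    if set(mapping) != set(STANDARD_AA):
        raise ValueError("reduced alphabet must cover exactly the 20 standard residues")
    if not set(mapping.values()) <= set("123456"):
        raise ValueError("reduced alphabet groups must be digits 1..6")


@dataclass(frozen=True)
class RegionSpec:
    """A 1-based inclusive sub-region of one protein."""

    protein_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError(f"invalid region ({self.start}, {self.end})")

    def extract(self, record: ProteinRecord) -> str:
        if record.id != self.protein_id:
            raise ValueError(
                f"region is for {self.protein_id!r}, record is {record.id!r}"
            )
        if self.end > len(record):
            raise ValueError(
                f"region ({self.start}, {self.end}) out of bounds for "
                f"{record.id!r} of length {len(record)}"
            )
        return record.sequence[self.start - 1 : self.end]


@dataclass(frozen=True)
class KmerSpectrum:
    """Counts and frequencies of length-k words pooled over regions."""

    k: int
    counts: dict[str, int]
    alphabet: str = "standard"  # "standard" or "reduced"

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def frequencies(self) -> dict[str, float]:
        t = self.total
        if t == 0:
            return {}
        return {w: c / t for w, c in self.counts.items()}


def residue_set_share(
    record: ProteinRecord, region: RegionSpec, residues: set[str] | str
) -> float:
    """Percentage of region residues belonging to ``residues``.

    E.g. the Arg+Gly share of an RGG-box region.  Returned unrounded;
    report to one decimal.
    """
    residues = set(residues)
    if not residues <= set(STANDARD_AA):
        raise ValueError(f"non-standard residues in query set: {residues - set(STANDARD_AA)}")
    seq = region.extract(record)
    return 100.0 * sum(aa in residues for aa in seq) / len(seq)


def kmer_spectrum(
    regions: list[tuple[ProteinRecord, RegionSpec]],
    k: int,
    alphabet: str = "standard",
    reduced_map: dict[str, str] | None = None,
) -> KmerSpectrum:
    """Pooled k-mer spectrum over a set of sequence regions.

    Windows are overlapping with stride 1 and are counted within each region
    independently — no window ever spans a region boundary.  Regions shorter
    than k contribute zero windows.  With ``alphabet="reduced"`` each region
    is first translated through the six-group reduced alphabet.
    """
    if k not in (1, 2, 3):
        raise ValueError(f"k must be 1, 2 or 3, got {k}")
    if alphabet not in ("standard", "reduced"):
        raise ValueError(f"unknown alphabet {alphabet!r}")
    mapping = None
    if alphabet == "reduced":
        mapping = reduced_map or DEFAULT_REDUCED_ALPHABET
        validate_reduced_alphabet(mapping)
    counts: Counter[str] = Counter()
    for record, region in regions:
        seq = region.extract(record)
        if mapping is not None:
            seq = "".join(mapping.get(aa, "") for aa in seq)
        for i in range(len(seq) - k + 1):
            counts[seq[i : i + k]] += 1
    return KmerSpectrum(k=k, counts=dict(counts), alphabet=alphabet)


def top_kmers(spectrum: KmerSpectrum, n: int) -> list[tuple[str, float]]:
    """Top-n words by frequency; ties broken lexicographically (ascending)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    freqs = spectrum.frequencies
    ranked = sorted(freqs.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked[:n]


def group_pair_fraction(spectrum2: KmerSpectrum, groups: set[str | int]) -> float:
    """Percentage of reduced-alphabet 2-mers with both positions in ``groups``."""
    if spectrum2.k != 2 or spectrum2.alphabet != "reduced":
        raise ValueError("group_pair_fraction requires a reduced-alphabet 2-mer spectrum")
    gset = {str(g) for g in groups}
    if not gset <= set("123456"):
        raise ValueError(f"groups must be within 1..6, got {groups}")
    return 100.0 * sum(
        f for w, f in spectrum2.frequencies.items() if w[0] in gset and w[1] in gset
    )


def profile_regions(profile: IDRProfile) -> list[RegionSpec]:
    """The IDR segments of a profile as RegionSpecs."""
    return [RegionSpec(s.protein_id, s.start, s.end) for s in profile.segments]


@dataclass
class CompositionReport:
    """Per-group composition tables produced by :func:`idr_composition_report`."""

    spectra: dict[tuple[str, int, str], KmerSpectrum]  # (group, k, alphabet)
    per_idr_top3: pd.DataFrame
    group_residue_table: pd.DataFrame
    warnings: list[str] = field(default_factory=list)

    def tables(self) -> dict[str, pd.DataFrame]:
        rows = []
        for (group, k, alphabet), spec in sorted(self.spectra.items()):
            freqs = spec.frequencies
            for w in sorted(spec.counts):
                rows.append(
                    (group, k, alphabet, w, spec.counts[w], round(freqs[w], 6))
                )
        spectra_df = pd.DataFrame(
            rows, columns=["group", "k", "alphabet", "word", "count", "frequency"]
        )
        return {
            "idr_kmer_spectra": spectra_df,
            "idr_top3_residues": self.per_idr_top3,
            "group_residue_frequencies": self.group_residue_table,
        }


def idr_composition_report(
    profiles: list[IDRProfile],
    records: dict[str, ProteinRecord],
    groups: dict[str, GroupLabel | str],
) -> CompositionReport:
    """Pooled 1/2/3-mer spectra per group over all IDR segments, plus the
    per-IDR top-3 residues with their joint share and an aromatic-content
    column (share of H/F/Y/W).

    Pooling is residue-weighted: counts from all IDRs of a group are summed,
    so long IDRs contribute proportionally more.  Proteins without IDRs
    contribute nothing; a group with zero IDR residues yields a warning row.
    """
    by_group: dict[str, list[tuple[ProteinRecord, RegionSpec]]] = {}
    top3_rows = []
    for p in profiles:
        rec = records[p.protein_id]
        g = groups.get(p.protein_id)
        g = g.value if isinstance(g, GroupLabel) else str(g)
        by_group.setdefault(g, [])
        for region in profile_regions(p):
            by_group[g].append((rec, region))
            seq = region.extract(rec)
            counts = Counter(seq)
            top3 = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[:3]
            joint = 100.0 * sum(c for _, c in top3) / len(seq)
            aromatic = 100.0 * sum(aa in AROMATIC_SET for aa in seq) / len(seq)
            top3_rows.append(
                (
                    p.protein_id, g, region.start, region.end,
                    "".join(w for w, _ in top3), round(joint, 1),
                    round(aromatic, 1),
                )
            )

    warnings: list[str] = []
    spectra: dict[tuple[str, int, str], KmerSpectrum] = {}
    residue_rows = []
    for g, regions in sorted(by_group.items()):
        if not regions:
            warnings.append(f"group {g!r} has no IDR residues")
        for k in (1, 2, 3):
            spectra[(g, k, "standard")] = kmer_spectrum(regions, k, "standard")
        spectra[(g, 2, "reduced")] = kmer_spectrum(regions, 2, "reduced")
        freqs = spectra[(g, 1, "standard")].frequencies
        for aa in STANDARD_AA:
            residue_rows.append((g, aa, round(freqs.get(aa, 0.0), 6)))

    return CompositionReport(
        spectra=spectra,
        per_idr_top3=pd.DataFrame(
            top3_rows,
            columns=["protein_id", "group", "start", "end", "top3_residues",
                     "top3_joint_share_pct", "aromatic_share_pct"],
        ),
        group_residue_table=pd.DataFrame(
            residue_rows, columns=["group", "residue", "frequency"]
        ),
        warnings=warnings,
    )
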