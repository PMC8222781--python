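"""Reading and writing of sequences, disorder tracks, annotations and result tables.

All on-disk formats are plain text: FASTA for sequences, tab-separated
tables for per-residue score tracks / group annotations / LLPS propensity
scores, one-accession-per-line files for database membership lists, and
TSV + JSON-manifest output for every result table the pipeline writes.

Coordinates are 1-based and inclusive on both ends throughout the package.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: The 20 standard one-letter amino-acid codes.
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"

#: Codes accepted under the ``keep-as-unknown`` policy: they count toward
#: sequence length but belong to no composition class.
NON_STANDARD_AA = "XBZUOJ*"


class ResiduePolicy(str, Enum):
    """How to treat non-standard residue codes (X, B, Z, U, O, J, *)."""

    strip = "strip"
    reject = "reject"
    keep_as_unknown = "keep-as-unknown"


class GroupLabel(str, Enum):
    reader = "reader"
    enzyme = "enzyme"
    combined_only = "combined_only"


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence with optional group/domain annotations."""

    id: str
    sequence: str
    description: str = ""
    group_label: GroupLabel | None = None
    domain_tags: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if len(self.sequence) == 0:
            raise ValueError(f"record {self.id!r}: empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ScoreTrack:
    """Per-residue disorder scores in [0, 1], one per residue of a protein."""

    protein_id: str
    scores: tuple[float, ...]
    mode: str = ""  # free-text predictor metadata, e.g. "iupred2a-long"

    def __post_init__(self) -> None:
        for i, s in enumerate(self.scores, start=1):
            if not 0.0 <= s <= 1.0:
                raise ValueError(
                    f"track {self.protein_id!r}: score {s} at position {i} "
                    "outside [0, 1]"
                )

    def __len__(self) -> int:
        return len(self.scores)


class PropensityMethod(str, Enum):
    catgranule = "catgranule"
    pscore = "pscore"
    other = "other"


@dataclass(frozen=True)
class PropensityRecord:
    """One per-protein LLPS propensity score from one predictor."""

    protein_id: str
    method: PropensityMethod
    score: float


@dataclass(frozen=True)
class MembershipList:
    """A named set of protein ids (e.g. an LLPS-database membership list)."""

    name: str
    members: frozenset[str]


def _apply_policy(seq: str, policy: ResiduePolicy, rec_id: str) -> str:
    seq = seq.upper()
    cleaned = []
    for pos, aa in enumerate(seq, start=1):
        if aa in STANDARD_AA:
            cleaned.append(aa)
        elif aa in NON_STANDARD_AA:
            if policy is ResiduePolicy.reject:
                raise ValueError(
                    f"record {rec_id!r}: non-standard residue {aa!r} at "
                    f"position {pos} (policy=reject)"
                )
            if policy is ResiduePolicy.keep_as_unknown:
                cleaned.append(aa)
            else:
                logger.warning(
                    "record %r: stripped non-standard residue %r at position %d",
                    rec_id, aa, pos,
                )
        else:
            raise ValueError(
                f"record {rec_id!r}: invalid character {aa!r} at position {pos}"
            )
    return "".join(cleaned)


def read_fasta(
    path: str | Path,
    policy: ResiduePolicy | str = ResiduePolicy.strip,
) -> list[ProteinRecord]:
    """Read a FASTA file into :class:`ProteinRecord` objects.

    Ids are the first whitespace-delimited token of each header; sequences
    are upper-cased and non-standard residues handled per ``policy``.
    """
    policy = ResiduePolicy(policy)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        if entry.id in seen:
            raise ValueError(f"duplicate record id {entry.id!r}")
        seen.add(entry.id)
        seq = _apply_policy(str(entry.seq), policy, entry.id)
        records.append(
            ProteinRecord(id=entry.id, sequence=seq, description=entry.description)
        )
    if not records:
        raise ValueError(f"no records in {path}")
    return records


def write_fasta(records: list[ProteinRecord], path: str | Path) -> None:
    entries = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description or r.id)
        for r in records
    ]
    SeqIO.write(entries, str(path), "fasta")


def read_score_tracks(
    path: str | Path, records: list[ProteinRecord], mode: str = ""
) -> list[ScoreTrack]:
    """Read a TSV of (protein_id, position, score) into validated ScoreTracks.

    Positions must be contiguous 1..L for each protein and L must equal the
    length of the matching sequence; scores must lie in [0, 1].
    """
    by_id = {r.id: r for r in records}
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
    required = {"protein_id", "position", "score"}
    if not required.issubset(df.columns):
        raise ValueError(f"score track file must have columns {sorted(required)}")
    tracks: list[ScoreTrack] = []
    for pid, sub in df.groupby("protein_id", sort=False):
        if pid not in by_id:
            raise ValueError(f"track for unknown protein {pid!r}")
        expected_len = len(by_id[pid])
        sub = sub.sort_values("position")
        positions = sub["position"].to_numpy()
        if len(positions) != expected_len:
            raise ValueError(
                f"track {pid!r}: {len(positions)} positions for a "
                f"{expected_len}-residue sequence"
            )
        for i, p in enumerate(positions, start=1):
            if p != i:
                raise ValueError(f"track {pid!r}: missing or duplicate position {i}")
        scores = tuple(float(s) for s in sub["score"])
        for i, s in enumerate(scores, start=1):
            if not 0.0 <= s <= 1.0:
                raise ValueError(
                    f"track {pid!r}: score {s} at position {i} outside [0, 1]"
                )
        tracks.append(ScoreTrack(protein_id=str(pid), scores=scores, mode=mode))
    return tracks


def write_score_tracks(tracks: list[ScoreTrack], path: str | Path) -> None:
    rows = [
        (t.protein_id, i, s)
        for t in tracks
        for i, s in enumerate(t.scores, start=1)
    ]
    pd.DataFrame(rows, columns=["protein_id", "position", "score"]).to_csv(
        path, sep="\t", index=False
    )


def read_annotations(path: str | Path) -> dict[str, ProteinRecord]:
    """Read a TSV of (protein_id, group_label, domain_tags) annotations.

    Returns a mapping protein_id -> (group_label, domain_tags) packed as a
    dict of plain tuples for merging onto records via :func:`annotate`.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    out = {}
    for _, row in df.iterrows():
        tags = frozenset(t for t in row.get("domain_tags", "").split(";") if t)
        label = GroupLabel(row["group_label"]) if row["group_label"] else None
        out[row["protein_id"]] = (label, tags)
    return out


def annotate(
    records: list[ProteinRecord], annotations: dict
) -> list[ProteinRecord]:
    """Return records with group/domain annotations merged on by id."""
    out = []
    for r in records:
        if r.id in annotations:
            label, tags = annotations[r.id]
            r = ProteinRecord(
                id=r.id, sequence=r.sequence, description=r.description,
                group_label=label, domain_tags=tags,
            )
        out.append(r)
    return out


def read_propensities(path: str | Path) -> list[PropensityRecord]:
    """Read a TSV of (protein_id, method, score) LLPS propensity records."""
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
    seen = set()
    out = []
    for _, row in df.iterrows():
        key = (row["protein_id"], row["method"])
        if key in seen:
            raise ValueError(f"duplicate propensity record for {key}")
        seen.add(key)
        out.append(
            PropensityRecord(
                protein_id=str(row["protein_id"]),
                method=PropensityMethod(row["method"]),
                score=float(row["score"]),
            )
        )
    return out


def write_propensities(records: list[PropensityRecord], path: str | Path) -> None:
    pd.DataFrame(
        [(r.protein_id, r.method.value, r.score) for r in records],
        columns=["protein_id", "method", "score"],
    ).to_csv(path, sep="\t", index=False)


def read_membership_list(path: str | Path, name: str | None = None) -> MembershipList:
    """Read a one-id-per-line membership list; blank lines and # comments skipped."""
    p = Path(path)
    members = frozenset(
        line.strip()
        for line in p.read_text().splitlines()
        if line.strip() and not line.startswith("#")
    )
    return MembershipList(name=name or p.stem, members=members)


def write_results(
    tables: dict[str, pd.DataFrame],
    out_dir: str | Path,
    config: dict | None = None,
) -> dict:
    """Write each table as a TSV plus a JSON manifest; returns the manifest.

    Re-running with identical tables and config produces byte-identical
    files (pandas' default float repr is deterministic).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"tables": {}, "config": config or {}}
    for name in sorted(tables):
        df = tables[name]
        fname = f"{name}.tsv"
        fpath = out / fname
        df.to_csv(fpath, sep="\t", index=False)
        digest = hashlib.sha256(fpath.read_bytes()).hexdigest()
        manifest["tables"][name] = {
            "file": fname,
            "rows": int(len(df)),
            "sha256": digest,
        }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
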