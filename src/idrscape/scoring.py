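"""Per-residue disorder scoring behind one scorer contract.

Two score sources are supported: externally computed predictor tracks
(e.g. IUPRED2A output converted to the package's track TSV) and a bundled
deterministic scorer — a sliding-window mean of a per-residue
disorder-propensity table.  The bundled scorer is pipeline plumbing for
self-contained runs and tests; it does not reproduce any pairwise-energy
disorder predictor, so cohort-level disorder statistics obtained with it
are not comparable to ones computed from real predictor tracks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path

import numpy as np

from .io import STANDARD_AA, ProteinRecord, ScoreTrack

_TABLE_RESOURCE = "top_idp_scaled.tsv"


def load_propensity_table(path: str | Path | None = None) -> dict[str, float]:
    """Load a residue -> propensity table (TSV: residue, value in [0, 1]).

    With no path, loads the bundled TOP-IDP disorder-propensity scale
    rescaled linearly to [0, 1] (see docs/methods.md for the citation).
    """
    if path is None:
        text = (
            resources.files("idrscape.data").joinpath(_TABLE_RESOURCE).read_text()
        )
    else:
        text = Path(path).read_text()
    table: dict[str, float] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("residue"):
            continue
        aa, val = line.split("\t")
        table[aa] = float(val)
    missing = set(STANDARD_AA) - set(table)
    if missing:
        raise ValueError(f"propensity table missing residues {sorted(missing)}")
    for aa, v in table.items():
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"propensity for {aa} = {v} outside [0, 1]")
    return table


class ScorerKind(str, Enum):
    external_track = "external_track"
    bundled_propensity = "bundled_propensity"


@dataclass
class ScorerSpec:
    """Configuration of the disorder-score source.

    For the bundled scorer, ``window`` is the (odd) sliding-window width and
    ``propensity_table`` maps each of the 20 standard residues to [0, 1].
    """

    kind: ScorerKind = ScorerKind.bundled_propensity
    window: int = 21
    propensity_table: dict[str, float] = field(default_factory=load_propensity_table)

    def __post_init__(self) -> None:
        self.kind = ScorerKind(self.kind)
        if self.kind is ScorerKind.bundled_propensity:
            if self.window < 1 or self.window % 2 == 0:
                raise ValueError(f"window must be odd and positive, got {self.window}")
            missing = set(STANDARD_AA) - set(self.propensity_table)
            if missing:
                raise ValueError(f"propensity table missing {sorted(missing)}")


def score_disorder(
    record: ProteinRecord,
    spec: ScorerSpec,
    external_tracks: dict[str, ScoreTrack] | None = None,
) -> ScoreTrack:
    """Produce a per-residue disorder track for one protein.

    The bundled scorer assigns each residue the mean table propensity over a
    centred window of width ``spec.window``; windows are truncated at the
    termini (no padding with phantom residues).  The output depends only on
    the sequence and the spec, never on annotations.
    """
    if spec.kind is ScorerKind.external_track:
        if external_tracks is None or record.id not in external_tracks:
            raise ValueError(f"no external track available for {record.id!r}")
        track = external_tracks[record.id]
        if len(track) != len(record):
            raise ValueError(
                f"external track for {record.id!r} has length {len(track)}, "
                f"sequence has {len(record)}"
            )
        return track

    table = spec.propensity_table
    try:
        vals = np.array([table[aa] for aa in record.sequence], dtype=float)
    except KeyError as exc:
        raise ValueError(
            f"record {record.id!r}: residue {exc.args[0]!r} missing from "
            "propensity table"
        ) from None
    half = spec.window // 2
    n = len(vals)
    cumsum = np.concatenate([[0.0], np.cumsum(vals)])
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half, n - 1)
    means = (cumsum[hi + 1] - cumsum[lo]) / (hi - lo + 1)
    # numerical guard: window means of values in [0,1] stay in [0,1]
    means = np.clip(means, 0.0, 1.0)
    return ScoreTrack(
        protein_id=record.id,
        scores=tuple(float(x) for x in means),
        mode=f"bundled_propensity:w{spec.window}",
    )
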