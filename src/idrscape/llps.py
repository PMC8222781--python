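"""LLPS-propensity classification and membership-fraction statistics.

Proteins are called LLPS-positive when an external predictor score meets
its critical threshold (boundary inclusive): catGRANULE >= 1.0 or
PScore >= 2.5 by default, with a parallel 25% IDR-content criterion
handled by the segmentation summary.  The module also computes, per
protein group, the percentage of members found in curated LLPS-database
membership lists (per list, plus their union and the per-list maximum),
and a descriptive pi-contact composition statistic: the share of residues
whose side chains carry aromatic (Y, F, W, H), amide (Q, N), carboxyl
(E, D) or guanidinium (R) groups.  The pi-contact share is a composition
summary only — it is not a reimplementation of, or substitute for, the
PScore predictor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .composition import RegionSpec
from .io import GroupLabel, MembershipList, PropensityMethod, PropensityRecord, ProteinRecord

logger = logging.getLogger(__name__)

PI_CONTACT_SET = frozenset("YFWHQNEDR")


@dataclass(frozen=True)
class LLPSThresholds:
    catgranule_min: float = 1.0
    pscore_min: float = 2.5
    idr_content_min_pct: float = 25.0

    def for_method(self, method: PropensityMethod) -> float:
        if method is PropensityMethod.catgranule:
            return self.catgranule_min
        if method is PropensityMethod.pscore:
            return self.pscore_min
        raise ValueError(f"no threshold defined for method {method!r}")


def classify_llps(rec: PropensityRecord, th: LLPSThresholds = LLPSThresholds()) -> bool:
    """True iff the record's score meets its method's threshold (inclusive)."""
    return rec.score >= th.for_method(rec.method)


def fraction_positive(
    records: list[PropensityRecord],
    groups: dict[str, GroupLabel | str],
    th: LLPSThresholds = LLPSThresholds(),
) -> pd.DataFrame:
    """Percentage of LLPS-positive proteins per group and predictor.

    Proteins lacking a score for a method are excluded from that method's
    denominator (logged); a group with no scores at all for a method is an
    error.  Returns a tidy table (group, method, n_scored, n_positive, pct).
    """
    scored: dict[tuple[str, str], list[bool]] = {}
    group_names: set[str] = set()
    for pid, g in groups.items():
        g = g.value if isinstance(g, GroupLabel) else str(g)
        group_names.add(g)
    for rec in records:
        if rec.protein_id not in groups:
            raise ValueError(f"protein {rec.protein_id!r} has no group annotation")
        if rec.method is PropensityMethod.other:
            continue
        g = groups[rec.protein_id]
        g = g.value if isinstance(g, GroupLabel) else str(g)
        scored.setdefault((g, rec.method.value), []).append(classify_llps(rec, th))

    methods = sorted({m for (_, m) in scored})
    rows = []
    for g in sorted(group_names):
        for m in methods:
            calls = scored.get((g, m), [])
            if not calls:
                raise ValueError(f"group {g!r} has no {m} scores (empty denominator)")
            n_group_members = sum(
                1
                for pid, gl in groups.items()
                if (gl.value if isinstance(gl, GroupLabel) else str(gl)) == g
            )
            if len(calls) < n_group_members:
                logger.warning(
                    "group %s: %d/%d proteins lack a %s score; excluded from denominator",
                    g, n_group_members - len(calls), n_group_members, m,
                )
            rows.append(
                (g, m, len(calls), sum(calls), 100.0 * sum(calls) / len(calls))
            )
    return pd.DataFrame(
        rows, columns=["group", "method", "n_scored", "n_positive", "pct_positive"]
    )


def membership_fraction(
    groups: dict[str, GroupLabel | str],
    lists: list[MembershipList],
) -> pd.DataFrame:
    """Percentage of each group found in each membership list.

    Adds a ``union`` row (membership in any list) and a ``max`` row (the
    best single list) per group, covering the "up to X%" reading either way.
    """
    members_by_group: dict[str, set[str]] = {}
    for pid, g in groups.items():
        g = g.value if isinstance(g, GroupLabel) else str(g)
        members_by_group.setdefault(g, set()).add(pid)

    rows = []
    for g, gmembers in sorted(members_by_group.items()):
        per_list = []
        for ml in lists:
            pct = 100.0 * len(gmembers & ml.members) / len(gmembers)
            per_list.append(pct)
            rows.append((g, ml.name, round(pct, 4)))
        union = set().union(*(ml.members for ml in lists)) if lists else set()
        rows.append((g, "union", round(100.0 * len(gmembers & union) / len(gmembers), 4)))
        rows.append((g, "max", round(max(per_list, default=0.0), 4)))
    return pd.DataFrame(rows, columns=["group", "list", "pct_in_list"])


def pi_contact_fraction(
    record: ProteinRecord, region: RegionSpec | None = None
) -> float:
    """Share (%) of residues bearing pi-contact-capable side-chain groups."""
    if region is None:
        region = RegionSpec(record.id, 1, len(record))
    seq = region.extract(record)
    return 100.0 * sum(aa in PI_CONTACT_SET for aa in seq) / len(seq)
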