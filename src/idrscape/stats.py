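"""Group comparison: one-way ANOVA, Tukey-Kramer post-hoc, boxplot summaries.

The ANOVA F statistic is the classical between/within mean-square ratio;
the Tukey-Kramer statistic for groups i, j is

    q_ij = |mean_i - mean_j| / sqrt((MSW / 2) * (1/n_i + 1/n_j)),

with p-values from the studentized-range distribution with (k, df_within)
parameters (scipy's ``studentized_range``, numerical rather than table
lookup).  With equal group sizes this reduces to the classical Tukey HSD.
Groups of size one are excluded with a logged warning.  A large
variance-ratio between groups triggers a heteroscedasticity warning but
no correction — plain ANOVA is the contract.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p_value: float


@dataclass(frozen=True)
class PosthocResult:
    pair: tuple[str, str]
    mean_diff: float
    q_statistic: float
    p_value: float
    significant: bool


@dataclass(frozen=True)
class GroupSummary:
    group: str
    n: int
    mean: float
    sd: float
    median: float
    q1: float
    q3: float
    fraction_above_threshold: float | None = None
    sd_undefined: bool = False  # n = 1: SD reported as 0 with this flag set


def _validated(samples: dict[str, list[float]]) -> dict[str, np.ndarray]:
    usable = {}
    for name, vals in samples.items():
        arr = np.asarray(vals, dtype=float)
        if arr.size == 1:
            logger.warning("group %r has n=1; excluded from ANOVA", name)
            continue
        if arr.size == 0:
            raise ValueError(f"group {name!r} is empty")
        usable[name] = arr
    if len(usable) < 2:
        raise ValueError("ANOVA requires at least two groups with n >= 2")
    return usable


def one_way_anova(samples: dict[str, list[float]]) -> AnovaResult:
    """Classical one-way fixed-effects ANOVA across named groups."""
    groups = _validated(samples)
    arrs = list(groups.values())
    all_vals = np.concatenate(arrs)
    if np.ptp(all_vals) == 0:
        raise ValueError("zero total variance: all values identical across groups")
    grand = all_vals.mean()
    k = len(arrs)
    n_total = all_vals.size
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrs)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrs)
    df_b, df_w = k - 1, n_total - k
    ms_b = ss_between / df_b
    ms_w = ss_within / df_w
    if ms_w == 0:
        # all within-group variance zero but groups differ: F diverges
        return AnovaResult(F=math.inf, df_between=df_b, df_within=df_w, p_value=0.0)
    F = ms_b / ms_w
    p = float(sps.f.sf(F, df_b, df_w))
    return AnovaResult(F=float(F), df_between=df_b, df_within=df_w, p_value=p)


def tukey_kramer(
    samples: dict[str, list[float]], alpha: float = 0.05
) -> list[PosthocResult]:
    """Tukey-Kramer all-pairs comparison (unequal n allowed)."""
    groups = _validated(samples)
    names = list(groups)
    arrs = [groups[n] for n in names]
    k = len(arrs)
    df_w = sum(a.size for a in arrs) - k
    ms_w = sum(((a - a.mean()) ** 2).sum() for a in arrs) / df_w
    variances = [a.var(ddof=1) for a in arrs]
    if min(variances) > 0 and max(variances) / min(variances) > 10:
        logger.warning(
            "group variance ratio %.1f > 10; ANOVA assumptions may be violated",
            max(variances) / min(variances),
        )
    results = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = arrs[i], arrs[j]
            diff = a.mean() - b.mean()
            se = math.sqrt((ms_w / 2.0) * (1.0 / a.size + 1.0 / b.size))
            if se == 0:
                q = 0.0 if diff == 0 else math.inf
            else:
                q = abs(diff) / se
            p = float(sps.studentized_range.sf(q, k, df_w)) if math.isfinite(q) else 0.0
            p = min(max(p, 0.0), 1.0)
            results.append(
                PosthocResult(
                    pair=(names[i], names[j]),
                    mean_diff=float(diff),
                    q_statistic=float(q),
                    p_value=p,
                    significant=bool(p < alpha),
                )
            )
    return results


def summarize_groups(
    values: dict[str, list[float]], threshold: float | None = None
) -> list[GroupSummary]:
    """Boxplot-style summaries: mean, sample SD, quartiles by linear
    interpolation, and (optionally) the fraction above ``threshold``."""
    out = []
    for name in sorted(values):
        arr = np.asarray(values[name], dtype=float)
        if arr.size == 0:
            raise ValueError(f"group {name!r} is empty")
        sd_undef = arr.size == 1
        if sd_undef:
            logger.warning("group %r has n=1; SD reported as 0", name)
        q1, med, q3 = (
            float(np.quantile(arr, q, method="linear")) for q in (0.25, 0.5, 0.75)
        )
        out.append(
            GroupSummary(
                group=name,
                n=int(arr.size),
                mean=float(arr.mean()),
                sd=0.0 if sd_undef else float(arr.std(ddof=1)),
                median=med,
                q1=q1,
                q3=q3,
                fraction_above_threshold=(
                    None if threshold is None else float(np.mean(arr > threshold))
                ),
                sd_undefined=sd_undef,
            )
        )
    return out


def stats_report(
    samples: dict[str, list[float]], alpha: float = 0.05
) -> pd.DataFrame:
    """ANOVA + Tukey-Kramer as one tidy report table."""
    anova = one_way_anova(samples)
    rows = [
        (
            "anova", "|".join(sorted(samples)), round(anova.F, 6),
            f"{anova.df_between},{anova.df_within}",
            anova.p_value, bool(anova.p_value < alpha),
        )
    ]
    for r in tukey_kramer(samples, alpha=alpha):
        rows.append(
            (
                "tukey_kramer", f"{r.pair[0]}|{r.pair[1]}",
                round(r.q_statistic, 6), "", r.p_value, r.significant,
            )
        )
    return pd.DataFrame(
        rows, columns=["test", "groups", "statistic", "df", "p", "significant"]
    )
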