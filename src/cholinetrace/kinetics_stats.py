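"""Time-course contrasts and group statistics.

Pairs of groups are compared with a two-tailed t test; families of
three time points with Tukey's range (HSD) test, with a Bonferroni
multiplication across the number of analyte families tested.  Since
published summaries print only mean ± SE and N, a summary-statistics
mode approximates the two-sample comparison with Welch's t computed
from the SEs; it is flagged as approximate in the output.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.libqsturng import psturng

from .core_io import ValidationError

__all__ = [
    "GroupSummary",
    "percent_change",
    "fold_ratio",
    "subgroup_profile",
    "profile_distance",
    "compare_groups",
    "compare_summaries",
    "normality_screen",
]

ALPHA = 0.05


@dataclass(frozen=True)
class GroupSummary:
    """Printed summary of one group: mean ± SE of n animals."""

    label: str
    n: int
    mean: float
    se: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValidationError(f"{self.label}: n must be ≥ 2 for inference")
        if self.se < 0:
            raise ValidationError(f"{self.label}: SE must be non-negative")

    @property
    def sd(self) -> float:
        return self.se * np.sqrt(self.n)


def percent_change(pool_t1: float, pool_t2: float) -> float:
    """Percent change between two pools: ``100·(t2 − t1)/t1``."""
    if pool_t1 <= 0:
        raise ValidationError("initial pool must be positive")
    return 100.0 * (pool_t2 - pool_t1) / pool_t1


def fold_ratio(a: float, b: float) -> float:
    """Plain ratio ``a / b`` (consistent with percent_change via
    ``fold = 1 + pct/100``)."""
    if b <= 0:
        raise ValidationError("denominator must be positive")
    return a / b


def subgroup_profile(amounts: dict) -> dict:
    """Normalize sub-group amounts to fractions of their total."""
    total = sum(amounts.values())
    if total <= 0:
        raise ValidationError("sub-group amounts must sum to > 0")
    if any(v < 0 for v in amounts.values()):
        raise ValidationError("sub-group amounts must be non-negative")
    return {k: v / total for k, v in amounts.items()}


def profile_distance(observed: dict, equilibrium: dict) -> dict:
    """Per-sub-group deviation of an observed profile from equilibrium.

    Both inputs are fraction profiles over the same sub-groups (as
    from :func:`subgroup_profile`).  Returns the signed deviation per
    sub-group and the total absolute deviation, which decreases in
    time as newly made PC remodels toward the organ's equilibrium
    composition.
    """
    if set(observed) != set(equilibrium):
        raise ValidationError("profiles cover different sub-groups")
    dev = {k: observed[k] - equilibrium[k] for k in observed}
    return {"deviation": dev,
            "total_abs": float(sum(abs(v) for v in dev.values()))}


def _check_groups(groups: Sequence[np.ndarray]) -> list[np.ndarray]:
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2:
        raise ValidationError("need at least two groups")
    for i, g in enumerate(arrs):
        if g.size < 2:
            raise ValidationError(f"group {i}: n must be ≥ 2")
    return arrs


def compare_groups(groups: Sequence[Sequence[float]],
                   labels: Sequence[str] | None = None,
                   n_families: int = 1) -> list[dict]:
    """Pairwise comparisons of raw per-animal vectors.

    Two groups: two-tailed Welch t test.  Three or more: Tukey's HSD
    within the family (studentized-range distribution with a pooled
    variance).  Raw p-values are then Bonferroni-multiplied by
    ``n_families`` — the number of analyte families in the whole
    analysis — and capped at 1.

    Returns a list of dicts with ``pair``, ``p_raw``, ``p_adj`` and
    ``significant`` (p_adj < 0.05).
    """
    arrs = _check_groups(groups)
    if labels is None:
        labels = [f"group{i}" for i in range(len(arrs))]
    if n_families < 1:
        raise ValidationError("n_families must be ≥ 1")
    results = []
    if len(arrs) == 2:
        t, p = stats.ttest_ind(arrs[0], arrs[1], equal_var=False)
        results.append({"pair": (labels[0], labels[1]),
                        "statistic": float(t), "p_raw": float(p)})
    else:
        k = len(arrs)
        ns = np.array([g.size for g in arrs])
        means = np.array([g.mean() for g in arrs])
        df = int(ns.sum() - k)
        sse = sum(((g - g.mean()) ** 2).sum() for g in arrs)
        ms_within = sse / df
        for i, j in combinations(range(k), 2):
            se = np.sqrt(ms_within / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
            q = abs(means[i] - means[j]) / se
            p = float(np.atleast_1d(psturng(q, k, df))[0])
            results.append({"pair": (labels[i], labels[j]),
                            "statistic": float(q), "p_raw": p})
    for r in results:
        r["p_adj"] = min(1.0, r["p_raw"] * n_families)
        r["significant"] = r["p_adj"] < ALPHA
    return results


def compare_summaries(a: GroupSummary, b: GroupSummary,
                      n_families: int = 1) -> dict:
    """Welch t test from printed mean ± SE summaries (approximate).

    The squared SEs estimate the per-group variance of the mean
    directly; degrees of freedom follow the Welch–Satterthwaite
    formula.  Flagged ``approximate`` because only summaries, not
    animal-level values, enter.
    """
    se2a, se2b = a.se ** 2, b.se ** 2
    if se2a + se2b == 0:
        raise ValidationError("both SEs are zero; no variance information")
    t = (a.mean - b.mean) / np.sqrt(se2a + se2b)
    df = (se2a + se2b) ** 2 / (
        se2a ** 2 / (a.n - 1) + se2b ** 2 / (b.n - 1))
    p_raw = float(2.0 * stats.t.sf(abs(t), df))
    p_adj = min(1.0, p_raw * max(1, n_families))
    return {"pair": (a.label, b.label), "statistic": float(t),
            "df": float(df), "p_raw": p_raw, "p_adj": p_adj,
            "significant": p_adj < ALPHA, "approximate": True}


def normality_screen(values: Sequence[float]) -> dict:
    """Advisory omnibus (skewness/kurtosis) normality screen.

    Returns ``status`` ``"pass"``/``"fail"`` at the 0.05 level, or
    ``"insufficient n"`` below 8 observations.  Advisory only: it does
    not gate any downstream analysis.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 8:
        return {"status": "insufficient n", "n": int(x.size),
                "statistic": float("nan"), "p": float("nan")}
    k2, p = stats.normaltest(x)
    return {"status": "pass" if p >= ALPHA else "fail", "n": int(x.size),
            "statistic": float(k2), "p": float(p)}
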