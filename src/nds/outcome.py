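"""Outcome-association tests for NDS cohorts.

The battery mirrors how a clinical reliability study relates an ordinal
disability score to outcomes: Kruskal-Wallis across the good/fair/poor
outcome classes, Mann-Whitney for two-group contrasts (survival to
discharge, relapse, response to rescue treatment), Pearson correlation for
NDS total against days in intensive care, and Monte-Carlo power estimation
for location-shift alternatives.

Rank statistics use midranks with tie-corrected variances (NDS totals are
small integers, so ties are certain). Small samples get exact p-values by
full enumeration of group assignments; larger ones use the chi-square /
normal approximations, with Monte-Carlo permutation available throughout.
All tests are two-sided.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Dict, Literal, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, model_validator
from scipy import stats

__all__ = [
    "TestResult",
    "OutcomeRecord",
    "PowerEstimate",
    "kruskal_wallis",
    "mann_whitney",
    "pearson_correlation",
    "simulate_power",
    "outcome_battery",
]

Method = Literal["auto", "asymptotic", "exact", "permutation"]

#: Largest pooled sample for which "auto" switches to full enumeration.
EXACT_ENUMERATION_LIMIT_KW = 12
EXACT_ENUMERATION_LIMIT_MW = 20


@dataclass
class TestResult:
    statistic_name: str
    statistic_value: float
    p_value: float
    method: str
    n_per_group: Tuple[int, ...]
    details: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value out of [0, 1]: {self.p_value}")


class OutcomeRecord(BaseModel):
    """Outcome data for one dog: NDS at presentation plus follow-up status."""

    model_config = ConfigDict(extra="forbid")

    subject_id: str
    nds_total: int
    outcome_class: Optional[Literal["good", "fair", "poor"]] = None
    survived_to_discharge: bool = True
    relapsed: bool = False
    time_to_relapse_months: Optional[float] = None
    responded_at_relapse: Optional[bool] = None
    icu_days: float = 0.0

    @model_validator(mode="after")
    def _check(self) -> "OutcomeRecord":
        if not 0 <= self.nds_total <= 21:
            raise ValueError("nds_total must be in 0..21")
        if self.relapsed != (self.time_to_relapse_months is not None):
            raise ValueError("time_to_relapse_months must be present iff relapsed")
        if self.time_to_relapse_months is not None and self.time_to_relapse_months < 0:
            raise ValueError("time_to_relapse_months must be nonnegative")
        if self.icu_days < 0:
            raise ValueError("icu_days must be nonnegative")
        return self


def _kw_h(pooled: np.ndarray, sizes: Sequence[int]) -> float:
    """Tie-corrected Kruskal-Wallis H for pooled values split by group sizes."""
    n = len(pooled)
    ranks = stats.rankdata(pooled)
    h = 0.0
    start = 0
    for size in sizes:
        r = ranks[start : start + size].sum()
        h += r * r / size
        start += size
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - float(((counts**3 - counts).sum())) / (n**3 - n)
    if correction == 0.0:  # all values identical
        return 0.0
    return h / correction


def _group_assignments(n: int, sizes: Sequence[int]):
    """Yield index tuples partitioning range(n) into groups of the given sizes."""
    if len(sizes) == 1:
        yield (tuple(range(n)),)
        return
    indices = list(range(n))

    def rec(remaining: Tuple[int, ...], sizes_left: Sequence[int]):
        if len(sizes_left) == 1:
            yield (remaining,)
            return
        first, rest_sizes = sizes_left[0], sizes_left[1:]
        for combo in itertools.combinations(remaining, first):
            chosen = set(combo)
            rest = tuple(i for i in remaining if i not in chosen)
            for tail in rec(rest, rest_sizes):
                yield (combo,) + tail

    yield from rec(tuple(indices), sizes)


def kruskal_wallis(
    groups: Sequence[Sequence[float]],
    method: Method = "auto",
    n_perm: int = 10_000,
    seed: Optional[int] = None,
) -> TestResult:
    """Kruskal-Wallis rank test across two or more groups.

    The H statistic uses midranks and the standard tie correction. The
    p-value comes from the chi-square approximation with ``len(groups) - 1``
    degrees of freedom, from full enumeration of group assignments when the
    pooled sample is small (n <= 12 under ``auto``), or from Monte-Carlo
    permutation.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(a) == 0 for a in arrays):
        raise ValueError("every group must be nonempty")
    sizes = tuple(len(a) for a in arrays)
    pooled = np.concatenate(arrays)
    n = len(pooled)
    if n < 3:
        raise ValueError("need at least 3 observations in total")
    h_obs = _kw_h(pooled, sizes)
    details = {"df": float(len(groups) - 1)}

    if np.all(pooled == pooled[0]):
        return TestResult("kruskal_wallis_H", 0.0, 1.0, "degenerate", sizes, details)

    if method == "auto":
        method = "exact" if n <= EXACT_ENUMERATION_LIMIT_KW else "asymptotic"

    if method == "asymptotic":
        p = float(stats.chi2.sf(h_obs, len(groups) - 1))
    elif method == "exact":
        total = 0
        extreme = 0
        for assignment in _group_assignments(n, sizes):
            perm = np.concatenate([pooled[list(idx)] for idx in assignment])
            total += 1
            if _kw_h(perm, sizes) >= h_obs - 1e-12:
                extreme += 1
        p = extreme / total
        details["n_assignments"] = float(total)
    elif method == "permutation":
        rng = np.random.default_rng(seed)
        extreme = 0
        work = pooled.copy()
        for _ in range(n_perm):
            rng.shuffle(work)
            if _kw_h(work, sizes) >= h_obs - 1e-12:
                extreme += 1
        p = (extreme + 1) / (n_perm + 1)
        details["n_perm"] = float(n_perm)
    else:
        raise ValueError(f"unknown method {method!r}")
    return TestResult("kruskal_wallis_H", float(h_obs), p, method, sizes, details)


def _mw_u(a: np.ndarray, b: np.ndarray) -> float:
    """U for sample a: number of (a_i, b_j) pairs with a_i > b_j plus half-ties."""
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    r_a = ranks[: len(a)].sum()
    return float(r_a - len(a) * (len(a) + 1) / 2.0)


def mann_whitney(
    a: Sequence[float],
    b: Sequence[float],
    method: Method = "auto",
    use_continuity: bool = True,
    n_perm: int = 10_000,
    seed: Optional[int] = None,
) -> TestResult:
    """Two-sided Mann-Whitney U test.

    U counts pairs where the first sample exceeds the second, ties counted as
    half. Under ``auto`` the p-value is exact (full enumeration of the
    ``C(n_a + n_b, n_a)`` group assignments) for pooled n <= 20 without ties,
    and otherwise uses the tie-corrected normal approximation with continuity
    correction. Exactness under ties, or Monte-Carlo permutation, can be
    requested explicitly.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be nonempty")
    n1, n2 = len(a), len(b)
    n = n1 + n2
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < n
    u_obs = _mw_u(a, b)
    mean_u = n1 * n2 / 2.0
    details: Dict[str, float] = {"U_other": n1 * n2 - u_obs}

    if method == "auto":
        method = (
            "exact" if (n <= EXACT_ENUMERATION_LIMIT_MW and not has_ties) else "asymptotic"
        )

    if method == "exact":
        total = 0
        extreme = 0
        dev_obs = abs(u_obs - mean_u)
        for combo in itertools.combinations(range(n), n1):
            chosen = set(combo)
            perm_a = pooled[list(combo)]
            perm_b = pooled[[i for i in range(n) if i not in chosen]]
            total += 1
            if abs(_mw_u(perm_a, perm_b) - mean_u) >= dev_obs - 1e-12:
                extreme += 1
        p = extreme / total
        details["n_assignments"] = float(total)
    elif method == "asymptotic":
        _, counts = np.unique(pooled, return_counts=True)
        tie_term = float((counts**3 - counts).sum()) / (n * (n - 1))
        var_u = n1 * n2 / 12.0 * ((n + 1) - tie_term)
        if var_u == 0.0:
            return TestResult("mann_whitney_U", u_obs, 1.0, "degenerate", (n1, n2), details)
        dev = abs(u_obs - mean_u)
        if use_continuity:
            dev = max(dev - 0.5, 0.0)
        z = dev / math.sqrt(var_u)
        p = float(min(2.0 * stats.norm.sf(z), 1.0))
        details["z"] = z
    elif method == "permutation":
        rng = np.random.default_rng(seed)
        dev_obs = abs(u_obs - mean_u)
        extreme = 0
        work = pooled.copy()
        for _ in range(n_perm):
            rng.shuffle(work)
            if abs(_mw_u(work[:n1], work[n1:]) - mean_u) >= dev_obs - 1e-12:
                extreme += 1
        p = (extreme + 1) / (n_perm + 1)
        details["n_perm"] = float(n_perm)
    else:
        raise ValueError(f"unknown method {method!r}")
    return TestResult("mann_whitney_U", u_obs, p, method, (n1, n2), details)


def pearson_correlation(
    x: Sequence[float],
    y: Sequence[float],
    method: Literal["asymptotic", "permutation"] = "asymptotic",
    n_perm: int = 10_000,
    seed: Optional[int] = None,
) -> TestResult:
    """Pearson product-moment correlation with a two-sided p-value.

    The asymptotic p-value uses the t-transform ``t = r sqrt((n-2)/(1-r^2))``
    on n - 2 degrees of freedom; permutation shuffles the pairing.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("samples must have equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        raise ValueError("correlation undefined: a sample has zero variance")
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(min(r, 1.0), -1.0)
    if method == "asymptotic":
        if abs(r) == 1.0:
            p = 0.0
        else:
            t = r * math.sqrt((n - 2) / (1.0 - r * r))
            p = float(min(2.0 * stats.t.sf(abs(t), n - 2), 1.0))
    elif method == "permutation":
        rng = np.random.default_rng(seed)
        extreme = 0
        work = y.copy()
        for _ in range(n_perm):
            rng.shuffle(work)
            if abs(float(np.corrcoef(x, work)[0, 1])) >= abs(r) - 1e-12:
                extreme += 1
        p = (extreme + 1) / (n_perm + 1)
    else:
        raise ValueError(f"unknown method {method!r}")
    return TestResult("pearson_r", r, p, method, (n,))


@dataclass
class PowerEstimate:
    power: float
    ci_low: float
    ci_high: float
    alpha: float
    reps: int
    n_per_group: Tuple[int, ...]


def simulate_power(
    shifts: Sequence[float],
    n_per_group: int,
    alpha: float = 0.05,
    test: Literal["kruskal_wallis", "mann_whitney"] = "kruskal_wallis",
    reps: int = 1000,
    seed: Optional[int] = None,
    sd: float = 1.0,
) -> PowerEstimate:
    """Monte-Carlo power of a rank test against normal location shifts.

    Each replicate draws ``n_per_group`` observations per group from
    ``Normal(shift_g, sd)`` and applies the asymptotic test at level
    ``alpha``; power is the rejection fraction, with a Wilson score CI for
    the Monte-Carlo uncertainty. With all shifts equal this estimates the
    realized type-I error, which should sit at the nominal level.
    """
    if reps < 100:
        raise ValueError("use at least 100 replicates")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    shifts = list(shifts)
    if test == "mann_whitney" and len(shifts) != 2:
        raise ValueError("mann_whitney power needs exactly 2 groups")
    if len(shifts) < 2:
        raise ValueError("need at least 2 groups")
    if sd <= 0:
        raise ValueError("sd must be positive")
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(reps):
        groups = [rng.normal(mu, sd, size=n_per_group) for mu in shifts]
        if test == "kruskal_wallis":
            res = kruskal_wallis(groups, method="asymptotic")
        else:
            res = mann_whitney(groups[0], groups[1], method="asymptotic")
        if res.p_value < alpha:
            rejections += 1
    power = rejections / reps
    z = stats.norm.ppf(0.975)
    denom = 1.0 + z * z / reps
    centre = (power + z * z / (2 * reps)) / denom
    half = z * math.sqrt(power * (1 - power) / reps + z * z / (4 * reps**2)) / denom
    return PowerEstimate(
        power, max(centre - half, 0.0), min(centre + half, 1.0),
        alpha, reps, (n_per_group,) * len(shifts),
    )


def outcome_battery(table: pd.DataFrame) -> Dict[str, TestResult]:
    """Run the outcome-association battery on a cohort outcome table.

    Expects columns ``nds_total``, ``outcome_class``, ``survived_to_discharge``,
    ``relapsed``, ``time_to_relapse_months``, ``responded_at_relapse`` and
    ``icu_days`` (missing analyses are skipped when their columns or groups
    are absent). Returns a mapping of analysis name to :class:`TestResult`:
    NDS vs outcome class (Kruskal-Wallis), NDS vs survival to discharge and
    vs relapse (Mann-Whitney), time-to-relapse vs response to rescue
    treatment (Mann-Whitney), and NDS vs ICU days (Pearson).
    """
    results: Dict[str, TestResult] = {}
    df = table

    if "outcome_class" in df:
        sub = df.dropna(subset=["outcome_class"])
        groups = [
            sub.loc[sub.outcome_class == c, "nds_total"].to_numpy()
            for c in ("good", "fair", "poor")
            if (sub.outcome_class == c).any()
        ]
        if len(groups) >= 2:
            results["nds_vs_outcome"] = kruskal_wallis(groups)

    def two_group(col: str, value_col: str = "nds_total") -> Optional[TestResult]:
        if col not in df:
            return None
        sub = df.dropna(subset=[col, value_col])
        yes = sub.loc[sub[col].astype(bool), value_col].to_numpy()
        no = sub.loc[~sub[col].astype(bool), value_col].to_numpy()
        if len(yes) == 0 or len(no) == 0:
            return None
        return mann_whitney(yes, no)

    for name, col in (
        ("nds_vs_survival", "survived_to_discharge"),
        ("nds_vs_relapse", "relapsed"),
    ):
        res = two_group(col)
        if res is not None:
            results[name] = res

    if {"responded_at_relapse", "time_to_relapse_months"} <= set(df.columns):
        res = two_group("responded_at_relapse", "time_to_relapse_months")
        if res is not None:
            results["relapse_time_vs_response"] = res

    if "icu_days" in df:
        sub = df.dropna(subset=["icu_days"])
        if len(sub) >= 3 and sub.nds_total.std() > 0 and sub.icu_days.std() > 0:
            results["nds_vs_icu_days"] = pearson_correlation(
                sub.nds_total.to_numpy(), sub.icu_days.to_numpy()
            )
    return results
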