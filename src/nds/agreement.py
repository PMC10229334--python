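"""Inter-rater agreement statistics for NDS ratings.

Implements, from their defining formulas:

* **Cohen's kappa** for binary (absent/present) items,
  ``kappa = (p_o - p_e) / (1 - p_e)`` with ``p_o`` the observed proportion of
  agreement and ``p_e`` the chance agreement from the margins;
* **weighted kappa** for the ordinal 0-3 category ratings,
  ``kappa_w = 1 - sum(w_ij o_ij) / sum(w_ij e_ij)`` with disagreement weights
  ``w_ij = |i-j|/(L-1)`` (linear) or ``((i-j)/(L-1))^2`` (quadratic); the
  ``identity`` scheme reproduces unweighted kappa exactly;
* the **intraclass correlation coefficient** for total scores, two-way
  random-effects, absolute agreement (McGraw & Wong forms A-1 and A-k), from
  the two-way ANOVA mean squares with F-based confidence intervals.

Kappa confidence intervals use the Fleiss-Cohen-Everitt large-sample
variance (normal CI), with a seeded multinomial bootstrap alternative for
small samples. Estimates are reported as computed — negative values are not
truncated at zero — and every result carries its variance components for
audit.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Dict, Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RatingMatrix",
    "AgreementResult",
    "UndefinedStatisticError",
    "contingency_from_pairs",
    "cohen_kappa",
    "weighted_kappa",
    "icc_absolute_agreement",
    "interpret_agreement",
]

WeightScheme = Literal["linear", "quadratic", "identity"]


class UndefinedStatisticError(ValueError):
    """An agreement statistic is undefined for the given data (e.g. chance
    agreement of 1, or a rating matrix with zero total variance)."""


@dataclass
class RatingMatrix:
    """Subjects x raters table of ordinal ratings or total scores.

    Missing cells are NaN; statistics that need complete rows (the ICC) drop
    subjects listwise and report the effective n.
    """

    subjects: list
    raters: list
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D subjects x raters table")
        n, k = self.values.shape
        if n != len(self.subjects) or k != len(self.raters):
            raise ValueError("values shape must match subjects x raters labels")
        if k < 2:
            raise ValueError("at least 2 raters required")
        finite_or_nan = np.isfinite(self.values) | np.isnan(self.values)
        if not finite_or_nan.all():
            raise ValueError("ratings must be finite numbers or missing (NaN)")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_raters(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "RatingMatrix":
        """Build from a DataFrame indexed by subject with one column per rater."""
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=float))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.subjects, columns=self.raters)

    def complete_cases(self) -> "RatingMatrix":
        """Listwise-deleted copy keeping only subjects rated by every rater."""
        keep = ~np.isnan(self.values).any(axis=1)
        return RatingMatrix(
            [s for s, k in zip(self.subjects, keep) if k],
            list(self.raters),
            self.values[keep],
        )


@dataclass
class AgreementResult:
    """A kappa or ICC estimate with its CI, variance components and band."""

    statistic_name: str
    estimate: float
    ci_low: float
    ci_high: float
    conf_level: float
    components: Dict[str, float] = field(default_factory=dict)
    band: str = ""

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.estimate <= self.ci_high):
            raise ValueError("confidence interval must bracket the estimate")


def contingency_from_pairs(
    ratings_a: Sequence, ratings_b: Sequence, levels: Sequence
) -> np.ndarray:
    """Cross-tabulate two raters' ratings of the same subjects.

    ``table[i, j]`` counts subjects rated ``levels[i]`` by rater A and
    ``levels[j]`` by rater B; the grand total is the number of subjects.
    """
    a = list(ratings_a)
    b = list(ratings_b)
    if len(a) != len(b):
        raise ValueError(f"rating sequences differ in length: {len(a)} vs {len(b)}")
    if len(a) == 0:
        raise ValueError("at least one rated subject is required")
    index = {lev: i for i, lev in enumerate(levels)}
    table = np.zeros((len(index), len(index)), dtype=int)
    for x, y in zip(a, b):
        if x not in index or y not in index:
            raise ValueError(f"rating outside declared levels: {(x, y)!r}")
        table[index[x], index[y]] += 1
    return table


def _disagreement_weights(n_levels: int, scheme: WeightScheme) -> np.ndarray:
    i, j = np.indices((n_levels, n_levels))
    if scheme == "identity":
        return (i != j).astype(float)
    d = np.abs(i - j) / (n_levels - 1)
    if scheme == "linear":
        return d
    if scheme == "quadratic":
        return d**2
    raise ValueError(f"unknown weight scheme {scheme!r}")


def weighted_kappa(
    table: np.ndarray,
    scheme: WeightScheme = "linear",
    conf_level: float = 0.95,
    ci_method: Literal["normal", "bootstrap"] = "normal",
    n_boot: int = 2000,
    seed: Optional[int] = None,
) -> AgreementResult:
    """Weighted kappa for an ordinal contingency table of two raters.

    ``kappa_w = 1 - sum(w o) / sum(w e)`` with disagreement weights ``w``;
    observed cell proportions ``o`` and chance-expected proportions ``e``
    (outer product of the margins). The default normal CI uses the
    Fleiss-Cohen-Everitt large-sample variance; ``ci_method="bootstrap"``
    resamples the table multinomially (recommended below ~30 subjects).
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or table.shape[0] != table.shape[1]:
        raise ValueError("contingency table must be square")
    n = table.sum()
    if n < 1:
        raise ValueError("empty contingency table")
    p = table / n
    row = p.sum(axis=1)
    col = p.sum(axis=0)
    expected = np.outer(row, col)
    w_dis = _disagreement_weights(table.shape[0], scheme)
    exp_dis = float((w_dis * expected).sum())
    if exp_dis == 0.0:
        raise UndefinedStatisticError(
            "kappa undefined: chance agreement is 1 (both raters are constant "
            "at the same level); margins "
            f"row={row.tolist()}, col={col.tolist()}"
        )
    obs_dis = float((w_dis * p).sum())
    kappa = 1.0 - obs_dis / exp_dis

    # Agreement-weight formulation of the same statistic, for p_o/p_e/variance
    # (disagreement weights already peak at 1 for every scheme).
    w_agr = 1.0 - w_dis
    p_o = float((w_agr * p).sum())
    p_e = float((w_agr * expected).sum())

    if ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        counts = rng.multinomial(int(n), p.ravel(), size=n_boot)
        reps = np.empty(n_boot)
        flat_w = w_dis.ravel()
        for b, c in enumerate(counts):
            pb = c.reshape(p.shape) / n
            eb = np.outer(pb.sum(axis=1), pb.sum(axis=0))
            denom = float((w_dis * eb).sum())
            reps[b] = 1.0 - float((flat_w * pb.ravel()).sum()) / denom if denom else 1.0
        alpha = 1.0 - conf_level
        ci_low, ci_high = np.quantile(reps, [alpha / 2, 1 - alpha / 2])
        se = float(np.std(reps, ddof=1))
        ci_low = min(ci_low, kappa)
        ci_high = max(ci_high, kappa)
    else:
        # Fleiss, Cohen & Everitt large-sample variance (agreement weights).
        wbar_i = w_agr @ col       # row-wise expected weight
        wbar_j = row @ w_agr       # column-wise expected weight
        penalty = w_agr - np.add.outer(wbar_i, wbar_j) * (1.0 - kappa)
        var = (
            float((p * penalty**2).sum()) - (kappa - p_e * (1.0 - kappa)) ** 2
        ) / (n * (1.0 - p_e) ** 2)
        se = float(np.sqrt(max(var, 0.0)))
        z = stats.norm.ppf(0.5 + conf_level / 2)
        ci_low = max(kappa - z * se, -1.0)
        ci_high = min(kappa + z * se, 1.0)

    name = "cohen_kappa" if scheme == "identity" else f"weighted_kappa_{scheme}"
    return AgreementResult(
        statistic_name=name,
        estimate=kappa,
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        conf_level=conf_level,
        components={
            "p_o": p_o,
            "p_e": p_e,
            "se": se,
            "n": float(n),
            "weight_scheme": scheme,  # type: ignore[dict-item]
        },
        band=interpret_agreement("kappa", kappa),
    )


def cohen_kappa(
    table: np.ndarray,
    conf_level: float = 0.95,
    ci_method: Literal["normal", "bootstrap"] = "normal",
    n_boot: int = 2000,
    seed: Optional[int] = None,
) -> AgreementResult:
    """Unweighted Cohen's kappa — weighted kappa under identity weights."""
    return weighted_kappa(
        table,
        scheme="identity",
        conf_level=conf_level,
        ci_method=ci_method,
        n_boot=n_boot,
        seed=seed,
    )


def icc_absolute_agreement(
    matrix: RatingMatrix,
    measure: Literal["single", "average"] = "single",
    conf_level: float = 0.95,
) -> AgreementResult:
    """Two-way random-effects, absolute-agreement ICC of a rating matrix.

    Subjects are rows, raters columns; subjects with any missing rating are
    dropped listwise (the effective n is reported in the components). The
    single-measure form (McGraw-Wong A-1) is

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))

    with MSR/MSC/MSE the subject, rater and residual mean squares of the
    two-way ANOVA; the average-measure form (A-k) is
    ``(MSR - MSE) / (MSR + (MSC - MSE)/n)``. The CI uses the McGraw-Wong
    F construction for A-1; A-k limits are the Spearman-Brown transform of
    the A-1 limits.
    """
    complete = matrix.complete_cases()
    x = complete.values
    n, k = x.shape
    if n < 2:
        raise ValueError(
            f"need at least 2 complete subjects after listwise deletion, got {n}"
        )
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * float(((row_means - grand) ** 2).sum())
    ss_cols = n * float(((col_means - grand) ** 2).sum())
    ss_total = float(((x - grand) ** 2).sum())
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = max(ss_err / ((n - 1) * (k - 1)), 0.0)
    if ss_total == 0.0:
        raise UndefinedStatisticError(
            "ICC undefined: all ratings identical (zero total variance)"
        )

    denom_single = msr + (k - 1) * mse + (k / n) * (msc - mse)
    icc_single = (msr - mse) / denom_single

    alpha = 1.0 - conf_level
    # McGraw-Wong A-1 CI: Satterthwaite df for the rater+error combination.
    r = icc_single
    a = (k * r) / (n * (1.0 - r)) if r < 1.0 else np.inf
    b = 1.0 + (k * r * (n - 1.0)) / (n * (1.0 - r)) if r < 1.0 else np.inf
    if np.isfinite(a):
        nu = (a * msc + b * mse) ** 2 / (
            (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        )
        f_l = stats.f.ppf(1 - alpha / 2, n - 1, nu)
        f_u = stats.f.ppf(1 - alpha / 2, nu, n - 1)
        mix = k * msc + (k * n - k - n) * mse
        low1 = n * (msr - f_l * mse) / (f_l * mix + n * msr)
        up1 = n * (f_u * msr - mse) / (mix + n * f_u * msr)
    else:  # perfect agreement: degenerate interval
        low1 = up1 = 1.0
    low1 = min(low1, r)
    up1 = max(up1, r)

    if measure == "single":
        estimate, ci_low, ci_high = r, low1, up1
        name = "icc_a1"
    elif measure == "average":
        estimate = (msr - mse) / (msr + (msc - mse) / n)

        def spearman_brown(v: float) -> float:
            return k * v / (1.0 + (k - 1.0) * v)

        ci_low = min(spearman_brown(low1), estimate)
        ci_high = max(spearman_brown(up1), estimate)
        name = "icc_ak"
    else:
        raise ValueError(f"measure must be 'single' or 'average', got {measure!r}")

    return AgreementResult(
        statistic_name=name,
        estimate=float(estimate),
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        conf_level=conf_level,
        components={"MSR": msr, "MSC": msc, "MSE": mse, "n": float(n), "k": float(k)},
        band=interpret_agreement("icc", float(estimate)),
    )


#: Landis-Koch interpretation bands for kappa: cut-points and the band labels
#: between them (a value equal to a cut-point takes the higher band).
KAPPA_BANDS = (
    (0.0, 0.20, 0.40, 0.60, 0.80),
    ("none", "slight", "fair", "moderate", "substantial", "almost perfect"),
)

#: Koo-Li interpretation bands for the ICC.
ICC_BANDS = ((0.50, 0.75, 0.90), ("poor", "moderate", "good", "excellent"))


def interpret_agreement(
    statistic_name: str,
    estimate: float,
    cutpoints: Optional[tuple] = None,
) -> str:
    """Qualitative band for an agreement estimate.

    Kappa statistics use the Landis-Koch bands, ICCs the Koo-Li bands; custom
    ``(cuts, labels)`` may be supplied. Boundary values go to the higher band.
    """
    if estimate > 1.0:
        raise ValueError("agreement estimates cannot exceed 1")
    if cutpoints is not None:
        cuts, labels = cutpoints
    elif "kappa" in statistic_name.lower():
        cuts, labels = KAPPA_BANDS
    elif "icc" in statistic_name.lower():
        cuts, labels = ICC_BANDS
    else:
        raise ValueError(f"unknown statistic {statistic_name!r}")
    return labels[bisect_right(list(cuts), estimate)]
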