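"""Inter-rater reliability and validation statistics.

Implements the statistics used to validate an ordinal bedside score
against raters and offline parameters:

* two-way random-effects intraclass correlation (consistency and
  agreement flavors, single- or average-measures) with F-based 95 %
  confidence intervals;
* "error score" regression: observed minus expert score regressed on
  rater and item as categorical predictors;
* ordinary least-squares R^2 of scores against continuous parameters;
* Kruskal-Wallis across score groups followed by Dunn's pairwise
  comparisons on pooled ranks, with tie correction.

The ICC follows the two-way ANOVA decomposition with items (rows) and
raters (columns) both treated as random samples. Writing MSR, MSC and MSE
for the item, rater and residual mean squares with n items and k raters:

    ICC(consistency, 1) = (MSR - MSE) / (MSR + (k-1) MSE)
    ICC(agreement, 1)   = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

Consistency asks whether raters order the items the same way and is
invariant to a constant offset per rater; agreement additionally charges
rater-mean differences to the denominator, so it can only be lower in the
presence of rater bias. Confidence intervals use the exact F bounds for
the consistency form and the Satterthwaite-degrees approximation for the
agreement form.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from collections.abc import Mapping, Sequence
from itertools import combinations

import numpy as np
import pandas as pd
import scipy.stats as ss
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .errors import DegenerateStatisticsError, DomainError, InputValidationError
from .types import ICCResult, RatingMatrix, RegressionResult


def _mean_squares(x: np.ndarray) -> tuple[float, float, float]:
    """Two-way ANOVA (no replication) mean squares: items, raters, residual."""
    n, k = x.shape
    grand = x.mean()
    item_means = x.mean(axis=1)
    rater_means = x.mean(axis=0)
    msr = k * ((item_means - grand) ** 2).sum() / (n - 1)
    msc = n * ((rater_means - grand) ** 2).sum() / (k - 1)
    resid = x - item_means[:, None] - rater_means[None, :] + grand
    mse = (resid**2).sum() / ((n - 1) * (k - 1))
    return float(msr), float(msc), float(mse)


def icc(
    matrix: RatingMatrix,
    flavor: str = "consistency",
    measures: str = "single",
    alpha: float = 0.05,
) -> ICCResult:
    """Two-way random-effects intraclass correlation with 95 % CI.

    Parameters
    ----------
    matrix
        Complete items x raters score matrix.
    flavor
        ``"consistency"`` ignores systematic rater offsets;
        ``"agreement"`` penalizes them.
    measures
        ``"single"`` for the reliability of one rater's score (the unit of
        interest at the bedside), ``"average"`` for the mean over all
        raters.
    """
    if flavor not in ("consistency", "agreement"):
        raise DomainError(f"flavor must be consistency|agreement, got {flavor!r}")
    if measures not in ("single", "average"):
        raise DomainError(f"measures must be single|average, got {measures!r}")

    x = matrix.scores.to_numpy(dtype=float)
    n, k = x.shape
    if np.ptp(x) == 0:
        raise DegenerateStatisticsError(
            "constant rating matrix: zero between-item variance, ICC undefined"
        )
    msr, msc, mse = _mean_squares(x)
    df1 = n - 1
    df2 = (n - 1) * (k - 1)
    f_value = np.inf if mse == 0 else msr / mse

    if flavor == "consistency":
        if measures == "single":
            est = (msr - mse) / (msr + (k - 1) * mse) if msr + (k - 1) * mse > 0 else 0.0
        else:
            est = (msr - mse) / msr if msr > 0 else 0.0
        if mse == 0:
            low = high = est
        else:
            fcrit1 = ss.f.ppf(1 - alpha / 2, df1, df2)
            fcrit2 = ss.f.ppf(1 - alpha / 2, df2, df1)
            fl = f_value / fcrit1
            fu = f_value * fcrit2
            if measures == "single":
                low = (fl - 1) / (fl + k - 1)
                high = (fu - 1) / (fu + k - 1)
            else:
                low = 1 - 1 / fl
                high = 1 - 1 / fu
    else:  # agreement
        denom_single = msr + (k - 1) * mse + k * (msc - mse) / n
        est_single = (msr - mse) / denom_single if denom_single > 0 else 0.0
        if est_single >= 1.0:  # perfect: MSE = MSC = 0
            est_single = 1.0
            low_s = high_s = 1.0
        else:
            a = k * est_single / (n * (1 - est_single))
            b = 1 + k * est_single * (n - 1) / (n * (1 - est_single))
            num = (a * msc + b * mse) ** 2
            den = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
            v = num / den if den > 0 else (k - 1)
            fl = ss.f.ppf(1 - alpha / 2, df1, v)
            fu = ss.f.ppf(1 - alpha / 2, v, df1)
            low_s = (
                n * (msr - fl * mse) / (fl * (k * msc + (k * n - k - n) * mse) + n * msr)
            )
            high_s = (
                n * (fu * msr - mse) / (k * msc + (k * n - k - n) * mse + n * fu * msr)
            )
        if measures == "single":
            est, low, high = est_single, low_s, high_s
        else:
            # Spearman-Brown step-up of the single-measures form
            def _step_up(r: float) -> float:
                return 1.0 if r >= 1.0 else k * r / (1 + (k - 1) * r)

            est, low, high = _step_up(est_single), _step_up(low_s), _step_up(high_s)

    # guard against floating-point inversions at the interval edges
    low = min(low, est)
    high = max(high, est)
    return ICCResult(
        estimate=float(est),
        ci_low=float(low),
        ci_high=float(high),
        flavor=flavor,
        measures=measures,
        f_value=float(f_value),
        df1=float(df1),
        df2=float(df2),
    )


@dataclass(frozen=True)
class ErrorScoreResult:
    """Linear model of rater error (observed - expert) on rater and item."""

    degenerate: bool
    p_rater: float = float("nan")
    p_item: float = float("nan")
    f_rater: float = float("nan")
    f_item: float = float("nan")
    n_obs: int = 0
    anova_table: pd.DataFrame | None = field(default=None, repr=False, compare=False)


def error_score_regression(
    naive: RatingMatrix, expert: Mapping | pd.Series
) -> ErrorScoreResult:
    """Regress rater error scores on rater and item as categorical predictors.

    The response is observed minus the expert's (true) score for each
    rater x item cell; per-predictor p-values come from the ANOVA F test.
    A model with zero error variance (every rater equal to expert, or a
    uniform constant error) is flagged degenerate rather than raised.
    """
    expert = pd.Series(expert)
    missing = [i for i in naive.items if i not in expert.index]
    if missing:
        raise InputValidationError(f"expert scores missing for items: {missing}")
    long = naive.to_long()
    long["error"] = long["score"].to_numpy(dtype=float) - expert.loc[
        long["item"]
    ].to_numpy(dtype=float)
    if np.ptp(long["error"].to_numpy()) == 0:
        return ErrorScoreResult(degenerate=True, n_obs=len(long))
    model = smf.ols("error ~ C(rater) + C(item)", data=long).fit()
    table = sm.stats.anova_lm(model, typ=2)
    return ErrorScoreResult(
        degenerate=False,
        p_rater=float(table.loc["C(rater)", "PR(>F)"]),
        p_item=float(table.loc["C(item)", "PR(>F)"]),
        f_rater=float(table.loc["C(rater)", "F"]),
        f_item=float(table.loc["C(item)", "F"]),
        n_obs=len(long),
        anova_table=table,
    )


def linear_r2(x: Sequence[float], y: Sequence[float]) -> RegressionResult:
    """Ordinary least-squares fit of y on x: R^2 and two-sided slope p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise DomainError(f"x and y must have equal length ({x.size} vs {y.size})")
    if x.size < 3:
        raise DomainError(f"need at least 3 paired points, got {x.size}")
    if np.ptp(x) == 0:
        raise DomainError("x is constant: slope undefined")
    if np.ptp(y) == 0:
        # flat response: zero slope explains everything and nothing
        return RegressionResult(r_squared=0.0, p_value=1.0, slope=0.0, intercept=float(y[0]))
    fit = ss.linregress(x, y)
    return RegressionResult(
        r_squared=float(fit.rvalue**2),
        p_value=float(fit.pvalue),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
    )


@dataclass(frozen=True)
class PairwiseComparison:
    group_a: str
    group_b: str
    z: float
    p_raw: float
    p_adjusted: float


@dataclass(frozen=True)
class GroupComparison:
    """Kruskal-Wallis H with Dunn's pairwise z tests on pooled ranks."""

    kw_h: float
    kw_p: float
    pairwise: tuple[PairwiseComparison, ...]


def kruskal_dunn(
    groups: Mapping[str, Sequence[float]], adjustment: str = "bonferroni"
) -> GroupComparison:
    """Kruskal-Wallis across groups, then Dunn's multiple-comparison z tests.

    Dunn's z for groups i, j uses pooled mid-ranks over all N values:

        z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T)(1/n_i + 1/n_j))

    with tie correction T = sum(t^3 - t) / (12 (N - 1)) over tie groups.
    Raw p-values are two-sided normal; ``bonferroni`` multiplies by the
    number of comparisons (capped at 1), ``none`` leaves them unadjusted.
    """
    if adjustment not in ("none", "bonferroni"):
        raise DomainError(f"adjustment must be none|bonferroni, got {adjustment!r}")
    labels = list(groups.keys())
    if len(labels) < 2:
        raise DomainError(f"need at least two groups, got {len(labels)}")
    arrays = {g: np.asarray(v, dtype=float) for g, v in groups.items()}
    for g, v in arrays.items():
        if v.size < 1:
            raise DomainError(f"group {g!r} is empty")

    kw_h, kw_p = ss.kruskal(*arrays.values())

    pooled = np.concatenate(list(arrays.values()))
    n_total = pooled.size
    ranks = ss.rankdata(pooled)
    mean_ranks: dict[str, float] = {}
    sizes: dict[str, int] = {}
    start = 0
    for g in labels:
        size = arrays[g].size
        mean_ranks[g] = float(ranks[start : start + size].mean())
        sizes[g] = size
        start += size

    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (12.0 * (n_total - 1))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term

    pairs = list(combinations(labels, 2))
    m = len(pairs)
    results = []
    for a, b in pairs:
        var = base_var * (1.0 / sizes[a] + 1.0 / sizes[b])
        if var <= 0:  # every pooled value tied
            z = 0.0
        else:
            z = (mean_ranks[a] - mean_ranks[b]) / np.sqrt(var)
        p_raw = float(2 * ss.norm.sf(abs(z)))
        p_adj = p_raw if adjustment == "none" else float(min(1.0, p_raw * m))
        results.append(
            PairwiseComparison(group_a=a, group_b=b, z=float(z), p_raw=p_raw, p_adjusted=p_adj)
        )
    return GroupComparison(kw_h=float(kw_h), kw_p=float(kw_p), pairwise=tuple(results))
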