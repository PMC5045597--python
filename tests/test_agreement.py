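"""Reliability and validation statistics against independent oracles."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import pytest
import scipy.stats as ss

from poemscore import (
    DegenerateStatisticsError,
    DomainError,
    RatingMatrix,
    error_score_regression,
    icc,
    kruskal_dunn,
    linear_r2,
)


def matrix_from(array) -> RatingMatrix:
    arr = np.asarray(array)
    return RatingMatrix.from_arrays(
        [f"item{i}" for i in range(arr.shape[0])],
        [f"r{j}" for j in range(arr.shape[1])],
        arr,
    )


def anova_mean_squares(x: np.ndarray) -> tuple[float, float, float]:
    """Plain-loop two-way ANOVA mean squares (items, raters, residual)."""
    n, k = x.shape
    grand = sum(x[i][j] for i in range(n) for j in range(k)) / (n * k)
    item_means = [sum(x[i]) / k for i in range(n)]
    rater_means = [sum(x[i][j] for i in range(n)) / n for j in range(k)]
    msr = k * sum((m - grand) ** 2 for m in item_means) / (n - 1)
    msc = n * sum((m - grand) ** 2 for m in rater_means) / (k - 1)
    sse = sum(
        (x[i][j] - item_means[i] - rater_means[j] + grand) ** 2
        for i in range(n)
        for j in range(k)
    )
    return msr, msc, sse / ((n - 1) * (k - 1))


def oracle_icc(x: np.ndarray, flavor: str) -> float:
    n, k = x.shape
    msr, msc, mse = anova_mean_squares(x)
    if flavor == "consistency":
        return (msr - mse) / (msr + (k - 1) * mse)
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


class TestICC:
    def test_identical_raters_give_one(self):
        m = matrix_from(np.tile([[1], [3], [5], [2]], (1, 4)))
        for flavor in ("consistency", "agreement"):
            res = icc(m, flavor)
            assert res.estimate == 1.0
            assert res.ci_low == res.ci_high == 1.0

    def test_rater_offset_hits_agreement_only(self):
        base = np.array([[1, 1, 1], [2, 2, 2], [3, 3, 3], [4, 4, 4]])
        biased = base.copy()
        biased[:, 0] += 1  # one rater systematically +1, still within 1..5
        cons_base = icc(matrix_from(base), "consistency").estimate
        cons_biased = icc(matrix_from(biased), "consistency").estimate
        agr_biased = icc(matrix_from(biased), "agreement").estimate
        assert cons_biased == pytest.approx(cons_base)  # unchanged: 1.0
        assert agr_biased < cons_biased

    def test_fixed_matrix_matches_hand_oracle(self):
        x = np.array([[1, 2, 2], [3, 3, 4], [5, 4, 5], [2, 1, 2]], dtype=float)
        m = matrix_from(x)
        for flavor in ("consistency", "agreement"):
            assert icc(m, flavor).estimate == pytest.approx(
                oracle_icc(x, flavor), rel=1e-12
            )

    @pytest.mark.parametrize("flavor", ["consistency", "agreement"])
    def test_matches_pingouin_on_random_matrices(self, flavor):
        pg = pytest.importorskip("pingouin")
        key = "ICC(C,1)" if flavor == "consistency" else "ICC(A,1)"
        rng = np.random.default_rng(42)
        for _ in range(10):
            n = int(rng.integers(4, 11))
            k = int(rng.integers(3, 10))
            x = rng.integers(1, 6, size=(n, k))
            m = matrix_from(x)
            long = m.to_long()
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                table = pg.intraclass_corr(
                    long, targets="item", raters="rater", ratings="score"
                ).set_index("Type")
            assert icc(m, flavor).estimate == pytest.approx(
                float(table.loc[key, "ICC"]), abs=1e-10
            )

    def test_average_measures_step_up(self):
        rng = np.random.default_rng(7)
        x = rng.integers(1, 6, size=(6, 5))
        m = matrix_from(x)
        k = 5
        single = icc(m, "agreement", measures="single").estimate
        average = icc(m, "agreement", measures="average").estimate
        assert average == pytest.approx(k * single / (1 + (k - 1) * single))

    def test_ci_brackets_estimate(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            x = rng.integers(1, 6, size=(rng.integers(4, 9), rng.integers(3, 8)))
            for flavor in ("consistency", "agreement"):
                for measures in ("single", "average"):
                    res = icc(matrix_from(x), flavor, measures=measures)
                    assert res.ci_low <= res.estimate <= res.ci_high

    def test_constant_matrix_degenerate(self):
        with pytest.raises(DegenerateStatisticsError):
            icc(matrix_from(np.full((4, 3), 3)), "consistency")

    def test_unknown_flavor_rejected(self):
        m = matrix_from(np.array([[1, 2], [3, 4]]))
        with pytest.raises(DomainError):
            icc(m, "absolute")


class TestErrorScoreRegression:
    def test_perfect_raters_flagged_degenerate(self):
        x = np.tile([[2], [3], [5], [1]], (1, 6))
        m = matrix_from(x)
        expert = pd.Series([2, 3, 5, 1], index=m.items)
        res = error_score_regression(m, expert)
        assert res.degenerate
        assert np.isnan(res.p_rater)

    def test_biased_rater_detected_and_matches_partial_f_oracle(self):
        truth = np.array([1, 2, 3, 4, 3, 2])
        x = np.tile(truth[:, None], (1, 8))
        x[:, 0] = truth + 1  # rater 0 systematically +1
        x[2, 1] += 1  # one stray disagreement keeps the fit well-conditioned
        m = matrix_from(x)
        expert = pd.Series(truth, index=m.items)
        res = error_score_regression(m, expert)
        assert not res.degenerate

        # independent oracle: partial F via explicit dummy design matrices
        long = m.to_long()
        err = long["score"].to_numpy(float) - expert.loc[long["item"]].to_numpy(float)
        rater_d = pd.get_dummies(long["rater"], drop_first=True, dtype=float)
        item_d = pd.get_dummies(long["item"], drop_first=True, dtype=float)
        ones = np.ones((len(err), 1))

        def sse(design):
            beta, *_ = np.linalg.lstsq(design, err, rcond=None)
            return float(((err - design @ beta) ** 2).sum())

        full = np.hstack([ones, rater_d.to_numpy(), item_d.to_numpy()])
        no_rater = np.hstack([ones, item_d.to_numpy()])
        no_item = np.hstack([ones, rater_d.to_numpy()])
        df_resid = len(err) - full.shape[1]
        for dropped, dof, p_obs in [
            (no_rater, rater_d.shape[1], res.p_rater),
            (no_item, item_d.shape[1], res.p_item),
        ]:
            f = ((sse(dropped) - sse(full)) / dof) / (sse(full) / df_resid)
            assert p_obs == pytest.approx(float(ss.f.sf(f, dof, df_resid)), rel=1e-8)
        assert res.p_rater < 0.01  # the +1 rater is detected

    def test_missing_expert_items_rejected(self):
        m = matrix_from(np.array([[1, 2], [3, 4]]))
        with pytest.raises(Exception, match="expert"):
            error_score_regression(m, pd.Series({"item0": 1}))


class TestLinearR2:
    def test_exact_line(self):
        x = np.array([1, 2, 3, 4, 5.0])
        res = linear_r2(x, 2 * x + 1)
        assert res.r_squared == pytest.approx(1.0)
        assert res.slope == pytest.approx(2.0)
        assert res.intercept == pytest.approx(1.0)

    def test_constant_response(self):
        res = linear_r2([1, 2, 3, 4], [7, 7, 7, 7])
        assert res.r_squared == 0.0
        assert res.p_value == 1.0

    def test_equals_squared_pearson(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            x = rng.normal(size=12)
            y = 0.5 * x + rng.normal(size=12)
            r, _ = ss.pearsonr(x, y)
            assert linear_r2(x, y).r_squared == pytest.approx(r**2, rel=1e-10)

    def test_fixed_fixture_matches_correlation_identity(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        y = [2.1, 2.9, 4.2, 4.8, 6.3, 6.6]
        r, _ = ss.pearsonr(x, y)
        assert linear_r2(x, y).r_squared == pytest.approx(r**2, rel=1e-12)

    def test_constant_x_rejected(self):
        with pytest.raises(DomainError):
            linear_r2([2, 2, 2], [1, 2, 3])

    def test_too_few_points(self):
        with pytest.raises(DomainError):
            linear_r2([1, 2], [1, 2])


def dunn_oracle(groups: dict) -> dict:
    """Dunn z by explicit rank-sum arithmetic, with tie correction."""
    pooled = [v for vals in groups.values() for v in vals]
    order = sorted(range(len(pooled)), key=lambda i: pooled[i])
    ranks = [0.0] * len(pooled)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and pooled[order[j + 1]] == pooled[order[i]]:
            j += 1
        mid_rank = (i + j) / 2 + 1
        for idx in order[i : j + 1]:
            ranks[idx] = mid_rank
        i = j + 1
    n_total = len(pooled)
    mean_rank, sizes, start = {}, {}, 0
    for g, vals in groups.items():
        sizes[g] = len(vals)
        mean_rank[g] = sum(ranks[start : start + len(vals)]) / len(vals)
        start += len(vals)
    tie_counts = {}
    for v in pooled:
        tie_counts[v] = tie_counts.get(v, 0) + 1
    tie_term = sum(t**3 - t for t in tie_counts.values()) / (12 * (n_total - 1))
    zs = {}
    labels = list(groups)
    for a_i in range(len(labels)):
        for b_i in range(a_i + 1, len(labels)):
            a, b = labels[a_i], labels[b_i]
            var = (n_total * (n_total + 1) / 12 - tie_term) * (
                1 / sizes[a] + 1 / sizes[b]
            )
            zs[(a, b)] = (mean_rank[a] - mean_rank[b]) / var**0.5
    return zs


THREE_GROUPS = {
    "score1": [2.1, 1.8, 2.5, 1.2, 2.2],
    "score3": [2.9, 3.3, 2.6, 3.1],
    "score5": [4.0, 3.8, 4.4, 3.5, 4.1, 3.9],
}


class TestKruskalDunn:
    def test_identical_groups_h_zero(self):
        res = kruskal_dunn({"a": [1, 2, 3, 4], "b": [1, 2, 3, 4]})
        assert res.kw_h == pytest.approx(0.0, abs=1e-12)

    def test_three_group_fixture_matches_oracle(self):
        res = kruskal_dunn(THREE_GROUPS, adjustment="none")
        oracle_z = dunn_oracle(THREE_GROUPS)
        assert len(res.pairwise) == 3
        for p in res.pairwise:
            assert p.z == pytest.approx(oracle_z[(p.group_a, p.group_b)], rel=1e-12)
            assert p.p_raw == pytest.approx(2 * ss.norm.sf(abs(p.z)), rel=1e-12)
        assert res.kw_h == pytest.approx(ss.kruskal(*THREE_GROUPS.values()).statistic)

    def test_two_group_h_equals_dunn_z_squared(self):
        # with two groups the rank-based H collapses to the square of the z
        groups = {"a": [1.0, 2.0, 5.0, 3.0], "b": [4.0, 6.0, 7.0, 5.5]}
        res = kruskal_dunn(groups)
        assert res.kw_h == pytest.approx(res.pairwise[0].z ** 2, rel=1e-10)

    def test_bonferroni_dominates_raw(self):
        res = kruskal_dunn(THREE_GROUPS, adjustment="bonferroni")
        raw = kruskal_dunn(THREE_GROUPS, adjustment="none")
        for adj, un in zip(res.pairwise, raw.pairwise):
            assert adj.p_adjusted >= adj.p_raw
            assert adj.p_adjusted == pytest.approx(min(1.0, un.p_raw * 3))

    def test_single_group_rejected(self):
        with pytest.raises(DomainError):
            kruskal_dunn({"only": [1, 2, 3]})

    def test_empty_group_rejected(self):
        with pytest.raises(DomainError):
            kruskal_dunn({"a": [1, 2], "b": []})
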