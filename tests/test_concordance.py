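"""Agreement statistics against independently coded oracles."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bodyscan.concordance import (
    best_subsets,
    bland_altman,
    bland_altman_plot,
    coefficient_of_variation,
    icc,
    loa_from_summary,
)
from bodyscan.errors import DomainError, InputError, UndefinedStatisticError


# ---------------------------------------------------------------------------
# independent oracles: raw sums of squares, no shared code with the package
# ---------------------------------------------------------------------------

def oracle_icc(x, form):
    x = np.asarray(x, float)
    n, k = x.shape
    mu = x.mean()
    ssr = sum(k * (x[i].mean() - mu) ** 2 for i in range(n))
    ssc = sum(n * (x[:, j].mean() - mu) ** 2 for j in range(k))
    sst = sum((v - mu) ** 2 for v in x.ravel())
    sse = sst - ssr - ssc
    msr, msc, mse = ssr / (n - 1), ssc / (k - 1), sse / ((n - 1) * (k - 1))
    if form == "ICC(2,1)":
        return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    return (msr - mse) / (msr + (k - 1) * mse)


def oracle_ols(X, y):
    X1 = np.column_stack([np.ones(len(y)), X])
    beta = np.linalg.solve(X1.T @ X1, X1.T @ y)
    resid = y - X1 @ beta
    return beta, float(resid @ resid)


class TestLoaFromSummary:
    def test_bv_summary(self):
        lo, hi = loa_from_summary(0.1670, 3.7504)
        assert hi == pytest.approx(7.5176, abs=1e-3)
        assert lo == pytest.approx(-7.1838, abs=1e-3)

    def test_fm_summary(self):
        lo, hi = loa_from_summary(-0.2911, 6.3625)
        assert lo == pytest.approx(-12.7613, abs=1e-3)
        assert hi == pytest.approx(12.1791, abs=1e-3)

    def test_unit_sd(self):
        assert loa_from_summary(0.0, 1.0) == pytest.approx((-1.96, 1.96))

    def test_negative_sd_rejected(self):
        with pytest.raises(DomainError):
            loa_from_summary(0.0, -1.0)


class TestBlandAltman:
    def test_identical_series(self):
        r = bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (r.mean_diff, r.sd_diff, r.loa_low, r.loa_high) == (0, 0, 0, 0)

    def test_hand_computed_n4(self):
        r = bland_altman([1.0, -1.0, 1.0, -1.0], [0.0, 0.0, 0.0, 0.0])
        assert r.mean_diff == pytest.approx(0.0)
        assert r.sd_diff == pytest.approx(np.sqrt(4 / 3), abs=1e-4)  # 1.1547
        assert r.loa_high == pytest.approx(1.96 * np.sqrt(4 / 3), abs=1e-4)  # 2.2632

    def test_loa_geometry_invariant(self):
        rng = np.random.default_rng(8)
        a, b = rng.normal(size=30), rng.normal(size=30)
        r = bland_altman(a, b)
        assert r.loa_high - r.mean_diff == pytest.approx(
            r.mean_diff - r.loa_low, abs=1e-12
        )
        assert r.loa_high - r.mean_diff == pytest.approx(1.96 * r.sd_diff, abs=1e-12)
        assert r.ci_mean[0] <= r.mean_diff <= r.ci_mean[1]
        assert r.ci_loa_low[0] <= r.loa_low <= r.ci_loa_low[1]
        assert r.ci_loa_high[0] <= r.loa_high <= r.ci_loa_high[1]

    @given(st.integers(0, 1000))
    @settings(max_examples=50, deadline=None)
    def test_argument_swap_mirrors(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(size=12), rng.normal(size=12)
        r1, r2 = bland_altman(a, b), bland_altman(b, a)
        assert r1.mean_diff == pytest.approx(-r2.mean_diff, abs=1e-12)
        assert r1.sd_diff == pytest.approx(r2.sd_diff, abs=1e-12)
        assert r1.loa_low == pytest.approx(-r2.loa_high, abs=1e-12)
        assert r1.loa_high == pytest.approx(-r2.loa_low, abs=1e-12)

    def test_too_few_pairs(self):
        with pytest.raises(InputError):
            bland_altman([1.0, 2.0], [0.0, 0.0])


class TestICC:
    def test_perfect_agreement_is_one(self):
        x = np.tile(np.array([[1.0], [2.0], [3.0], [4.0]]), (1, 3))
        assert icc(x, "ICC(2,1)").icc_value == pytest.approx(1.0)
        assert icc(x, "ICC(3,1)").icc_value == pytest.approx(1.0)

    def test_no_subject_variance_warns_nonpositive(self):
        rng = np.random.default_rng(0)
        x = np.zeros((6, 3)) + rng.normal(0, 1, size=(6, 3))
        x -= x.mean(axis=1, keepdims=True)  # remove subject signal
        with pytest.warns(UserWarning):
            res = icc(x, "ICC(2,1)")
        assert res.icc_value <= 0

    def test_zero_variance_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            icc(np.ones((5, 3)))

    @pytest.mark.parametrize("form", ["ICC(2,1)", "ICC(3,1)"])
    def test_matches_sums_of_squares_oracle_100_grids(self, form):
        for seed in range(100):
            rng = np.random.default_rng(seed)
            x = rng.normal(size=(5, 3)) + rng.normal(size=(5, 1)) * rng.uniform(0.5, 3)
            res = icc(x, form)
            assert res.icc_value == pytest.approx(oracle_icc(x, form), abs=1e-9)
            assert res.ci[0] <= res.icc_value <= res.ci[1]

    def test_invariance_under_shift_and_scale(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(8, 3)) + rng.normal(size=(8, 1)) * 2
        base = icc(x, "ICC(2,1)").icc_value
        assert icc(x + 17.3, "ICC(2,1)").icc_value == pytest.approx(base, abs=1e-9)
        assert icc(x * 4.2, "ICC(2,1)").icc_value == pytest.approx(base, abs=1e-9)

    def test_matches_pingouin_cross_check(self):
        """Independent library cross-check on one grid."""
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(12)
        x = rng.normal(size=(7, 3)) + rng.normal(size=(7, 1)) * 2
        df = pd.DataFrame(
            {
                "s": np.repeat(np.arange(7), 3),
                "r": np.tile(np.arange(3), 7),
                "y": x.ravel(),
            }
        )
        res = pg.intraclass_corr(df, targets="s", raters="r", ratings="y").set_index("Type")
        assert icc(x, "ICC(2,1)").icc_value == pytest.approx(
            res.loc["ICC(A,1)", "ICC"], abs=1e-9
        )
        assert icc(x, "ICC(3,1)").icc_value == pytest.approx(
            res.loc["ICC(C,1)", "ICC"], abs=1e-9
        )


class TestCV:
    def test_constant_is_zero(self):
        assert coefficient_of_variation([5.0, 5.0, 5.0]) == 0.0

    def test_two_values(self):
        assert coefficient_of_variation([1.0, 3.0]) == pytest.approx(
            np.sqrt(2.0) / 2.0, abs=1e-9
        )

    def test_cohort_scale_summary(self):
        """A sample constructed with mean 66.5 and SD 13.03 yields CV ~0.196."""
        rng = np.random.default_rng(9)
        x = rng.normal(size=200)
        x = (x - x.mean()) / x.std(ddof=1) * 13.03 + 66.5
        assert coefficient_of_variation(x) == pytest.approx(13.03 / 66.5, abs=1e-9)

    def test_zero_mean_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            coefficient_of_variation([-1.0, 1.0])


class TestBestSubsets:
    def test_exact_linear_predictor_wins(self):
        rng = np.random.default_rng(5)
        x1 = rng.normal(size=40)
        x2 = rng.normal(size=40)
        models = best_subsets({"x1": x1, "x2": x2}, 3.0 * x1 + 1.0, criterion="r2")
        assert models[0].r2 == pytest.approx(1.0, abs=1e-12)
        assert "x1" in models[0].predictor_names

    def test_full_model_cp_identity_and_count(self):
        rng = np.random.default_rng(6)
        cols = {f"x{i}": rng.normal(size=100) for i in range(3)}
        y = cols["x0"] + rng.normal(size=100)
        models = best_subsets(cols, y)
        assert len(models) == 7  # 2^3 - 1 subsets
        full = [m for m in models if m.p == 3][0]
        assert full.mallows_cp == pytest.approx(4.0, abs=1e-9)  # p + 1 exactly
        best1 = min((m for m in models if m.p == 1), key=lambda m: -m.r2)
        assert best1.predictor_names == ("x0",)

    def test_adjusted_r2_never_exceeds_r2(self):
        rng = np.random.default_rng(7)
        cols = {f"x{i}": rng.normal(size=50) for i in range(4)}
        y = rng.normal(size=50)
        for m in best_subsets(cols, y):
            assert m.adjusted_r2 <= m.r2 + 1e-12

    def test_ranking_monotone_for_nested_models(self):
        """Sorted by adjusted R2, a strict superset with lower adjusted R2
        never outranks its subset."""
        rng = np.random.default_rng(11)
        cols = {f"x{i}": rng.normal(size=60) for i in range(4)}
        y = cols["x0"] - 0.5 * cols["x1"] + rng.normal(size=60)
        models = best_subsets(cols, y, criterion="adjusted_r2")
        rank = {m.predictor_names: i for i, m in enumerate(models)}
        for a, b in itertools.permutations(models, 2):
            if set(a.predictor_names) < set(b.predictor_names):
                if b.adjusted_r2 < a.adjusted_r2:
                    assert rank[b.predictor_names] > rank[a.predictor_names]

    def test_matches_ols_oracle(self):
        rng = np.random.default_rng(13)
        cols = {f"x{i}": rng.normal(size=30) for i in range(3)}
        y = 2 * cols["x1"] + rng.normal(size=30)
        tss = ((y - y.mean()) ** 2).sum()
        for m in best_subsets(cols, y):
            X = np.column_stack([cols[n] for n in m.predictor_names])
            beta, rss = oracle_ols(X, y)
            assert m.r2 == pytest.approx(1 - rss / tss, abs=1e-9)
            np.testing.assert_allclose(m.coefficients, beta, atol=1e-8)

    def test_too_few_observations(self):
        with pytest.raises(InputError):
            best_subsets(
                {"x": np.arange(3.0), "z": np.array([1.0, 4.0, 2.0])},
                np.arange(3.0) * 2,
            )


class TestPlot:
    def test_plot_written_with_loa_lines(self, tmp_path):
        rng = np.random.default_rng(14)
        a, b = rng.normal(60, 5, 20), rng.normal(60, 5, 20)
        r = bland_altman(a, b)
        out = bland_altman_plot(r, a, b, tmp_path / "ba.png")
        assert out.exists() and out.stat().st_size > 0

    def test_empty_pairs_rejected(self):
        r = bland_altman([1.0, 2.0, 3.0], [0.0, 0.0, 0.0])
        with pytest.raises(InputError):
            bland_altman_plot(r, [], [], "unused.png")
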