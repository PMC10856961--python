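"""Replicate selection, density, Siri, calibration, fat-mass equation."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bodyscan.densitometry import (
    SubjectRecord,
    apply_calibration,
    body_density,
    fit_bv_calibration,
    predict_fat_mass,
    report_bv_error,
    select_replicates,
    siri_percent_fat,
)
from bodyscan.errors import DomainError, InputError, ReplicateError, SingularFitError


def brute_force_closest_pair(vals):
    """Independent oracle: enumerate all pairs, smallest |diff| wins; ties by
    mean closest to median, then earliest index pair."""
    med = np.median(vals)
    pairs = sorted(
        itertools.combinations(range(len(vals)), 2),
        key=lambda p: (
            abs(vals[p[0]] - vals[p[1]]),
            abs((vals[p[0]] + vals[p[1]]) / 2 - med),
            p,
        ),
    )
    i, j = pairs[0]
    return (vals[i] + vals[j]) / 2


class TestSelectReplicates:
    def test_agreeing_pair_averaged(self):
        assert select_replicates([62.00, 62.10]).selected_value == pytest.approx(62.05)

    def test_disagreeing_pair_needs_third(self):
        with pytest.raises(ReplicateError):
            select_replicates([62.00, 62.40])

    def test_point_three_percent_branch(self):
        # 0.3% of ~70 L is 210 mL > 150 mL: the relative branch is the binding one
        assert select_replicates([70.00, 70.20]).selected_value == pytest.approx(70.10)

    def test_third_value_closest_pair(self):
        r = select_replicates([62.00, 62.40, 62.10])
        assert r.selected_value == pytest.approx(62.05)
        assert r.selected_pair == (0, 2)

    def test_matches_brute_force_on_random_triples(self):
        rng = np.random.default_rng(2024)
        for _ in range(1000):
            vals = list(np.round(rng.uniform(50, 90, size=3), 3))
            assert select_replicates(vals).selected_value == pytest.approx(
                brute_force_closest_pair(vals), abs=1e-12
            )

    @given(st.lists(st.floats(40, 100), min_size=3, max_size=6))
    @settings(max_examples=200, deadline=None)
    def test_permutation_stable_selected_value(self, vals):
        """The selected value is invariant under input permutation whenever
        the closest pair is unique (the documented tie-break handles the rest)."""
        base = select_replicates(vals).selected_value
        diffs = sorted(
            abs(vals[i] - vals[j]) for i, j in itertools.combinations(range(len(vals)), 2)
        )
        if len(diffs) > 1 and diffs[1] - diffs[0] < 1e-9:
            return  # tied closest pairs: order-dependent by design
        for perm in itertools.islice(itertools.permutations(vals), 12):
            assert select_replicates(list(perm)).selected_value == pytest.approx(base)

    def test_fewer_than_two_raises(self):
        with pytest.raises(InputError):
            select_replicates([62.0])


class TestDensitySiri:
    @pytest.mark.parametrize(
        "w, v, expected", [(66, 60, 1.1), (70, 70, 1.0), (78.1, 69.7, 78.1 / 69.7)]
    )
    def test_density(self, w, v, expected):
        assert body_density(w, v) == pytest.approx(expected, rel=1e-12)

    def test_density_domain(self):
        with pytest.raises(DomainError):
            body_density(-1, 60)

    @pytest.mark.parametrize("d, pct", [(1.1, 0.0), (1.0, 45.0), (0.99, 50.0)])
    def test_siri_values(self, d, pct):
        assert siri_percent_fat(d) == pytest.approx(pct, abs=1e-9)

    def test_siri_strictly_decreasing(self):
        ds = np.linspace(0.95, 1.12, 50)
        pf = [siri_percent_fat(d) for d in ds]
        assert all(a > b for a, b in zip(pf, pf[1:]))

    def test_siri_warns_outside_band(self):
        with pytest.warns(UserWarning):
            siri_percent_fat(1.3)


class TestCalibration:
    def test_identity_when_reference_equals_raw(self):
        raw = [60.0, 65.0, 72.0, 80.0]
        m = fit_bv_calibration(raw, raw)
        assert m.slope == pytest.approx(1.0, abs=1e-12)
        assert m.intercept == pytest.approx(0.0, abs=1e-9)
        assert m.residual_sd == pytest.approx(0.0, abs=1e-9)

    def test_exact_linear_relation_recovered(self):
        raw = np.array([60.0, 65.0, 72.0, 80.0])
        m = fit_bv_calibration(raw, 0.9 * raw + 2.0)
        assert m.slope == pytest.approx(0.9, abs=1e-9)
        assert m.intercept == pytest.approx(2.0, abs=1e-9)
        assert apply_calibration(m, 70.0) == pytest.approx(65.0, abs=1e-9)

    def test_noisy_slope_within_3_se(self):
        rng = np.random.default_rng(77)
        raw = rng.uniform(55, 85, size=50)
        ref = 0.93 * raw + rng.normal(0, 1.0, size=50)
        m = fit_bv_calibration(raw, ref)
        se = m.residual_sd / np.sqrt(((raw - raw.mean()) ** 2).sum())
        assert abs(m.slope - 0.93) < 3 * se

    def test_mean_fitted_equals_mean_reference(self):
        """OLS property: fitted values and reference share the mean on the
        fitting set."""
        rng = np.random.default_rng(3)
        raw = rng.uniform(55, 85, size=20)
        ref = 1.05 * raw - 2 + rng.normal(0, 1, size=20)
        m = fit_bv_calibration(raw, ref)
        fitted = apply_calibration(m, raw)
        assert fitted.mean() == pytest.approx(ref.mean(), abs=1e-9)

    def test_constant_raw_is_singular(self):
        with pytest.raises(SingularFitError):
            fit_bv_calibration([70.0] * 5, [68.0, 69.0, 70.0, 71.0, 72.0])


class TestFatMass:
    @pytest.mark.parametrize(
        "sex, pa, h, bv, expected",
        [
            # independent hand arithmetic of the prediction equation
            (2, 150.0, 1.72, 69.7, 42.5 - 5.73 * 2 - 0.02254 * 150 - 26.3 * 1.72 + 0.4879 * 69.7),
            (1, 0.0, 1.60, 60.7, 42.5 - 5.73 - 26.3 * 1.60 + 0.4879 * 60.7),
            (1, 300.0, 1.55, 55.0, 42.5 - 5.73 - 0.02254 * 300 - 26.3 * 1.55 + 0.4879 * 55.0),
            (2, 0.0, 1.90, 85.0, 42.5 - 11.46 - 26.3 * 1.90 + 0.4879 * 85.0),
            (2, 600.0, 1.65, 70.0, 42.5 - 11.46 - 0.02254 * 600 - 26.3 * 1.65 + 0.4879 * 70.0),
        ],
    )
    def test_matches_hand_arithmetic(self, sex, pa, h, bv, expected):
        est = predict_fat_mass(None, bv, sex_code=sex, pa_min_week=pa, height_m=h)
        assert est.fm_kg == pytest.approx(expected, abs=1e-9)

    def test_worked_examples(self):
        assert predict_fat_mass(None, 69.7, sex_code=2, pa_min_week=150, height_m=1.72
                                ).fm_kg == pytest.approx(16.429, abs=1e-3)
        assert predict_fat_mass(None, 60.7, sex_code=1, pa_min_week=0, height_m=1.60
                                ).fm_kg == pytest.approx(24.306, abs=1e-3)

    def test_linearity_in_each_covariate(self):
        base = predict_fat_mass(None, 65.0, sex_code=1, pa_min_week=100, height_m=1.65).fm_kg
        d_bv = predict_fat_mass(None, 67.0, sex_code=1, pa_min_week=100, height_m=1.65).fm_kg - base
        d_bv2 = predict_fat_mass(None, 69.0, sex_code=1, pa_min_week=100, height_m=1.65).fm_kg - base
        assert d_bv2 == pytest.approx(2 * d_bv, abs=1e-9)
        d_pa = predict_fat_mass(None, 65.0, sex_code=1, pa_min_week=200, height_m=1.65).fm_kg - base
        d_pa2 = predict_fat_mass(None, 65.0, sex_code=1, pa_min_week=300, height_m=1.65).fm_kg - base
        assert d_pa2 == pytest.approx(2 * d_pa, abs=1e-9)

    def test_invalid_sex_code(self):
        with pytest.raises(DomainError):
            predict_fat_mass(None, 65.0, sex_code=3, pa_min_week=0, height_m=1.7)

    def test_estimate_echo_reproduces_value(self):
        est = predict_fat_mass(None, 68.2, sex_code=2, pa_min_week=45, height_m=1.78)
        re = predict_fat_mass(
            None, est.fitted_bv_liters, sex_code=est.sex_code,
            pa_min_week=est.pa_min_week, height_m=est.height_m,
        )
        assert re.fm_kg == est.fm_kg


class TestSubjectRecord:
    def test_bmi_derived(self):
        s = SubjectRecord("S0", 2, 30, 1.72, 78.1, 150)
        assert s.bmi_kg_m2 == pytest.approx(78.1 / 1.72**2, abs=1e-9)

    def test_inclusion_bounds_warn_not_fail(self):
        with pytest.warns(UserWarning):
            SubjectRecord("S1", 1, 30, 1.98, 70.0, 0)
        with pytest.warns(UserWarning):
            SubjectRecord("S2", 1, 30, 1.70, 150.0, 0)


class TestReportBVError:
    def test_worked_example(self):
        out = report_bv_error([72.31], [67.03])
        assert out["absolute_error_l"] == pytest.approx(5.28, abs=1e-9)
        assert out["percent_error"] == pytest.approx(5.28 / 67.03 * 100, abs=1e-9)

    def test_identical_lists_zero(self):
        out = report_bv_error([61.0, 70.0], [61.0, 70.0])
        assert out["absolute_error_l"] == 0.0
        assert out["percent_error"] == 0.0

    def test_single_pair(self):
        out = report_bv_error([61.0], [60.0])
        assert out["absolute_error_l"] == pytest.approx(1.0)
        assert out["percent_error"] == pytest.approx(100.0 / 60.0)

    def test_length_mismatch(self):
        with pytest.raises(InputError):
            report_bv_error([1.0, 2.0], [1.0])
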