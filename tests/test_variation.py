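import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from qgtempo import (
    SpeciesCVTable,
    SpecimenTable,
    ValidationError,
    cv_estimate,
    cv_percentile,
    delta_cv,
    delta_cv_ci,
    pooled_within_sex_cv,
    total_cv_from_rows,
)


def two_point_sample(mean, cv, n=2):
    """n=2 sample with exactly the requested uncorrected CV."""
    d = cv * mean / math.sqrt(2)
    return [mean - d, mean + d]


class TestCVEstimate:
    def test_constant_sample(self):
        assert cv_estimate([10, 10, 10], corrected=False).cv == 0.0

    def test_hand_values(self):
        assert cv_estimate([8, 10, 12], corrected=False).cv == pytest.approx(0.2000)
        assert cv_estimate([8, 10, 12], corrected=True).cv == pytest.approx(0.21667, abs=5e-5)

    def test_correction_auto_by_sample_size(self):
        small = cv_estimate([8.0, 10.0, 12.0])
        large = cv_estimate(list(np.linspace(8, 12, 40)))
        assert small.corrected and not large.corrected

    @given(st.lists(st.floats(min_value=1, max_value=1e4), min_size=2, max_size=30),
           st.floats(min_value=1e-3, max_value=1e3))
    def test_scale_invariance(self, values, k):
        base = cv_estimate(values, corrected=False).cv
        scaled = cv_estimate([k * v for v in values], corrected=False).cv
        assert scaled == pytest.approx(base, rel=1e-9, abs=1e-12)

    def test_translation_changes_cv(self):
        base = cv_estimate([8, 10, 12], corrected=False).cv
        shifted = cv_estimate([18, 20, 22], corrected=False).cv
        assert shifted != pytest.approx(base)

    def test_preconditions(self):
        with pytest.raises(ValidationError):
            cv_estimate([5.0])
        with pytest.raises(ValidationError):
            cv_estimate([-5.0, 3.0])


class TestPooledWithinSexCV:
    def make_table(self, females, males, unknown=()):
        rows = [(f"f{i}", "g", "female", v) for i, v in enumerate(females)]
        rows += [(f"m{i}", "g", "male", v) for i, v in enumerate(males)]
        rows += [(f"u{i}", "g", "unknown", v) for i, v in enumerate(unknown)]
        return SpecimenTable(records=pd.DataFrame(
            rows, columns=["specimen_id", "group", "sex", "value"]))

    def test_hand_example_and_dimorphism_removal(self):
        table = self.make_table([110, 120, 130], [90, 100, 110])
        est = pooled_within_sex_cv(table, corrected=False)
        assert est.cv == pytest.approx(10 / 110, abs=5e-5)  # 0.0909
        total = cv_estimate([90, 100, 110, 110, 120, 130], corrected=False)
        assert total.cv == pytest.approx(0.1286, abs=5e-5)
        assert est.cv < total.cv  # dimorphism contribution removed

    def test_identical_sexes_match_single_sex_cv(self):
        table = self.make_table([90, 100, 110], [90, 100, 110])
        est = pooled_within_sex_cv(table, corrected=False)
        single = cv_estimate([90, 100, 110], corrected=False)
        assert est.cv == pytest.approx(single.cv)

    def test_unknown_sex_excluded_and_counted(self):
        table = self.make_table([110, 120, 130], [90, 100, 110], unknown=[500, 600])
        est = pooled_within_sex_cv(table, corrected=False)
        assert est.n_excluded_unknown_sex == 2
        assert est.cv == pytest.approx(10 / 110, abs=5e-5)

    def test_summary_rows_input(self):
        rows = pd.DataFrame({"sex": ["female", "male"], "n": [3, 3],
                             "mean": [120.0, 100.0], "sd": [10.0, 10.0]})
        est = pooled_within_sex_cv(rows, corrected=False)
        assert est.cv == pytest.approx(10 / 110)

    def test_needs_a_sex_class_with_two(self):
        table = self.make_table([100], [200])
        with pytest.raises(ValidationError):
            pooled_within_sex_cv(table)


class TestTotalCVFromRows:
    def test_matches_direct_computation(self):
        # recombining per-sex summaries must equal the CV of the raw sample
        females, males = [110.0, 120.0, 130.0], [90.0, 100.0, 110.0]
        rows = pd.DataFrame({
            "sex": ["female", "male"], "n": [3, 3],
            "mean": [np.mean(females), np.mean(males)],
            "sd": [np.std(females, ddof=1), np.std(males, ddof=1)]})
        est = total_cv_from_rows(rows, corrected=False)
        direct = cv_estimate(females + males, corrected=False)
        assert est.cv == pytest.approx(direct.cv)


class TestDeltaCV:
    def test_identical_samples(self):
        x = [8.0, 10.0, 12.0]
        assert delta_cv(x, x).delta == 0.0

    def test_constructed_two_point_difference(self):
        a = two_point_sample(100, 0.12)
        b = two_point_sample(100, 0.10)
        assert delta_cv(a, b, corrected=False).delta == pytest.approx(2.0)

    @given(st.lists(st.floats(min_value=1, max_value=100), min_size=2, max_size=10),
           st.lists(st.floats(min_value=1, max_value=100), min_size=2, max_size=10))
    def test_antisymmetry(self, a, b):
        assert delta_cv(a, b).delta == pytest.approx(-delta_cv(b, a).delta, abs=1e-9)


class TestDeltaCVCI:
    def test_identical_samples_interval_contains_zero(self):
        x = list(np.linspace(90, 110, 12))
        r = delta_cv_ci(x, x, n_boot=1000, seed=1)
        assert r.delta == 0.0
        assert r.ci_low <= 0 <= r.ci_high

    def test_seeded_reproducibility(self, rng):
        a = rng.lognormal(4.6, 0.1, 20)
        b = rng.lognormal(4.6, 0.12, 20)
        r1 = delta_cv_ci(a, b, n_boot=1000, seed=99)
        r2 = delta_cv_ci(a, b, n_boot=1000, seed=99)
        assert (r1.ci_low, r1.ci_high) == (r2.ci_low, r2.ci_high)
        r3 = delta_cv_ci(a, b, n_boot=1000, seed=100)
        assert (r3.ci_low, r3.ci_high) != (r1.ci_low, r1.ci_high)

    def test_asymptotic_matches_closed_form(self, rng):
        a = rng.lognormal(4.6, 0.1, 50)
        b = rng.lognormal(4.6, 0.1, 60)
        r = delta_cv_ci(a, b, method="asymptotic", corrected=False)
        cv_a, cv_b = (np.std(x, ddof=1) / np.mean(x) for x in (a, b))
        var = cv_a**2 * (0.5 + cv_a**2) / 50 + cv_b**2 * (0.5 + cv_b**2) / 60
        half = 1.959963984540054 * math.sqrt(var) * 100
        assert r.ci_high - r.ci_low == pytest.approx(2 * half, rel=1e-6)

    def test_bootstrap_asymptotic_agreement_at_large_n(self, rng):
        # midpoint difference < half-width at n = 100 on well-behaved data
        a = rng.lognormal(4.6, 0.10, 100)
        b = rng.lognormal(4.6, 0.08, 100)
        boot = delta_cv_ci(a, b, n_boot=4000, seed=2)
        asym = delta_cv_ci(a, b, method="asymptotic")
        mid_b = (boot.ci_low + boot.ci_high) / 2
        mid_a = (asym.ci_low + asym.ci_high) / 2
        half = (asym.ci_high - asym.ci_low) / 2
        assert abs(mid_b - mid_a) < half

    def test_parameter_validation(self):
        x = [8.0, 10.0, 12.0]
        with pytest.raises(ValidationError):
            delta_cv_ci(x, x, n_boot=100)
        with pytest.raises(ValidationError):
            delta_cv_ci(x, x, method="asymptotic")  # n < 5
        with pytest.raises(ValidationError):
            delta_cv_ci(x, x, method="jackknife")


def comparative_table(cvs, n=50, mean=100.0):
    rows = []
    for i, cv in enumerate(cvs):
        for sex in ("female", "male"):
            rows.append((f"sp{i}", sex, n, mean, cv * mean))
    return SpeciesCVTable(rows=pd.DataFrame(
        rows, columns=["species", "sex", "n", "mean", "sd"]))


class TestCVPercentile:
    def test_extremes_and_median(self):
        table = comparative_table([0.02, 0.04, 0.06, 0.08, 0.10])
        assert cv_percentile(0.01, table, corrected=False).percentile == 0.0
        assert cv_percentile(0.2, table, corrected=False).percentile == 100.0
        assert cv_percentile(0.06, table, corrected=False).percentile == 50.0

    def test_summary_statistics(self):
        table = comparative_table([0.02, 0.04, 0.06])
        res = cv_percentile(0.05, table, corrected=False)
        assert res.n_species == 3
        assert res.cv_min == pytest.approx(0.02)
        assert res.cv_max == pytest.approx(0.06)

    def test_small_comparative_set_rejected(self):
        table = comparative_table([0.05])
        with pytest.raises(ValidationError):
            cv_percentile(0.05, table)


class TestPlot:
    def test_histogram_written(self, tmp_path):
        import matplotlib

        matplotlib.use("Agg")
        from qgtempo import plot_cv_distribution

        table = comparative_table(list(np.linspace(0.02, 0.12, 20)))
        out = tmp_path / "cv.png"
        ax = plot_cv_distribution(table, focal={"H. erectus": 0.08}, path=out)
        assert out.exists()
        assert ax.get_xlabel() == "CV (%)"
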