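import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pulmodens.longitudinal import (
    STATUS_DEGENERATE,
    STATUS_INSUFFICIENT,
    STATUS_OK,
    bonferroni,
    change_tests,
    cohort_test,
    correlation_triangle,
    fisher_z,
    pearson_three_point,
    significance_tier,
    volume_size_prediction,
)
from pulmodens.types import VolumeRange

finite = st.floats(-100, 100, allow_nan=False)


class TestPearson:
    def test_perfect_linear(self):
        r, status = pearson_three_point([1, 2, 3], [2, 4, 6])
        assert status == STATUS_OK and r == pytest.approx(1.0)

    def test_zero_variance_is_degenerate(self):
        _, status = pearson_three_point([1, 2, 3], [5, 5, 5])
        assert status == STATUS_DEGENERATE

    def test_missing_pair_gives_insufficient(self):
        _, status = pearson_three_point([1, 2, np.nan], [1, 2, 3])
        assert status == STATUS_INSUFFICIENT

    @given(
        x=st.lists(finite, min_size=3, max_size=3, unique=True),
        y=st.lists(finite, min_size=3, max_size=3, unique=True),
        a=st.floats(0.1, 10),
        b=finite,
    )
    def test_affine_invariance_and_sign_flip(self, x, y, a, b):
        r0, s0 = pearson_three_point(x, y)
        if s0 != STATUS_OK:
            return
        r1, _ = pearson_three_point([a * v + b for v in x], y)
        r2, _ = pearson_three_point([-v for v in x], y)
        assert r1 == pytest.approx(r0, abs=1e-9)
        assert r2 == pytest.approx(-r0, abs=1e-9)

    def test_matches_covariance_oracle_on_random_triples(self, rng):
        for _ in range(100):
            x, y = rng.normal(size=3), rng.normal(size=3)
            r, status = pearson_three_point(x, y)
            cov = np.mean((x - x.mean()) * (y - y.mean()))
            oracle = cov / (x.std() * y.std())
            assert status == STATUS_OK
            assert r == pytest.approx(oracle, abs=1e-12)


class TestFisherZ:
    def test_fixed_points(self):
        assert fisher_z(0.0) == 0.0
        assert fisher_z(0.5) == pytest.approx(0.5 * math.log(3))

    def test_clamp_keeps_unit_correlation_finite(self):
        z = fisher_z(1.0)
        assert math.isfinite(z)
        assert z == pytest.approx(math.atanh(1 - 1e-7))
        assert fisher_z(-1.0) == -z

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fisher_z(1.5)

    @given(r=st.floats(-0.999, 0.999))
    def test_odd_and_increasing(self, r):
        assert fisher_z(-r) == pytest.approx(-fisher_z(r), abs=1e-12)
        assert fisher_z(min(r + 1e-3, 0.9999)) > fisher_z(r)


class TestBonferroni:
    @pytest.mark.parametrize(
        "p,m,expected",
        [(0.003, 10, 0.03), (0.005, 10, 0.05), (0.029, 10, 0.29),
         (0.042, 10, 0.42), (0.5, 10, 1.0)],
    )
    def test_examples_and_cap(self, p, m, expected):
        assert bonferroni(p, m) == pytest.approx(expected)

    @given(p=st.floats(0, 1), m1=st.integers(1, 50), m2=st.integers(1, 50))
    def test_monotone_and_bounded(self, p, m1, m2):
        assert 0 <= bonferroni(p, m1) <= 1
        lo, hi = sorted((m1, m2))
        assert bonferroni(p, lo) <= bonferroni(p, hi)

    def test_tiers(self):
        assert significance_tier(0.005) == "high"
        assert significance_tier(0.02) == "moderate"
        assert significance_tier(0.2) == "ns"


class TestCohortTest:
    def test_zero_variance_zero_mean_reports_one(self):
        t, p, n = cohort_test([0.0, 0.0, 0.0])
        assert p == 1.0 and n == 3

    def test_insufficient_patients(self):
        _, p, n = cohort_test([0.5])
        assert math.isnan(p) and n == 1

    def test_power_under_planted_effect(self, rng):
        """z ~ N(0.5, 0.1), n=40: the right-tailed test must essentially
        always reject at far below 0.001."""
        hits = sum(
            cohort_test(rng.normal(0.5, 0.1, size=40))[1] < 1e-3
            for _ in range(200)
        )
        assert hits >= 198

    def test_type_one_error_near_nominal(self, rng):
        """Standard-normal z, n=40: rejection rate at alpha=0.05 stays within
        Monte-Carlo error of nominal."""
        reps = 2000
        rate = (
            sum(cohort_test(rng.normal(0, 1, size=40))[1] < 0.05 for _ in range(reps))
            / reps
        )
        assert rate == pytest.approx(0.05, abs=0.02)


def _df(rows, cols):
    return pd.DataFrame(rows, columns=cols)


def _cohort_frames(n_rho_by_patient, pft_by_patient, parameter="dlco", label="V65-45%"):
    den_rows, pft_rows = [], []
    for pid, xs in n_rho_by_patient.items():
        for tp, x in zip(("tpre", "t3m", "t6m"), xs):
            if not np.isnan(x):
                den_rows.append({"patient_id": pid, "range": label,
                                 "timepoint": tp, "n_rho": x})
    for pid, ys in pft_by_patient.items():
        for tp, y in zip(("tpre", "t3m", "t6m"), ys):
            pft_rows.append({"patient_id": pid, "timepoint": tp,
                             parameter: y,
                             ("fev1" if parameter == "dlco" else "dlco"): 2.0})
    return (
        _df(den_rows, ["patient_id", "range", "timepoint", "n_rho"]),
        _df(pft_rows, ["patient_id", "timepoint", "dlco", "fev1"]),
    )


class TestChangeTests:
    def test_no_change_reports_zero_and_p_one(self):
        den, pft = _cohort_frames(
            {f"P{i}": (0.9, 0.9, 0.9) for i in range(5)},
            {f"P{i}": (5.0, 5.0, 5.0) for i in range(5)},
        )
        out = change_tests(den, pft, quantities=["dlco", "V65-45%"])
        assert (out["mean_relative_change_pct"] == 0).all()
        assert (out["p_value"] == 1.0).all()

    def test_recovers_planted_decline(self, rng):
        """A uniform -5% DLCO change with small noise, n=40: mean within
        +-1 percentage point and p < 0.01."""
        pft = {}
        for i in range(40):
            base = 5.0 * (1 + rng.normal(0, 0.2))
            pft[f"P{i}"] = (
                base,
                base * (0.95 + rng.normal(0, 0.01)),
                base * (0.95 + rng.normal(0, 0.01)),
            )
        den, pft_df = _cohort_frames({p: (0.9, 0.9, 0.9) for p in pft}, pft)
        out = change_tests(den, pft_df, quantities=["dlco"])
        t3m = out[out["comparison"] == "tpre->t3m"].iloc[0]
        assert t3m["mean_relative_change_pct"] == pytest.approx(-5.0, abs=1.0)
        assert t3m["p_value"] < 0.01

    def test_quantities_are_independent(self, rng):
        """Constant n_rho with declining PFT: only the PFT change test fires."""
        pft = {f"P{i}": (5.0 * (1 + rng.normal(0, 0.1)),) * 1 for i in range(20)}
        pft = {
            p: (v[0], v[0] * 0.9 * (1 + rng.normal(0, 0.01)), v[0] * 0.9)
            for p, v in pft.items()
        }
        den, pft_df = _cohort_frames({p: (0.9, 0.9, 0.9) for p in pft}, pft)
        out = change_tests(den, pft_df, quantities=["dlco", "V65-45%"]).set_index(
            ["quantity", "comparison"]
        )
        assert out.loc[("dlco", "tpre->t3m"), "p_value"] < 0.01
        assert out.loc[("V65-45%", "tpre->t3m"), "p_value"] == 1.0


class TestTriangleAndPrediction:
    def test_single_cell_matches_full_triangle(self, small_cohort):
        from pulmodens.density import density_table
        from pulmodens.dose_volumes import triangle_ranges
        from pulmodens.io import pft_dataframe

        cohort, _ = small_cohort
        den = density_table(cohort, triangle_ranges())
        pft = pft_dataframe(cohort)
        full = correlation_triangle(den, pft, "dlco", family_size=40)
        single = correlation_triangle(
            den, pft, "dlco", pairs=[VolumeRange(65, 45)], family_size=40
        )
        row_full = full[full["range"] == "V65-45%"].iloc[0]
        row_single = single.iloc[0]
        for col in ("n_patients", "mean_z", "t_statistic", "p_raw", "p_corrected"):
            assert row_single[col] == pytest.approx(row_full[col], nan_ok=True)

    def test_prediction_degenerate_sizes_reported(self):
        sizes = _df(
            [{"patient_id": f"P{i}", "range": "V65-45%",
              "volume_ml": 10.0, "relative_size_pct": 12.0} for i in range(5)],
            ["patient_id", "range", "volume_ml", "relative_size_pct"],
        )
        _, pft = _cohort_frames({}, {f"P{i}": (5.0, 4.0 + 0.1 * i, 4.5) for i in range(5)})
        out = volume_size_prediction(sizes, pft, [VolumeRange(65, 45)])
        assert out.iloc[0]["status"] == STATUS_DEGENERATE

    def test_prediction_recovers_planted_negative_slope(self, rng):
        """Patients whose mid-dose volume is larger decline more: r < 0 and
        small p."""
        sizes_rows, pft = [], {}
        for i in range(40):
            size = rng.uniform(5, 30)
            sizes_rows.append({"patient_id": f"P{i}", "range": "V65-45%",
                               "volume_ml": size, "relative_size_pct": size})
            base = 5.0 * (1 + rng.normal(0, 0.2))
            decline = 0.01 * size + rng.normal(0, 0.02)
            pft[f"P{i}"] = (base, base * (1 - decline), base)
        sizes = _df(sizes_rows, ["patient_id", "range", "volume_ml",
                                 "relative_size_pct"])
        _, pft_df = _cohort_frames({}, pft)
        out = volume_size_prediction(sizes, pft_df, [VolumeRange(65, 45)])
        assert out.iloc[0]["r"] < -0.5
        assert out.iloc[0]["p_raw"] < 0.01

    def test_prediction_null_under_permutation(self, rng):
        """Shuffling which patient owns which volume size kills the
        association on average."""
        rs = []
        for _ in range(50):
            sizes_rows, pft = [], {}
            perm = rng.permutation(30)
            raw_sizes = rng.uniform(5, 30, size=30)
            for i in range(30):
                sizes_rows.append(
                    {"patient_id": f"P{i}", "range": "V65-45%",
                     "volume_ml": 1.0, "relative_size_pct": raw_sizes[perm[i]]}
                )
                base = 5.0
                decline = 0.01 * raw_sizes[i] + rng.normal(0, 0.02)
                pft[f"P{i}"] = (base, base * (1 - decline), base)
            sizes = _df(sizes_rows, ["patient_id", "range", "volume_ml",
                                     "relative_size_pct"])
            _, pft_df = _cohort_frames({}, pft)
            out = volume_size_prediction(sizes, pft_df, [VolumeRange(65, 45)])
            rs.append(out.iloc[0]["r"])
        assert abs(np.mean(rs)) < 0.15
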