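"""BMI computation, log-normalisation and stratified residualisation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from twinpaths import compute_bmi, log_normalize, residualize_stratum
from twinpaths.preprocessing import (
    assign_age_bin,
    build_panel,
    deduplicate_bins,
    sample_skewness,
)


class TestComputeBMI:
    @pytest.mark.parametrize(
        "w,h,expected",
        [(60, 150, 60 / 1.5**2), (50, 200, 12.5), (77.7, 100, 77.7)],
    )
    def test_direct_formula(self, w, h, expected):
        assert compute_bmi(w, h) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("w,h", [(0, 150), (-3, 150), (60, 0), (60, np.inf), (np.nan, 150)])
    def test_rejects_nonpositive_or_nonfinite(self, w, h):
        with pytest.raises(ValueError):
            compute_bmi(w, h)

    @given(
        w=st.floats(1, 200),
        h=st.floats(40, 220),
        s=st.floats(0.5, 2.0),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_scale_consistency(self, w, h, s):
        base = compute_bmi(w, h)
        assert compute_bmi(2 * w, h) == pytest.approx(2 * base, rel=1e-9)
        assert compute_bmi(w, s * h) == pytest.approx(base / s**2, rel=1e-9)


class TestLogNormalize:
    def test_symmetric_logs_have_zero_skewness(self):
        logs, _, after = log_normalize(np.exp([1.0, 2.0, 3.0]))
        assert np.allclose(logs, [1, 2, 3])
        assert after == pytest.approx(0.0, abs=1e-12)

    def test_lognormal_sample_normalized(self):
        # closed-form skewness of LN(0, 0.5): (e^{s2}+2) sqrt(e^{s2}-1) ~ 1.75
        rng = np.random.default_rng(4)
        x = rng.lognormal(0.0, 0.5, size=10000)
        _, before, after = log_normalize(x)
        assert before > 1.0
        assert abs(after) < 0.1

    def test_constant_sample_skewness_zero(self):
        _, before, after = log_normalize(np.full(20, 3.3))
        assert before == 0.0 and after == 0.0
        assert sample_skewness([5.0]) == 0.0

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            log_normalize([1.0, 0.0, 2.0])


class TestResidualize:
    def test_constant_covariates_center_only(self):
        y = np.array([1.0, 3.0, 5.0, 11.0])
        cov = pd.DataFrame(
            {"exact_age": 7.0, "birth_year": 1990, "cohort": "x"}, index=range(4)
        )
        r = residualize_stratum(y, cov)
        assert np.allclose(r, y - y.mean(), atol=1e-10)

    def test_perfect_linear_fit_gives_zero_residuals(self):
        age = np.linspace(6.6, 7.4, 30)
        y = 2.0 + 0.5 * age
        cov = pd.DataFrame({"exact_age": age, "birth_year": 1990, "cohort": "x"})
        assert np.max(np.abs(residualize_stratum(y, cov))) < 1e-10

    def test_matches_normal_equations_oracle(self):
        """Residuals equal (I - X (X'X)^-1 X') y via explicit elimination."""
        rng = np.random.default_rng(77)
        n = 200
        cov = pd.DataFrame(
            {
                "exact_age": rng.uniform(6.5, 7.5, n),
                "birth_year": rng.integers(1980, 2005, n),
                "cohort": rng.choice(["a", "b", "c"], n),
            }
        )
        y = rng.normal(size=n)
        X = np.column_stack(
            [
                np.ones(n),
                cov["exact_age"],
                cov["birth_year"],
                (cov["cohort"] == "b").astype(float),
                (cov["cohort"] == "c").astype(float),
            ]
        )
        # explicit Gauss-Jordan solve of the normal equations
        A = X.T @ X
        b = X.T @ y
        aug = np.hstack([A, b[:, None]])
        k = A.shape[0]
        for i in range(k):
            piv = i + np.argmax(np.abs(aug[i:, i]))
            aug[[i, piv]] = aug[[piv, i]]
            aug[i] = aug[i] / aug[i, i]
            for j in range(k):
                if j != i:
                    aug[j] -= aug[j, i] * aug[i]
        beta = aug[:, -1]
        oracle = y - X @ beta
        assert np.max(np.abs(residualize_stratum(y, cov) - oracle)) < 1e-8

    def test_idempotent(self):
        rng = np.random.default_rng(5)
        cov = pd.DataFrame(
            {
                "exact_age": rng.uniform(3.5, 4.5, 80),
                "birth_year": rng.integers(1985, 2000, 80),
                "cohort": rng.choice(["a", "b"], 80),
            }
        )
        y = rng.normal(size=80)
        once = residualize_stratum(y, cov)
        twice = residualize_stratum(once, cov)
        assert np.max(np.abs(once - twice)) < 1e-10

    def test_collinear_cohort_dropped(self, caplog):
        # two cohort labels perfectly aligned with birth_year
        cov = pd.DataFrame(
            {
                "exact_age": [7.1, 7.2, 6.9, 7.0],
                "birth_year": [1990, 1990, 2000, 2000],
                "cohort": ["a", "a", "b", "b"],
            }
        )
        y = np.array([0.1, 0.4, -0.2, 0.3])
        r = residualize_stratum(y, cov)
        assert abs(r.mean()) < 1e-10

    def test_tiny_stratum_centers(self):
        cov = pd.DataFrame(
            {"exact_age": [7.0, 7.4], "birth_year": [1990, 1991], "cohort": ["a", "b"]}
        )
        y = np.array([1.0, 2.0])
        assert np.allclose(residualize_stratum(y, cov), [-0.5, 0.5])


class TestBinning:
    def test_round_and_clip(self):
        assert assign_age_bin([0.2, 1.4, 7.5, 19.6]).tolist() == [1, 1, 8, 19]

    def test_duplicate_bin_keeps_closest_to_center(self):
        rec = pd.DataFrame(
            {
                "family_id": ["f"] * 3,
                "twin_index": [1] * 3,
                "exact_age": [6.8, 7.1, 7.4],
                "height_cm": [120.0, 121.0, 122.0],
            }
        )
        out = deduplicate_bins(rec)
        assert len(out) == 1
        assert out.loc[0, "height_cm"] == 121.0  # exact age 7.1 nearest bin 7


def test_panel_strata_are_centered_and_traceable(small_panel, small_cohort):
    means = small_panel.groupby(["trait", "age", "sex"])["value"].mean()
    assert means.abs().max() < 1e-8
    # each residual traces to exactly one source record
    n_source = small_cohort.groupby(
        ["family_id", "twin_index", "age_years"]
    ).ngroups
    per_trait = small_panel.groupby("trait").size()
    assert (per_trait <= n_source).all()
    assert small_panel.groupby(
        ["trait", "family_id", "twin_index", "age"]
    ).size().max() == 1
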