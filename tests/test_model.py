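"""Expected covariances, FIML likelihood, and ML estimation."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from twinpaths import (
    CholeskyPaths,
    CholeskyTwinModel,
    PairedAgeData,
    expected_pair_covariance,
    pair_loglikelihood,
    paired_from_panel,
)
from twinpaths.model import GROUP_SEXES, expected_pair_mean

from conftest import balanced_pairs, structural_config
from twinpaths import build_panel, simulate_cohort


def _univariate_paths(a2, c2, e2, total=1.0):
    La = np.array([[np.sqrt(a2 * total)]])
    Lc = np.array([[np.sqrt(c2 * total)]])
    Le = np.array([[np.sqrt(e2 * total)]])
    return CholeskyPaths(
        L_A={"M": La, "F": La},
        L_C={"M": Lc, "F": Lc},
        L_E={"M": Le, "F": Le},
        means={(zc, s): np.zeros(1) for zc in ("MZ", "DZ") for s in ("M", "F")},
        rg_os=1.0,
    )


def _bivariate_paths(L_A, L_C, L_E, rg_os=1.0):
    return CholeskyPaths(
        L_A={"M": L_A, "F": L_A},
        L_C={"M": L_C, "F": L_C},
        L_E={"M": L_E, "F": L_E},
        means={(zc, s): np.zeros(2) for zc in ("MZ", "DZ") for s in ("M", "F")},
        rg_os=rg_os,
    )


class TestExpectedCovariance:
    def test_univariate_mz_dz(self):
        paths = _univariate_paths(0.6, 0.2, 0.2)
        mz = expected_pair_covariance(paths, "MZM")
        dz = expected_pair_covariance(paths, "DZF")
        assert np.allclose(mz, [[1.0, 0.8], [0.8, 1.0]])
        assert np.allclose(dz, [[1.0, 0.5], [0.5, 1.0]])

    def test_bivariate_cross_block_by_hand(self):
        L_A = np.array([[1.0, 0.0], [0.5, np.sqrt(0.75)]])
        zero = np.zeros((2, 2))
        paths = _bivariate_paths(L_A, zero, zero)
        sig = expected_pair_covariance(paths, "MZM")
        A = L_A @ L_A.T
        # implied genetic correlation 0.5; MZ cross-twin cross-age entry 0.5
        assert A[0, 1] / np.sqrt(A[0, 0] * A[1, 1]) == pytest.approx(0.5)
        assert sig[0, 3] == pytest.approx(0.5)
        assert np.allclose(sig[:2, 2:], A)

    def test_osdz_with_rg1_equals_ssdz(self):
        L_A = np.array([[0.8, 0.0], [0.3, 0.6]])
        L_E = np.array([[0.5, 0.0], [0.1, 0.45]])
        paths = _bivariate_paths(L_A, np.zeros((2, 2)), L_E, rg_os=1.0)
        assert np.allclose(
            expected_pair_covariance(paths, "OSDZ"),
            expected_pair_covariance(paths, "DZM"),
        )

    def test_always_positive_semidefinite(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            tril = lambda: np.tril(rng.normal(size=(2, 2)))
            paths = _bivariate_paths(tril(), tril(), tril(), rg_os=rng.uniform())
            for g in GROUP_SEXES:
                w = np.linalg.eigvalsh(expected_pair_covariance(paths, g))
                assert w.min() > -1e-10


class TestLikelihood:
    def test_standard_normal_mode_value(self):
        paths = _bivariate_paths(
            np.zeros((2, 2)), np.zeros((2, 2)), np.eye(2)
        )
        data = PairedAgeData(y=np.zeros((1, 4)), zygosity=np.array(["MZM"]))
        ll = pair_loglikelihood(data, paths)
        assert ll == pytest.approx(-2.0 * np.log(2 * np.pi), abs=1e-12)

    def test_additivity_over_families(self):
        paths = _bivariate_paths(
            np.array([[0.7, 0.0], [0.3, 0.6]]),
            np.zeros((2, 2)),
            np.array([[0.6, 0.0], [0.0, 0.7]]),
        )
        rng = np.random.default_rng(3)
        y = rng.normal(size=(2, 4))
        both = pair_loglikelihood(
            PairedAgeData(y=y, zygosity=np.array(["MZM", "DZF"])), paths
        )
        single = sum(
            pair_loglikelihood(
                PairedAgeData(y=y[i : i + 1], zygosity=np.array([g])), paths
            )
            for i, g in enumerate(["MZM", "DZF"])
        )
        assert both == pytest.approx(single, abs=1e-10)

    def test_matches_brute_force_density_with_missingness(self):
        """50 random families with random masks vs scipy's mvn density."""
        rng = np.random.default_rng(19)
        L_A = np.tril(rng.normal(size=(2, 2))) + 2 * np.eye(2)
        L_C = 0.3 * (np.tril(rng.normal(size=(2, 2))) + np.eye(2))
        L_E = np.tril(rng.normal(size=(2, 2))) * 0.2 + 0.8 * np.eye(2)
        paths = _bivariate_paths(L_A, L_C, L_E, rg_os=0.7)
        for zc, s in paths.means:
            paths.means[(zc, s)] = rng.normal(size=2) * 0.3
        groups = rng.choice(list(GROUP_SEXES), size=50)
        y = rng.normal(size=(50, 4)) * 2
        for i in range(50):
            # random mask leaving at least one value per twin
            drop = rng.uniform(size=4) < 0.3
            y[i, drop] = np.nan
        data = PairedAgeData(y=y, zygosity=groups)
        brute = 0.0
        for i in range(data.n_families):
            g = data.zygosity[i]
            sig = expected_pair_covariance(paths, g)
            mu = expected_pair_mean(paths, g)
            obs = ~np.isnan(data.y[i])
            brute += multivariate_normal.logpdf(
                data.y[i][obs], mu[obs], sig[np.ix_(obs, obs)]
            )
        assert pair_loglikelihood(data, paths) == pytest.approx(brute, abs=1e-8)

    def test_drops_families_with_unobserved_cotwin(self):
        y = np.array(
            [[0.1, 0.2, 0.3, 0.4], [np.nan, np.nan, 0.3, 0.4], [0.5, np.nan, 0.1, 0.2]]
        )
        data = PairedAgeData(y=y, zygosity=np.array(["MZM"] * 3))
        assert data.n_families == 2
        assert data.n_dropped == 1


@pytest.fixture(scope="module")
def ae_fit(bivariate_panel):
    data = paired_from_panel(bivariate_panel, "logbmi", (8, 12))
    return CholeskyTwinModel(data, model_tag="AE", design="five_group").fit()


class TestFit:
    def test_parameter_recovery(self, ae_fit):
        # generator truth: a2 = 0.6, e2 = 0.4, rA = 0.8 (MC noise at 600/group)
        assert ae_fit.converged
        for sex in ("M", "F"):
            sh = ae_fit.standardized_components(sex)
            assert sh["A"] == pytest.approx([0.6, 0.6], abs=0.1)
            assert ae_fit.quantity("rA", sex) == pytest.approx(0.8, abs=0.1)
            assert abs(sum(sh[c][0] for c in "ACE") - 1) < 1e-8
            assert abs(ae_fit.quantity("rP", sex)) <= 1

    def test_fit_deterministic(self, bivariate_panel):
        data = paired_from_panel(bivariate_panel, "logbmi", (8, 12))
        m = CholeskyTwinModel(data, model_tag="AE", design="five_group")
        r1, r2 = m.fit(), m.fit()
        assert np.max(np.abs(r1.params - r2.params)) < 1e-10

    def test_ace_nests_ae(self, bivariate_panel):
        data = paired_from_panel(bivariate_panel, "logbmi", (8, 12))
        ll_ae = CholeskyTwinModel(data, "AE", "five_group").fit().llf
        ll_ace = CholeskyTwinModel(data, "ACE", "five_group").fit().llf
        assert ll_ace >= ll_ae - 1e-6

    def test_sign_convention_canonical(self, ae_fit):
        # E flips per sex; A/C columns flip jointly across sexes (the
        # opposite-sex block ties them), keyed on the male diagonal
        assert np.all(np.diag(ae_fit.paths.L_A["M"]) >= 0)
        for s in ("M", "F"):
            assert np.all(np.diag(ae_fit.paths.L_E[s]) >= 0)

    def test_canonicalization_preserves_likelihood(self, bivariate_panel):
        from twinpaths import pair_loglikelihood

        data = paired_from_panel(bivariate_panel, "logbmi", (8, 12))
        m = CholeskyTwinModel(data, "ACE", "five_group")
        rng = np.random.default_rng(55)
        theta = m.start_params() * (1 + 0.2 * rng.standard_normal(m.k_params))
        ll_raw = pair_loglikelihood(data, m.unpack(theta))
        ll_canon = pair_loglikelihood(data, m.unpack(m._canonicalize(theta)))
        assert ll_canon == pytest.approx(ll_raw, abs=1e-8)

    def test_five_group_requires_all_groups(self, bivariate_panel):
        sub = bivariate_panel[bivariate_panel["zygosity_group"] != "OSDZ"]
        data = paired_from_panel(sub, "logbmi", (8, 12))
        with pytest.raises(ValueError, match="five-group"):
            CholeskyTwinModel(data, "AE", "five_group")

    def test_too_few_pairs_rejected(self, bivariate_panel):
        data = paired_from_panel(bivariate_panel, "logbmi", (8, 12))
        idx = np.concatenate(
            [np.flatnonzero(data.zygosity == g)[:4] for g in ("MZM", "DZM")]
        )
        tiny = PairedAgeData(
            y=data.y[idx], zygosity=data.zygosity[idx], var_names=data.var_names
        )
        with pytest.raises(ValueError, match="identify"):
            CholeskyTwinModel(tiny, "AE", "single_sex")

    def test_summary_mentions_key_quantities(self, ae_fit):
        text = ae_fit.summary()
        assert "rA" in text and "log-likelihood" in text and "rg_os" in text


def test_univariate_fit_recovers_shares():
    cfg = structural_config(
        shares=(0.6, 0.2, 0.2), r_a=0.8, r_c=0.5, r_e=0.2, ages=[8],
        n_pairs=balanced_pairs(3000, groups=("MZM", "DZM")),
    )
    panel = build_panel(simulate_cohort(cfg, seed=23))
    data = paired_from_panel(panel, "logbmi", (8,))
    res = CholeskyTwinModel(data, "ACE", "single_sex").fit()
    sh = res.standardized_components()
    assert sh["A"][0] == pytest.approx(0.6, abs=0.08)
    assert sh["C"][0] == pytest.approx(0.2, abs=0.06)
    assert sh["E"][0] == pytest.approx(0.2, abs=0.04)
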