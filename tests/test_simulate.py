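"""Generator structure: determinism, record invariants, implied moments."""

import numpy as np
import pandas as pd
import pytest

from twinpaths import ConfigError, SimulationConfig, pairs_from_total, simulate_cohort
from twinpaths.defaults import power_decay_matrix
from twinpaths.simulate import matrix_sqrt_psd

from conftest import balanced_pairs, structural_config


def _pair_values(records, trait="logbmi"):
    """(twin1, twin2) value arrays per family at each age, NaN if missing."""
    rec = records.copy()
    if trait == "logbmi":
        rec["val"] = np.log(rec["weight_kg"] / (rec["height_cm"] / 100) ** 2)
    else:
        rec["val"] = rec["height_cm"]
    wide = rec.pivot_table(
        index="family_id", columns=["twin_index", "age_years"], values="val",
        aggfunc="first",
    )
    return wide


def test_identical_seed_identical_records():
    cfg = SimulationConfig(n_pairs=pairs_from_total(80), ages=[2, 7])
    a = simulate_cohort(cfg, seed=5)
    b = simulate_cohort(cfg, seed=5)
    pd.testing.assert_frame_equal(a, b)
    c = simulate_cohort(cfg, seed=6)
    assert not a["height_cm"].equals(c["height_cm"])


def test_record_invariants():
    cfg = SimulationConfig(n_pairs=pairs_from_total(120), ages=[1, 5, 19], seed=3)
    rec = simulate_cohort(cfg)
    assert (rec["height_cm"] > 0).all() and (rec["weight_kg"] > 0).all()
    assert set(rec["twin_index"]) == {1, 2}
    per_fam = rec.groupby("family_id")["twin_index"].nunique()
    assert (per_fam <= 2).all()
    sexes = rec.groupby(["family_id", "twin_index"])["sex"].first().unstack()
    zyg = rec.groupby("family_id")["zygosity_group"].first()
    both = sexes.dropna()
    os = both[zyg.loc[both.index] == "OSDZ"]
    assert (os[1] == "M").all() and (os[2] == "F").all()
    mz = both[zyg.loc[both.index].isin(["MZM", "MZF"])]
    assert (mz[1] == mz[2]).all()
    # age bins stay inside the configured set, exact ages within half a year
    assert set(rec["age_years"]) <= {1, 5, 19}
    assert (np.abs(rec["exact_age"] - rec["age_years"]) < 0.5).all()


def test_no_familial_component_gives_zero_cross_twin_correlation():
    n = 4000
    cfg = structural_config(
        shares=(0.0, 0.0, 1.0), r_a=0.5, r_c=0.5, r_e=0.3,
        ages=[4, 9], n_pairs=balanced_pairs(n),
    )
    wide = _pair_values(simulate_cohort(cfg, seed=13))
    for g in ("MZM", "DZF", "OSDZ"):
        sub = wide[wide.index.str.startswith(g)]
        for age in (4, 9):
            r = np.corrcoef(sub[(1, age)], sub[(2, age)])[0, 1]
            assert abs(r) < 3.0 / np.sqrt(len(sub))


def test_mz_intraclass_correlation_matches_a2_plus_c2():
    """a2=0.6, c2=0.2 => model-implied rMZ = 0.8, recovered within MC error."""
    cfg = structural_config(
        shares=(0.6, 0.2, 0.2), r_a=0.8, r_c=0.5, r_e=0.2,
        ages=[8], n_pairs=balanced_pairs(20000, groups=("MZM",)),
    )
    wide = _pair_values(simulate_cohort(cfg, seed=17))
    r = np.corrcoef(wide[(1, 8)], wide[(2, 8)])[0, 1]
    assert abs(r - 0.8) < 0.02


def test_dz_cross_twin_covariance_structure():
    """DZ cross-twin cov of the standardized phenotype is a2/2*R_A + c2*R_C."""
    ages = [3, 8, 13]
    a2, c2 = 0.5, 0.3
    R_A = power_decay_matrix(ages, 0.9)
    R_C = power_decay_matrix(ages, 0.7)
    cfg = structural_config(
        shares=(a2, c2, 0.2), r_a=R_A, r_c=R_C, r_e=0.2,
        ages=ages, n_pairs=balanced_pairs(10000, groups=("DZM",)),
    )
    rec = simulate_cohort(cfg, seed=29)
    wide = _pair_values(rec)
    mu = cfg.means["logbmi"]["M"][:, 0]
    sd = cfg.means["logbmi"]["M"][:, 1]
    z1 = (wide[1][ages].to_numpy() - mu) / sd
    z2 = (wide[2][ages].to_numpy() - mu) / sd
    emp = (z1.T @ z2) / len(z1)
    expected = 0.5 * a2 * R_A + c2 * R_C
    assert np.max(np.abs((emp + emp.T) / 2 - expected)) < 0.03


def test_total_variance_and_zygosity_equality():
    """Per-age variance matches calibration (<5% rel. err.) and MZ == DZ."""
    cfg = structural_config(
        shares=(0.6, 0.2, 0.2), r_a=0.8, r_c=0.5, r_e=0.2, ages=[5, 15],
        n_pairs=balanced_pairs(10000, groups=("MZM", "DZM")),
    )
    rec = simulate_cohort(cfg, seed=31)
    rec["logbmi"] = np.log(rec["weight_kg"] / (rec["height_cm"] / 100) ** 2)
    for age in (5, 15):
        i = cfg.ages.index(age)
        target = cfg.means["logbmi"]["M"][i, 1] ** 2
        by_zyg = {}
        for g in ("MZM", "DZM"):
            sub = rec[(rec["age_years"] == age) & (rec["zygosity_group"] == g)]
            v = sub["logbmi"].var(ddof=1)
            assert abs(v - target) / target < 0.05
            by_zyg[g] = v
        assert abs(by_zyg["MZM"] - by_zyg["DZM"]) / target < 0.05


def test_latent_a_part_has_configured_cross_age_correlation():
    ages = [2, 6, 11]
    R_A = power_decay_matrix(ages, 0.85)
    cfg = structural_config(
        shares=(0.7, 0.1, 0.2), r_a=R_A, r_c=0.5, r_e=0.2, ages=ages,
        n_pairs=balanced_pairs(12000, groups=("MZF",)),
    )
    _, latents = simulate_cohort(cfg, seed=37, return_latent=True)
    a1, _ = latents[("MZF", "logbmi", "A")]
    emp = np.corrcoef(a1, rowvar=False)
    assert np.max(np.abs(emp - R_A)) < 0.03


def test_bad_configs_rejected_with_named_matrix():
    bad_R = np.array([[1.0, 0.99], [0.99, 1.0]])
    bad_R[0, 1] = 1.2  # symmetric but indefinite
    bad_R[1, 0] = 1.2
    with pytest.raises(ConfigError, match="R_A"):
        structural_config(
            shares=(0.5, 0.2, 0.3), r_a=bad_R, r_c=0.5, r_e=0.2,
            ages=[4, 9], n_pairs=balanced_pairs(10),
        )
    with pytest.raises(ConfigError, match="sum to 1"):
        structural_config(
            shares=(0.5, 0.2, 0.2), r_a=0.5, r_c=0.5, r_e=0.2,
            ages=[4, 9], n_pairs=balanced_pairs(10),
        )
    with pytest.raises(ConfigError, match="rg_os"):
        structural_config(
            shares=(0.5, 0.2, 0.3), r_a=0.5, r_c=0.5, r_e=0.2,
            ages=[4, 9], n_pairs=balanced_pairs(10), rg_os=1.4,
        )


def test_matrix_sqrt_tolerates_semidefinite_input():
    R = np.ones((3, 3))  # rank one, eigenvalues (3, 0, 0)
    S = matrix_sqrt_psd(R)
    assert np.allclose(S @ S, R, atol=1e-10)
    with pytest.raises(ConfigError, match="positive semidefinite"):
        matrix_sqrt_psd(np.array([[1.0, 2.0], [2.0, 1.0]]))


def test_weight_encodes_logbmi_exactly(small_cohort):
    implied = np.log(
        small_cohort["weight_kg"] / (small_cohort["height_cm"] / 100) ** 2
    )
    assert np.isfinite(implied).all()
    # BMI near the calibrated range for children (log scale ~ log 13..30)
    assert implied.between(np.log(9), np.log(40)).all()
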