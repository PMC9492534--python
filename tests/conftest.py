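"""Shared fixtures: small seeded cohorts and panels built at test time."""

from __future__ import annotations

import numpy as np
import pytest

from twinpaths import SimulationConfig, build_panel, pairs_from_total, simulate_cohort


def structural_config(
    shares,
    r_a,
    r_c,
    r_e,
    ages,
    n_pairs,
    rg_os=1.0,
    missingness=0.0,
    nuisance=False,
    dz_offset=0.0,
):
    """Config with explicit A/C/E structure and (by default) no nuisance signal.

    ``shares`` is a single (a2, c2, e2) triple applied to every trait, sex
    and age; ``r_a``/``r_c``/``r_e`` are either scalars (constant cross-age
    correlation, exchangeable structure) or full matrices.
    """
    ages = list(ages)
    m = len(ages)

    def _mat(r):
        r = np.asarray(r, dtype=float)
        if r.ndim == 0:
            out = np.full((m, m), float(r))
            np.fill_diagonal(out, 1.0)
            return out
        return r

    share_arr = np.tile(np.asarray(shares, dtype=float), (m, 1))
    kwargs = dict(
        ages=ages,
        n_pairs=dict(n_pairs),
        shares={
            t: {s: share_arr.copy() for s in ("M", "F")} for t in ("logbmi", "height")
        },
        corr={
            t: {"A": _mat(r_a), "C": _mat(r_c), "E": _mat(r_e)}
            for t in ("logbmi", "height")
        },
        rg_os=rg_os,
        missingness=missingness,
        dz_mean_offset={"logbmi": dz_offset, "height": dz_offset},
    )
    if not nuisance:
        kwargs.update(
            cohort_effects={"only": {"logbmi": 0.0, "height": 0.0}},
            birth_year_slope={"logbmi": 0.0, "height": 0.0},
            age_slope={"logbmi": 0.0, "height": 0.0},
        )
    return SimulationConfig(**kwargs)


def balanced_pairs(n, groups=("MZM", "MZF", "DZM", "DZF", "OSDZ")):
    return {g: (n if g in groups else 0) for g in ("MZM", "MZF", "DZM", "DZF", "OSDZ")}


@pytest.fixture(scope="session")
def small_cohort():
    """Default-calibration cohort, 300 pairs, ages 3 and 8."""
    cfg = SimulationConfig(n_pairs=pairs_from_total(300), ages=[3, 8], seed=11)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_panel(small_cohort):
    return build_panel(small_cohort)


@pytest.fixture(scope="session")
def bivariate_panel():
    """Nuisance-free AE-structured panel at two ages for model unit tests."""
    cfg = structural_config(
        shares=(0.6, 0.0, 0.4),
        r_a=0.8,
        r_c=0.5,
        r_e=0.2,
        ages=[8, 12],
        n_pairs=balanced_pairs(600),
        missingness=0.1,
    )
    return build_panel(simulate_cohort(cfg, seed=21))
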