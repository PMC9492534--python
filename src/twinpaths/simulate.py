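"""Seeded simulation of longitudinal twin cohorts.

Each family carries, per trait, a latent multi-age phenotype built from three
latent components:

* A (additive genetic): cross-age covariance diag(a) R_A diag(a); cross-twin
  correlation 1 in MZ pairs, 0.5 in same-sex DZ pairs and 0.5 * rg_os in
  opposite-sex DZ pairs.
* C (shared environment): one draw per family with cross-age correlation R_C,
  scaled by each twin's sex-specific path c; cross-twin correlation 1.
* E (unique environment): independent per twin, cross-age correlation R_E.

Because the per-age shares a2 + c2 + e2 sum to 1, the latent phenotype has
unit variance at every age and is mapped onto the observed scale by the
configured per-age mean/SD, after which nuisance structure (zygosity mean
offset, cohort effects, birth-year trend, within-bin growth) is added.
log-BMI is exponentiated to BMI and converted to weight via the simulated
height, so the generated weight/height records reproduce the BMI model
exactly on the log scale.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import ConfigError, SimulationConfig

RECORD_COLUMNS = [
    "family_id",
    "twin_index",
    "zygosity_group",
    "sex",
    "age_years",
    "exact_age",
    "height_cm",
    "weight_kg",
    "birth_year",
    "cohort",
]

_GROUP_SEXES = {
    "MZM": ("M", "M"),
    "MZF": ("F", "F"),
    "DZM": ("M", "M"),
    "DZF": ("F", "F"),
    "OSDZ": ("M", "F"),
}


def matrix_sqrt_psd(R: np.ndarray, name: str = "R") -> np.ndarray:
    """Symmetric matrix square root via spectral decomposition.

    Eigenvalues inside [-1e-10, 0) are clipped to 0 so numerically
    semi-definite inputs are tolerated; anything below that is rejected.
    """
    w, U = np.linalg.eigh(np.asarray(R, dtype=float))
    if w.min() < -1e-10:
        raise ConfigError(
            f"correlation matrix {name} is not positive semidefinite "
            f"(smallest eigenvalue {w.min():.3e})"
        )
    return (U * np.sqrt(np.clip(w, 0.0, None))) @ U.T


def _cross_twin_k(group: str, rg_os: float) -> float:
    if group in ("MZM", "MZF"):
        return 1.0
    if group in ("DZM", "DZF"):
        return 0.5
    return 0.5 * rg_os


def _latent_pair(
    rng: np.random.Generator, sqrt_R: np.ndarray, k: float, n: int
) -> tuple[np.ndarray, np.ndarray]:
    """Standardised latent vectors for both co-twins of n families.

    Returns two (n, m) arrays, each N(0, R) marginally, with cross-twin
    cross-age covariance k * R, built from a shared and two private draws.
    """
    m = sqrt_R.shape[0]
    z = rng.standard_normal((3, n, m)) @ sqrt_R.T
    x1 = np.sqrt(k) * z[0] + np.sqrt(1.0 - k) * z[1]
    x2 = np.sqrt(k) * z[0] + np.sqrt(1.0 - k) * z[2]
    return x1, x2


def simulate_cohort(
    config: SimulationConfig,
    seed: int | None = None,
    return_latent: bool = False,
) -> pd.DataFrame | tuple[pd.DataFrame, dict]:
    """Generate a long-format twin cohort.

    Parameters
    ----------
    config : SimulationConfig
        Validated generative configuration.
    seed : int, optional
        Overrides ``config.seed``.  Identical (config, seed) pairs produce
        byte-identical output.
    return_latent : bool
        Also return the pre-noise latent component draws, keyed by
        (zygosity_group, trait, component); used by tests that check the
        latent correlation structure directly.

    Returns
    -------
    DataFrame with one row per observed (twin, age) measurement occasion,
    columns :data:`RECORD_COLUMNS`; rows removed completely at random per
    (twin, age) at the configured rate.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    ages = np.asarray(config.ages)
    m = len(ages)
    by_lo, by_hi = config.birth_year_range
    by_ref = (by_lo + by_hi) / 2.0
    cohort_labels = sorted(config.cohort_effects)
    sqrt_R = {
        t: {
            comp: matrix_sqrt_psd(config.corr[t][comp], name=f"R_{comp}[{t}]")
            for comp in ("A", "C", "E")
        }
        for t in config.traits
    }
    miss_p = np.array([config.missing_rate(a) for a in ages])

    frames = []
    latents: dict = {}
    for group in ("MZM", "MZF", "DZM", "DZF", "OSDZ"):
        n = int(config.n_pairs.get(group, 0))
        if n == 0:
            continue
        sex1, sex2 = _GROUP_SEXES[group]
        is_dz = group in ("DZM", "DZF", "OSDZ")
        k = _cross_twin_k(group, config.rg_os)

        birth_year = rng.integers(by_lo, by_hi + 1, size=n)
        cohort_idx = rng.integers(0, len(cohort_labels), size=n)
        # co-twins measured on the same occasion: shared exact-age jitter
        age_jitter = rng.uniform(-0.49, 0.49, size=(n, m))
        exact_age = ages[None, :] + age_jitter

        values: dict[tuple[str, int], np.ndarray] = {}
        for t in config.traits:
            a1 = np.sqrt(config.shares[t][sex1][:, 0])
            c1 = np.sqrt(config.shares[t][sex1][:, 1])
            e1 = np.sqrt(config.shares[t][sex1][:, 2])
            a2_ = np.sqrt(config.shares[t][sex2][:, 0])
            c2_ = np.sqrt(config.shares[t][sex2][:, 1])
            e2_ = np.sqrt(config.shares[t][sex2][:, 2])

            xa1, xa2 = _latent_pair(rng, sqrt_R[t]["A"], k, n)
            u_c = rng.standard_normal((n, m)) @ sqrt_R[t]["C"].T
            eps1 = rng.standard_normal((n, m)) @ sqrt_R[t]["E"].T
            eps2 = rng.standard_normal((n, m)) @ sqrt_R[t]["E"].T

            P1 = xa1 * a1 + u_c * c1 + eps1 * e1
            P2 = xa2 * a2_ + u_c * c2_ + eps2 * e2_
            if return_latent:
                latents[(group, t, "A")] = (xa1 * a1, xa2 * a2_)
                latents[(group, t, "C")] = (u_c * c1, u_c * c2_)
                latents[(group, t, "E")] = (eps1 * e1, eps2 * e2_)

            coh_eff = np.array(
                [config.cohort_effects[c].get(t, 0.0) for c in cohort_labels]
            )[cohort_idx]
            nuisance = (
                coh_eff[:, None]
                + config.birth_year_slope.get(t, 0.0) * (birth_year - by_ref)[:, None]
                + config.age_slope.get(t, 0.0) * age_jitter
            )
            dz_off = config.dz_mean_offset.get(t, 0.0) if is_dz else 0.0
            for tw, P, sex in ((1, P1, sex1), (2, P2, sex2)):
                mu = config.means[t][sex][:, 0]
                sd = config.means[t][sex][:, 1]
                values[(t, tw)] = mu + sd * P + nuisance + dz_off

        miss1 = rng.uniform(size=(n, m)) < miss_p
        miss2 = rng.uniform(size=(n, m)) < miss_p

        fam_ids = np.array([f"{group}{i:06d}" for i in range(n)])
        for tw, sex, miss in ((1, sex1, miss1), (2, sex2, miss2)):
            keep = ~miss
            fam_grid, age_grid = np.where(keep)
            height = values[("height", tw)][keep]
            if "logbmi" in config.traits:
                bmi = np.exp(values[("logbmi", tw)][keep])
                weight = bmi * (height / 100.0) ** 2
            else:
                weight = np.full(height.shape, np.nan)
            frames.append(
                pd.DataFrame(
                    {
                        "family_id": fam_ids[fam_grid],
                        "twin_index": tw,
                        "zygosity_group": group,
                        "sex": sex,
                        "age_years": ages[age_grid],
                        "exact_age": exact_age[keep],
                        "height_cm": height,
                        "weight_kg": weight,
                        "birth_year": birth_year[fam_grid],
                        "cohort": np.array(cohort_labels)[cohort_idx[fam_grid]],
                    }
                )
            )

    if not frames:
        out = pd.DataFrame(columns=RECORD_COLUMNS)
    else:
        out = pd.concat(frames, ignore_index=True)
        out = out.sort_values(
            ["zygosity_group", "family_id", "twin_index", "age_years"],
            kind="mergesort",
        ).reset_index(drop=True)
    if return_latent:
        return out, latents
    return out


def write_cohort_csv(records: pd.DataFrame, path) -> None:
    """Write a cohort deterministically (fixed column order and float format)."""
    records.to_csv(path, index=False, columns=RECORD_COLUMNS, float_format="%.10g")
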