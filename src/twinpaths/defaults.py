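"""Default calibration of the synthetic twin cohort.

The per-age, per-sex means and standard deviations of BMI (kg/m^2) and height
(cm) below are the descriptive moments of a large pooled longitudinal twin
database spanning ages 1-19; they give the generator a realistic scale
without shipping any individual-level data.  BMI is simulated on the natural
log scale, so the arithmetic BMI moments are converted to log-normal
parameters (matching mean and variance) at config-build time.

Default variance-component shares and cross-age correlation structures encode
the qualitative picture from the twin literature on body size: BMI is highly
heritable with a shared-environment contribution confined to early childhood,
height is highly heritable with a persistent moderate shared-environment
component, and additive-genetic age-to-age correlations decay slowly with the
age gap (more slowly for height than for BMI).
"""

from __future__ import annotations

import numpy as np

AGES: tuple[int, ...] = tuple(range(1, 20))

ZYGOSITY_GROUPS: tuple[str, ...] = ("MZM", "MZF", "DZM", "DZF", "OSDZ")

#: MZ : same-sex DZ : opposite-sex DZ proportions among complete pairs.
ZYGOSITY_MIX: dict[str, float] = {"MZ": 0.38, "SSDZ": 0.33, "OSDZ": 0.29}

# age -> (N, BMI mean, BMI SD, height mean, height SD)
BMI_HEIGHT_TABLE_MALES: dict[int, tuple[int, float, float, float, float]] = {
    1: (14860, 17.1, 1.40, 73.9, 4.43),
    2: (12379, 16.5, 1.41, 86.8, 4.31),
    3: (14835, 15.9, 1.42, 96.1, 4.40),
    4: (7633, 15.8, 1.69, 102.5, 4.89),
    5: (6603, 15.2, 1.43, 111.4, 5.91),
    6: (2233, 15.4, 1.52, 114.1, 5.61),
    7: (11856, 15.4, 1.77, 124.4, 6.50),
    8: (5217, 15.7, 1.79, 128.3, 6.38),
    9: (5149, 16.4, 2.33, 133.8, 6.78),
    10: (9687, 16.6, 2.34, 141.0, 7.15),
    11: (7177, 17.3, 2.65, 144.4, 7.09),
    12: (9831, 17.8, 2.82, 151.9, 7.98),
    13: (3474, 18.4, 2.90, 158.4, 8.94),
    14: (7250, 19.5, 3.07, 165.7, 8.84),
    15: (3270, 19.9, 3.20, 172.1, 8.42),
    16: (5540, 20.7, 2.89, 175.7, 7.39),
    17: (6125, 21.2, 2.86, 177.8, 7.12),
    18: (3692, 21.7, 2.98, 178.8, 7.28),
    19: (2901, 22.0, 2.87, 179.3, 7.29),
}

BMI_HEIGHT_TABLE_FEMALES: dict[int, tuple[int, float, float, float, float]] = {
    1: (14978, 16.8, 1.42, 72.5, 4.47),
    2: (12134, 16.2, 1.42, 85.6, 4.36),
    3: (15279, 15.7, 1.48, 95.1, 4.50),
    4: (7737, 15.7, 1.81, 101.3, 4.86),
    5: (6564, 15.1, 1.54, 110.7, 6.05),
    6: (2065, 15.3, 1.60, 113.2, 5.57),
    7: (12305, 15.4, 1.98, 123.5, 6.50),
    8: (5192, 15.7, 2.03, 127.6, 6.40),
    9: (5120, 16.5, 2.62, 133.0, 6.97),
    10: (9940, 16.7, 2.62, 140.6, 7.30),
    11: (7357, 17.5, 2.83, 144.8, 7.47),
    12: (10161, 18.0, 2.93, 153.0, 8.06),
    13: (3413, 18.7, 3.11, 158.0, 7.49),
    14: (7800, 19.8, 3.19, 162.1, 6.79),
    15: (3266, 20.2, 3.23, 164.7, 7.11),
    16: (6350, 20.7, 3.01, 164.9, 6.50),
    17: (6904, 20.7, 2.80, 165.7, 6.54),
    18: (3960, 21.3, 3.34, 165.8, 6.71),
    19: (3529, 21.4, 3.29, 166.1, 6.71),
}

DESCRIPTIVE_TABLES = {"M": BMI_HEIGHT_TABLE_MALES, "F": BMI_HEIGHT_TABLE_FEMALES}

TRAITS: tuple[str, ...] = ("logbmi", "height")


def lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """Log-scale (mu, sigma) of a log-normal with the given arithmetic moments."""
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return float(mu), float(np.sqrt(sigma2))


def default_component_shares(trait: str, age: int) -> tuple[float, float, float]:
    """Default (a2, c2, e2) variance shares for a trait at an integer age.

    BMI: shared environment only in early childhood (ages 1-5); afterwards an
    essentially AE architecture with high heritability.  Height: persistently
    heritable with a shared-environment share that shrinks after early
    childhood.  Same defaults for both sexes.
    """
    if trait == "logbmi":
        if age <= 5:
            return (0.65, 0.15, 0.20)
        return (0.80, 0.00, 0.20)
    if trait == "height":
        if age <= 4:
            return (0.55, 0.30, 0.15)
        return (0.75, 0.12, 0.13)
    raise ValueError(f"unknown trait {trait!r}")


#: base of the |age_j - age_k| power-decay for the default cross-age
#: correlation matrices of the A, C and E latent components.
DEFAULT_DECAY = {
    "logbmi": {"A": 0.95, "C": 0.90, "E": 0.30},
    "height": {"A": 0.98, "C": 0.95, "E": 0.40},
}


def power_decay_matrix(ages: list[int] | tuple[int, ...], base: float) -> np.ndarray:
    """Correlation matrix with entries base ** |age_j - age_k| (AR(1)-like)."""
    a = np.asarray(ages, dtype=float)
    return base ** np.abs(a[:, None] - a[None, :])


DEFAULT_RG_OS = 0.95
DEFAULT_DZ_MEAN_OFFSET = {"logbmi": 0.005, "height": 0.4}
DEFAULT_COHORT_EFFECTS = {
    "cohortA": {"logbmi": -0.010, "height": -0.5},
    "cohortB": {"logbmi": 0.000, "height": 0.0},
    "cohortC": {"logbmi": 0.010, "height": 0.5},
}
DEFAULT_BIRTH_YEAR_SLOPE = {"logbmi": 0.002, "height": 0.02}
DEFAULT_BIRTH_YEAR_RANGE = (1980, 2005)
#: within-bin growth per year of exact age (height grows ~4 cm/yr on average
#: over this span; log-BMI within-year drift is negligible at this scale).
DEFAULT_AGE_SLOPE = {"logbmi": 0.0, "height": 4.0}
DEFAULT_MISSINGNESS = 0.25
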