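"""Simulation configuration for the synthetic twin cohort generator."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import defaults as d


class ConfigError(ValueError):
    """Raised when a simulation configuration violates an invariant."""


def pairs_from_total(
    n_total: int, mix: dict[str, float] | None = None
) -> dict[str, int]:
    """Split a total pair count into the five zygosity-by-sex groups.

    MZ and SSDZ pairs are divided equally between the sexes; rounding goes to
    the male group.  `mix` maps {MZ, SSDZ, OSDZ} to proportions summing to 1.
    """
    mix = dict(mix or d.ZYGOSITY_MIX)
    total_p = sum(mix.values())
    if abs(total_p - 1.0) > 1e-9:
        raise ConfigError(f"zygosity mix must sum to 1, got {total_p}")
    n_mz = int(round(n_total * mix["MZ"]))
    n_ss = int(round(n_total * mix["SSDZ"]))
    n_os = n_total - n_mz - n_ss
    return {
        "MZM": n_mz - n_mz // 2,
        "MZF": n_mz // 2,
        "DZM": n_ss - n_ss // 2,
        "DZF": n_ss // 2,
        "OSDZ": n_os,
    }


@dataclass
class SimulationConfig:
    """Generative configuration of a longitudinal twin cohort.

    Latent phenotypes follow the classical additive-genetic (A) /
    shared-environment (C) / unique-environment (E) decomposition with
    configurable per-age variance shares and cross-age correlation matrices
    per latent component.  Cross-twin correlations are 1 (MZ), 0.5 (SSDZ) and
    ``0.5 * rg_os`` (OSDZ) for A, 1 for C in every group, and 0 for E.

    Parameters
    ----------
    ages : list of int
        Integer age bins simulated (default 1..19).
    n_pairs : dict
        Complete-pair counts per group {MZM, MZF, DZM, DZF, OSDZ}.
    shares : {trait: {sex: (n_ages, 3) array}}
        Per-age (a2, c2, e2) variance shares; each row sums to 1.
    corr : {trait: {"A"|"C"|"E": (n_ages, n_ages) array}}
        Cross-age correlation matrices of the latent components.
    rg_os : float in [0, 1]
        Scaling of the OSDZ cross-twin additive-genetic correlation on top of
        the DZ factor 0.5 (1 = no sex-specific genetic effects).
    means : {trait: {sex: (n_ages, 2) array}}
        Per-age (mean, sd) of the observed scale: natural-log BMI for
        "logbmi", centimetres for "height".
    dz_mean_offset : {trait: float}
        Mean shift of DZ relative to MZ twins (DZ twins run slightly bigger).
    cohort_effects : {label: {trait: float}}
        Additive study-cohort offsets (nuisance signal for residualisation).
    birth_year_slope : {trait: float}
        Linear secular trend per birth year (nuisance signal).
    birth_year_range : (int, int)
        Inclusive uniform range of family birth years.
    age_slope : {trait: float}
        Within-bin growth per year of exact age.
    missingness : float or {age: float}
        Probability that a (twin, age) measurement occasion is missing (MCAR).
    seed : int
        Default seed for :func:`twinpaths.simulate.simulate_cohort`.
    """

    ages: list[int] = field(default_factory=lambda: list(d.AGES))
    n_pairs: dict[str, int] = field(default_factory=lambda: pairs_from_total(1000))
    shares: dict = field(default_factory=dict)
    corr: dict = field(default_factory=dict)
    rg_os: float = d.DEFAULT_RG_OS
    means: dict = field(default_factory=dict)
    dz_mean_offset: dict[str, float] = field(
        default_factory=lambda: dict(d.DEFAULT_DZ_MEAN_OFFSET)
    )
    cohort_effects: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in d.DEFAULT_COHORT_EFFECTS.items()}
    )
    birth_year_slope: dict[str, float] = field(
        default_factory=lambda: dict(d.DEFAULT_BIRTH_YEAR_SLOPE)
    )
    birth_year_range: tuple[int, int] = d.DEFAULT_BIRTH_YEAR_RANGE
    age_slope: dict[str, float] = field(default_factory=lambda: dict(d.DEFAULT_AGE_SLOPE))
    missingness: float | dict[int, float] = d.DEFAULT_MISSINGNESS
    seed: int = 0
    traits: tuple[str, ...] = d.TRAITS

    def __post_init__(self) -> None:
        self.ages = [int(a) for a in self.ages]
        if not self.shares:
            self.shares = {
                t: {
                    s: np.array([d.default_component_shares(t, a) for a in self.ages])
                    for s in ("M", "F")
                }
                for t in self.traits
            }
        if not self.corr:
            self.corr = {
                t: {
                    comp: d.power_decay_matrix(self.ages, base)
                    for comp, base in d.DEFAULT_DECAY[t].items()
                }
                for t in self.traits
            }
        if not self.means:
            self.means = {t: {} for t in self.traits}
            for sex, table in d.DESCRIPTIVE_TABLES.items():
                lb, ht = [], []
                for a in self.ages:
                    _, bmi_m, bmi_sd, h_m, h_sd = table[a]
                    lb.append(d.lognormal_params(bmi_m, bmi_sd))
                    ht.append((h_m, h_sd))
                if "logbmi" in self.traits:
                    self.means["logbmi"][sex] = np.array(lb)
                if "height" in self.traits:
                    self.means["height"][sex] = np.array(ht)
        for t in self.traits:
            for s in ("M", "F"):
                self.shares[t][s] = np.asarray(self.shares[t][s], dtype=float)
                self.means[t][s] = np.asarray(self.means[t][s], dtype=float)
            for comp in ("A", "C", "E"):
                self.corr[t][comp] = np.asarray(self.corr[t][comp], dtype=float)
        self.validate()

    # ------------------------------------------------------------------
    def validate(self) -> None:
        """Check every structural invariant; raise ConfigError on violation."""
        m = len(self.ages)
        for g, n in self.n_pairs.items():
            if g not in d.ZYGOSITY_GROUPS:
                raise ConfigError(f"unknown zygosity group {g!r}")
            if n < 0:
                raise ConfigError(f"negative pair count for {g}")
        if not 0.0 <= self.rg_os <= 1.0:
            raise ConfigError(f"rg_os must lie in [0, 1], got {self.rg_os}")
        for t in self.traits:
            for s in ("M", "F"):
                sh = self.shares[t][s]
                if sh.shape != (m, 3):
                    raise ConfigError(f"shares[{t}][{s}] must have shape ({m}, 3)")
                if np.any(sh < 0) or np.any(sh > 1):
                    raise ConfigError(f"shares[{t}][{s}] outside [0, 1]")
                bad = np.abs(sh.sum(axis=1) - 1.0) > 1e-12
                if bad.any():
                    age = self.ages[int(np.argmax(bad))]
                    raise ConfigError(
                        f"component shares for trait {t!r}, sex {s}, age {age} "
                        f"do not sum to 1"
                    )
                if self.means[t][s].shape != (m, 2):
                    raise ConfigError(f"means[{t}][{s}] must have shape ({m}, 2)")
                if np.any(self.means[t][s][:, 1] <= 0):
                    raise ConfigError(f"means[{t}][{s}] has non-positive SD")
            for comp in ("A", "C", "E"):
                R = self.corr[t][comp]
                name = f"R_{comp}[{t}]"
                if R.shape != (m, m):
                    raise ConfigError(f"{name} must have shape ({m}, {m})")
                if not np.allclose(R, R.T, atol=1e-12):
                    raise ConfigError(f"{name} is not symmetric")
                if not np.allclose(np.diag(R), 1.0, atol=1e-12):
                    raise ConfigError(f"{name} does not have a unit diagonal")
                w = np.linalg.eigvalsh(R)
                if w.min() < -1e-10:
                    raise ConfigError(
                        f"{name} is not positive semidefinite "
                        f"(smallest eigenvalue {w.min():.3e})"
                    )
        for age in self.ages:
            if not 0.0 <= self.missing_rate(age) < 1.0:
                raise ConfigError(f"missingness rate at age {age} outside [0, 1)")

    def missing_rate(self, age: int) -> float:
        if isinstance(self.missingness, dict):
            return float(self.missingness.get(age, 0.0))
        return float(self.missingness)

    # ------------------------------------------------------------------
    def to_dict(self) -> dict:
        def conv(x):
            if isinstance(x, np.ndarray):
                return x.tolist()
            if isinstance(x, dict):
                return {k: conv(v) for k, v in x.items()}
            if isinstance(x, (list, tuple)):
                return [conv(v) for v in x]
            if isinstance(x, (np.floating, np.integer)):
                return x.item()
            return x

        return {
            "ages": list(self.ages),
            "n_pairs": dict(self.n_pairs),
            "shares": conv(self.shares),
            "corr": conv(self.corr),
            "rg_os": self.rg_os,
            "means": conv(self.means),
            "dz_mean_offset": dict(self.dz_mean_offset),
            "cohort_effects": conv(self.cohort_effects),
            "birth_year_slope": dict(self.birth_year_slope),
            "birth_year_range": list(self.birth_year_range),
            "age_slope": dict(self.age_slope),
            "missingness": conv(self.missingness),
            "seed": self.seed,
            "traits": list(self.traits),
        }

    @classmethod
    def from_dict(cls, data: dict) -> "SimulationConfig":
        data = dict(data)
        if "birth_year_range" in data:
            data["birth_year_range"] = tuple(data["birth_year_range"])
        if "traits" in data:
            data["traits"] = tuple(data["traits"])
        if "missingness" in data and isinstance(data["missingness"], dict):
            data["missingness"] = {int(k): float(v) for k, v in data["missingness"].items()}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_file(cls, path: str | Path) -> "SimulationConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(data)
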