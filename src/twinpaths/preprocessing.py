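"""Raw height/weight records -> residualized analysis-ready phenotypes.

The analysis phenotype is the regression residual of log-BMI (natural log)
or raw height on exact age, birth year and study-cohort indicators, computed
independently within each 1-year-age x sex stratum.  Height enters without
transformation (its distribution is already close to normal); BMI is
log-transformed first.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

PANEL_COLUMNS = [
    "family_id",
    "twin_index",
    "zygosity_group",
    "sex",
    "age",
    "trait",
    "value",
    "stratum_n",
]

TRAIT_ALIASES = {"bmi": "logbmi", "logbmi": "logbmi", "height": "height"}


def compute_bmi(weight_kg, height_cm):
    """Body mass index, weight (kg) / height (m)^2.

    Scalars or arrays; every input must be positive and finite.
    """
    w = np.asarray(weight_kg, dtype=float)
    h = np.asarray(height_cm, dtype=float)
    if not np.all(np.isfinite(w)) or np.any(w <= 0):
        raise ValueError("weight_kg must be positive and finite")
    if not np.all(np.isfinite(h)) or np.any(h <= 0):
        raise ValueError("height_cm must be positive and finite")
    out = w / (h / 100.0) ** 2
    return float(out) if out.ndim == 0 else out


def sample_skewness(values) -> float:
    """Adjusted Fisher-Pearson sample skewness; 0 for zero-variance samples."""
    v = np.asarray(values, dtype=float)
    if v.size < 3 or np.ptp(v) == 0.0:
        return 0.0
    return float(stats.skew(v, bias=False))


def log_normalize(values):
    """Natural-log transform with before/after skewness diagnostics.

    Returns
    -------
    (log_values, skewness_before, skewness_after)
    """
    v = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(v)) or np.any(v <= 0):
        raise ValueError("log_normalize requires strictly positive finite values")
    logs = np.log(v)
    return logs, sample_skewness(v), sample_skewness(logs)


def assign_age_bin(exact_age) -> np.ndarray:
    """Integer age bin: round(exact_age) clipped to [1, 19]."""
    return np.clip(np.round(np.asarray(exact_age, dtype=float)).astype(int), 1, 19)


def _stratum_design(cov: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    cols = [np.ones(len(cov))]
    names = ["intercept"]
    for name in ("exact_age", "birth_year"):
        if name in cov:
            cols.append(np.asarray(cov[name], dtype=float))
            names.append(name)
    if "cohort" in cov:
        levels = sorted(pd.unique(cov["cohort"].astype(str)))
        for lev in levels[1:]:  # first level is the reference
            cols.append((cov["cohort"].astype(str) == lev).to_numpy(float))
            names.append(f"cohort[{lev}]")
    return np.column_stack(cols), names


def residualize_stratum(values, covariates: pd.DataFrame) -> np.ndarray:
    """OLS residuals of values on [1, exact_age, birth_year, cohort dummies].

    Rank-deficient designs are repaired by dropping collinear columns in a
    fixed order (cohort indicators first, last-entered first), with a logged
    warning; strata smaller than the remaining parameter count fall back to
    plain centering.  Residuals are invariant to which of the collinear
    columns is dropped, so the rule only fixes the reported design.
    """
    y = np.asarray(values, dtype=float)
    X, names = _stratum_design(covariates)
    if len(y) != X.shape[0]:
        raise ValueError("values and covariates have different lengths")
    # drop exactly-constant non-intercept columns, then any remaining
    # collinear cohort indicators from the right
    keep = [0] + [j for j in range(1, X.shape[1]) if np.ptp(X[:, j]) > 0]
    X = X[:, keep]
    names = [names[j] for j in keep]
    while X.shape[1] > 1 and np.linalg.matrix_rank(X) < X.shape[1]:
        logger.warning("dropping collinear column %s from stratum design", names[-1])
        X = X[:, :-1]
        names = names[:-1]
    if len(y) <= X.shape[1]:
        # saturated or under-determined stratum: plain centering, never a
        # perfect fit that would zero the phenotype out
        logger.warning(
            "stratum of size %d leaves no residual df (%d columns); centering only",
            len(y),
            X.shape[1],
        )
        return y - y.mean()
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def deduplicate_bins(records: pd.DataFrame) -> pd.DataFrame:
    """Keep one measurement per (family, twin, age bin).

    A measurement at exact age x belongs to bin round(x) clipped to [1, 19];
    within a bin the record whose exact age is closest to the bin centre wins,
    ties going to the earliest record.
    """
    rec = records.copy()
    rec["age"] = assign_age_bin(rec["exact_age"])
    rec["_dist"] = np.abs(rec["exact_age"] - rec["age"])
    rec["_order"] = np.arange(len(rec))
    rec = rec.sort_values(["family_id", "twin_index", "age", "_dist", "_order"],
                          kind="mergesort")
    rec = rec.drop_duplicates(["family_id", "twin_index", "age"], keep="first")
    return rec.drop(columns=["_dist", "_order"]).reset_index(drop=True)


def build_panel(
    records: pd.DataFrame, traits: tuple[str, ...] = ("logbmi", "height")
) -> pd.DataFrame:
    """Residualized long-format phenotype panel from raw cohort records.

    Steps: log-BMI from weight/height, integer age binning with
    de-duplication, then per-(trait, age bin, sex) OLS residualisation on
    exact age, birth year and cohort.

    Returns a DataFrame with columns :data:`PANEL_COLUMNS`; ``value`` is the
    residual (mean 0 within each stratum), ``stratum_n`` the stratum size.
    """
    traits = tuple(TRAIT_ALIASES[t] for t in traits)
    rec = deduplicate_bins(records)

    out_frames = []
    for trait in traits:
        if trait == "logbmi":
            ok = rec["weight_kg"].notna() & rec["height_cm"].notna()
            sub = rec[ok].copy()
            bmi = compute_bmi(sub["weight_kg"].to_numpy(), sub["height_cm"].to_numpy())
            sub["_y"] = np.log(bmi)
        else:
            ok = rec["height_cm"].notna()
            sub = rec[ok].copy()
            sub["_y"] = sub["height_cm"].astype(float)

        for (age, sex), grp in sub.groupby(["age", "sex"], sort=True):
            resid = residualize_stratum(
                grp["_y"].to_numpy(),
                grp[["exact_age", "birth_year", "cohort"]],
            )
            out_frames.append(
                pd.DataFrame(
                    {
                        "family_id": grp["family_id"].to_numpy(),
                        "twin_index": grp["twin_index"].to_numpy(),
                        "zygosity_group": grp["zygosity_group"].to_numpy(),
                        "sex": sex,
                        "age": age,
                        "trait": trait,
                        "value": resid,
                        "stratum_n": len(grp),
                    }
                )
            )
    if not out_frames:
        return pd.DataFrame(columns=PANEL_COLUMNS)
    panel = pd.concat(out_frames, ignore_index=True)
    return panel.sort_values(
        ["trait", "age", "sex", "family_id", "twin_index"], kind="mergesort"
    ).reset_index(drop=True)


def write_panel_csv(panel: pd.DataFrame, path) -> None:
    panel.to_csv(path, index=False, columns=PANEL_COLUMNS, float_format="%.10g")
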