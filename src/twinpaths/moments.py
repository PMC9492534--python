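"""Closed-form method-of-moments (Falconer-style) estimators.

Under the classical twin model the co-twin correlations satisfy
rMZ = a2 + c2 and rDZ = a2/2 + c2, which inverts to

    a2 = 2 (rMZ - rDZ),   c2 = 2 rDZ - rMZ,   e2 = 1 - rMZ,

and the cross-twin cross-age covariances satisfy the analogous linear system
covMZ = covA + covC, covDZ = covA/2 + covC, within-person cov = covA + covC
+ covE.  These estimators are used for two things only: starting values for
the maximum-likelihood fits and independent oracles in the test suite; they
are never the reported results.

Empirical co-twin moments are computed with double entry (each pair counted
in both twin orders) so that the arbitrary labelling of co-twins cannot
influence the estimate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class MomentEstimates:
    """Raw and zero-truncated standardized variance components."""

    a2: float
    c2: float
    e2: float
    a2_raw: float
    c2_raw: float
    e2_raw: float
    truncated: bool


def falconer_estimates(r_mz: float, r_dz: float) -> MomentEstimates:
    """Invert (rMZ, rDZ) into standardized (a2, c2, e2).

    Raw values may fall outside [0, 1]; the truncated versions clip negative
    components at 0 and renormalize to sum 1, with a flag.
    """
    if abs(r_mz) > 1 + 1e-9 or abs(r_dz) > 1 + 1e-9:
        raise ValueError("correlations must lie in [-1, 1]")
    r_mz = float(np.clip(r_mz, -1.0, 1.0))
    r_dz = float(np.clip(r_dz, -1.0, 1.0))
    a2 = 2.0 * (r_mz - r_dz)
    c2 = 2.0 * r_dz - r_mz
    e2 = 1.0 - r_mz
    raw = np.array([a2, c2, e2])
    truncated = bool(np.any(raw < 0))
    clipped = np.clip(raw, 0.0, None)
    s = clipped.sum()
    clipped = clipped / s if s > 0 else np.array([0.0, 0.0, 1.0])
    return MomentEstimates(
        a2=float(clipped[0]),
        c2=float(clipped[1]),
        e2=float(clipped[2]),
        a2_raw=float(a2),
        c2_raw=float(c2),
        e2_raw=float(e2),
        truncated=truncated,
    )


def moment_bivariate(
    cov_mz_ct: float, cov_dz_ct: float, cov_wp: float
) -> tuple[float, float, float]:
    """Cross-age (covA, covC, covE) from cross-twin and within-person moments.

    ``cov_mz_ct`` / ``cov_dz_ct`` are cross-twin cross-age covariances (twin 1
    at age j with twin 2 at age k), ``cov_wp`` the within-person cross-age
    covariance.
    """
    cov_a = 2.0 * (cov_mz_ct - cov_dz_ct)
    cov_c = 2.0 * cov_dz_ct - cov_mz_ct
    cov_e = cov_wp - cov_mz_ct
    return float(cov_a), float(cov_c), float(cov_e)


# ----------------------------------------------------------------------
# empirical moments with double entry


def double_entry_correlation(x1: np.ndarray, x2: np.ndarray) -> float:
    """Intraclass-style correlation from co-twin value pairs, double entered."""
    m = np.isfinite(x1) & np.isfinite(x2)
    if m.sum() < 3:
        return np.nan
    a = np.concatenate([x1[m], x2[m]])
    b = np.concatenate([x2[m], x1[m]])
    return float(np.corrcoef(a, b)[0, 1])


def double_entry_covariance(x1: np.ndarray, x2: np.ndarray) -> float:
    """Cross covariance of co-twin values, symmetrised over twin order."""
    m = np.isfinite(x1) & np.isfinite(x2)
    if m.sum() < 3:
        return np.nan
    a = np.concatenate([x1[m], x2[m]])
    b = np.concatenate([x2[m], x1[m]])
    return float(np.cov(a, b, ddof=1)[0, 1])


def pair_moments(y: np.ndarray) -> dict:
    """Summary moments of stacked pair data.

    Parameters
    ----------
    y : (n, 2p) array
        Per family: twin 1's p variables then twin 2's p variables, NaN for
        missing.  p = 1 (univariate) or 2 (one trait at two ages).

    Returns dict with per-variable variances, co-twin same-variable
    correlations, and (p = 2) within-person and cross-twin cross-age moments.
    """
    p = y.shape[1] // 2
    t1, t2 = y[:, :p], y[:, p:]
    both = np.concatenate([t1, t2], axis=0)
    out = {
        "var": np.nanvar(both, axis=0, ddof=1),
        "r_ct": np.array(
            [double_entry_correlation(t1[:, i], t2[:, i]) for i in range(p)]
        ),
    }
    if p == 2:
        m = np.isfinite(t1).all(axis=1) | np.isfinite(t2).all(axis=1)
        wp = np.concatenate([t1, t2], axis=0)
        ok = np.isfinite(wp).all(axis=1)
        out["cov_wp"] = float(np.cov(wp[ok, 0], wp[ok, 1], ddof=1)[0, 1]) if ok.sum() > 2 else np.nan
        # cross-twin cross-age, symmetrised over both twin order and age order
        c12 = double_entry_covariance(t1[:, 0], t2[:, 1])
        c21 = double_entry_covariance(t1[:, 1], t2[:, 0])
        out["cov_ct_cross"] = np.nanmean([c12, c21])
        del m
    return out
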