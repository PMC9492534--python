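"""Profile-likelihood confidence intervals.

A level-(1-alpha) profile interval for a scalar quantity q collects the
values v for which twice the log-likelihood drop of the profile fit
(all other parameters re-optimised with q fixed at v) stays below the
chi-square(1) critical value (3.841 at 95%).  Component correlations
(rA, rC, rE) are profiled exactly by reparameterising the relevant 2x2
Cholesky block as two standard deviations plus the fixed correlation, which
turns each profile evaluation into an unconstrained inner optimisation
warm-started from its neighbour.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize
from scipy.stats import chi2

__all__ = ["likelihood_ratio_interval", "profile_ci"]


def likelihood_ratio_interval(
    profile_fn,
    mle_value: float,
    llmax: float,
    lower_bound: float,
    upper_bound: float,
    level: float = 0.95,
    xtol: float = 1e-3,
    init_step: float = 0.02,
):
    """Two-sided likelihood-ratio interval by monotone bracketing + Brent.

    Parameters
    ----------
    profile_fn : callable v -> profiled log-likelihood at q = v
    mle_value, llmax : the MLE of the quantity and the maximised loglik
    lower_bound, upper_bound : hard parameter bounds (e.g. -1, 1)
    level : coverage level (chi-square(1) calibration)
    xtol : absolute tolerance on the interval endpoints
    init_step : first outward step, doubled until the drop brackets

    Returns
    -------
    (lo, hi, info) where info flags endpoints stuck at a hard bound
    (profile failed to cross the critical drop inside it).
    """
    crit = chi2.ppf(level, df=1) / 2.0
    # tolerate an inner optimiser that edges past the original optimum
    ll0 = profile_fn(mle_value)
    llmax = max(llmax, ll0)

    def drop(v: float) -> float:
        return llmax - profile_fn(v) - crit

    info = {"lower_at_bound": False, "upper_at_bound": False, "level": level}
    out = []
    for sign, bound, flag in (
        (-1.0, lower_bound, "lower_at_bound"),
        (+1.0, upper_bound, "upper_at_bound"),
    ):
        step = init_step
        inside = mle_value
        endpoint = None
        while True:
            v = mle_value + sign * step
            v = max(lower_bound, min(upper_bound, v))
            d = drop(v)
            if d > 0.0:
                endpoint = optimize.brentq(drop, inside, v, xtol=xtol) if v != inside else v
                break
            if v == bound:
                endpoint = bound
                info[flag] = True
                break
            inside = v
            step *= 2.0
        out.append(float(endpoint))
    lo, hi = min(out[0], mle_value), max(out[1], mle_value)
    return lo, hi, info


# ----------------------------------------------------------------------
# component-correlation profiles for TwinModelResults


def _component_block(model, comp: str, sex: str):
    """Index range of a component's triangular entries in the theta vector."""
    if comp not in model.components:
        raise ValueError(f"component {comp!r} not free in an {model.model_tag} model")
    s_idx = model.sexes.index(sex)
    c_idx = model.components.index(comp)
    start = (s_idx * len(model.components) + c_idx) * model.ntri
    return start, start + model.ntri


def _correlation_profile_fn(results, comp: str, sex: str):
    """Profiled loglik over rho for one component, with warm starting."""
    model = results.model
    if model.p != 2:
        raise ValueError("correlation profiles need a bivariate model")
    lo, hi = _component_block(model, comp, sex)
    theta_hat = results.params
    rest_idx = np.r_[0:lo, hi : len(theta_hat)]
    cov = results.paths.component_cov(comp, "M" if sex == "*" else sex)
    s1 = np.sqrt(max(cov[0, 0], 1e-8))
    s2 = np.sqrt(max(cov[1, 1], 1e-8))
    state = {"free": np.concatenate([theta_hat[rest_idx], np.log([s1, s2])])}

    def assemble(free: np.ndarray, rho: float) -> np.ndarray:
        theta = np.empty_like(theta_hat)
        theta[rest_idx] = free[:-2]
        sd1, sd2 = np.exp(free[-2:])
        theta[lo] = sd1
        theta[lo + 1] = rho * sd2
        theta[lo + 2] = sd2 * np.sqrt(max(1.0 - rho * rho, 0.0))
        return theta

    def profile_fn(rho: float) -> float:
        res = optimize.minimize(
            lambda f: model._negloglike_avg(assemble(f, rho)),
            state["free"],
            method="L-BFGS-B",
            options={"maxiter": 200, "ftol": 1e-11, "gtol": 3e-6},
        )
        state["free"] = res.x  # warm start the next evaluation
        return -res.fun * model.data.n_families

    return profile_fn


def profile_ci(
    results,
    name: str,
    sex: str | None = None,
    level: float = 0.95,
    init_step: float | None = None,
):
    """Profile-likelihood CI for rA, rC or rE of a fitted bivariate model.

    Bounds are clipped to [-1, 1]; an endpoint that fails to bracket inside
    the unit interval is returned at the bound with a one-sided flag in the
    info dict.  Other quantities (variance shares, rP, rg_os) are profiled
    through the generic machinery only indirectly; use Wald CIs for those.
    """
    if name not in ("rA", "rC", "rE"):
        raise ValueError(
            f"profile CIs implemented for rA/rC/rE; use wald_ci for {name!r}"
        )
    model = results.model
    sex_key = sex if model.design == "five_group" else "*"
    if model.design == "five_group" and sex not in ("M", "F"):
        raise ValueError("five-group profile needs sex 'M' or 'F'")
    mle = results.quantity(name, sex)
    if not np.isfinite(mle):
        return (np.nan, np.nan, {"lower_at_bound": False, "upper_at_bound": False})
    if init_step is None:
        # a Wald half-width seeds the bracketing so one or two outward steps
        # usually suffice; fall back to a fixed step if the Hessian is flat
        lo_w, hi_w = results.wald_ci(name, sex=sex, level=level)
        half = (hi_w - lo_w) / 2.0
        init_step = half * 0.85 if np.isfinite(half) and half > 1e-4 else 0.05
    fn = _correlation_profile_fn(results, name[1], sex_key)
    return likelihood_ratio_interval(
        fn, mle, results.llf, -1.0, 1.0, level=level, init_step=init_step
    )
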