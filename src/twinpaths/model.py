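"""Maximum-likelihood Cholesky ACE/AE twin models.

The classical twin design decomposes phenotypic variance into additive
genetic (A), shared environmental (C) and unique environmental (E) latent
components, identified by the different cross-twin correlations of A in
monozygotic (1) and dizygotic (0.5) pairs, with C perfectly correlated and E
uncorrelated across co-twins in every group.  In the bivariate case (one
trait measured at two ages) each component's 2x2 covariance block is
parameterised by a lower-triangular path matrix L, so the implied covariance
L L' is positive semidefinite by construction, and standardising the A, C
and E cross-age covariances yields the genetic (rA), shared-environmental
(rC) and unique-environmental (rE) correlations.  The phenotypic cross-age
correlation then decomposes as

    rP = a1 * rA * a2 + c1 * rC * c2 + e1 * rE * e2

with a, c, e the square roots of the standardized variance components.

Estimation is full-information maximum likelihood over families: each
family contributes the multivariate-normal log density of its *observed*
sub-vector of (twin1@age_j, twin1@age_k, twin2@age_j, twin2@age_k), with
zygosity-specific means (DZ twins run slightly larger than MZ twins) and,
in the five-group sex-limitation design, sex-specific path matrices plus a
freely estimated opposite-sex DZ genetic-correlation scaling rg_os in place
of the constrained 0.5.

The public surface follows the statsmodels convention: build a
:class:`CholeskyTwinModel` from data, call :meth:`~CholeskyTwinModel.fit`,
and read estimates, correlations, confidence intervals and ``summary()``
off the returned :class:`TwinModelResults`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import norm
from statsmodels.tools import numdiff

logger = logging.getLogger(__name__)

LOG2PI = np.log(2.0 * np.pi)

GROUP_SEXES = {
    "MZM": ("M", "M"),
    "MZF": ("F", "F"),
    "DZM": ("M", "M"),
    "DZF": ("F", "F"),
    "OSDZ": ("M", "F"),
}
MZ_GROUPS = ("MZM", "MZF")
ALL_GROUPS = tuple(GROUP_SEXES)


# ======================================================================
# data container


@dataclass
class PairedAgeData:
    """Per-family observed phenotype vectors for one trait at one or two ages.

    ``y`` holds one row per family: twin 1's values at the p ages followed by
    twin 2's, NaN marking missing occasions.  Families whose co-twin is
    entirely unobserved carry no cross-twin information under known
    (residualized, near-zero) means and are dropped at construction, counted
    in ``n_dropped``.  In OSDZ families twin 1 is the male.
    """

    y: np.ndarray
    zygosity: np.ndarray
    var_names: tuple[str, ...] = ("age_j", "age_k")
    n_dropped: int = 0
    groups: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.zygosity = np.asarray(self.zygosity)
        if self.y.ndim != 2 or self.y.shape[1] not in (2, 4):
            raise ValueError("y must be (n, 2) or (n, 4)")
        p = self.y.shape[1] // 2
        t1_missing = np.isnan(self.y[:, :p]).all(axis=1)
        t2_missing = np.isnan(self.y[:, p:]).all(axis=1)
        keep = ~(t1_missing | t2_missing)
        n_drop = int((~keep).sum())
        if n_drop:
            logger.info("dropping %d families with an entirely unobserved co-twin", n_drop)
        self.n_dropped += n_drop
        self.y = self.y[keep]
        self.zygosity = self.zygosity[keep]
        self.groups = {}
        for g in ALL_GROUPS:
            rows = np.flatnonzero(self.zygosity == g)
            if rows.size == 0:
                continue
            obs = ~np.isnan(self.y[rows])
            patterns: dict[tuple, list] = {}
            for r, o in zip(rows, obs):
                patterns.setdefault(tuple(o), []).append(r)
            self.groups[g] = {k: np.asarray(v) for k, v in patterns.items()}

    @property
    def n_vars(self) -> int:
        return self.y.shape[1] // 2

    @property
    def n_families(self) -> int:
        return self.y.shape[0]

    def n_pairs(self) -> dict[str, int]:
        return {g: int(sum(len(v) for v in pat.values())) for g, pat in self.groups.items()}

    def _suffstats(self):
        """Per-(group, pattern) sufficient statistics, grouped by pattern size.

        The Gaussian FIML objective only needs, per missingness pattern, the
        family count n, the sum of observed sub-vectors and the sum of their
        outer products; batching patterns of equal size lets each likelihood
        evaluation run as a handful of vectorised small-matrix operations.
        """
        if getattr(self, "_ss", None) is None:
            group_order = [g for g in ALL_GROUPS if g in self.groups]
            by_size: dict[int, dict[str, list]] = {}
            for gi, g in enumerate(group_order):
                for pattern, idx in self.groups[g].items():
                    obs = np.flatnonzero(pattern)
                    k = len(obs)
                    rows = self.y[np.ix_(idx, obs)]
                    e = by_size.setdefault(
                        k, {"group": [], "obs": [], "n": [], "sy": [], "syy": []}
                    )
                    e["group"].append(gi)
                    e["obs"].append(obs)
                    e["n"].append(len(idx))
                    e["sy"].append(rows.sum(axis=0))
                    e["syy"].append(rows.T @ rows)
            self._ss = (
                group_order,
                {
                    k: {key: np.asarray(v) for key, v in e.items()}
                    for k, e in by_size.items()
                },
            )
        return self._ss


def paired_from_panel(
    panel: pd.DataFrame, trait: str, ages: tuple[int, ...] | list[int]
) -> PairedAgeData:
    """Assemble :class:`PairedAgeData` from a long residualized panel.

    ``ages`` holds one age (univariate) or two ages (bivariate).  Rows are
    keyed by family; OSDZ families are ordered male-first regardless of the
    recorded twin index.
    """
    ages = [int(a) for a in ages]
    sub = panel[(panel["trait"] == trait) & panel["age"].isin(ages)]
    if sub.empty:
        raise ValueError(f"panel has no rows for trait {trait!r} at ages {ages}")
    wide = sub.pivot_table(
        index="family_id", columns=["twin_index", "age"], values="value", aggfunc="first"
    )
    fam_info = sub.drop_duplicates("family_id").set_index("family_id")
    fam_ids = sorted(wide.index)
    zyg = fam_info.loc[fam_ids, "zygosity_group"].to_numpy()
    # male-first ordering for opposite-sex pairs
    sex1 = (
        sub[sub["twin_index"] == 1]
        .drop_duplicates("family_id")
        .set_index("family_id")["sex"]
        .reindex(fam_ids)
    )
    cols = []
    for tw in (1, 2):
        for a in ages:
            c = wide[(tw, a)] if (tw, a) in wide.columns else pd.Series(np.nan, index=wide.index)
            cols.append(c.reindex(fam_ids).to_numpy(dtype=float))
    y = np.column_stack(cols)
    p = len(ages)
    swap = (zyg == "OSDZ") & (sex1.to_numpy() == "F")
    if swap.any():
        y[swap] = np.column_stack([y[swap, p:], y[swap, :p]])
    return PairedAgeData(
        y=y, zygosity=zyg, var_names=tuple(f"{trait}@{a}" for a in ages)
    )


# ======================================================================
# paths and implied moments


@dataclass
class CholeskyPaths:
    """Lower-triangular path matrices per sex plus means and rg_os.

    ``L_A``/``L_C``/``L_E`` map sex -> (p, p) lower-triangular matrix (in a
    single-sex design both sexes share the same objects).  ``means`` maps
    (zygosity class in {"MZ", "DZ"}, sex) -> length-p mean vector.  ``rg_os``
    scales the OSDZ cross-twin additive-genetic correlation on top of the
    dizygotic factor 0.5; None in single-sex designs.
    """

    L_A: dict[str, np.ndarray]
    L_C: dict[str, np.ndarray]
    L_E: dict[str, np.ndarray]
    means: dict[tuple[str, str], np.ndarray]
    rg_os: float | None = None

    @property
    def n_vars(self) -> int:
        return next(iter(self.L_A.values())).shape[0]

    def component_cov(self, comp: str, sex: str) -> np.ndarray:
        L = {"A": self.L_A, "C": self.L_C, "E": self.L_E}[comp][sex]
        return L @ L.T

    def within_cov(self, sex: str) -> np.ndarray:
        return sum(self.component_cov(c, sex) for c in ("A", "C", "E"))


def genetic_cross_factor(zygosity_group: str, rg_os: float | None) -> float:
    """Cross-twin additive-genetic correlation scale for a zygosity group."""
    if zygosity_group in MZ_GROUPS:
        return 1.0
    if zygosity_group == "OSDZ":
        if rg_os is None:
            raise ValueError("OSDZ pairs require rg_os (five-group design)")
        return 0.5 * float(rg_os)
    return 0.5


def expected_pair_covariance(paths: CholeskyPaths, zygosity_group: str) -> np.ndarray:
    """Model-implied covariance of (twin1, twin2) stacked observation vectors.

    Within-twin block: A + C + E.  Cross-twin block: k * L_A(s1) L_A(s2)' +
    L_C(s1) L_C(s2)' with k = 1 (MZ), 0.5 (same-sex DZ) or 0.5 * rg_os
    (opposite-sex DZ, male paths for twin 1, female for twin 2); E never
    crosses twins.  Positive semidefinite by construction.
    """
    s1, s2 = GROUP_SEXES[zygosity_group]
    k = genetic_cross_factor(zygosity_group, paths.rg_os)
    cross = k * paths.L_A[s1] @ paths.L_A[s2].T + paths.L_C[s1] @ paths.L_C[s2].T
    top = np.hstack([paths.within_cov(s1), cross])
    bot = np.hstack([cross.T, paths.within_cov(s2)])
    return np.vstack([top, bot])


def expected_pair_mean(paths: CholeskyPaths, zygosity_group: str) -> np.ndarray:
    s1, s2 = GROUP_SEXES[zygosity_group]
    zc = "MZ" if zygosity_group in MZ_GROUPS else "DZ"
    return np.concatenate([paths.means[(zc, s1)], paths.means[(zc, s2)]])


def standardize_correlation(cov_x: float, v_x1: float, v_x2: float) -> float:
    """Correlation cov / sqrt(v1 v2), tolerating <1e-8 numerical overshoot.

    Values outside [-1, 1] by at least 1e-8 indicate an invalid covariance
    decomposition and are rejected.
    """
    if v_x1 <= 0 or v_x2 <= 0:
        raise ValueError("variances must be positive")
    r = cov_x / np.sqrt(v_x1 * v_x2)
    if abs(r) > 1.0 + 1e-8:
        raise ValueError(f"correlation {r} outside [-1, 1] beyond tolerance")
    if abs(r) > 1.0:
        logger.warning("clipping correlation %.12f to unit interval", r)
    return float(np.clip(r, -1.0, 1.0))


# ======================================================================
# likelihood


def pair_loglikelihood(
    data: PairedAgeData, paths: CholeskyPaths, return_jitter_count: bool = False
):
    """Full-information Gaussian log likelihood summed over families.

    Each family contributes the log density of its observed sub-vector under
    the zygosity-appropriate mean and expected-covariance sub-matrix.
    Numerically singular observed sub-matrices get a 1e-8 diagonal jitter and
    are counted; callers flag the fit when more than 1% of families needed it.
    """
    group_order, by_size = data._suffstats()
    sigma_all = np.stack([expected_pair_covariance(paths, g) for g in group_order])
    mu_all = np.stack([expected_pair_mean(paths, g) for g in group_order])

    total = 0.0
    n_jitter = 0
    for k, e in by_size.items():
        gi, obs = e["group"], e["obs"]  # (m,), (m, k)
        sub = sigma_all[gi[:, None, None], obs[:, :, None], obs[:, None, :]]
        mu = mu_all[gi[:, None], obs]  # (m, k)
        sign, logdet = np.linalg.slogdet(sub)
        bad = sign <= 0
        if bad.any():
            n_jitter += int(e["n"][bad].sum())
            sub[bad] += 1e-8 * np.eye(k)
            sign, logdet = np.linalg.slogdet(sub)
            if np.any(sign <= 0):
                return (-np.inf, n_jitter) if return_jitter_count else -np.inf
        prec = np.linalg.inv(sub)
        n, sy, syy = e["n"], e["sy"], e["syy"]
        # sum_i (y_i - mu)(y_i - mu)' from the sufficient statistics
        s_mat = (
            syy
            - sy[:, :, None] * mu[:, None, :]
            - mu[:, :, None] * sy[:, None, :]
            + n[:, None, None] * mu[:, :, None] * mu[:, None, :]
        )
        quad = np.einsum("mij,mij->m", prec, s_mat)
        total += -0.5 * float((n * (k * LOG2PI + logdet) + quad).sum())
    if return_jitter_count:
        return float(total), n_jitter
    return float(total)


# ======================================================================
# parameter packing


def _tri_indices(p: int) -> list[tuple[int, int]]:
    return [(i, j) for i in range(p) for j in range(i + 1)]


def _vec_to_tril(vec: np.ndarray, p: int) -> np.ndarray:
    L = np.zeros((p, p))
    for v, (i, j) in zip(vec, _tri_indices(p)):
        L[i, j] = v
    return L


def _tril_to_vec(L: np.ndarray) -> np.ndarray:
    p = L.shape[0]
    return np.array([L[i, j] for (i, j) in _tri_indices(p)])


def _canonical_tril(L: np.ndarray) -> np.ndarray:
    """Flip column signs so diagonal entries are non-negative (L L' invariant)."""
    L = L.copy()
    for j in range(L.shape[1]):
        if L[j, j] < 0:
            L[:, j] *= -1.0
    return L


def _logistic(x: float) -> float:
    return 1.0 / (1.0 + np.exp(-x))


def _logit(p: float) -> float:
    p = min(max(p, 1e-6), 1 - 1e-6)
    return float(np.log(p / (1 - p)))


# ======================================================================
# the model


class CholeskyTwinModel:
    """Univariate or bivariate Cholesky ACE/AE twin model.

    Parameters
    ----------
    data : PairedAgeData
        Observed (possibly partially missing) co-twin phenotype vectors.
    model_tag : {"AE", "ACE"}
        Whether the shared-environment paths are estimated or fixed at zero.
        AE is the main model; ACE the sensitivity model.
    design : {"five_group", "single_sex"}
        ``five_group`` fits sex-specific path matrices to all five
        zygosity-by-sex groups jointly, with the opposite-sex DZ genetic
        correlation scale rg_os estimated freely (logistic map onto [0, 1]).
        ``single_sex`` fits one shared path set to MZ and same-sex DZ pairs
        only (opposite-sex pairs, if present, are ignored).

    Free parameters are the unconstrained lower-triangular path entries per
    component (and sex), zygosity-specific means per variable, and (five
    group) the logit of rg_os.  Diagonal path entries are sign-fixed to be
    non-negative after optimisation, which leaves the likelihood unchanged.
    """

    def __init__(
        self,
        data: PairedAgeData,
        model_tag: str = "AE",
        design: str = "five_group",
    ) -> None:
        if model_tag not in ("AE", "ACE"):
            raise ValueError("model_tag must be 'AE' or 'ACE'")
        if design not in ("five_group", "single_sex"):
            raise ValueError("design must be 'five_group' or 'single_sex'")
        present = set(data.groups)
        if design == "five_group":
            missing = set(ALL_GROUPS) - present
            if missing:
                raise ValueError(
                    f"five-group design requires all five zygosity groups; "
                    f"missing {sorted(missing)}"
                )
        else:
            if present & set(ALL_GROUPS[:2]) == set() or not (present & {"DZM", "DZF"}):
                raise ValueError(
                    "single-sex design needs at least one MZ and one same-sex "
                    "DZ group for identification"
                )
            if "OSDZ" in present:
                rows = ~np.isin(data.zygosity, ["OSDZ"])
                logger.info("single-sex design: ignoring %d OSDZ families",
                            int((~rows).sum()))
                data = PairedAgeData(
                    y=data.y[rows],
                    zygosity=data.zygosity[rows],
                    var_names=data.var_names,
                    n_dropped=data.n_dropped,
                )
        if len(data.groups) < 2:
            raise ValueError("need MZ and DZ groups for identification")
        self.data = data
        self.model_tag = model_tag
        self.design = design
        self.p = data.n_vars
        self.ntri = self.p * (self.p + 1) // 2
        self.sexes = ("M", "F") if design == "five_group" else ("*",)
        self.components = ("A", "C", "E") if model_tag == "ACE" else ("A", "E")
        n_path = len(self.sexes) * len(self.components) * self.ntri
        n_mean = 2 * len(self.sexes) * self.p  # MZ and DZ means per sex
        self.k_params = n_path + n_mean + (1 if design == "five_group" else 0)
        if data.n_families < self.k_params:
            raise ValueError(
                f"{data.n_families} families cannot identify {self.k_params} parameters"
            )
        self.param_names = self._param_names()

    # ------------------------------------------------------------------
    def _param_names(self) -> list[str]:
        names = []
        for s in self.sexes:
            for comp in self.components:
                for (i, j) in _tri_indices(self.p):
                    names.append(f"L{comp}[{i},{j}]_{s}")
        for s in self.sexes:
            for zc in ("MZ", "DZ"):
                for i in range(self.p):
                    names.append(f"mu_{zc}[{i}]_{s}")
        if self.design == "five_group":
            names.append("logit_rg_os")
        return names

    def unpack(self, theta: np.ndarray) -> CholeskyPaths:
        theta = np.asarray(theta, dtype=float)
        pos = 0
        mats: dict[str, dict[str, np.ndarray]] = {"A": {}, "C": {}, "E": {}}
        for s in self.sexes:
            for comp in self.components:
                mats[comp][s] = _vec_to_tril(theta[pos : pos + self.ntri], self.p)
                pos += self.ntri
            if self.model_tag == "AE":
                mats["C"][s] = np.zeros((self.p, self.p))
        means = {}
        for s in self.sexes:
            for zc in ("MZ", "DZ"):
                means[(zc, s)] = theta[pos : pos + self.p].copy()
                pos += self.p
        rg = _logistic(theta[pos]) if self.design == "five_group" else None
        if self.design == "single_sex":
            # same objects under both sex keys so group lookup works
            for comp in ("A", "C", "E"):
                mats[comp] = {"M": mats[comp]["*"], "F": mats[comp]["*"]}
            means = {
                (zc, s): means[(zc, "*")] for zc in ("MZ", "DZ") for s in ("M", "F")
            }
        return CholeskyPaths(
            L_A=mats["A"], L_C=mats["C"], L_E=mats["E"], means=means, rg_os=rg
        )

    def pack(self, paths: CholeskyPaths) -> np.ndarray:
        vec = []
        mats = {"A": paths.L_A, "C": paths.L_C, "E": paths.L_E}
        for s in self.sexes:
            key = "M" if s == "*" else s
            for comp in self.components:
                vec.append(_tril_to_vec(mats[comp][key]))
        for s in self.sexes:
            key = "M" if s == "*" else s
            for zc in ("MZ", "DZ"):
                vec.append(np.asarray(paths.means[(zc, key)], dtype=float))
        if self.design == "five_group":
            vec.append([_logit(paths.rg_os if paths.rg_os is not None else 0.9)])
        return np.concatenate(vec)

    # ------------------------------------------------------------------
    def loglike(self, theta: np.ndarray) -> float:
        return pair_loglikelihood(self.data, self.unpack(theta))

    def _negloglike_avg(self, theta: np.ndarray) -> float:
        ll = self.loglike(theta)
        if not np.isfinite(ll):
            return 1e10
        return -ll / self.data.n_families

    # ------------------------------------------------------------------
    def start_params(self) -> np.ndarray:
        """Moment-oracle (Falconer) starting values, floored and repaired."""
        from .moments import falconer_estimates, moment_bivariate, pair_moments

        paths_L: dict[str, dict[str, np.ndarray]] = {"A": {}, "C": {}, "E": {}}
        means: dict[tuple[str, str], np.ndarray] = {}
        for s in self.sexes:
            mz_g = MZ_GROUPS if s == "*" else (f"MZ{s}",)
            dz_g = ("DZM", "DZF") if s == "*" else (f"DZ{s}",)
            y_mz = self._stack_groups(mz_g)
            y_dz = self._stack_groups(dz_g)
            comp_cov = self._moment_component_cov(
                y_mz, y_dz, falconer_estimates, moment_bivariate, pair_moments
            )
            for comp in ("A", "C", "E"):
                C = comp_cov[comp]
                # tiny ridge so the Cholesky exists even at zero shares
                paths_L[comp][s] = np.linalg.cholesky(C + 1e-4 * np.eye(self.p))
            for zc, yy in (("MZ", y_mz), ("DZ", y_dz)):
                if yy is None:
                    mu = np.zeros(self.p)
                else:
                    t = np.vstack([yy[:, : self.p], yy[:, self.p :]])
                    mu = np.nan_to_num(np.nanmean(t, axis=0))
                means[(zc, s)] = mu
        theta = []
        for s in self.sexes:
            for comp in self.components:
                vec = _tril_to_vec(paths_L[comp][s])
                if comp == "A" and self.model_tag == "AE":
                    # fold the C start into A so total variance is preserved
                    a_cov = paths_L["A"][s] @ paths_L["A"][s].T
                    c_cov = paths_L["C"][s] @ paths_L["C"][s].T
                    vec = _tril_to_vec(np.linalg.cholesky(a_cov + c_cov + 1e-6 * np.eye(self.p)))
                theta.append(vec)
        for s in self.sexes:
            for zc in ("MZ", "DZ"):
                theta.append(means[(zc, s)])
        if self.design == "five_group":
            theta.append([_logit(0.9)])
        return np.concatenate(theta)

    def _stack_groups(self, groups: tuple[str, ...]):
        rows = np.flatnonzero(np.isin(self.data.zygosity, groups))
        return self.data.y[rows] if rows.size else None

    def _moment_component_cov(self, y_mz, y_dz, falconer, mom_biv, pair_moments):
        """Component covariance matrices from empirical co-twin moments."""
        p = self.p
        default = {"A": 0.5 * np.eye(p), "C": 0.1 * np.eye(p), "E": 0.4 * np.eye(p)}
        if y_mz is None or y_dz is None or len(y_mz) < 5 or len(y_dz) < 5:
            return default
        m_mz = pair_moments(y_mz)
        m_dz = pair_moments(y_dz)
        var = np.nanmean([m_mz["var"], m_dz["var"]], axis=0)
        out = {c: np.zeros((p, p)) for c in ("A", "C", "E")}
        for i in range(p):
            r_mz, r_dz = m_mz["r_ct"][i], m_dz["r_ct"][i]
            if not (np.isfinite(r_mz) and np.isfinite(r_dz)) or not np.isfinite(var[i]):
                return default
            est = falconer(r_mz, r_dz)
            shares = np.clip([est.a2, est.c2, est.e2], 0.05, None)
            shares = shares / shares.sum()
            for c, sh in zip(("A", "C", "E"), shares):
                out[c][i, i] = sh * var[i]
        if p == 2:
            cov_a, cov_c, cov_e = mom_biv(
                m_mz["cov_ct_cross"], m_dz["cov_ct_cross"], m_mz["cov_wp"]
            )
            if np.all(np.isfinite([cov_a, cov_c, cov_e])):
                for c, cv in zip(("A", "C", "E"), (cov_a, cov_c, cov_e)):
                    lim = 0.95 * np.sqrt(out[c][0, 0] * out[c][1, 1])
                    out[c][0, 1] = out[c][1, 0] = np.clip(cv, -lim, lim)
        return out

    # ------------------------------------------------------------------
    def fit(
        self,
        start_params: np.ndarray | None = None,
        max_restarts: int = 3,
        maxiter: int = 1000,
    ) -> "TwinModelResults":
        """Maximise the likelihood with L-BFGS-B (numerical gradients).

        The first attempt starts from the moment-oracle values; if it fails
        the convergence check, up to ``max_restarts - 1`` further attempts
        start from deterministically perturbed copies.  The best point found
        is always returned, flagged appropriately.
        """
        theta0 = np.asarray(
            self.start_params() if start_params is None else start_params, dtype=float
        )
        best = None
        for attempt in range(max(1, max_restarts)):
            if attempt == 0:
                x0 = theta0
            else:
                rng = np.random.default_rng(attempt)
                x0 = theta0 * (1.0 + 0.1 * rng.standard_normal(theta0.shape)) + \
                    0.02 * rng.standard_normal(theta0.shape)
            res = optimize.minimize(
                self._negloglike_avg,
                x0,
                method="L-BFGS-B",
                options={"maxiter": maxiter, "ftol": 1e-13, "gtol": 1e-8},
            )
            if best is None or res.fun < best.fun - 1e-12:
                best = res
            if self._converged(best):
                break
        return self._build_results(best)

    @staticmethod
    def _converged(res) -> bool:
        grad_norm = float(np.max(np.abs(res.jac)))
        return bool(res.success or grad_norm < 1e-4)

    def _build_results(self, res) -> "TwinModelResults":
        theta = self._canonicalize(res.x)
        ll, n_jitter = pair_loglikelihood(
            self.data, self.unpack(theta), return_jitter_count=True
        )
        jitter_frac = n_jitter / max(1, self.data.n_families)
        converged = self._converged(res) and jitter_frac <= 0.01
        return TwinModelResults(
            model=self,
            params=theta,
            llf=float(ll),
            converged=bool(converged),
            grad_norm=float(np.max(np.abs(res.jac))),
            n_iter=int(res.nit),
            n_jittered=int(n_jitter),
        )

    def _canonicalize(self, theta: np.ndarray) -> np.ndarray:
        """Fix latent-factor sign indeterminacies without moving the likelihood.

        E never crosses twins, so its columns flip freely per sex.  A and C
        enter the opposite-sex cross-twin block as L(M) L(F)', which ties the
        column signs of the two sexes together: only *joint* flips are
        likelihood-invariant, so those are keyed on the male diagonal (a
        residual negative female diagonal then genuinely encodes a negative
        cross-sex factor loading, not an unfixed sign).
        """
        theta = np.asarray(theta, dtype=float).copy()
        nblock = len(self.components) * self.ntri

        def block(s_idx: int, c_idx: int) -> slice:
            start = s_idx * nblock + c_idx * self.ntri
            return slice(start, start + self.ntri)

        for c_idx, comp in enumerate(self.components):
            if self.design == "five_group" and comp in ("A", "C"):
                bm, bf = block(0, c_idx), block(1, c_idx)
                L_m = _vec_to_tril(theta[bm], self.p)
                L_f = _vec_to_tril(theta[bf], self.p)
                for j in range(self.p):
                    if L_m[j, j] < 0:
                        L_m[:, j] *= -1.0
                        L_f[:, j] *= -1.0
                theta[bm] = _tril_to_vec(L_m)
                theta[bf] = _tril_to_vec(L_f)
            else:
                for s_idx in range(len(self.sexes)):
                    b = block(s_idx, c_idx)
                    theta[b] = _tril_to_vec(
                        _canonical_tril(_vec_to_tril(theta[b], self.p))
                    )
        return theta


def fit_model(
    data: PairedAgeData,
    model_tag: str = "AE",
    design: str = "five_group",
    **kwargs,
) -> "TwinModelResults":
    """Convenience wrapper: build a :class:`CholeskyTwinModel` and fit it."""
    return CholeskyTwinModel(data, model_tag=model_tag, design=design).fit(**kwargs)


# ======================================================================
# results


class TwinModelResults:
    """MLE results for a Cholesky twin model.

    Exposes the estimated paths, standardized variance components,
    component correlations (rA, rC, rE) and the model-implied phenotypic
    cross-age correlation rP per sex, the log likelihood, convergence
    diagnostics, and Wald / profile-likelihood confidence intervals.
    """

    def __init__(self, model, params, llf, converged, grad_norm, n_iter, n_jittered):
        self.model = model
        self.params = np.asarray(params, dtype=float)
        self.llf = llf
        self.converged = converged
        self.grad_norm = grad_norm
        self.n_iter = n_iter
        self.n_jittered = n_jittered
        self.paths = model.unpack(self.params)
        self.n_pairs = model.data.n_pairs()
        self._hess_inv = None

    # -- derived quantities --------------------------------------------
    @property
    def result_sexes(self) -> tuple[str, ...]:
        return ("M", "F") if self.model.design == "five_group" else ("*",)

    def standardized_components(self, sex: str | None = None) -> dict[str, np.ndarray]:
        """Per-variable standardized shares {A, C, E}, summing to 1."""
        s = self._resolve_sex(sex)
        tot = np.diag(self.paths.within_cov(s))
        return {
            c: np.diag(self.paths.component_cov(c, s)) / tot for c in ("A", "C", "E")
        }

    def _resolve_sex(self, sex: str | None) -> str:
        if self.model.design == "single_sex":
            return "M"  # both keys alias the same matrices
        if sex not in ("M", "F"):
            raise ValueError("five-group results need sex 'M' or 'F'")
        return sex

    def component_correlation(self, comp: str, sex: str | None = None) -> float:
        """rA / rC / rE between the two variables for one sex."""
        if self.model.p != 2:
            raise ValueError("component correlations need a bivariate model")
        s = self._resolve_sex(sex)
        C = self.paths.component_cov(comp, s)
        if C[0, 0] <= 1e-12 or C[1, 1] <= 1e-12:
            return np.nan  # component absent at one age: correlation undefined
        return standardize_correlation(C[0, 1], C[0, 0], C[1, 1])

    def phenotypic_correlation(self, sex: str | None = None) -> float:
        if self.model.p != 2:
            raise ValueError("phenotypic cross-age correlation needs a bivariate model")
        s = self._resolve_sex(sex)
        W = self.paths.within_cov(s)
        return standardize_correlation(W[0, 1], W[0, 0], W[1, 1])

    def quantity(self, name: str, sex: str | None = None) -> float:
        """Scalar derived quantity by name.

        Names: "rA", "rC", "rE", "rP", "rg_os", "a2_i" / "c2_i" / "e2_i"
        (standardized share of variable i in {0, 1}).
        """
        if name == "rg_os":
            return float(self.paths.rg_os)
        if name in ("rA", "rC", "rE"):
            return self.component_correlation(name[1], sex)
        if name == "rP":
            return self.phenotypic_correlation(sex)
        comp, idx = name.split("_")
        shares = self.standardized_components(sex)
        return float(shares[comp[0].upper()][int(idx)])

    # -- uncertainty ----------------------------------------------------
    def cov_params(self) -> np.ndarray:
        """Inverse observed information (numerical Hessian of -loglik)."""
        if self._hess_inv is None:
            H = numdiff.approx_hess(
                self.params, lambda t: -self.model.loglike(t)
            )
            # pseudo-inverse guards against flat directions (e.g. c2 at 0)
            self._hess_inv = np.linalg.pinv((H + H.T) / 2.0)
        return self._hess_inv

    def _quantity_fn(self, name: str, sex: str | None):
        model = self.model

        def f(theta: np.ndarray) -> float:
            r = TwinModelResults(model, theta, np.nan, True, 0.0, 0, 0)
            return r.quantity(name, sex)

        return f

    def wald_ci(self, name: str, sex: str | None = None, level: float = 0.95):
        """Delta-method CI for a derived quantity; correlations clipped to [-1, 1]."""
        f = self._quantity_fn(name, sex)
        val = f(self.params)
        if not np.isfinite(val):
            return (np.nan, np.nan)
        g = numdiff.approx_fprime(self.params, f, centered=True).ravel()
        var = float(g @ self.cov_params() @ g)
        se = np.sqrt(max(var, 0.0))
        z = norm.ppf(0.5 + level / 2.0)
        lo, hi = val - z * se, val + z * se
        if name in ("rA", "rC", "rE", "rP", "rg_os"):
            lo, hi = max(lo, -1.0), min(hi, 1.0)
        return (float(lo), float(hi))

    def profile_ci(self, name: str, sex: str | None = None, level: float = 0.95):
        """Profile-likelihood CI (see :func:`profile_ci`)."""
        from .profiling import profile_ci as _profile

        return _profile(self, name, sex=sex, level=level)

    def conf_int(
        self, name: str, sex: str | None = None, level: float = 0.95,
        method: str = "profile",
    ):
        if method == "profile":
            return self.profile_ci(name, sex=sex, level=level)[:2]
        return self.wald_ci(name, sex=sex, level=level)

    # -- reporting ------------------------------------------------------
    def summary(self) -> str:
        m = self.model
        lines = [
            f"Cholesky twin model  ({m.model_tag}, {m.design})",
            "=" * 58,
            f"variables: {', '.join(m.data.var_names)}",
            f"families: {m.data.n_families}  "
            + "  ".join(f"{g}={n}" for g, n in sorted(self.n_pairs.items())),
            f"log-likelihood: {self.llf:.4f}   converged: {self.converged}"
            f"   |grad|={self.grad_norm:.2e}  iter={self.n_iter}",
            "-" * 58,
        ]
        for s in self.result_sexes:
            label = "" if s == "*" else f" [{s}]"
            shares = self.standardized_components(None if s == "*" else s)
            for i, vn in enumerate(m.data.var_names):
                lines.append(
                    f"{vn}{label}:  A={shares['A'][i]:.3f}  "
                    f"C={shares['C'][i]:.3f}  E={shares['E'][i]:.3f}"
                )
            if m.p == 2:
                sx = None if s == "*" else s
                parts = [f"rA={self.quantity('rA', sx):+.3f}"]
                if m.model_tag == "ACE":
                    parts.append(f"rC={self.quantity('rC', sx):+.3f}")
                parts.append(f"rE={self.quantity('rE', sx):+.3f}")
                parts.append(f"rP={self.quantity('rP', sx):+.3f}")
                lines.append(f"correlations{label}:  " + "  ".join(parts))
        if self.paths.rg_os is not None:
            lines.append(f"rg_os = {self.paths.rg_os:.3f}")
        lines.append("=" * 58)
        return "\n".join(lines)

    def to_dict(self) -> dict:
        """JSON-ready serialization of estimates and diagnostics."""
        m = self.model
        out = {
            "model_tag": m.model_tag,
            "design": m.design,
            "var_names": list(m.data.var_names),
            "loglik": self.llf,
            "converged": self.converged,
            "grad_norm": self.grad_norm,
            "n_iter": self.n_iter,
            "n_jittered": self.n_jittered,
            "n_pairs": self.n_pairs,
            "n_dropped": m.data.n_dropped,
            "params": dict(zip(m.param_names, self.params.tolist())),
            "rg_os": self.paths.rg_os,
            "sexes": {},
        }
        for s in self.result_sexes:
            sx = None if s == "*" else s
            shares = self.standardized_components(sx)
            entry = {
                "A": shares["A"].tolist(),
                "C": shares["C"].tolist(),
                "E": shares["E"].tolist(),
            }
            if m.p == 2:
                entry["rA"] = self.quantity("rA", sx)
                entry["rE"] = self.quantity("rE", sx)
                entry["rP"] = self.quantity("rP", sx)
                if m.model_tag == "ACE":
                    entry["rC"] = self.quantity("rC", sx)
            out["sexes"][s] = entry
        return out
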