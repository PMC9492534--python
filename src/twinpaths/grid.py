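"""Age-to-age correlation grids from repeated bivariate Cholesky fits.

One bivariate twin model is fitted independently per unordered age pair
(j < k), and the resulting phenotypic, additive-genetic, shared- and
unique-environmental correlations are collected per sex into a grid covering
every age combination — the structure displayed in the square matrices with
males in the upper and females in the lower triangle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from .model import (
    CholeskyTwinModel,
    paired_from_panel,
    standardize_correlation,  # noqa: F401  (re-exported: grid-level surface)
)

logger = logging.getLogger(__name__)

GRID_COLUMNS = [
    "sex",
    "age_j",
    "age_k",
    "r_trait",
    "r_A",
    "r_C",
    "r_E",
    "r_A_lo",
    "r_A_hi",
    "r_E_lo",
    "r_E_hi",
    "n_pairs",
    "converged",
    "skipped",
]


def decompose_phenotypic_correlation(
    a1: float, a2: float, c1: float, c2: float, e1: float, e2: float,
    r_a: float, r_c: float, r_e: float,
) -> float:
    """Phenotypic cross-age correlation rP = a1 rA a2 + c1 rC c2 + e1 rE e2.

    Inputs are standardized paths (square roots of the variance shares), so
    a^2 + c^2 + e^2 must equal 1 for each variable.  A component with zero
    paths contributes nothing regardless of its (then-undefined) correlation.
    """
    for tag, (a, c, e) in {"1": (a1, c1, e1), "2": (a2, c2, e2)}.items():
        tot = a * a + c * c + e * e
        if abs(tot - 1.0) > 1e-6:
            raise ValueError(
                f"paths for variable {tag} are not standardized (a2+c2+e2={tot})"
            )
    terms = 0.0
    for x1, x2, r in ((a1, a2, r_a), (c1, c2, r_c), (e1, e2, r_e)):
        w = x1 * x2
        terms += 0.0 if w == 0.0 else w * r
    return float(terms)


@dataclass
class CorrelationGrid:
    """All pairwise age-to-age correlation estimates for one trait."""

    trait: str
    model_tag: str
    design: str
    ages: list[int]
    table: pd.DataFrame
    summary: dict = field(default_factory=dict)
    fits: dict = field(default_factory=dict, repr=False)

    @property
    def sexes(self) -> tuple[str, ...]:
        return tuple(sorted(self.table["sex"].unique()))

    def n_coefficients(self, quantity: str = "r_A") -> int:
        """Count of estimated (non-skipped) coefficients of one kind."""
        ok = ~self.table["skipped"] & self.table[quantity].notna()
        return int(ok.sum())

    def to_matrix(self, quantity: str = "r_A") -> pd.DataFrame:
        """Square age-by-age matrix: males upper triangle, females lower.

        In a single-sex grid, the single series fills both triangles.
        """
        m = pd.DataFrame(np.nan, index=self.ages, columns=self.ages, dtype=float)
        for row in self.table.itertuples():
            if row.skipped:
                continue
            val = getattr(row, quantity)
            j, k = int(row.age_j), int(row.age_k)
            if row.sex in ("M", "*"):
                m.loc[j, k] = val  # upper triangle: males
            if row.sex in ("F", "*"):
                m.loc[k, j] = val  # lower triangle: females
        return m

    def write(self, path: str | Path) -> None:
        out = self.table.copy()
        out.to_csv(path, index=False, columns=GRID_COLUMNS, float_format="%.6g")

    def write_matrices(self, directory: str | Path, quantities=None) -> list[Path]:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        if quantities is None:
            quantities = ["r_trait", "r_A", "r_E"] + (
                ["r_C"] if self.model_tag == "ACE" else []
            )
        written = []
        for q in quantities:
            p = directory / f"{self.trait}_{q}.csv"
            self.to_matrix(q).to_csv(p, float_format="%.6g")
            written.append(p)
        return written

    def plot_heatmap(self, quantity: str, path: str | Path, vmin=-0.2, vmax=1.0):
        """Basic heatmap of one quantity's matrix (males upper / females lower)."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        m = self.to_matrix(quantity)
        fig, ax = plt.subplots(figsize=(6, 5))
        im = ax.imshow(m.to_numpy(), vmin=vmin, vmax=vmax, cmap="viridis",
                       origin="upper", extent=None)
        ax.set_xticks(range(len(self.ages)), self.ages, fontsize=6)
        ax.set_yticks(range(len(self.ages)), self.ages, fontsize=6)
        ax.set_xlabel("age (males: columns of upper triangle)")
        ax.set_ylabel("age (females: rows of lower triangle)")
        ax.set_title(f"{self.trait} {quantity}")
        fig.colorbar(im, ax=ax)
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)


def _cell_row(sex, j, k, results, ci_method, n_pairs):
    sx = None if sex == "*" else sex
    row = {
        "sex": sex,
        "age_j": j,
        "age_k": k,
        "r_trait": results.quantity("rP", sx),
        "r_A": results.quantity("rA", sx),
        "r_C": results.quantity("rC", sx) if results.model.model_tag == "ACE" else np.nan,
        "r_E": results.quantity("rE", sx),
        "n_pairs": n_pairs,
        "converged": results.converged,
        "skipped": False,
    }
    for q, lo_c, hi_c in (("rA", "r_A_lo", "r_A_hi"), ("rE", "r_E_lo", "r_E_hi")):
        if ci_method == "none":
            row[lo_c] = row[hi_c] = np.nan
        elif ci_method == "profile":
            lo, hi, _ = results.profile_ci(q, sex=sx)
            row[lo_c], row[hi_c] = lo, hi
        else:
            row[lo_c], row[hi_c] = results.wald_ci(q, sex=sx)
    return row


def run_grid(
    panel: pd.DataFrame,
    trait: str,
    ages=None,
    model_tag: str = "AE",
    design: str = "five_group",
    ci_method: str = "wald",
    min_pairs: int = 30,
    max_restarts: int = 3,
    keep_fits: bool = False,
) -> CorrelationGrid:
    """Fit one bivariate model per age pair and assemble the grid.

    Parameters
    ----------
    panel : residualized long panel (see :func:`twinpaths.preprocessing.build_panel`)
    trait : "logbmi" or "height"
    ages : iterable of int, default all ages present for the trait
    model_tag, design : passed to :class:`CholeskyTwinModel`
    ci_method : {"wald", "profile", "none"} per-cell CI computation
    min_pairs : cells with fewer informative families are skipped (marked,
        not silently dropped)

    Returns a :class:`CorrelationGrid` whose table has one row per
    (sex, age_j < age_k) cell; a five-group design yields both sexes from
    each fit (2 * n_pairs(ages) coefficients per quantity).
    """
    panel_ages = sorted(panel.loc[panel["trait"] == trait, "age"].unique())
    if ages is None:
        ages = panel_ages
    ages = sorted(int(a) for a in ages)
    usable = [a for a in ages if a in panel_ages]
    if not usable:
        raise ValueError(f"no requested ages present in panel for trait {trait!r}")
    if len(usable) < 2:
        raise ValueError("need at least two ages to form an age pair")
    if len(usable) < len(ages):
        logger.warning("ages %s absent from panel; using %s",
                       sorted(set(ages) - set(usable)), usable)

    sexes = ("M", "F") if design == "five_group" else ("*",)
    rows = []
    fits: dict = {}
    n_fitted = n_skipped = n_converged = 0
    for j, k in combinations(usable, 2):
        data = paired_from_panel(panel, trait, (j, k))
        enough = data.n_families >= min_pairs
        groups_ok = design != "five_group" or len(data.groups) == 5
        if not (enough and groups_ok):
            reason = "too few pairs" if not enough else "missing zygosity group"
            logger.warning("skipping cell (%d, %d): %s (n=%d)", j, k, reason,
                           data.n_families)
            n_skipped += 1
            for sex in sexes:
                rows.append({
                    "sex": sex, "age_j": j, "age_k": k, "r_trait": np.nan,
                    "r_A": np.nan, "r_C": np.nan, "r_E": np.nan,
                    "r_A_lo": np.nan, "r_A_hi": np.nan,
                    "r_E_lo": np.nan, "r_E_hi": np.nan,
                    "n_pairs": data.n_families, "converged": False, "skipped": True,
                })
            continue
        results = CholeskyTwinModel(data, model_tag=model_tag, design=design).fit(
            max_restarts=max_restarts
        )
        n_fitted += 1
        n_converged += int(results.converged)
        if keep_fits:
            fits[(j, k)] = results
        counts = results.n_pairs
        for sex in sexes:
            if sex == "*":
                n_sex = sum(counts.values())
            else:
                n_sex = sum(
                    counts.get(g, 0)
                    for g in (f"MZ{sex}", f"DZ{sex}", "OSDZ")
                )
            rows.append(_cell_row(sex, j, k, results, ci_method, n_sex))

    table = pd.DataFrame(rows, columns=GRID_COLUMNS)
    table = table.sort_values(["sex", "age_j", "age_k"], kind="mergesort").reset_index(
        drop=True
    )
    n_cells = len(list(combinations(usable, 2)))
    grid = CorrelationGrid(
        trait=trait,
        model_tag=model_tag,
        design=design,
        ages=usable,
        table=table,
        fits=fits,
        summary={
            "n_age_pairs": n_cells,
            "n_cells_fitted": n_fitted,
            "n_cells_skipped": n_skipped,
            "n_cells_converged": n_converged,
            "n_coefficients": int((~table["skipped"]).sum()),
        },
    )
    return grid
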