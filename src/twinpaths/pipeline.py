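"""End-to-end pipeline: simulate (or load) -> preprocess -> grids -> report.

All randomness flows from the single pipeline seed through named substreams,
and every output file (cohort CSV, panel CSV, grid CSVs, matrices, report
JSON, MANIFEST) is written deterministically, so a rerun with the same
config and seed reproduces the outputs byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .config import ConfigError, SimulationConfig, pairs_from_total
from .grid import run_grid
from .preprocessing import build_panel, write_panel_csv
from .simulate import write_cohort_csv, simulate_cohort

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Configuration of a full analysis run.

    ``input_csv`` switches the first stage between loading an existing
    cohort and simulating one (``n_pairs_total`` pairs split by the default
    zygosity mix, or a full :class:`SimulationConfig` under ``sim``).
    ``stratify_by`` reruns every grid within each level of a cohort column
    (e.g. per study cohort or region) in addition to the pooled run.
    """

    out_dir: str = "twinpaths_run"
    input_csv: str | None = None
    sim: SimulationConfig | None = None
    n_pairs_total: int = 1000
    traits: tuple[str, ...] = ("logbmi", "height")
    ages: tuple[int, int] = (1, 19)
    model_tag: str = "AE"
    design: str = "five_group"
    ci_method: str = "wald"
    min_pairs: int = 30
    stratify_by: str | None = None
    heatmaps: bool = False
    seed: int = 0
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        lo, hi = self.ages
        if not (1 <= lo < hi <= 19):
            raise ConfigError(f"age range {self.ages} must satisfy 1 <= lo < hi <= 19")
        if self.model_tag not in ("AE", "ACE"):
            raise ConfigError("model_tag must be 'AE' or 'ACE'")
        if self.ci_method not in ("profile", "wald", "none"):
            raise ConfigError("ci_method must be 'profile', 'wald' or 'none'")
        if self.design not in ("five_group", "single_sex"):
            raise ConfigError("design must be 'five_group' or 'single_sex'")

    @property
    def age_list(self) -> list[int]:
        return list(range(self.ages[0], self.ages[1] + 1))

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        sim = data.pop("sim", None)
        cfg = cls(**{k: v for k, v in data.items() if k != "sim"})
        if sim is not None:
            cfg.sim = SimulationConfig.from_dict(sim)
        if "ages" in data:
            cfg.ages = tuple(data["ages"])
        if "traits" in data:
            cfg.traits = tuple(data["traits"])
        return cfg


def _stage_seeds(seed: int) -> dict[str, int]:
    state = np.random.SeedSequence(seed).generate_state(4)
    names = ("simulate", "reserved1", "reserved2", "reserved3")
    return {n: int(s % (2**31)) for n, s in zip(names, state)}


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=1, sort_keys=True) + "\n")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage; return (and write) the machine-readable report.

    On stage failure the report carries the failing stage and cause, partial
    outputs stay on disk, and the MANIFEST is marked incomplete.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    report: dict = {
        "seed": config.seed,
        "stage_seeds": seeds,
        "versions": {
            "twinpaths": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "stages": {},
        "error": None,
    }
    manifest: list[str] = []
    stage = "setup"
    try:
        # ---- stage 1: cohort -----------------------------------------
        stage = "simulate"
        if config.input_csv is not None:
            cohort = pd.read_csv(config.input_csv)
            report["stages"][stage] = {"source": str(config.input_csv),
                                       "n_records": len(cohort)}
        else:
            sim = config.sim or SimulationConfig(
                n_pairs=pairs_from_total(config.n_pairs_total),
                ages=config.age_list,
            )
            cohort = simulate_cohort(sim, seed=seeds["simulate"])
            write_cohort_csv(cohort, out / "cohort.csv")
            sim.to_yaml(out / "sim_config.yaml")
            manifest += ["cohort.csv", "sim_config.yaml"]
            report["stages"][stage] = {
                "n_records": len(cohort),
                "n_pairs": {k: int(v) for k, v in sim.n_pairs.items()},
                "seed": seeds["simulate"],
            }
        logger.info("stage %s done: %d records", stage, len(cohort))

        # ---- stage 2: preprocessing ----------------------------------
        stage = "preprocess"
        panel = build_panel(cohort, traits=config.traits)
        write_panel_csv(panel, out / "panel.csv")
        manifest.append("panel.csv")
        report["stages"][stage] = {
            "n_values": len(panel),
            "n_strata": int(panel.groupby(["trait", "age", "sex"]).ngroups),
        }
        logger.info("stage %s done: %d residualized values", stage, len(panel))

        # ---- stage 3: grids ------------------------------------------
        stage = "grid"
        strata: list[tuple[str, pd.DataFrame]] = [("pooled", panel)]
        if config.stratify_by is not None:
            col = config.stratify_by
            if col not in cohort.columns:
                raise ConfigError(f"stratification column {col!r} not in cohort")
            fam_level = cohort.drop_duplicates("family_id").set_index("family_id")[col]
            for level in sorted(fam_level.unique()):
                fams = fam_level[fam_level == level].index
                strata.append((str(level), panel[panel["family_id"].isin(fams)]))

        grid_report = {}
        traits = tuple("logbmi" if t == "bmi" else t for t in config.traits)
        for label, sub_panel in strata:
            for trait in traits:
                grid = run_grid(
                    sub_panel,
                    trait,
                    ages=config.age_list,
                    model_tag=config.model_tag,
                    design=config.design,
                    ci_method=config.ci_method,
                    min_pairs=config.min_pairs,
                )
                tag = trait if label == "pooled" else f"{trait}_{label}"
                grid.write(out / f"grid_{tag}.csv")
                manifest.append(f"grid_{tag}.csv")
                written = grid.write_matrices(out / "matrices" / tag)
                manifest += [str(p.relative_to(out)) for p in written]
                if config.heatmaps:
                    for q in ("r_trait", "r_A", "r_E"):
                        hp = out / "matrices" / tag / f"{q}.png"
                        grid.plot_heatmap(q, hp)
                grid_report[tag] = grid.summary
                logger.info("grid %s: %s", tag, grid.summary)
        report["stages"][stage] = grid_report
    except Exception as exc:  # record the failing stage, keep partial outputs
        report["error"] = {"stage": stage, "cause": f"{type(exc).__name__}: {exc}"}
        _write_json(out / "report.json", report)
        (out / "MANIFEST").write_text(
            "\n".join(["# INCOMPLETE RUN", *manifest]) + "\n"
        )
        raise

    _write_json(out / "report.json", report)
    manifest.append("report.json")
    (out / "MANIFEST").write_text("\n".join(manifest) + "\n")
    return report
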