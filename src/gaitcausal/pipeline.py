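"""End-to-end orchestration: cohort in (CSV or simulator), report out.

Stages run in protocol order — screen, code, bootstrap-stabilized
structure discovery, outcome-parent selection, confirmatory logistic
regression, LASSO robustness check — and the run report carries a
provenance block (config hash, seed, package versions) sufficient to
reproduce the run bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import (BinaryDesign, CohortTable, apply_screening,
                     default_variable_specs, define_outcome,
                     descriptive_table, make_binary_design)
from .direct_lingam import fit_direct_lingam
from .ensemble import (EnsembleConfig, EnsembleGraph, build_ensemble_graph,
                       select_outcome_parents, stability_report)
from .models import (LassoConfig, fit_lasso_logistic, fit_logistic,
                     forest_table)
from .simulate import (CohortSimSpec, generate_cohort,
                       generate_screening_fixture)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "validate_config"]

OUTCOME_NODE = "walking_with_supervision"


@dataclass
class PipelineConfig:
    """One input source (cohort CSV path or simulator spec), the protocol
    parameters, and a root seed that fixes every stochastic step."""

    cohort_csv: str | None = None
    simulator: CohortSimSpec | None = None
    outcome_cutoff: int = 5
    dichotomize_direction: Literal[">", ">="] = ">"
    ensemble: EnsembleConfig = field(default_factory=EnsembleConfig)
    lasso: LassoConfig = field(default_factory=LassoConfig)
    run_screening: bool = False
    run_lasso: bool = True
    output_dir: str | None = None
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        # one input source exactly; the seed propagates to both stages
        self.ensemble = dataclasses.replace(self.ensemble, seed=self.seed)
        self.lasso = dataclasses.replace(self.lasso, seed=self.seed)

    def to_dict(self) -> dict:
        d = {
            "cohort_csv": self.cohort_csv,
            "simulator": None if self.simulator is None else {
                "n_patients": self.simulator.n_patients,
                "seed": self.simulator.seed,
                "intercept": self.simulator.intercept,
                "target_prevalence": self.simulator.target_prevalence,
                "outcome_coefs": self.simulator.outcome_coefs,
            },
            "outcome_cutoff": self.outcome_cutoff,
            "dichotomize_direction": self.dichotomize_direction,
            "ensemble": dataclasses.asdict(self.ensemble),
            "lasso": dataclasses.asdict(self.lasso),
            "run_screening": self.run_screening,
            "run_lasso": self.run_lasso,
            "seed": self.seed,
        }
        return d

    def content_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        if "ensemble" in kwargs:
            kwargs["ensemble"] = EnsembleConfig(**kwargs["ensemble"])
        if "lasso" in kwargs:
            kwargs["lasso"] = LassoConfig(**kwargs["lasso"])
        if kwargs.get("simulator") is not None:
            kwargs["simulator"] = CohortSimSpec(**kwargs["simulator"])
        return cls(**kwargs)


def validate_config(config: PipelineConfig) -> list[dict]:
    """Static checks; empty list means runnable.  Findings carry a level
    ('error' stops a run, 'warning' does not) and a message."""
    findings: list[dict] = []

    def err(msg: str) -> None:
        findings.append({"level": "error", "message": msg})

    def warn(msg: str) -> None:
        findings.append({"level": "warning", "message": msg})

    n_sources = (config.cohort_csv is not None) + (config.simulator is not None)
    if n_sources != 1:
        err(f"exactly one input source required, got {n_sources}")
    if config.cohort_csv is not None and not Path(config.cohort_csv).exists():
        err(f"cohort CSV not found: {config.cohort_csv}")
    if config.ensemble.n_boot < 1:
        err("n_boot must be >= 1")
    roster = {s.name for s in default_variable_specs()}
    if config.simulator is not None:
        unknown = set(config.simulator.outcome_coefs) - roster
        if unknown:
            err(f"outcome parents not in roster: {sorted(unknown)}")
    if not (1 <= config.outcome_cutoff <= 7):
        err(f"outcome cutoff {config.outcome_cutoff} outside the 1-7 scale")
    if config.ensemble.stability_min != 0.20:
        warn(f"stability_min={config.ensemble.stability_min} differs from "
             "the protocol default 0.20")
    if config.ensemble.edge_threshold != 0.05:
        warn(f"edge_threshold={config.ensemble.edge_threshold} differs from "
             "the protocol default 0.05")
    if config.ensemble.n_boot < 200:
        warn(f"n_boot={config.ensemble.n_boot} is small; edge stability "
             "estimates will be noisy")
    return findings


@dataclass
class RunReport:
    """Everything a run produced, stage by stage."""

    provenance: dict
    screening_tally: dict | None
    descriptive: pd.DataFrame
    ensemble_edges: pd.DataFrame
    stability: pd.DataFrame
    selected_parents: list[str]
    logistic_forest: pd.DataFrame
    lasso_forest: pd.DataFrame
    removal_log: list[dict]
    bootstrap_failures: int
    coding_log: dict
    degenerate_columns: list[str]

    def to_json_dict(self) -> dict:
        return {
            "provenance": self.provenance,
            "screening_tally": self.screening_tally,
            "descriptive": self.descriptive.reset_index().to_dict(orient="records"),
            "ensemble_edges": self.ensemble_edges.to_dict(orient="records"),
            "stability": self.stability.to_dict(orient="records"),
            "selected_parents": self.selected_parents,
            "logistic_forest": self.logistic_forest.to_dict(orient="records"),
            "lasso_forest": self.lasso_forest.to_dict(orient="records"),
            "removal_log": self.removal_log,
            "bootstrap_failures": self.bootstrap_failures,
            "coding_log": self.coding_log,
            "degenerate_columns": self.degenerate_columns,
        }

    def to_json(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_json_dict(), fh, indent=2, sort_keys=True,
                      default=_jsonify)

    def content_hash(self) -> str:
        payload = json.dumps(self.to_json_dict(), sort_keys=True,
                             default=_jsonify)
        return hashlib.sha256(payload.encode()).hexdigest()


def _jsonify(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return None if np.isnan(x) else float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, float) and np.isnan(x):
        return None
    return str(x)


def _load_cohort(config: PipelineConfig) -> CohortTable:
    if config.cohort_csv is not None:
        return CohortTable.from_csv(config.cohort_csv)
    assert config.simulator is not None
    return generate_cohort(config.simulator)


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute all stages; identical config + seed gives a byte-identical
    report.  Any stage failure aborts with the stage name attached."""
    logging.basicConfig(level=config.log_level)
    findings = validate_config(config)
    errors = [f for f in findings if f["level"] == "error"]
    if errors:
        raise ValueError(f"invalid config: {[e['message'] for e in errors]}")
    for f in findings:
        logger.warning("config: %s", f["message"])

    stage = "screen"
    try:
        tally = None
        if config.run_screening:
            records = generate_screening_fixture(seed=config.seed)
            _, tally = apply_screening(records)

        stage = "load-cohort"
        cohort = _load_cohort(config)

        stage = "code"
        design: BinaryDesign = make_binary_design(
            cohort, direction=config.dichotomize_direction,
            outcome_cutoff=config.outcome_cutoff)
        outcome = define_outcome(cohort, cutoff=config.outcome_cutoff)
        table1 = descriptive_table(cohort, outcome)

        stage = "discover"
        names = design.columns + [OUTCOME_NODE]
        X = np.column_stack([design.matrix.to_numpy(dtype=float),
                             outcome.astype(float)])
        learner = lambda Xb: fit_direct_lingam(Xb)[1]  # noqa: E731
        eg, failures = build_ensemble_graph(X, learner, config.ensemble, names)
        assert eg.final_dag is not None

        stage = "select"
        parents = select_outcome_parents(eg.final_dag, OUTCOME_NODE)
        stab = stability_report(eg, config.ensemble)

        stage = "logistic"
        if parents:
            logit_fit = fit_logistic(design, parents)
            logit_forest = forest_table(logit_fit, parents)
        else:
            logit_forest = forest_table(
                fit_logistic(design), design.columns).iloc[0:0]

        stage = "lasso"
        if config.run_lasso:
            lasso_fit = fit_lasso_logistic(design, config=config.lasso)
            lasso_forest = forest_table(lasso_fit)
        else:
            lasso_forest = pd.DataFrame(
                columns=["term", "or", "ci_low", "ci_high"])

        stage = "report"
        provenance = {
            "config": config.to_dict(),
            "config_hash": config.content_hash(),
            "seed": config.seed,
            "package_version": __version__,
            "versions": _library_versions(),
        }
        report = RunReport(
            provenance=provenance,
            screening_tally=tally,
            descriptive=table1,
            ensemble_edges=eg.to_edge_frame(),
            stability=stab,
            selected_parents=parents,
            logistic_forest=logit_forest,
            lasso_forest=lasso_forest,
            removal_log=eg.removal_log,
            bootstrap_failures=failures,
            coding_log=design.coding_log,
            degenerate_columns=design.degenerate,
        )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    if config.output_dir is not None:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        report.to_json(str(out / "run_report.json"))
        report.descriptive.to_csv(out / "descriptive_table.csv")
        report.stability.to_csv(out / "stability_report.csv", index=False)
        report.logistic_forest.to_csv(out / "logistic_forest.csv", index=False)
        report.lasso_forest.to_csv(out / "lasso_forest.csv", index=False)
        if eg.final_dag is not None:
            (out / "final_dag.dot").write_text(eg.final_dag.to_dot(),
                                               encoding="utf-8")
    return report


def _library_versions() -> dict:
    import networkx
    import scipy
    import sklearn
    import statsmodels

    return {
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "statsmodels": statsmodels.__version__,
        "sklearn": sklearn.__version__,
        "networkx": networkx.__version__,
    }
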