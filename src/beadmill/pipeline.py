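"""End-to-end workflow: fit → ANOVA → reduce → optimize (RSM and ANN-GA).

A :class:`PipelineReport` embeds every setting and seed used, so a rerun from
the report's configuration reproduces it exactly (timestamps excluded).  The
economic comparison is deliberately minimal: a single fold-change of two
productivity figures (mg COD/USD/day); no cost model is implemented.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import ann, design, ga, rsm

log = logging.getLogger("beadmill")

__all__ = [
    "PipelineConfig",
    "PipelineReport",
    "PipelineError",
    "run_pipeline",
    "fold_productivity",
]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


@dataclass
class PipelineConfig:
    """Every tunable of the workflow, with library defaults.

    ``optimum_bounds`` are coded-unit bounds for the polynomial optimum and
    actual-unit bounds for the GA (per factor, low/high); when None the axial
    box of the design is used for both.
    """

    anova_spec: str = "fifteen"  # "fifteen" | "eleven"
    p_individual: float = 0.05
    p_interaction: float = 0.10
    hierarchy: bool = True
    grid_points: int = 21
    hidden_sizes: tuple[int, ...] = (10,)
    split: tuple[int, int, int] = (20, 5, 5)
    max_epochs: int = 300
    patience: int = 6
    population_size: int = 50
    generations: int = 100
    crossover_fraction: float = 0.8
    mutation_scale: float = 0.1
    elite_count: int = 2
    alpha: float = design.DEFAULT_ALPHA
    seed: int = 0

    def term_spec(self) -> rsm.TermSpec:
        if self.anova_spec == "fifteen":
            return rsm.FIFTEEN_TERMS
        if self.anova_spec == "eleven":
            return rsm.ELEVEN_TERMS
        raise ValueError(f"unknown anova_spec {self.anova_spec!r}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["hidden_sizes"] = list(self.hidden_sizes)
        d["split"] = list(self.split)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        kwargs = dict(d)
        if "hidden_sizes" in kwargs:
            kwargs["hidden_sizes"] = tuple(kwargs["hidden_sizes"])
        if "split" in kwargs:
            kwargs["split"] = tuple(kwargs["split"])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


@dataclass
class PipelineReport:
    config: dict
    input_hash: str
    design_summary: dict
    anova: dict
    reduced_terms: list[str]
    reduced_anova: dict
    rsm_optimum: dict
    ann_training: dict
    ga_optimum: dict
    stage_seconds: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    def to_text(self) -> str:
        lines = [
            "bead-milling optimization report",
            f"input sha256: {self.input_hash}",
            f"runs: {self.design_summary['n_runs']}  "
            f"(factorial {self.design_summary['n_factorial']}, "
            f"axial {self.design_summary['n_axial']}, "
            f"center {self.design_summary['n_center']})",
            "",
            f"full model R^2 = {self.anova['summary']['r2']:.4f}, "
            f"model F = {self.anova['rows'][0]['f']:.2f}, "
            f"pred R^2 = {self.anova['summary']['pred_r2']:.4f}",
            f"reduced terms: {', '.join(self.reduced_terms)}",
            "",
            "RSM optimum (actual units): "
            + ", ".join(f"{v:.2f}" for v in self.rsm_optimum["actual"])
            + f" -> {self.rsm_optimum['value']:.3f} g/L",
            "GA-ANN optimum (actual units): "
            + ", ".join(f"{v:.2f}" for v in self.ga_optimum["actual"])
            + f" -> {self.ga_optimum['value']:.3f} g/L",
            f"ANN stop: {self.ann_training['stop_reason']} "
            f"(best epoch {self.ann_training['best_epoch']})",
        ]
        return "\n".join(lines)


def _hash_table(table: design.DesignTable) -> str:
    payload = repr(
        (table.actual_matrix.tolist(),
         None if table.response is None else table.response.tolist())
    ).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def _stage(name: str, report_times: dict, fn, *args, **kwargs):
    t0 = time.perf_counter()
    try:
        out = fn(*args, **kwargs)
    except Exception as exc:  # noqa: BLE001 - reported with stage context
        raise PipelineError(f"stage {name!r} failed: {exc}") from exc
    dt = time.perf_counter() - t0
    report_times[name] = round(dt, 4)
    log.info("stage=%s elapsed=%.3fs", name, dt)
    return out


def run_pipeline(
    source,
    config: PipelineConfig = PipelineConfig(),
) -> PipelineReport:
    """Run the full workflow on a design CSV path or a DesignTable."""
    if isinstance(source, design.DesignTable):
        table = source
    else:
        table = design.load_design_csv(source)
    if table.response is None:
        raise PipelineError("stage 'load' failed: design has no response column")
    input_hash = _hash_table(table)
    log.info("input=%s seed=%d", input_hash, config.seed)
    times: dict = {}

    classes = [pt.point_class for pt in table.points]
    summary = {
        "n_runs": table.n_runs,
        "n_factorial": classes.count("factorial"),
        "n_axial": classes.count("axial"),
        "n_center": classes.count("center"),
        "response_min": float(np.min(table.response)),
        "response_max": float(np.max(table.response)),
    }

    spec = config.term_spec()
    fit = _stage("fit", times, rsm.fit_ols, table, spec)
    report = _stage("anova", times, rsm.anova_type3, fit, table)
    reduced_spec = _stage(
        "reduce", times, rsm.reduce_model, report,
        config.p_individual, config.p_interaction, config.hierarchy,
    )
    reduced_fit = _stage("refit", times, rsm.fit_ols, table, reduced_spec)
    reduced_report = _stage("anova_reduced", times, rsm.anova_type3,
                            reduced_fit, table)

    a = config.alpha
    coded_bounds = [(-a, a)] * len(table.factors)
    opt = _stage(
        "optimize_rsm", times, rsm.rsm_optimum,
        reduced_fit, coded_bounds, table.factors, config.grid_points,
    )

    ann_cfg = ann.TrainingConfig(
        hidden_sizes=config.hidden_sizes,
        split=config.split,
        seed=config.seed,
        max_epochs=config.max_epochs,
        patience=config.patience,
    )
    net, norms, record = _stage("train_ann", times, ann.train_lm, table, ann_cfg)

    # the surrogate's training range (for the packaged design this is the
    # axial box); using it verbatim keeps chained CLI runs bit-identical
    actual_bounds = list(zip(norms[0].lo, norms[0].hi))
    ga_cfg = ga.GaConfig(
        population_size=config.population_size,
        generations=config.generations,
        crossover_fraction=config.crossover_fraction,
        mutation_scale=config.mutation_scale,
        elite_count=config.elite_count,
        seed=config.seed,
    )
    best, value, ga_result = _stage(
        "optimize_ga", times, ga.optimize_surrogate,
        (net, norms), actual_bounds, ga_cfg,
    )

    return PipelineReport(
        config=config.to_dict(),
        input_hash=input_hash,
        design_summary=summary,
        anova=report.to_dict(),
        reduced_terms=reduced_spec.names,
        reduced_anova=reduced_report.to_dict(),
        rsm_optimum={
            "coded": list(opt.coded),
            "actual": list(opt.actual),
            "value": opt.value,
        },
        ann_training={
            "stop_reason": record.stop_reason,
            "best_epoch": record.best_epoch,
            "best_val_mse": record.best_val_mse,
            "final_train_mse": record.train_mse[-1] if record.train_mse else None,
            "epochs": len(record.train_mse),
        },
        ga_optimum={
            "actual": best.tolist(),
            "value": value,
            "generations": len(ga_result.history_best),
        },
        stage_seconds=times,
    )


def fold_productivity(value_a: float, value_b: float) -> float:
    """Fold change value_a / value_b of two productivities (mg COD/USD/day)."""
    if value_b == 0:
        raise ValueError("reference productivity must be nonzero")
    return value_a / value_b
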