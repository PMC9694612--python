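"""End-to-end orchestration: simulate → encode/scale → train → evaluate →
sensitivity → optimize, with reproducible seeding and atomic report output.

A single global seed fans out to the stochastic stages by fixed offsets
(simulation +1, splitting +2, training +3, genetic algorithm +4), so stages
are individually reproducible while remaining independent.
"""

from __future__ import annotations

import os
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .design import AGRONOMIC_RESPONSES, DesignSpec, EO_RESPONSES, RESPONSE_NAMES
from .fit_stats import fit_table
from .io import (
    ResponseScaler,
    SplitIndices,
    encode_design,
    read_trial_csv,
    split_indices,
    write_trial_csv,
)
from .mlp import (
    TrainedModel,
    TrainingConfig,
    load_params_text,
    save_params_text,
    search_architectures,
    train_mlp,
)
from .moo import GAConfig, best_condition_per_output, ga_optimize
from .sensitivity import yoon_relative_importance
from .simulate import EffectsConfig, default_effects, generate_trial

__all__ = ["RunConfig", "ReportBundle", "run_pipeline", "save_trained_model", "load_trained_model"]

# seed offsets per stage
_SEED_SIMULATE, _SEED_SPLIT, _SEED_TRAIN, _SEED_GA = 1, 2, 3, 4


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs have been removed."""


@dataclass
class RunConfig:
    """Everything needed to reproduce a full pipeline run."""

    outdir: str = "anisann_run"
    seed: int = 0
    table_path: str | None = None          # None → simulate
    effects_path: str | None = None        # None → default effect tables
    split_fractions: tuple[float, float, float] = (0.6, 0.2, 0.2)
    hidden_sizes: tuple[int, ...] = (10,)
    activations: tuple[tuple[str, str], ...] = (("exponential", "exponential"),)
    restarts: int = 50
    max_iterations: int = 1000
    n_const: int = 1
    ga_population: int = 100
    ga_generations: int = 200
    ga_mode: str = "discrete"
    design: DesignSpec = field(default_factory=DesignSpec)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "design" in d:
            d["design"] = DesignSpec(
                years=tuple(d["design"]["years"]),
                localities=tuple(d["design"]["localities"]),
                fertilizations=tuple(d["design"]["fertilizations"]),
                replications=int(d["design"].get("replications", 4)),
            )
        if "split_fractions" in d:
            d["split_fractions"] = tuple(d["split_fractions"])
        if "hidden_sizes" in d:
            d["hidden_sizes"] = tuple(d["hidden_sizes"])
        if "activations" in d:
            d["activations"] = tuple(tuple(a) for a in d["activations"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class ReportBundle:
    """Paths and in-memory artifacts of one completed run."""

    outdir: Path
    table: pd.DataFrame
    architecture_summary: pd.DataFrame
    model: TrainedModel
    fit_agronomic: pd.DataFrame
    fit_eo: pd.DataFrame
    relative_importance: pd.DataFrame
    pareto_front: pd.DataFrame
    per_output_optima: pd.DataFrame
    files: list[str]


class _AtomicWriter:
    """Write files via temp + rename; remove everything written on failure."""

    def __init__(self, outdir: Path):
        self.outdir = outdir
        self.written: list[Path] = []

    def write_df(self, df: pd.DataFrame, name: str, index: bool = False) -> None:
        tmp = self.outdir / f".tmp-{name}"
        df.to_csv(tmp, index=index, float_format="%.17g", encoding="utf-8")
        self._commit(tmp, name)

    def write_text(self, fn, name: str) -> None:
        tmp = self.outdir / f".tmp-{name}"
        fn(tmp)
        self._commit(tmp, name)

    def _commit(self, tmp: Path, name: str) -> None:
        final = self.outdir / name
        os.replace(tmp, final)
        self.written.append(final)

    def rollback(self) -> None:
        for p in self.written:
            p.unlink(missing_ok=True)


def save_trained_model(model: TrainedModel, outdir: str | Path,
                       params_name: str = "model.txt",
                       meta_name: str = "model_meta.yaml") -> None:
    """Persist a trained model as a text weight file plus YAML metadata."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    save_params_text(model.params, outdir / params_name)
    meta = {
        "output_names": list(model.output_names),
        "scaler": model.scaler.to_dict(),
        "split": model.split.to_dict(),
        "sos": model.sos,
        "sos_original": model.sos_original,
        "performance": model.performance,
        "n_parameters": model.n_parameters,
        "n_iterations": model.n_iterations,
    }
    with open(outdir / meta_name, "w", encoding="utf-8") as fh:
        yaml.safe_dump(meta, fh, allow_unicode=True, sort_keys=False)


def load_trained_model(outdir: str | Path,
                       params_name: str = "model.txt",
                       meta_name: str = "model_meta.yaml") -> TrainedModel:
    outdir = Path(outdir)
    params = load_params_text(outdir / params_name)
    with open(outdir / meta_name, encoding="utf-8") as fh:
        meta = yaml.safe_load(fh)
    return TrainedModel(
        params=params,
        scaler=ResponseScaler.from_dict(meta["scaler"]),
        split=SplitIndices.from_dict(meta["split"]),
        output_names=list(meta["output_names"]),
        sos={k: float(v) for k, v in meta["sos"].items()},
        sos_original={k: float(v) for k, v in meta["sos_original"].items()},
        performance={k: float(v) for k, v in meta["performance"].items()},
        loss_trajectory=np.array([]),
        restart_log=[],
        n_iterations=int(meta["n_iterations"]),
    )


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Execute all stages and write the report bundle.

    Reruns with an identical configuration and seed reproduce numerically
    identical artifacts.  A stage failure removes all files already written
    and raises :class:`StageError` naming the stage.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    writer = _AtomicWriter(outdir)
    timings: dict[str, float] = {}
    stage = "setup"
    try:
        # --- data -----------------------------------------------------
        stage = "simulate"
        t0 = time.perf_counter()
        if config.table_path:
            table = read_trial_csv(config.table_path)
        else:
            if config.effects_path:
                with open(config.effects_path, encoding="utf-8") as fh:
                    effects = EffectsConfig.from_dict(yaml.safe_load(fh))
            else:
                effects = default_effects(
                    config.seed + _SEED_SIMULATE, config.design
                )
            table = generate_trial(
                config.design, effects, config.seed + _SEED_SIMULATE
            )
        writer.write_df(table, "trial_table.csv")
        timings[stage] = time.perf_counter() - t0

        # --- encode + split -------------------------------------------
        stage = "encode"
        t0 = time.perf_counter()
        dm = encode_design(table, config.design)
        Y = table[list(RESPONSE_NAMES)].to_numpy(dtype=float)
        split = split_indices(
            len(table), config.split_fractions, config.seed + _SEED_SPLIT
        )
        timings[stage] = time.perf_counter() - t0

        # --- training / architecture search ---------------------------
        stage = "train"
        t0 = time.perf_counter()
        tc = TrainingConfig(
            hidden_sizes=config.hidden_sizes,
            activations=config.activations,
            restarts=config.restarts,
            max_iterations=config.max_iterations,
            seed=config.seed + _SEED_TRAIN,
        )
        summary, model = search_architectures(
            dm, Y, split, tc, output_names=list(RESPONSE_NAMES)
        )
        writer.write_df(summary, "architecture_summary.csv")
        writer.write_text(lambda p: save_params_text(model.params, p), "model.txt")
        save_trained_model(model, outdir)
        writer.written.append(outdir / "model_meta.yaml")
        timings[stage] = time.perf_counter() - t0

        # --- goodness of fit ------------------------------------------
        stage = "evaluate"
        t0 = time.perf_counter()
        pred = model.predict(dm)
        full = fit_table(Y, pred, list(RESPONSE_NAMES), n_const=config.n_const)
        writer.write_df(full.loc[list(AGRONOMIC_RESPONSES)], "fit_agronomic.csv", index=True)
        writer.write_df(full.loc[list(EO_RESPONSES)], "fit_eo.csv", index=True)
        timings[stage] = time.perf_counter() - t0

        # --- sensitivity ----------------------------------------------
        stage = "sensitivity"
        t0 = time.perf_counter()
        ri = yoon_relative_importance(
            model.params.W1, model.params.W2,
            input_names=config.design.input_names(),
            output_names=list(RESPONSE_NAMES),
        )
        writer.write_df(ri.to_frame(), "relative_importance.csv", index=True)
        writer.write_df(ri.to_long_frame(), "relative_importance_long.csv")
        timings[stage] = time.perf_counter() - t0

        # --- multi-objective optimization -----------------------------
        stage = "optimize"
        t0 = time.perf_counter()
        ga = GAConfig(
            population_size=config.ga_population,
            generations=config.ga_generations,
            mode=config.ga_mode,
        )
        result = ga_optimize(model, config.design, ga, seed=config.seed + _SEED_GA)
        front_df = result.to_frame(list(RESPONSE_NAMES))
        writer.write_df(front_df, "pareto_front.csv")
        optima = best_condition_per_output(result, list(RESPONSE_NAMES))
        optima_df = pd.DataFrame(
            [
                {
                    "output": name,
                    "year": cand.year,
                    "locality": cand.locality,
                    "fertilization": cand.fertilization,
                    "predicted_maximum": value,
                }
                for name, (cand, value) in optima.items()
            ]
        )
        writer.write_df(optima_df, "per_output_optima.csv")
        timings[stage] = time.perf_counter() - t0

        # --- metadata --------------------------------------------------
        stage = "metadata"
        meta = {
            "seed": config.seed,
            "stage_seeds": {
                "simulate": config.seed + _SEED_SIMULATE,
                "split": config.seed + _SEED_SPLIT,
                "train": config.seed + _SEED_TRAIN,
                "ga": config.seed + _SEED_GA,
            },
            "split_sizes": list(split.sizes),
            "ga": {
                "population_size": result.population_size,
                "generations_run": result.generations_run,
                "mode": result.mode,
                "front_size": len(result.front),
            },
            "net_name": model.net_name,
            "n_parameters": model.n_parameters,
            "timings_s": {k: round(v, 4) for k, v in timings.items()},
        }
        writer.write_text(
            lambda p: Path(p).write_text(
                yaml.safe_dump(meta, allow_unicode=True, sort_keys=False),
                encoding="utf-8",
            ),
            "run_metadata.yaml",
        )
    except Exception as exc:
        writer.rollback()
        raise StageError(f"pipeline stage {stage!r} failed: {exc}") from exc

    return ReportBundle(
        outdir=outdir,
        table=table,
        architecture_summary=summary,
        model=model,
        fit_agronomic=full.loc[list(AGRONOMIC_RESPONSES)],
        fit_eo=full.loc[list(EO_RESPONSES)],
        relative_importance=ri.to_frame(),
        pareto_front=front_df,
        per_output_optima=optima_df,
        files=[str(p) for p in writer.written],
    )
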