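"""Monte-Carlo experiment runner: parameter grids, replication, aggregation.

Reproduces the simulation-study design: a main 3x3 grid over the random
intercept and random slope variances, one-at-a-time sweeps of the unknown
covariate effect (beta2), the volume effect (gamma, with and without the
quintile fixed effect), the update interval (theta), and the residual share
(alpha) -- each cell replicated with independent, reproducible seeds and
summarized as the mean (SD) relative improvement per model and scope.
"""

from __future__ import annotations

import json
import math
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .dynamic import run_dynamic, run_static, select_training_clinics
from .evaluate import learning_curve, score_predictions, score_trace
from .lmm import ClusteredLMM, ModelSpec, standard_specs
from .params import SimulationParams
from .simulate import generate_population

__all__ = [
    "ExperimentGrid",
    "GridResult",
    "replicate_seeds",
    "run_replicate",
    "run_cell",
    "run_grid",
    "summarize",
    "main_grid",
    "beta2_sweep",
    "gamma_sweep",
    "theta_sweep",
    "alpha_sweep",
]

SCOPES = ("training", "testing_static", "testing_dynamic")

MAIN_TAU0 = (0.5, 1.0, 2.0)
MAIN_TAU1 = (0.0, 0.25, 0.5)
EFFECT_VALUES = (math.sqrt(0.5), 1.0, math.sqrt(2.0))
THETA_VALUES = (250, 500, 1000, 5000)
ALPHA_VALUES = (0.05, 0.2, 0.5, 0.8)


# ----------------------------------------------------------------------
# sweep builders
# ----------------------------------------------------------------------

def main_grid(base: SimulationParams | None = None) -> dict[str, SimulationParams]:
    """The 9 main parameter combinations: tau0^2 x tau1^2."""
    base = base or SimulationParams()
    return {
        f"tau0={t0:g}_tau1={t1:g}": base.evolve(tau0_sq=t0, tau1_sq=t1)
        for t0 in MAIN_TAU0
        for t1 in MAIN_TAU1
    }


def beta2_sweep(base: SimulationParams | None = None) -> dict[str, SimulationParams]:
    """Unknown patient-level effect sweep; tau2^2 follows tau1^2 when
    beta2 != 0 (the generator convention)."""
    base = base or SimulationParams()
    return {f"beta2={v:.3f}": base.evolve(beta2=v) for v in EFFECT_VALUES}


def gamma_sweep(base: SimulationParams | None = None) -> dict[str, SimulationParams]:
    base = base or SimulationParams()
    return {f"gamma={v:.3f}": base.evolve(gamma=v) for v in EFFECT_VALUES}


def theta_sweep(base: SimulationParams | None = None) -> dict[str, SimulationParams]:
    base = base or SimulationParams()
    return {f"theta={v}": base.evolve(theta=v) for v in THETA_VALUES}


def alpha_sweep(base: SimulationParams | None = None) -> dict[str, SimulationParams]:
    base = base or SimulationParams()
    return {f"alpha={v:g}": base.evolve(alpha=v) for v in ALPHA_VALUES}


_SWEEPS = {
    "main": main_grid,
    "beta2": beta2_sweep,
    "gamma": gamma_sweep,
    "theta": theta_sweep,
    "alpha": alpha_sweep,
}


@dataclass
class ExperimentGrid:
    """A named collection of simulation cells plus replication settings."""

    base: SimulationParams = field(default_factory=SimulationParams)
    cells: dict[str, SimulationParams] = field(default_factory=dict)
    n_replicates: int = 200
    seed_base: int = 0
    scopes: tuple[str, ...] = ("training", "testing_static")
    quintile_fe: bool = False  # additionally run each model with the quintile fixed effect

    def __post_init__(self) -> None:
        if not self.cells:
            self.cells = {"base": self.base}
        for scope in self.scopes:
            if scope not in SCOPES:
                raise ValueError(f"unknown scope {scope!r}; choose from {SCOPES}")

    @classmethod
    def from_config(cls, cfg: dict) -> "ExperimentGrid":
        """Build a grid from a plain config mapping (YAML/JSON friendly).

        Keys: ``base`` (parameter overrides), ``sweeps`` (names among
        main/beta2/gamma/theta/alpha), ``cells`` (explicit name -> overrides),
        ``n_replicates``, ``seed_base``, ``scopes``, ``quintile_fe``.
        """
        base = SimulationParams(**cfg.get("base", {}))
        cells: dict[str, SimulationParams] = {}
        for name in cfg.get("sweeps", []):
            if name not in _SWEEPS:
                raise ValueError(f"unknown sweep {name!r}; choose from {sorted(_SWEEPS)}")
            cells.update(_SWEEPS[name](base))
        for name, overrides in cfg.get("cells", {}).items():
            cells[name] = base.evolve(**overrides)
        return cls(
            base=base,
            cells=cells,
            n_replicates=int(cfg.get("n_replicates", 200)),
            seed_base=int(cfg.get("seed_base", 0)),
            scopes=tuple(cfg.get("scopes", ("training", "testing_static"))),
            quintile_fe=bool(cfg.get("quintile_fe", False)),
        )


# ----------------------------------------------------------------------
# replication machinery
# ----------------------------------------------------------------------

def replicate_seeds(seed_base: int, cell: str, replicate: int) -> tuple[int, int, int]:
    """Three independent stream seeds (population, selection, evaluation)
    for one replicate, derived reproducibly from the grid seed, the cell
    name and the replicate index. Replicates are independent of execution
    order, so cells parallelize trivially."""
    cell_key = zlib.crc32(cell.encode()) & 0x7FFFFFFF
    ss = np.random.SeedSequence((int(seed_base) & 0x7FFFFFFF, cell_key, int(replicate)))
    pop, sel, ev = ss.generate_state(3, dtype=np.uint32)
    return int(pop), int(sel), int(ev)


def run_replicate(
    params: SimulationParams,
    seeds: tuple[int, int, int],
    specs: tuple[ModelSpec, ...] | None = None,
    scopes: tuple[str, ...] = ("training", "testing_static"),
    keep_traces: bool = False,
    wishart_df: float | None = None,
) -> dict:
    """One replicate: generate, select the training sample, fit, score.

    Static and dynamic evaluations reuse the same evaluation seed, so all
    models -- and the static/dynamic variants of each -- face the same
    prediction order and the same incorporation draws (a paired design).
    """
    specs = standard_specs() if specs is None else tuple(specs)
    pop_seed, sel_seed, eval_seed = seeds
    population = generate_population(params, rng=np.random.default_rng(pop_seed))
    training_ids = select_training_clinics(
        population, np.random.default_rng(sel_seed)
    )
    train = population.patients_of(training_ids)
    ybar_train = float(train["y"].mean())

    out: dict = {"metrics": [], "traces": {}, "baselines": {},
                 "training_ids": training_ids, "ybar_train": ybar_train}

    if "training" in scopes:
        for spec in specs:
            fit = ClusteredLMM(train, spec).fit(wishart_df=wishart_df)
            res = score_predictions(
                fit.predict(train), train["y"], train["mu_true"], ybar_train,
                model=spec.name, scope="training", quintile=train["quintile"],
            )
            out["metrics"].append(res)

    if "testing_static" in scopes:
        traces = run_static(
            population, training_ids, specs,
            rng=np.random.default_rng(eval_seed), wishart_df=wishart_df,
        )
        for name, trace in traces.items():
            out["metrics"].append(score_trace(trace, ybar_train, scope="testing_static"))
        if keep_traces:
            out["traces"]["static"] = traces

    if "testing_dynamic" in scopes:
        traces = run_dynamic(
            population, training_ids, specs,
            theta=params.theta, p_incorporate=params.p_incorporate,
            rng=np.random.default_rng(eval_seed), wishart_df=wishart_df,
        )
        first = next(iter(traces.values()))
        ev = first.events
        phi0 = float(np.mean(np.abs(ev["y"] - ybar_train)))
        phi1 = float(np.mean(np.abs(ev["y"] - ev["mu_true"])))
        out["baselines"]["testing"] = (phi0, phi1)
        for name, trace in traces.items():
            out["metrics"].append(score_trace(trace, ybar_train, scope="testing_dynamic"))
        if keep_traces:
            out["traces"]["dynamic"] = traces

    return out


def run_cell(
    params: SimulationParams,
    n_replicates: int,
    seed_base: int = 0,
    cell_name: str = "base",
    specs: tuple[ModelSpec, ...] | None = None,
    scopes: tuple[str, ...] = ("training", "testing_static"),
    keep_traces: bool = False,
    n_jobs: int = 1,
    wishart_df: float | None = None,
) -> dict:
    """Run all replicates of one cell; returns tidy metrics and, when
    requested, the dynamic traces with their per-replicate baselines
    (needed for pooled learning curves)."""
    specs = standard_specs() if specs is None else tuple(specs)

    def one(r: int) -> dict:
        seeds = replicate_seeds(seed_base, cell_name, r)
        try:
            rep = run_replicate(
                params, seeds, specs=specs, scopes=scopes,
                keep_traces=keep_traces, wishart_df=wishart_df,
            )
            rep["failed"] = False
        except Exception as exc:  # flagged, never silently dropped
            rep = {"metrics": [], "traces": {}, "baselines": {},
                   "failed": True, "error": repr(exc)}
        rep["replicate"] = r
        rep["seeds"] = seeds
        return rep

    if n_jobs != 1:
        from joblib import Parallel, delayed

        reps = Parallel(n_jobs=n_jobs)(delayed(one)(r) for r in range(n_replicates))
    else:
        reps = [one(r) for r in range(n_replicates)]

    rows = []
    dynamic_traces: dict[str, list] = {}
    dynamic_baselines: list = []
    failures = []
    for rep in reps:
        if rep["failed"]:
            failures.append({"replicate": rep["replicate"], "error": rep["error"]})
            continue
        for res in rep["metrics"]:
            row = res.to_row()
            row.update(cell=cell_name, replicate=rep["replicate"],
                       seed_pop=rep["seeds"][0], seed_eval=rep["seeds"][2])
            rows.append(row)
        if keep_traces and "dynamic" in rep["traces"]:
            for name, trace in rep["traces"]["dynamic"].items():
                dynamic_traces.setdefault(name, []).append(trace)
            dynamic_baselines.append(rep["baselines"]["testing"])

    return {
        "cell": cell_name,
        "params": params,
        "metrics": pd.DataFrame(rows),
        "dynamic_traces": dynamic_traces,
        "dynamic_baselines": dynamic_baselines,
        "failures": failures,
    }


@dataclass
class GridResult:
    grid: ExperimentGrid
    metrics: pd.DataFrame            # tidy: cell, replicate, model, scope, ri, mae, ...
    failures: list = field(default_factory=list)


def run_grid(
    grid: ExperimentGrid,
    out_dir: str | Path | None = None,
    n_jobs: int = 1,
    wishart_df: float | None = None,
) -> GridResult:
    """Run every cell of the grid with independent per-replicate seeds.

    With ``out_dir``, per-cell tidy CSVs are written as each cell finishes
    and cells whose CSV already exists are loaded instead of re-run, so a
    partially completed grid resumes where it left off.
    """
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    specs = standard_specs()
    if grid.quintile_fe:
        specs = specs + standard_specs(quintile=True)

    frames = []
    failures = []
    for name, params in grid.cells.items():
        if out is not None:
            cell_csv = out / f"cell_{zlib.crc32(name.encode()):08x}.csv"
            if cell_csv.exists():
                frames.append(pd.read_csv(cell_csv))
                continue
        cell = run_cell(
            params, grid.n_replicates, seed_base=grid.seed_base, cell_name=name,
            specs=specs, scopes=grid.scopes, n_jobs=n_jobs, wishart_df=wishart_df,
        )
        frames.append(cell["metrics"])
        failures.extend(dict(cell=name, **f) for f in cell["failures"])
        if out is not None:
            cell["metrics"].to_csv(cell_csv, index=False)
    metrics = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    return GridResult(grid=grid, metrics=metrics, failures=failures)


# ----------------------------------------------------------------------
# reporting
# ----------------------------------------------------------------------

def summarize(result: GridResult, out_dir: str | Path | None = None) -> dict:
    """Aggregate a grid result into mean (SD) summary tables.

    Returns a dict with ``cell_summary`` (tidy mean/SD of RI per cell,
    model and scope, SD across replicates only), ``training_table`` (the
    model x tau1^2 by tau0^2 layout for the main grid's training scope,
    when those cells are present), and a JSON-able ``manifest``.
    """
    df = result.metrics
    if df.empty:
        summary = pd.DataFrame(
            columns=["cell", "model", "scope", "n_replicates", "ri_mean", "ri_sd"]
        )
    else:
        summary = (
            df.groupby(["cell", "model", "scope"])["ri"]
            .agg(n_replicates="count", ri_mean="mean", ri_sd="std")
            .reset_index()
        )

    tables: dict = {"cell_summary": summary}

    main_cells = {
        name for name in result.grid.cells
        if name.startswith("tau0=") or name == "base"
    }
    train = df[(df["scope"] == "training") & df["cell"].isin(main_cells)] if not df.empty else df
    if len(train):
        cells = result.grid.cells
        rows = []
        for name in sorted(main_cells & set(train["cell"])):
            p = cells[name]
            sub = train[train["cell"] == name]
            for model, grp in sub.groupby("model"):
                rows.append({
                    "tau1_sq": p.tau1_sq, "model": model, "tau0_sq": p.tau0_sq,
                    "value": f"{grp['ri'].mean():.3f} ({grp['ri'].std():.3f})",
                })
        pivot = pd.DataFrame(rows).pivot_table(
            index=["tau1_sq", "model"], columns="tau0_sq", values="value",
            aggfunc="first",
        )
        tables["training_table"] = pivot

    manifest = {
        "dynmix_version": __version__,
        "seed_base": result.grid.seed_base,
        "n_replicates": result.grid.n_replicates,
        "scopes": list(result.grid.scopes),
        "cells": {name: p.to_dict() for name, p in result.grid.cells.items()},
        "failures": result.failures,
    }
    tables["manifest"] = manifest

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        summary.to_csv(out / "cell_summary.csv", index=False)
        if "training_table" in tables:
            tables["training_table"].to_csv(out / "training_table.csv")
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return tables
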