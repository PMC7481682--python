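"""Experiment drivers, result tables and the motor-number inference.

Each driver runs a named computational experiment - a force-velocity scan,
a bound-motor distribution, a stall-force curve, run-length statistics, or
one of the two literature comparisons - and returns a tidy
:class:`pandas.DataFrame`.  :func:`run_experiment` dispatches on a
configuration mapping (usually loaded from a YAML file), writes the table
as TSV together with a JSON metadata record (fully resolved parameters,
seed, package version), and is deterministic given the seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .analytic import (
    average_cluster_velocity,
    bound_distribution_limited,
    bound_distribution_unlimited,
    leading_motor_velocity,
    stall_force,
)
from .lattice import SimulationConfig, SimulationResult, run
from .parameters import MotorParameters, get_preset, preset_names

__all__ = [
    "EXPERIMENT_TYPES",
    "run_experiment",
    "load_results",
    "compare_to_analytic",
    "infer_motor_number",
]

log = logging.getLogger(__name__)

EXPERIMENT_TYPES = (
    "force-velocity-curve",
    "velocity-vs-N",
    "bound-distribution",
    "stall-vs-N",
    "run-length",
    "furuta-comparison",
    "pilling-prediction",
)


def _resolve_params(config: Mapping) -> MotorParameters:
    if "preset" in config:
        params = get_preset(config["preset"])
        overrides = config.get("params", {})
        return params.with_(**overrides) if overrides else params
    if "params" in config:
        return MotorParameters(**config["params"])
    raise ValueError("experiment config must name a 'preset' or give 'params'")


def _sim_config(config: Mapping, **overrides) -> dict:
    controls = dict(config.get("simulation", {}))
    controls.update(overrides)
    controls.setdefault("seed", int(config.get("seed", 0)))
    return controls


def _sim_row(res: SimulationResult) -> dict:
    v, vse, _ = res.velocity()
    row = {
        "velocity_steps_s": v,
        "velocity_se_steps_s": vse,
        "velocity_um_s": res.to_um_per_s(v),
        "velocity_se_um_s": res.to_um_per_s(vse),
        "n_replicates": len(res.replicates),
    }
    rl, rlse, nrl = res.run_length()
    if nrl > 0:
        row.update(
            run_length_sites=rl,
            run_length_se_sites=rlse,
            run_length_um=res.to_um(rl),
            run_length_se_um=res.to_um(rlse),
        )
    return row


# ---------------------------------------------------------------------------
# drivers

def _force_velocity_curve(config: Mapping) -> pd.DataFrame:
    params = _resolve_params(config)
    n_list = config.get("N", [1, 2, 5, 20])
    f_grid = list(config.get("f", np.arange(0.0, 5.01, 0.5)))
    if len(f_grid) == 0:
        raise ValueError("f grid must not be empty")
    scenario = config.get("scenario", "processive" if params.processive else "B")
    rows = []
    for N in n_list:
        for f in f_grid:
            cfg = SimulationConfig(
                scenario=scenario, N=int(N), f=float(f),
                **_sim_config(config),
            )
            res = run(cfg, params)
            row = {"N": int(N), "f": float(f), "scenario": scenario}
            row.update(_sim_row(res))
            rows.append(row)
    return pd.DataFrame(rows)


def _velocity_vs_N(config: Mapping) -> pd.DataFrame:
    cfg2 = dict(config)
    cfg2["N"] = config.get("N", list(range(1, 11)))
    cfg2["f"] = config.get("f", [0.0, 2.0, 4.0])
    return _force_velocity_curve(cfg2)


def _bound_distribution(config: Mapping) -> pd.DataFrame:
    params = _resolve_params(config)
    N = int(config.get("N", 10))
    f = float(config.get("f", 0.0))
    scenario = config.get("scenario", "A")
    m_list = config.get("M", [20, 30, 100])
    rows = []
    for M in m_list:
        cfg = SimulationConfig(
            scenario=scenario, N=N, f=f,
            M_fixed=int(M) if scenario == "A" else None,
            **_sim_config(config),
        )
        res = run(cfg, params)
        probs, se = res.occupancy()
        mw, _, _ = res.mean_window()
        dl = bound_distribution_limited(params, N, int(M))
        du = bound_distribution_unlimited(params, N)
        for n in range(N + 1):
            rows.append({
                "M": int(M), "N": N, "f": f, "n_bound": n,
                "p_sim": probs[n], "p_se": se[n],
                "p_limited": dl.probs[n], "p_unlimited": du.probs[n],
                "mean_window": mw,
            })
    return pd.DataFrame(rows)


def _stall_vs_N(config: Mapping) -> pd.DataFrame:
    params = _resolve_params(config)
    n_list = config.get("N", list(range(1, 11)))
    rows = []
    for N in n_list:
        row = {"N": int(N), "stall_processive": stall_force(params, int(N), processive=True)}
        if not params.processive:
            row["stall_unlimited"] = stall_force(params, int(N), processive=False)
        rows.append(row)
    return pd.DataFrame(rows)


def _run_length(config: Mapping) -> pd.DataFrame:
    params = _resolve_params(config)
    n_list = config.get("N", list(range(1, 11)))
    f = float(config.get("f", 2.0))
    rows = []
    for N in n_list:
        cfg = SimulationConfig(scenario="B", N=int(N), f=f, **_sim_config(config))
        res = run(cfg, params)
        runs = res.run_values()
        row = {"N": int(N), "f": f, "n_runs_observed": runs.size}
        if runs.size:
            row.update(
                run_length_sites=float(runs.mean()),
                run_length_um=res.to_um(runs.mean()),
                run_length_sd_um=res.to_um(runs.std()),
                negative_fraction=float((runs < 0).mean()),
            )
        rows.append(row)
    return pd.DataFrame(rows)


def _furuta_comparison(config: Mapping) -> pd.DataFrame:
    """Zero-load velocity against motor number for the DNA-scaffold assay:
    processive kinesin-1 (faster single-motor rates) and non-processive Ncd
    (slower single-motor rates)."""
    n_list = config.get("N", [1, 2, 3, 4])
    rows = []
    for species, single, multi, scenario in (
        ("kinesin1", "kinesin1-single", "kinesin1-processive", "processive"),
        ("ncd", "ncd-single", "ncd", "B"),
    ):
        for N in n_list:
            params = get_preset(single if N == 1 else multi)
            cfg = SimulationConfig(scenario=scenario, N=int(N), f=0.0,
                                   **_sim_config(config))
            res = run(cfg, params)
            v, vse, _ = res.velocity()
            if scenario == "processive":
                v_ana = leading_motor_velocity(params, 0.0, int(N))
            else:
                v_ana = average_cluster_velocity(params, 0.0, int(N))
            rows.append({
                "species": species, "N": int(N), "f": 0.0,
                "velocity_um_s": res.to_um_per_s(v),
                "velocity_se_um_s": res.to_um_per_s(vse),
                "velocity_analytic_um_s": v_ana * params.dx * 1e-3,
            })
    return pd.DataFrame(rows)


def _pilling_prediction(config: Mapping) -> pd.DataFrame:
    """Velocity and run-length statistics of weakly non-processive axonal
    kinesin-1 under a ~1 pN load, per candidate motor number."""
    cfg2 = dict(config)
    cfg2.setdefault("preset", "kinesin1-axonal")
    params = _resolve_params(cfg2)
    n_list = config.get("N", [2, 3, 4, 10])
    f = float(config.get("f", 2.0))
    rows = []
    for N in n_list:
        cfg = SimulationConfig(scenario="B", N=int(N), f=f, **_sim_config(config))
        res = run(cfg, params)
        v, vse, _ = res.velocity()
        runs = res.run_values()
        rv = res.run_velocity_values()
        row = {"N": int(N), "f": f,
               "velocity_um_s": res.to_um_per_s(v),
               "velocity_se_um_s": res.to_um_per_s(vse)}
        if rv.size:
            row["run_velocity_um_s"] = res.to_um_per_s(rv.mean())
            row["run_velocity_sd_um_s"] = res.to_um_per_s(rv.std())
        if runs.size:
            row["run_length_um"] = res.to_um(runs.mean())
            row["run_length_sd_um"] = res.to_um(runs.std())
            row["n_runs_observed"] = runs.size
        rows.append(row)
    return pd.DataFrame(rows)


_DRIVERS = {
    "force-velocity-curve": _force_velocity_curve,
    "velocity-vs-N": _velocity_vs_N,
    "bound-distribution": _bound_distribution,
    "stall-vs-N": _stall_vs_N,
    "run-length": _run_length,
    "furuta-comparison": _furuta_comparison,
    "pilling-prediction": _pilling_prediction,
}


def run_experiment(config: Union[str, Path, Mapping], outdir: Union[str, Path]) -> pd.DataFrame:
    """Run a named experiment and write its result bundle.

    ``config`` is a mapping (or path to a YAML file) with at least an
    ``experiment`` key naming one of :data:`EXPERIMENT_TYPES`, a ``preset``
    or explicit ``params``, and optional ``simulation`` controls mirroring
    :class:`SimulationConfig` fields.  Writes ``results.tsv``,
    ``metadata.json`` and ``run.log`` into ``outdir`` and returns the table.
    """
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    if not isinstance(config, Mapping):
        raise ValueError("config must be a mapping or a path to a YAML file")
    exp = config.get("experiment")
    if exp not in _DRIVERS:
        raise ValueError(
            f"unknown experiment {exp!r}; available: {', '.join(EXPERIMENT_TYPES)}"
        )
    if exp == "pilling-prediction":
        config = {"preset": "kinesin1-axonal", **config}
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    table = _DRIVERS[exp](config)
    params = _resolve_params(config) if exp != "furuta-comparison" else None
    meta = {
        "experiment": exp,
        "config": _jsonable(config),
        "params": dataclasses.asdict(params) if params is not None else None,
        "seed": int(config.get("seed", 0)),
        "version": __version__,
        "runtime_s": round(time.time() - t0, 3),
    }
    table.to_csv(outdir / "results.tsv", sep="\t", index=False, float_format="%.10g")
    with open(outdir / "metadata.json", "w") as fh:
        json.dump(meta, fh, indent=2)
    with open(outdir / "run.log", "a") as fh:
        fh.write(
            f"{time.strftime('%Y-%m-%dT%H:%M:%S')} experiment={exp} "
            f"seed={meta['seed']} rows={len(table)} runtime_s={meta['runtime_s']}\n"
        )
    log.info("experiment %s: %d rows in %.1fs", exp, len(table), meta["runtime_s"])
    return table


def _jsonable(obj):
    if isinstance(obj, Mapping):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, np.ndarray)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def load_results(outdir: Union[str, Path]) -> pd.DataFrame:
    """Re-ingest a result bundle; metadata is attached as ``df.attrs``."""
    outdir = Path(outdir)
    table = pd.read_csv(outdir / "results.tsv", sep="\t")
    with open(outdir / "metadata.json") as fh:
        table.attrs["metadata"] = json.load(fh)
    return table


_MODELS = ("leading", "unlimited", "limited")


def compare_to_analytic(table: pd.DataFrame, model: str) -> pd.DataFrame:
    """Annotate a velocity table with analytic predictions and z-scores.

    ``model`` selects the leading-motor law for a fully bound cluster
    (``"leading"``), or the binding-averaged velocity with the unlimited or
    limited bound-number distribution.  Rows gain ``velocity_analytic_um_s``
    and ``z`` = (sim - analytic)/SE columns.
    """
    if model not in _MODELS:
        raise ValueError(f"unknown model {model!r}; expected one of {_MODELS}")
    if table.empty:
        out = table.copy()
        out["velocity_analytic_um_s"] = pd.Series(dtype=float)
        out["z"] = pd.Series(dtype=float)
        return out
    meta = table.attrs.get("metadata")
    if meta is None or meta.get("params") is None:
        raise ValueError("table carries no parameter metadata; load it with load_results")
    params = MotorParameters(**meta["params"])
    if model in ("unlimited", "limited") and (params.k_on <= 0 or params.k_off <= 0):
        raise ValueError(
            f"model {model!r} requires binding kinetics but the table was "
            "produced with a processive parameter set"
        )
    if not {"N", "f", "velocity_um_s", "velocity_se_um_s"} <= set(table.columns):
        raise ValueError("table lacks the velocity columns produced by run_experiment")
    out = table.copy()
    preds = []
    for _, row in out.iterrows():
        N, f = int(row["N"]), float(row["f"])
        if model == "leading":
            v = leading_motor_velocity(params, f, N)
        elif model == "unlimited":
            v = average_cluster_velocity(params, f, N)
        else:
            if "mean_window" in out.columns and np.isfinite(row.get("mean_window", np.nan)):
                M = int(round(row["mean_window"]))
            elif "M" in out.columns:
                M = int(row["M"])
            else:
                raise ValueError("limited model needs a mean_window or M column")
            v = average_cluster_velocity(params, f, N, M=M)
        preds.append(v * params.dx * 1e-3)
    out["velocity_analytic_um_s"] = preds
    out["z"] = (out["velocity_um_s"] - out["velocity_analytic_um_s"]) / out[
        "velocity_se_um_s"
    ]
    return out


def infer_motor_number(
    observed_velocity: float,
    observed_velocity_sd: float,
    observed_run_length: float,
    observed_run_length_sd: float,
    candidates: Sequence[int],
    params: Union[str, MotorParameters] = "kinesin1-axonal",
    f: float = 2.0,
    simulation: Optional[Mapping] = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Rank candidate motor numbers against an observed (velocity, run
    length) pair.

    Each candidate ``N`` is simulated (scenario B) and scored by the sum of
    squared z-distances of its simulated mean velocity and mean run length
    from the observations, using the observed standard deviations as scale.
    Velocities are in um/s, run lengths in um.  Candidates whose simulation
    produced no completed attachment periods are excluded with a warning
    column.  Returns the per-candidate summary sorted by score.
    """
    if isinstance(params, str):
        params = get_preset(params)
    candidates = sorted(set(int(N) for N in candidates))
    if not candidates or min(candidates) < 1 or max(candidates) > 20:
        raise ValueError("candidate N range must be within [1, 20]")
    if observed_velocity_sd <= 0 or observed_run_length_sd <= 0:
        raise ValueError("observed standard deviations must be positive")
    controls = dict(simulation or {})
    controls.setdefault("seed", seed)
    rows = []
    for N in candidates:
        cfg = SimulationConfig(scenario="B", N=N, f=f, **controls)
        res = run(cfg, params)
        v, vse, _ = res.velocity()
        runs = res.run_values()
        row = {"N": N, "velocity_um_s": res.to_um_per_s(v)}
        if runs.size == 0:
            row["excluded"] = "no completed attachment periods"
            log.warning("candidate N=%d excluded: no completed runs", N)
        else:
            rl = res.to_um(runs.mean())
            row["run_length_um"] = rl
            row["n_runs_observed"] = runs.size
            zv = (row["velocity_um_s"] - observed_velocity) / observed_velocity_sd
            zl = (rl - observed_run_length) / observed_run_length_sd
            row["z_velocity"] = zv
            row["z_run_length"] = zl
            row["score"] = zv**2 + zl**2
        rows.append(row)
    df = pd.DataFrame(rows)
    return df.sort_values("score", na_position="last").reset_index(drop=True)
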