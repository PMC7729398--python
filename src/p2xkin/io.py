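"""File formats and pipeline orchestration.

Dataset bundles travel as plain CSV tables with a JSON sidecar: one
``traces.csv`` (tidy: trace id, concentration, time, normalized
current, variance), one ``steady_state.csv``, and ``bundle.json``
recording the condition, variant, Po,max and provenance.  Results are
JSON; flux tables and energy tables are CSV; pathway graphs are DOT.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from p2xkin import __version__ as _version
from p2xkin.energetics import cooperativity_profile, energy_profile
from p2xkin.fitting import (
    VARIANT_FOR_CONDITION,
    DatasetBundle,
    FitOptions,
    FitResult,
    SteadyStateRelationship,
    Trace,
    fit_global,
    standard_errors,
)
from p2xkin.flux import flux_densities, flux_table, graph_to_dot, pathway_report, total_net_flux
from p2xkin.model import CouplingFactors, ModelVariant, RateConstantSet, effective_rates
from p2xkin.relax import ConcentrationProtocol, concentration_po_curve, simulate_protocol
from p2xkin.synthetic import GroundTruth, default_rates, generate_bundle

__all__ = ["RunConfig", "write_bundle", "read_bundle", "run_pipeline"]


class LMOptions(BaseModel):
    model_config = ConfigDict(extra="forbid")
    max_iter: int = 200
    rel_s_threshold: float = 1e-6


class RunConfig(BaseModel):
    """Schema-validated pipeline configuration (unknown keys rejected)."""

    model_config = ConfigDict(extra="forbid")

    bundles: list[str] = Field(default_factory=list)  # bundle directories
    simulate_if_missing: bool = True
    u: float = 0.1
    lm: LMOptions = Field(default_factory=LMOptions)
    rate_upper_bound: float | None = None
    temperature_K: float = 293.0
    reference_L_uM: float = 1.0
    flux_threshold: float = 0.01
    flux_t_end_s: float = 5.0
    flux_concentration_uM: float = 1.0
    seed: int = 0
    init_perturbation: float = 1.5  # fit start: truth perturbed by this spread

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        doc = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
        return cls.model_validate(doc)


def write_bundle(bundle: DatasetBundle, directory: str | Path) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for idx, tr in enumerate(bundle.traces):
        for t, c, v in zip(tr.times, tr.current, tr.variance):
            rows.append({"trace": idx, "L_uM": tr.L, "t_on_s": tr.t_on,
                         "time_s": t, "current": c, "variance": v})
    pd.DataFrame(rows).to_csv(directory / "traces.csv", index=False)
    ss = bundle.steady_state
    pd.DataFrame({"L_uM": ss.concentrations, "Po": ss.po,
                  "variance": ss.variance}).to_csv(directory / "steady_state.csv",
                                                   index=False)
    (directory / "bundle.json").write_text(json.dumps({
        "condition": bundle.condition,
        "variant": bundle.variant.value,
        "po_max": bundle.po_max,
        "n_traces": len(bundle.traces),
        "writer": f"p2xkin {_version}",
    }, indent=1))
    return directory


def read_bundle(directory: str | Path) -> DatasetBundle:
    """Read a bundle directory, validating structure and values."""
    directory = Path(directory)
    meta_path = directory / "bundle.json"
    if not meta_path.exists():
        raise FileNotFoundError(f"{meta_path} missing")
    meta = json.loads(meta_path.read_text())
    traces_df = pd.read_csv(directory / "traces.csv")
    ss_df = pd.read_csv(directory / "steady_state.csv")
    for name, df, cols in (
        ("traces.csv", traces_df, ["trace", "L_uM", "t_on_s", "time_s", "current", "variance"]),
        ("steady_state.csv", ss_df, ["L_uM", "Po", "variance"]),
    ):
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise ValueError(f"{directory / name}: missing columns {missing}")
        bad = df.index[df["variance"] <= 0]
        if len(bad):
            raise ValueError(f"{directory / name}: non-positive variance at row {bad[0]}")

    traces = []
    for _, grp in traces_df.groupby("trace", sort=True):
        times = grp["time_s"].to_numpy()
        if np.any(np.diff(times) < 0):
            raise ValueError(f"{directory}: non-monotone times in trace")
        traces.append(Trace(
            L=float(grp["L_uM"].iloc[0]),
            t_on=float(grp["t_on_s"].iloc[0]),
            times=times,
            current=grp["current"].to_numpy(),
            variance=grp["variance"].to_numpy(),
        ))
    ss = SteadyStateRelationship(
        concentrations=ss_df["L_uM"].to_numpy(),
        po=ss_df["Po"].to_numpy(),
        variance=ss_df["variance"].to_numpy(),
    )
    return DatasetBundle(
        condition=meta["condition"],
        variant=ModelVariant(meta["variant"]),
        traces=traces,
        steady_state=ss,
        po_max=float(meta["po_max"]),
    )


def _fit_result_doc(fit: FitResult) -> dict:
    report = standard_errors(fit)
    return {
        "S": fit.s_value,
        "converged": fit.converged,
        "n_evaluations": fit.n_evaluations,
        "message": fit.message,
        "parameters": {
            n: {"value": float(v), "se": None if not np.isfinite(s) else float(s),
                "relative_error": None if not np.isfinite(r) else float(r)}
            for n, v, s, r in zip(report.names, report.values, report.se, report.relative)
        },
        "median_relative_error": report.median_relative,
        "effective_points": fit.weights.effective_points if fit.weights else None,
    }


def run_pipeline(config: RunConfig, out_dir: str | Path) -> Path:
    """Reduction -> coupled fit -> occupancy/flux -> energetics -> binding.

    Deterministic given the config seed; every output carries the config
    hash.  Any stage failure aborts with a stage-named diagnostic.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_json = config.model_dump_json(indent=1)
    cfg_hash = hashlib.sha256(cfg_json.encode()).hexdigest()[:16]

    # --- stage: data ---------------------------------------------------------
    if config.bundles:
        missing = [b for b in config.bundles if not Path(b).exists()]
        if missing:
            raise FileNotFoundError(f"data stage: bundle paths missing: {missing}")
        bundles = [read_bundle(b) for b in config.bundles]
    elif config.simulate_if_missing:
        truth = GroundTruth()
        bundles = generate_bundle(truth, seed=config.seed)
        for b in bundles:
            write_bundle(b, out / "data" / b.condition.replace("·", "_"))
    else:
        raise ValueError("data stage: no bundles configured")

    # --- stage: fit ----------------------------------------------------------
    rng = np.random.default_rng(config.seed + 1)
    truth_rates = default_rates()
    spread = np.log(config.init_perturbation)
    init = RateConstantSet(truth_rates.as_array()
                           * np.exp(rng.uniform(-spread, spread, 26)))
    options = FitOptions(u=config.u, rel_s_tol=config.lm.rel_s_threshold,
                         max_iter=config.lm.max_iter,
                         rate_upper_bound=config.rate_upper_bound,
                         seed=config.seed)
    try:
        fit = fit_global(bundles, init, CouplingFactors(), options)
    except Exception as exc:  # noqa: BLE001 - annotate the failing stage
        raise RuntimeError(f"fit stage failed: {exc}") from exc
    (out / "fit.json").write_text(json.dumps(
        {"config_hash": cfg_hash, **_fit_result_doc(fit)}, indent=1))

    # --- stage: curves -------------------------------------------------------
    L_grid = np.geomspace(1e-3, 1e3, 61)
    curves = {}
    for b in bundles:
        curve = concentration_po_curve(fit.rates, b.variant, fit.factors, L_grid)
        df = curve.to_frame()
        df.to_csv(out / f"equilibrium_{b.condition.replace('·', '_')}.csv", index=False)
        curves[b.condition] = curve

    # --- stage: flux ---------------------------------------------------------
    eff = effective_rates(fit.rates, fit.factors, ModelVariant.F1)
    protocol = ConcentrationProtocol(
        segments=((config.flux_concentration_uM, 2.0), (0.0, config.flux_t_end_s)),
        points_per_segment=400,
    )
    traj = simulate_protocol(eff, ModelVariant.F1, CouplingFactors(), protocol)
    n_act = traj.segment_bounds[0]
    act = _slice_trajectory(traj, 0, n_act)
    deact = _slice_trajectory(traj, n_act, len(traj.times))
    F_act = total_net_flux(flux_densities(act, eff))
    F_deact = total_net_flux(flux_densities(deact, eff))
    flux_table(F_act, F_deact).to_csv(out / "flux.csv", index=False)
    (out / "pathways_activation.dot").write_text(
        graph_to_dot(pathway_report(F_act, config.flux_threshold)))
    (out / "pathways_deactivation.dot").write_text(
        graph_to_dot(pathway_report(F_deact, config.flux_threshold)))

    # --- stage: energetics ---------------------------------------------------
    profile = energy_profile(fit.rates, fit.factors, ModelVariant.F1,
                             L=config.reference_L_uM, T=config.temperature_K)
    profile.to_frame().to_csv(out / "energies.csv", index=False)
    coop = cooperativity_profile(profile)
    (out / "cooperativity.json").write_text(json.dumps(
        {"ddG": coop.ddG, "labels": coop.labels, "dead_band": coop.dead_band},
        indent=1))

    # --- log -----------------------------------------------------------------
    (out / "run.json").write_text(json.dumps({
        "p2xkin_version": _version,
        "config": json.loads(cfg_json),
        "config_hash": cfg_hash,
        "conditions": [b.condition for b in bundles],
        "S": fit.s_value,
    }, indent=1))
    return out


def _slice_trajectory(traj, start: int, stop: int):
    from p2xkin.relax import OccupancyTrajectory

    t = traj.times[start:stop]
    return OccupancyTrajectory(
        times=t - t[0],
        occupancies=traj.occupancies[start:stop],
        concentrations=None if traj.concentrations is None
        else traj.concentrations[start:stop],
    )
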