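"""Probability-flux densities, total net fluxes and transition pathways.

For every adjacent state pair (X, Y) the unidirectional flux density is
f_u,XY(t) = p_X(t) * k_XY, with k_XY the full transition rate including
statistical multiplicity and, for association steps, the ligand
concentration.  The net density f_XY = f_u,XY - f_u,YX integrated from
the concentration jump to t_end gives the total net probability flux
F_XY, whose pattern over the scheme identifies the dominant activation
and deactivation pathways and any hysteresis between them.

Sign convention: the forward direction of each pair points toward O3
(increasing liganding, or C->F->O), so fluxes toward O3 are positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from p2xkin.model import (
    PAIR_INDEX,
    STATES,
    ModelVariant,
    RateConstantSet,
    build_transition_table,
)
from p2xkin.relax import OccupancyTrajectory

__all__ = ["FluxMap", "flux_densities", "total_net_flux", "pathway_report",
           "hysteresis_scores"]

PAIRS: tuple[tuple[str, str], ...] = tuple((a, b) for a, b, _, _ in PAIR_INDEX)


@dataclass
class FluxMap:
    """Unidirectional and net flux densities on a trajectory grid."""

    times: np.ndarray
    forward: dict[tuple[str, str], np.ndarray]   # f_u,XY for the pair (X,Y)
    backward: dict[tuple[str, str], np.ndarray]  # f_u,YX
    trajectory: OccupancyTrajectory

    def net(self, pair: tuple[str, str]) -> np.ndarray:
        if pair in self.forward:
            return self.forward[pair] - self.backward[pair]
        rev = (pair[1], pair[0])
        return -(self.forward[rev] - self.backward[rev])

    def to_frame(self) -> pd.DataFrame:
        data = {"time_s": self.times}
        for pair in PAIRS:
            data[f"{pair[0]}->{pair[1]}"] = self.net(pair)
        return pd.DataFrame(data)


def _full_rate_lookup(rates: RateConstantSet) -> dict[tuple[str, str], tuple[float, bool]]:
    """(multiplicity * k, ligand_dependent) for every directed transition."""
    table = build_transition_table(ModelVariant.F1)
    return {
        (e.from_state, e.to_state): (e.multiplicity * rates[e.rate_index], e.ligand_dependent)
        for e in table.entries
    }


def flux_densities(
    trajectory: OccupancyTrajectory,
    rates: RateConstantSet,
    concentrations: np.ndarray | float | None = None,
) -> FluxMap:
    """Unidirectional flux densities for all 13 pairs on the trajectory grid.

    ``rates`` must be the effective (factor-applied) rate set that
    generated the trajectory.  ``concentrations`` is L(t) on the same
    grid (a scalar for constant-L segments); defaults to the L(t) the
    trajectory recorded.
    """
    t = trajectory.times
    if concentrations is None:
        if trajectory.concentrations is None:
            raise ValueError("trajectory carries no L(t); pass concentrations")
        L = trajectory.concentrations
    else:
        L = np.broadcast_to(np.asarray(concentrations, dtype=float), t.shape)
    if L.shape != t.shape:
        raise ValueError("concentration grid does not match trajectory grid")

    lookup = _full_rate_lookup(rates)
    forward: dict[tuple[str, str], np.ndarray] = {}
    backward: dict[tuple[str, str], np.ndarray] = {}
    for a, b in PAIRS:
        kf, ligf = lookup[(a, b)]
        kb, ligb = lookup[(b, a)]
        forward[(a, b)] = trajectory.state(a) * kf * (L if ligf else 1.0)
        backward[(a, b)] = trajectory.state(b) * kb * (L if ligb else 1.0)
    return FluxMap(times=t, forward=forward, backward=backward, trajectory=trajectory)


def total_net_flux(fluxmap: FluxMap, t_end: float | None = None) -> dict[tuple[str, str], float]:
    """Trapezoidal time integral of each net flux density over [t0, t_end]."""
    t = fluxmap.times
    if t_end is None:
        t_end = float(t[-1])
    if t_end > t[-1] * (1 + 1e-12):
        raise ValueError(f"t_end={t_end} beyond trajectory span {t[-1]}")
    mask = t <= t_end * (1 + 1e-12)
    out = {}
    for pair in PAIRS:
        out[pair] = float(np.trapezoid(fluxmap.net(pair)[mask], t[mask]))
    return out


def activation_deactivation_fluxes(
    rates: RateConstantSet,
    L: float,
    t_act: float = 2.0,
    t_deact: float = 5.0,
    n_points: int = 2000,
    refine_rtol: float = 1e-3,
    max_refinements: int = 4,
    cut_activation_at_peak: bool = True,
) -> tuple[dict[tuple[str, str], float], dict[tuple[str, str], float]]:
    """Total net fluxes for a 0 -> L -> 0 jump, activation and deactivation.

    ``rates`` is the effective rate set of the condition.  The
    trapezoidal grids are doubled until the largest total flux changes
    by less than ``refine_rtol`` relative (fast flip/open transients
    need far denser grids than the fitted traces).  Activation fluxes
    are integrated from the jump to the time of peak open probability
    (the window the time-course fit uses); deactivation runs over the
    full off-segment.
    """
    from p2xkin.model import CouplingFactors, ModelVariant  # local: avoid cycle
    from p2xkin.relax import ConcentrationProtocol, OccupancyTrajectory, simulate_protocol

    def compute(n: int):
        protocol = ConcentrationProtocol(
            segments=((L, t_act), (0.0, t_deact)), points_per_segment=n)
        traj = simulate_protocol(rates, ModelVariant.F1, CouplingFactors(), protocol)
        cut = traj.segment_bounds[0]
        act_end = cut
        if cut_activation_at_peak:
            act_end = int(np.argmax(traj.po[:cut])) + 1
        act = OccupancyTrajectory(times=traj.times[:act_end] - traj.times[0],
                                  occupancies=traj.occupancies[:act_end],
                                  concentrations=traj.concentrations[:act_end])
        dea = OccupancyTrajectory(times=traj.times[cut:] - traj.times[cut],
                                  occupancies=traj.occupancies[cut:],
                                  concentrations=traj.concentrations[cut:])
        return (total_net_flux(flux_densities(act, rates)),
                total_net_flux(flux_densities(dea, rates)))

    F_act, F_deact = compute(n_points)
    for _ in range(max_refinements):
        n_points *= 2
        F_act2, F_deact2 = compute(n_points)
        delta = max(
            max(abs(F_act2[p] - F_act[p]) for p in PAIRS),
            max(abs(F_deact2[p] - F_deact[p]) for p in PAIRS),
        )
        scale = max(max(abs(v) for v in F_act2.values()), 1e-12)
        F_act, F_deact = F_act2, F_deact2
        if delta / scale < refine_rtol:
            break
    return F_act, F_deact


def hysteresis_scores(
    F_act: dict[tuple[str, str], float],
    F_deact: dict[tuple[str, str], float],
) -> dict[tuple[str, str], float]:
    """|F_act + F_deact| per pair: zero for a fully retraced path.

    A reversible pair traversed forward in activation and backward in
    deactivation by the same amount cancels; a large score marks a pair
    where the cycle does not retrace itself (pathway hysteresis).
    """
    return {p: abs(F_act[p] + F_deact[p]) for p in PAIRS}


def pathway_report(
    F: dict[tuple[str, str], float],
    threshold: float = 0.01,
) -> nx.DiGraph:
    """Directed pathway graph keeping pairs with |F| >= threshold.

    Edge direction follows the net flux sign; edge attribute ``flux``
    stores |F_XY|.  Node attributes carry tier and liganding for layout.
    """
    from p2xkin.model import BOUND_LIGANDS, TIERS

    G = nx.DiGraph()
    for s in STATES:
        G.add_node(s, tier=TIERS[s], bound=BOUND_LIGANDS[s])
    for (a, b), val in F.items():
        if abs(val) >= threshold:
            src, dst = (a, b) if val >= 0 else (b, a)
            G.add_edge(src, dst, flux=abs(val))
    return G


def flux_table(
    F_act: dict[tuple[str, str], float],
    F_deact: dict[tuple[str, str], float],
) -> pd.DataFrame:
    rows = []
    hyst = hysteresis_scores(F_act, F_deact)
    for pair in PAIRS:
        rows.append({
            "pair": f"{pair[0]}-{pair[1]}",
            "F_activation": F_act[pair],
            "F_deactivation": F_deact[pair],
            "hysteresis": hyst[pair],
        })
    return pd.DataFrame(rows)


def graph_to_dot(G: nx.DiGraph) -> str:
    """Minimal DOT serialization of a pathway graph."""
    lines = ["digraph pathways {"]
    for n, attrs in G.nodes(data=True):
        lines.append(f'  {n} [tier="{attrs.get("tier", "")}"];')
    for a, b, attrs in G.edges(data=True):
        lines.append(f'  {a} -> {b} [label="{attrs["flux"]:.3f}", penwidth={1 + 6 * attrs["flux"]:.2f}];')
    lines.append("}")
    return "\n".join(lines)
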