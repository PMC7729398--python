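"""Master-equation solutions for concentration-jump protocols.

The occupancy vector p(t) of the 10-state scheme obeys dp/dt = Q(L) p
with the generator Q assembled in :mod:`p2xkin.model`.  Relaxations are
solved by spectral decomposition of Q (the eigenvalue method), with a
dense stiff integrator as fallback when the eigenvector matrix is
ill-conditioned.  Equilibrium occupancies come from the null space of Q.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from p2xkin.model import (
    BOUND_LIGANDS,
    N_SITES,
    OPEN_STATES,
    STATES,
    CouplingFactors,
    ModelVariant,
    RateConstantSet,
    effective_rates,
    generator_matrix,
)

__all__ = [
    "ConcentrationProtocol",
    "OccupancyTrajectory",
    "EquilibriumCurve",
    "solve_relaxation",
    "equilibrium_distribution",
    "simulate_protocol",
    "concentration_po_curve",
    "binding_occupancy_curve",
]

_OPEN_IDX = [STATES.index(s) for s in OPEN_STATES]
_COND_LIMIT = 1e12  # eigenvector condition number above which we integrate
_NEG_TOL = 1e-9  # occupancy below -NEG_TOL is an error, above is clipped


@dataclass(frozen=True)
class ConcentrationProtocol:
    """Piecewise-constant ligand protocol: [(L_uM, duration_s), ...].

    ``points_per_segment`` sets the uniform sampling grid used when no
    explicit grids are given (100 points per fitted segment by default).
    """

    segments: tuple[tuple[float, float], ...]
    grids: tuple[np.ndarray, ...] | None = None
    points_per_segment: int = 100

    def __post_init__(self):
        if len(self.segments) == 0:
            raise ValueError("protocol must contain at least one segment")
        for L, dur in self.segments:
            if L < 0:
                raise ValueError(f"negative concentration {L}")
            if dur <= 0:
                raise ValueError(f"non-positive duration {dur}")
        if self.grids is not None:
            if len(self.grids) != len(self.segments):
                raise ValueError("one sampling grid per segment required")
            for (L, dur), g in zip(self.segments, self.grids):
                g = np.asarray(g)
                if g.ndim != 1 or np.any(np.diff(g) < 0):
                    raise ValueError("grids must be monotone 1-D arrays")
                if g.size and (g[0] < 0 or g[-1] > dur * (1 + 1e-12)):
                    raise ValueError("grid outside segment bounds")

    def segment_grid(self, i: int) -> np.ndarray:
        if self.grids is not None:
            return np.asarray(self.grids[i], dtype=float)
        return np.linspace(0.0, self.segments[i][1], self.points_per_segment)

    @classmethod
    def jump(cls, L: float, on: float, off: float = 5.0,
             points_per_segment: int = 100) -> "ConcentrationProtocol":
        """Standard activation/deactivation protocol: 0 -> L -> 0."""
        return cls(segments=((L, on), (0.0, off)),
                   points_per_segment=points_per_segment)


@dataclass
class OccupancyTrajectory:
    """p_x(t) over the 10 states with derived open probability."""

    times: np.ndarray
    occupancies: np.ndarray  # shape (n_times, 10), rows sum to 1
    concentrations: np.ndarray | None = None  # L at each sample
    segment_bounds: tuple[int, ...] = field(default_factory=tuple)

    @property
    def po(self) -> np.ndarray:
        return self.occupancies[:, _OPEN_IDX].sum(axis=1)

    def state(self, label: str) -> np.ndarray:
        return self.occupancies[:, STATES.index(label)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.occupancies, columns=list(STATES))
        df.insert(0, "time_s", self.times)
        df["Po"] = self.po
        if self.concentrations is not None:
            df["L_uM"] = self.concentrations
        return df


@dataclass
class EquilibriumCurve:
    """Equilibrium occupancies, open probability and fractional binding vs L."""

    concentrations: np.ndarray
    occupancies: np.ndarray  # (n_L, 10)

    @property
    def po(self) -> np.ndarray:
        return self.occupancies[:, _OPEN_IDX].sum(axis=1)

    @property
    def binding(self) -> np.ndarray:
        nb = np.array([BOUND_LIGANDS[s] for s in STATES], dtype=float)
        return self.occupancies @ nb / N_SITES

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.occupancies, columns=list(STATES))
        df.insert(0, "L_uM", self.concentrations)
        df["Po"] = self.po
        df["binding"] = self.binding
        return df


def _check_generator(Q: np.ndarray) -> None:
    if Q.shape[0] != Q.shape[1]:
        raise ValueError("generator must be square")
    colsums = Q.sum(axis=0)
    if np.max(np.abs(colsums)) > 1e-8 * max(1.0, np.max(np.abs(Q))):
        raise ValueError("not a generator: columns do not sum to zero")


def _clip_occupancies(p: np.ndarray) -> np.ndarray:
    if np.min(p) < -_NEG_TOL:
        raise RuntimeError(f"occupancy fell below -{_NEG_TOL}: min={np.min(p):.3e}")
    p = np.clip(p, 0.0, None)
    return p / p.sum(axis=-1, keepdims=True)


def solve_relaxation(Q: np.ndarray, p0: np.ndarray, times: np.ndarray) -> OccupancyTrajectory:
    """Relax p0 under constant Q: p(t) = V exp(diag(w) t) V^-1 p0.

    Falls back to LSODA integration when the eigenvector matrix is too
    ill-conditioned for the spectral form to be trustworthy.
    """
    _check_generator(Q)
    p0 = np.asarray(p0, dtype=float)
    times = np.atleast_1d(np.asarray(times, dtype=float))
    if np.any(times < 0):
        raise ValueError("times must be >= 0")
    if abs(p0.sum() - 1.0) > 1e-8 or np.min(p0) < -_NEG_TOL:
        raise ValueError("p0 must be a probability vector")

    w, V = np.linalg.eig(Q)
    # a generator's spectrum has non-positive real parts; positive values
    # are rounding noise and would blow up exp(w t) on long grids
    w = np.where(w.real > 0, 1j * w.imag, w)
    cond = np.linalg.cond(V)
    if np.isfinite(cond) and cond < _COND_LIMIT:
        c = np.linalg.solve(V, p0.astype(complex))
        # p(t_i) = V @ (c * exp(w t_i)); vectorized over times
        phases = np.exp(np.outer(times, w))  # (n_t, 10)
        P = (phases * c) @ V.T
        P = np.real(P)
    else:  # defective or near-defective Q: integrate directly
        sol = solve_ivp(
            lambda t, p: Q @ p, (0.0, float(times.max()) if times.size else 0.0),
            p0, t_eval=times, method="LSODA", rtol=1e-10, atol=1e-12,
            jac=lambda t, p: Q,
        )
        if not sol.success:
            raise RuntimeError(f"fallback integration failed: {sol.message}")
        P = sol.y.T
    P = _clip_occupancies(P)
    return OccupancyTrajectory(times=times, occupancies=P)


def equilibrium_distribution(Q: np.ndarray) -> np.ndarray:
    """Stationary distribution: the normalized null vector of Q.

    At L = 0 the chain is reducible (all liganded states drain into C0)
    and the null space found by SVD is exactly the point mass on the
    absorbing unliganded closed state, which is also what this returns.
    """
    _check_generator(Q)
    _, s, Vt = np.linalg.svd(Q)
    null_mask = s < max(1e-10, s[0] * 1e-12)
    # SVD orders singular values descending: the last right-singular vector
    # spans the null space for a rank n-1 generator.
    if null_mask.sum() > 1 and not np.allclose(Q[:, 0], 0):
        raise ValueError("degenerate generator: multiple stationary directions")
    v = Vt[-1]
    v = np.abs(np.real(v))
    total = v.sum()
    if total <= 0:
        raise ValueError("null vector is not a distribution")
    return v / total


def simulate_protocol(
    rates: RateConstantSet,
    variant: ModelVariant | str,
    factors: CouplingFactors,
    protocol: ConcentrationProtocol,
    p_init: np.ndarray | None = None,
) -> OccupancyTrajectory:
    """Piecewise relaxation through a concentration protocol.

    Each segment relaxes under its own generator; the initial condition
    of segment i+1 is the exact final occupancy of segment i.  Default
    start is the equilibrium at zero concentration (all probability in
    C0), the resting condition before a ligand jump.
    """
    eff = effective_rates(rates, factors, variant)
    if p_init is None:
        p = equilibrium_distribution(generator_matrix(eff, 0.0))
    else:
        p = np.asarray(p_init, dtype=float)

    all_t, all_p, all_L, bounds = [], [], [], []
    t_offset = 0.0
    n_so_far = 0
    for i, (L, dur) in enumerate(protocol.segments):
        Q = generator_matrix(eff, L)
        grid = protocol.segment_grid(i)
        # always propagate to the exact segment end for the handoff
        solve_grid = grid if grid.size and np.isclose(grid[-1], dur) else np.append(grid, dur)
        traj = solve_relaxation(Q, p, solve_grid)
        keep = len(grid)
        all_t.append(traj.times[:keep] + t_offset)
        all_p.append(traj.occupancies[:keep])
        all_L.append(np.full(keep, L))
        p = traj.occupancies[-1]
        t_offset += dur
        n_so_far += keep
        bounds.append(n_so_far)
    return OccupancyTrajectory(
        times=np.concatenate(all_t),
        occupancies=np.vstack(all_p),
        concentrations=np.concatenate(all_L),
        segment_bounds=tuple(bounds),
    )


def concentration_po_curve(
    rates: RateConstantSet,
    variant: ModelVariant | str,
    factors: CouplingFactors,
    concentrations: np.ndarray,
) -> EquilibriumCurve:
    """Equilibrium concentration-Po relationship (with full occupancies)."""
    eff = effective_rates(rates, factors, variant)
    L_list = np.atleast_1d(np.asarray(concentrations, dtype=float))
    occ = np.vstack([
        equilibrium_distribution(generator_matrix(eff, L)) for L in L_list
    ])
    return EquilibriumCurve(concentrations=L_list, occupancies=occ)


def binding_occupancy_curve(
    rates: RateConstantSet,
    variant: ModelVariant | str,
    factors: CouplingFactors,
    concentrations: np.ndarray,
) -> EquilibriumCurve:
    """Equilibrium mean fractional ligand binding B(L).

    B(L) = sum_x n_bound(x) p_x(L) / 3; the model analogue of a
    fluorescence concentration-binding relationship.
    """
    return concentration_po_curve(rates, variant, factors, concentrations)
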