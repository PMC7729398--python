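"""Coupled global fitting of the F1-F4 schemes to current and Po data.

The four experimental conditions (wt ATP, H319K ATP, wt fATP, H319K
fATP) are described by four schemes sharing one set of 26 rate
constants; the mutant/ligand variants differ only through the coupling
factors f, g, h, j, m.  The fit minimizes a weighted sum of squared
deviations over (i) normalized activation/deactivation time courses and
(ii) equilibrium concentration-Po relationships,

    S = sum_traces u * sum_t (I_m - I_c)^2 / sigma_I^2
      + sum_rel  s_k * sum_L (P_om - P_oc)^2 / sigma_Po^2,

with the weighting factors u and s_k chosen so that all time courses
together and all concentration-Po relationships together carry the same
effective number of fit points.  Optimization is Levenberg-Marquardt on
log-transformed parameters (positivity by construction); standard
errors come from the inverse Gauss-Newton normal matrix of the weighted
residuals at the optimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares

from p2xkin.model import (
    N_RATES,
    CouplingFactors,
    ModelVariant,
    RateConstantSet,
    effective_rates,
    generator_matrix,
)
from p2xkin.relax import (
    ConcentrationProtocol,
    equilibrium_distribution,
    simulate_protocol,
    concentration_po_curve,
)

__all__ = [
    "Trace",
    "SteadyStateRelationship",
    "DatasetBundle",
    "WeightScheme",
    "FitResult",
    "FitOptions",
    "ObjectiveEvaluationError",
    "compute_weights",
    "objective",
    "residual_vector",
    "fit_global",
    "standard_errors",
    "VARIANT_FOR_CONDITION",
]

#: canonical condition -> scheme mapping of the 4-way coupled fit
VARIANT_FOR_CONDITION: dict[str, ModelVariant] = {
    "wt·ATP": ModelVariant.F1,
    "H319K·ATP": ModelVariant.F2,
    "wt·fATP": ModelVariant.F3,
    "H319K·fATP": ModelVariant.F4,
}

#: which coupling factors each variant actually uses
FACTORS_USED: dict[ModelVariant, tuple[str, ...]] = {
    ModelVariant.F1: (),
    ModelVariant.F2: ("f", "g"),
    ModelVariant.F3: ("h", "j", "m"),
    ModelVariant.F4: ("f", "g", "h", "j"),
}


class ObjectiveEvaluationError(RuntimeError):
    """A model evaluation inside the objective failed (reported, not hidden)."""


@dataclass
class Trace:
    """One normalized concentration-jump current time course.

    ``times`` spans the fitted window: activation points in [0, t_on]
    (already truncated at the current peak upstream) followed by
    deactivation points in (t_on, t_end].  ``current`` is normalized to
    the trace maximum; ``variance`` is the per-point measurement
    variance of the normalized current.
    """

    L: float
    t_on: float
    times: np.ndarray
    current: np.ndarray
    variance: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.current = np.asarray(self.current, dtype=float)
        self.variance = np.asarray(self.variance, dtype=float)
        if not (self.times.shape == self.current.shape == self.variance.shape):
            raise ValueError("times/current/variance must share a shape")
        if np.any(np.diff(self.times) < 0):
            raise ValueError("trace times must be monotone")
        if np.any(self.variance <= 0):
            raise ValueError("per-point variances must be positive")

    @property
    def n_points(self) -> int:
        return self.times.size

    def activation_mask(self) -> np.ndarray:
        return self.times <= self.t_on * (1 + 1e-12)


@dataclass
class SteadyStateRelationship:
    """Equilibrium concentration-Po points with measurement variances."""

    concentrations: np.ndarray
    po: np.ndarray
    variance: np.ndarray

    def __post_init__(self):
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.po = np.asarray(self.po, dtype=float)
        self.variance = np.asarray(self.variance, dtype=float)
        if np.any(self.variance <= 0):
            raise ValueError("variances must be positive")

    @property
    def n_points(self) -> int:
        return self.concentrations.size


@dataclass
class DatasetBundle:
    """All data for one condition: traces + one steady-state relationship."""

    condition: str
    variant: ModelVariant
    traces: list[Trace]
    steady_state: SteadyStateRelationship
    po_max: float = 0.719  # pooled open probability at saturation

    def trace_point_counts(self) -> list[int]:
        return [t.n_points for t in self.traces]


@dataclass(frozen=True)
class WeightScheme:
    """Trace weight u and per-relationship weights s_k.

    Chosen so the effective number of fit points (points x weight) of
    all time courses equals that of all concentration-Po relationships,
    and every relationship carries the same effective weight.
    """

    u: float
    s: tuple[float, ...]
    effective_points: float
    relationship_sizes: tuple[int, ...]


def compute_weights(
    trace_points: list[int],
    relationship_sizes: list[int],
    u: float = 0.1,
) -> WeightScheme:
    """Balance time-course and steady-state contributions to the objective.

    E = u * sum(trace_points) effective points are granted to the time
    courses; each of the n_s relationships receives s_k = (E / n_s) / n_k
    so that s_k * n_k is equal across relationships and sums to E.
    """
    if u <= 0:
        raise ValueError("u must be positive")
    if not trace_points or not relationship_sizes:
        raise ValueError("trace_points and relationship_sizes must be non-empty")
    if min(trace_points) < 1 or min(relationship_sizes) < 1:
        raise ValueError("point counts must be >= 1")
    E = u * float(sum(trace_points))
    n_s = len(relationship_sizes)
    s = tuple(E / n_s / n_k for n_k in relationship_sizes)
    return WeightScheme(u=u, s=s, effective_points=E,
                        relationship_sizes=tuple(relationship_sizes))


def weights_for(datasets: list[DatasetBundle], u: float = 0.1) -> WeightScheme:
    trace_points = [n for d in datasets for n in d.trace_point_counts()]
    sizes = [d.steady_state.n_points for d in datasets]
    return compute_weights(trace_points, sizes, u)


def _simulate_trace_po(eff: RateConstantSet, trace: Trace) -> np.ndarray:
    """Open probability on the trace grid for a 0 -> L -> 0 jump."""
    act = trace.activation_mask()
    grids = (trace.times[act], trace.times[~act] - trace.t_on)
    t_end = max(float(trace.times[-1]) - trace.t_on, 1e-6)
    protocol = ConcentrationProtocol(
        segments=((trace.L, trace.t_on), (0.0, t_end)),
        grids=grids,
    )
    traj = simulate_protocol(eff, ModelVariant.F1, CouplingFactors(), protocol)
    return traj.po


def _trace_residuals(eff: RateConstantSet, trace: Trace, u: float) -> np.ndarray:
    po = _simulate_trace_po(eff, trace)
    act = trace.activation_mask()
    peak = po[act].max() if act.any() else po.max()
    if not np.isfinite(peak) or peak <= 0:
        raise ObjectiveEvaluationError(
            f"simulated trace at L={trace.L} uM never opens; cannot normalize"
        )
    ic = po / peak
    return np.sqrt(u / trace.variance) * (trace.current - ic)


def residual_vector(
    rates: RateConstantSet,
    factors: CouplingFactors,
    datasets: list[DatasetBundle],
    weights: WeightScheme,
) -> np.ndarray:
    """Weighted residuals; S = sum of squares of this vector."""
    parts = []
    k = 0
    for d in datasets:
        eff = effective_rates(rates, factors, d.variant)
        for tr in d.traces:
            parts.append(_trace_residuals(eff, tr, weights.u))
        ss = d.steady_state
        try:
            curve = concentration_po_curve(rates, d.variant, factors, ss.concentrations)
        except (ValueError, np.linalg.LinAlgError) as exc:
            raise ObjectiveEvaluationError(
                f"equilibrium curve failed for {d.condition}: {exc}"
            ) from exc
        parts.append(np.sqrt(weights.s[k] / ss.variance) * (ss.po - curve.po))
        k += 1
    return np.concatenate(parts)


def objective(
    rates: RateConstantSet,
    factors: CouplingFactors,
    datasets: list[DatasetBundle],
    weights: WeightScheme,
) -> float:
    """The weighted sum of squared deviations S."""
    r = residual_vector(rates, factors, datasets, weights)
    return float(r @ r)


@dataclass(frozen=True)
class FitOptions:
    u: float = 0.1
    rel_s_tol: float = 1e-6  # relative change of S at which iteration stops
    max_iter: int = 200  # LM iterations (scaled to function evaluations)
    n_starts: int = 1  # >1: multi-start from log-uniform perturbations
    start_spread: float = 3.0  # multiplicative spread of extra starts
    seed: int | None = None
    rate_upper_bound: float | None = None  # optional cap on rate constants


@dataclass
class FitResult:
    rates: RateConstantSet
    factors: CouplingFactors
    s_value: float
    converged: bool
    n_evaluations: int
    message: str
    param_names: list[str]
    param_values: np.ndarray  # natural scale, order = param_names
    cov_log: np.ndarray | None  # covariance in the log parameterization
    weights: WeightScheme | None = None
    history: list[float] = field(default_factory=list)

    @property
    def se(self) -> np.ndarray:
        """Standard errors on the natural scale (delta method from log)."""
        if self.cov_log is None:
            return np.full(len(self.param_names), np.nan)
        se_log = np.sqrt(np.clip(np.diag(self.cov_log), 0, None))
        return np.abs(self.param_values) * se_log

    @property
    def relative_errors(self) -> np.ndarray:
        return self.se / np.abs(self.param_values)

    @property
    def median_relative_error(self) -> float:
        rel = self.relative_errors
        rel = rel[np.isfinite(rel)]
        return float(np.median(rel)) if rel.size else float("nan")


def _pack_names(variants: set[ModelVariant]) -> list[str]:
    names = [f"k{i}" for i in range(1, N_RATES + 1)]
    used: list[str] = []
    for v in (ModelVariant.F2, ModelVariant.F3, ModelVariant.F4):
        if v in variants:
            for f in FACTORS_USED[v]:
                if f not in used:
                    used.append(f)
    return names + used


_LOG_CLIP = 60.0  # |log k| cap inside optimization; e^60 ~ 1e26


def _unpack(x: np.ndarray, names: list[str]) -> tuple[RateConstantSet, CouplingFactors]:
    vals = np.exp(np.clip(x, -_LOG_CLIP, _LOG_CLIP))
    rates = RateConstantSet(vals[:N_RATES])
    fdict = {n: v for n, v in zip(names[N_RATES:], vals[N_RATES:])}
    return rates, CouplingFactors(**{k: fdict.get(k, 1.0) for k in ("f", "g", "h", "j", "m")})


def fit_global(
    datasets: list[DatasetBundle],
    init_rates: RateConstantSet,
    init_factors: CouplingFactors | None = None,
    options: FitOptions | None = None,
) -> FitResult:
    """Coupled least-squares fit of one, two or four schemes.

    All datasets share the 26 rate constants; coupling factors are added
    as free parameters only for the variants present (none for a pure-F1
    fit).  Parameters are optimized as logarithms, so positivity holds
    throughout and the Levenberg-Marquardt steps act on relative changes.
    """
    if not datasets:
        raise ValueError("at least one dataset required")
    options = options or FitOptions()
    init_factors = init_factors or CouplingFactors()
    weights = weights_for(datasets, options.u)
    names = _pack_names({d.variant for d in datasets})
    x0 = np.log(np.concatenate([
        init_rates.as_array(),
        [getattr(init_factors, n) for n in names[N_RATES:]],
    ]))

    n_residuals = residual_vector(*_unpack(x0, names), datasets, weights).size
    n_eval = [0]

    def fun(x: np.ndarray) -> np.ndarray:
        n_eval[0] += 1
        rates, factors = _unpack(x, names)
        if options.rate_upper_bound is not None:
            capped = np.minimum(rates.as_array(), options.rate_upper_bound)
            rates = RateConstantSet(capped)
        try:
            with np.errstate(all="ignore"):
                r = residual_vector(rates, factors, datasets, weights)
        except (ObjectiveEvaluationError, RuntimeError, ValueError,
                np.linalg.LinAlgError):
            # pathological corner of parameter space: steer LM away
            return np.full(n_residuals, 1e6)
        if not np.all(np.isfinite(r)):
            return np.full(n_residuals, 1e6)
        return r

    starts = [x0]
    if options.n_starts > 1:
        rng = np.random.default_rng(options.seed)
        for _ in range(options.n_starts - 1):
            starts.append(x0 + rng.uniform(
                -np.log(options.start_spread), np.log(options.start_spread), x0.size))

    best = None
    for start in starts:
        sol = least_squares(
            fun, start, method="lm",
            ftol=options.rel_s_tol, xtol=1e-12, gtol=1e-12,
            max_nfev=options.max_iter * (len(start) + 1),
        )
        if best is None or sol.cost < best.cost:
            best = sol

    s_value = float(2.0 * best.cost)
    J = best.jac
    cov_log = _covariance_from_jacobian(J)
    rates, factors = _unpack(best.x, names)
    converged = bool(best.status > 0)
    return FitResult(
        rates=rates, factors=factors, s_value=s_value,
        converged=converged, n_evaluations=n_eval[0],
        message=str(best.message), param_names=names,
        param_values=np.exp(best.x), cov_log=cov_log, weights=weights,
    )


def _covariance_from_jacobian(J: np.ndarray) -> np.ndarray | None:
    """Inverse Gauss-Newton normal matrix, with non-influential parameters
    flagged as unavailable (NaN rows/columns) rather than fabricated."""
    col_norm = np.linalg.norm(J, axis=0)
    scale = col_norm.max() if col_norm.size else 0.0
    if scale == 0:
        return None
    dead = col_norm < 1e-12 * scale
    cov = np.full((J.shape[1], J.shape[1]), np.nan)
    live = ~dead
    Jl = J[:, live]
    JtJ = Jl.T @ Jl
    try:
        cov_live = np.linalg.inv(JtJ)
    except np.linalg.LinAlgError:
        return cov  # all live entries stay NaN: singular normal matrix
    if np.linalg.cond(JtJ) > 1e14:
        return cov
    cov[np.ix_(live, live)] = cov_live
    return cov


@dataclass
class ErrorReport:
    names: list[str]
    values: np.ndarray
    se: np.ndarray
    relative: np.ndarray
    median_relative: float


def standard_errors(fit: FitResult) -> ErrorReport:
    """Per-parameter standard errors se(p_i) = sqrt(cov_ii) and relatives.

    The covariance is computed in the log parameterization and mapped to
    the natural scale by the delta method; the relative error se/|p| is
    parameterization-free.  Parameters without influence on any residual
    are reported as NaN (unavailable).
    """
    se = fit.se
    rel = fit.relative_errors
    finite = rel[np.isfinite(rel)]
    return ErrorReport(
        names=list(fit.param_names),
        values=fit.param_values.copy(),
        se=se,
        relative=rel,
        median_relative=float(np.median(finite)) if finite.size else float("nan"),
    )
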