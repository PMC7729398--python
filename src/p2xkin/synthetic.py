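"""Synthetic patch-clamp style data for the full analysis pipeline.

No public recordings accompany the P2X2 gating problem, so this module
generates every input the pipeline consumes from a documented
ground-truth parameter set: noisy ensemble current time courses for the
four conditions (wt/H319K x ATP/fATP), equilibrium concentration-Po
points with variances, two-level single-channel amplitude samples, and
ensemble sweeps for the noise-based Po,max estimate.

The default ground-truth rate set is a plausible fixture, not a fitted
result.  It was constructed to reproduce the phenomenology of wild-type
P2X2 activation: EC50 near 1.2 uM with a Hill slope near 2, maximal
open probability near 0.72 (set by the fast F3-O3 equilibrium,
2380/938 s^-1), pronounced negative binding cooperativity and strongly
positive flip cooperativity, with an H319K-like left shift produced by
the printed coupling factors.  Backward rates off the spanning tree are
derived from cycle closure, so the fixture satisfies detailed balance
exactly (the fitter itself never imposes this).

Ensemble noise model: N independent channels of unitary current i give
a current variance i^2 N Po (1 - Po), plus an additive Gaussian
instrument floor.  Desensitization and solution-exchange kinetics are
not emulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from p2xkin.fitting import (
    VARIANT_FOR_CONDITION,
    DatasetBundle,
    SteadyStateRelationship,
    Trace,
)
from p2xkin.model import (
    CouplingFactors,
    ModelVariant,
    RateConstantSet,
    effective_rates,
)
from p2xkin.relax import ConcentrationProtocol, concentration_po_curve, simulate_protocol

__all__ = [
    "GroundTruth",
    "default_ground_truth",
    "default_rates",
    "generate_bundle",
    "generate_single_channel_samples",
    "generate_noise_sweeps",
    "NoiseSweepSet",
    "DEFAULT_CONCENTRATIONS",
    "STEADY_STATE_COUNTS",
]


def default_rates() -> RateConstantSet:
    """The documented ground-truth fixture rate set (units: uM, s).

    Forward rates and equilibrium constants are free choices; backward
    rates on the F- and O-row binding steps close the four elementary
    cycles so the set obeys detailed balance exactly.
    """
    K_C = (0.6, 0.17, 0.057)       # per-site association constants, uM^-1
    E_F = (1.0e-3, 0.25, 100.0)    # flip equilibrium constants by liganding
    E_O1, E_O2 = 0.5, 1.2
    k21, k22 = 2.38e3, 9.38e2      # F3-O3 pair (physically rescaled scale)
    E_O3 = k21 / k22

    k = np.empty(26)
    # C-row binding
    k[0], k[1] = 4.0, 4.0 / K_C[0]          # k1, k2
    k[2], k[3] = 2.4, 2.4 / K_C[1]          # k3, k4
    k[4], k[5] = 1.2, 1.2 / K_C[2]          # k5, k6
    # flips
    k[6], k[7] = 2.0, 2.0 / E_F[0]          # k7, k8
    k[8], k[9] = 100.0, 100.0 / E_F[1]      # k9, k10
    k[10], k[11] = 4000.0, 4000.0 / E_F[2]  # k11, k12
    # F-row binding (cycle closure: K_Fx = K_Cx * E_Fx / E_F(x-1))
    K_F2 = K_C[1] * E_F[1] / E_F[0]
    K_F3 = K_C[2] * E_F[2] / E_F[1]
    k[12], k[13] = 8.5, 8.5 / K_F2          # k13, k14
    k[14], k[15] = 10.0, 10.0 / K_F3        # k15, k16
    # openings
    k[16], k[17] = 150.0, 150.0 / E_O1      # k17, k18
    k[18], k[19] = 600.0, 600.0 / E_O2      # k19, k20
    k[20], k[21] = k21, k22
    # O-row binding (cycle closure: K_Ox = K_Fx * E_Ox / E_O(x-1))
    K_O2 = K_F2 * E_O2 / E_O1
    K_O3 = K_F3 * E_O3 / E_O2
    k[22], k[23] = 10.0, 10.0 / K_O2        # k23, k24
    k[24], k[25] = 10.0, 10.0 / K_O3        # k25, k26
    return RateConstantSet(k)


#: coupling factors as printed for the 4-way coupled fit
DEFAULT_FACTORS = CouplingFactors(f=11.20, g=5.14e-4, h=0.17, j=5.57, m=15.59)

#: pulse concentrations (uM) per condition, spanning each EC50 range
DEFAULT_CONCENTRATIONS: dict[str, tuple[float, ...]] = {
    "wt·ATP": (0.3, 1.0, 3.0, 10.0, 100.0),
    "H319K·ATP": (0.01, 0.03, 0.1, 0.3, 1.0),
    "wt·fATP": (3.0, 10.0, 30.0, 100.0, 300.0),
    "H319K·fATP": (0.1, 0.3, 1.0, 3.0, 10.0),
}

#: steady-state relationship sizes per condition (as in the 4-way fit data)
STEADY_STATE_COUNTS: dict[str, int] = {
    "wt·ATP": 6, "wt·fATP": 4, "H319K·ATP": 7, "H319K·fATP": 11,
}

#: log-spaced spans (uM) of the steady-state relationships
STEADY_STATE_SPANS: dict[str, tuple[float, float]] = {
    "wt·ATP": (0.1, 100.0),
    "H319K·ATP": (0.003, 1.0),
    "wt·fATP": (1.0, 1000.0),
    "H319K·fATP": (0.03, 30.0),
}


@dataclass(frozen=True)
class GroundTruth:
    """Generating parameters for a synthetic data bundle."""

    rates: RateConstantSet = field(default_factory=default_rates)
    factors: CouplingFactors = DEFAULT_FACTORS
    po_max: float = 0.719
    i_wt: float = 0.80  # single-channel current, pA
    i_mut: float = 0.78
    n_channels: int = 1000
    n_sweeps: int = 10
    noise_scale: float = 1.0  # 0 disables stochastic noise
    instrument_sd: float = 2.0  # pA, additive floor per sweep

    def unitary_current(self, condition: str) -> float:
        return self.i_mut if condition.startswith("H319K") else self.i_wt


def default_ground_truth(**overrides) -> GroundTruth:
    return replace(GroundTruth(), **overrides) if overrides else GroundTruth()


def _make_trace(
    truth: GroundTruth,
    condition: str,
    L: float,
    t_on: float,
    t_off: float,
    points_per_segment: int,
    rng: np.random.Generator,
) -> Trace:
    variant = VARIANT_FOR_CONDITION[condition]
    eff = effective_rates(truth.rates, truth.factors, variant)
    protocol = ConcentrationProtocol.jump(L, on=t_on, off=t_off,
                                          points_per_segment=points_per_segment)
    traj = simulate_protocol(eff, ModelVariant.F1, CouplingFactors(), protocol)
    po = traj.po
    i = truth.unitary_current(condition)
    N = truth.n_channels
    mean_current = i * N * po
    var_current = (i**2) * N * po * (1.0 - po) + truth.instrument_sd**2

    # mean over n_sweeps independent sweeps; the quoted per-point variance
    # is exactly the variance of the injected noise (var_mean > 0 always,
    # the instrument floor survives even at Po = 0)
    var_mean = var_current / truth.n_sweeps
    if truth.noise_scale > 0:
        noisy = mean_current + truth.noise_scale * rng.normal(
            0.0, np.sqrt(var_mean), size=mean_current.shape)
        var_quoted = var_mean * truth.noise_scale**2
    else:
        noisy = mean_current
        var_quoted = var_mean  # weights only; the data are exact

    act = traj.times <= t_on * (1 + 1e-12)
    peak = np.abs(noisy[act]).max()
    current = np.abs(noisy) / peak
    return Trace(L=L, t_on=t_on, times=traj.times, current=current,
                 variance=var_quoted / peak**2)


def _steady_state(
    truth: GroundTruth,
    condition: str,
    concentrations: np.ndarray,
    rng: np.random.Generator,
    n_cells: int = 2000,
) -> SteadyStateRelationship:
    variant = VARIANT_FOR_CONDITION[condition]
    curve = concentration_po_curve(truth.rates, variant, truth.factors, concentrations)
    po = curve.po
    var = po * (1.0 - po) / n_cells + 1e-6
    if truth.noise_scale > 0:
        po_obs = po + truth.noise_scale * rng.normal(0.0, np.sqrt(var))
        po_obs = np.clip(po_obs, 0.0, 1.0)
    else:
        po_obs = po
    # quoted variance matches the noise actually injected (var > 0 always)
    var_quoted = var * truth.noise_scale**2 if truth.noise_scale > 0 else var
    return SteadyStateRelationship(concentrations=concentrations, po=po_obs,
                                   variance=var_quoted)


def generate_bundle(
    truth: GroundTruth | None = None,
    concentrations: dict[str, tuple[float, ...]] | None = None,
    t_on: float = 2.0,
    t_off: float = 5.0,
    points_per_segment: int = 50,
    seed: int = 0,
    conditions: tuple[str, ...] = tuple(VARIANT_FOR_CONDITION),
) -> list[DatasetBundle]:
    """Synthetic 4-condition dataset bundles for the coupled global fit.

    Each condition gets one activation/deactivation trace per pulse
    concentration (``points_per_segment`` samples per segment) plus a
    steady-state concentration-Po relationship with the per-condition
    point counts of the coupled-fit design.  All randomness flows from
    ``seed``; identical seeds give identical bundles.
    """
    truth = truth or GroundTruth()
    concentrations = concentrations or DEFAULT_CONCENTRATIONS
    rng = np.random.default_rng(seed)
    bundles = []
    for condition in conditions:
        traces = [
            _make_trace(truth, condition, L, t_on, t_off, points_per_segment, rng)
            for L in concentrations[condition]
        ]
        lo, hi = STEADY_STATE_SPANS[condition]
        n_ss = STEADY_STATE_COUNTS[condition]
        ss_conc = np.geomspace(lo, hi, n_ss)
        ss = _steady_state(truth, condition, ss_conc, rng)
        bundles.append(DatasetBundle(
            condition=condition,
            variant=VARIANT_FOR_CONDITION[condition],
            traces=traces,
            steady_state=ss,
            po_max=truth.po_max,
        ))
    return bundles


def generate_single_channel_samples(
    i_s: float = 0.80,
    sigma: float = 0.15,
    p_open: float = 0.5,
    n: int = 10_000,
    seed: int = 0,
) -> np.ndarray:
    """Amplitude samples from a closed/open two-Gaussian mixture.

    Closed level at 0 pA, open level at ``i_s`` pA, common width
    ``sigma`` (filtered-record noise).  Emulates the amplitude
    histograms used to measure the single-channel current.
    """
    if n < 100:
        raise ValueError("need at least 100 samples for a histogram fit")
    rng = np.random.default_rng(seed)
    is_open = rng.random(n) < p_open
    centers = np.where(is_open, i_s, 0.0)
    return centers + (rng.normal(0.0, sigma, size=n) if sigma > 0 else 0.0)


@dataclass
class NoiseSweepSet:
    """Ensemble sweeps around the peak at saturating ligand, plus baseline."""

    peak_currents: np.ndarray  # pA, one sample per sweep at the peak
    baseline_currents: np.ndarray  # pA
    i: float  # generating unitary current
    true_po: float  # generating open probability at the peak

    @property
    def sigma2_peak(self) -> float:
        return float(np.var(self.peak_currents, ddof=1))

    @property
    def sigma2_baseline(self) -> float:
        return float(np.var(self.baseline_currents, ddof=1))

    @property
    def i_max(self) -> float:
        return float(np.mean(self.peak_currents))


def generate_noise_sweeps(
    truth: GroundTruth | None = None,
    condition: str = "wt·ATP",
    L_saturating: float = 100.0,
    n_sweeps: int = 100,
    seed: int = 0,
) -> NoiseSweepSet:
    """Binomial channel-count fluctuations at the peak for noise analysis.

    Each sweep contributes one peak-current sample drawn from the
    binomial open-channel count at the equilibrium Po of the saturating
    concentration, plus instrument noise; the baseline segment has
    instrument noise only (no channels active at L = 0).
    """
    truth = truth or GroundTruth()
    rng = np.random.default_rng(seed)
    variant = VARIANT_FOR_CONDITION[condition]
    curve = concentration_po_curve(truth.rates, variant, truth.factors,
                                   np.array([L_saturating]))
    po = float(curve.po[0])
    i = truth.unitary_current(condition)
    n_open = rng.binomial(truth.n_channels, po, size=n_sweeps)
    peak = i * n_open + rng.normal(0.0, truth.instrument_sd, size=n_sweeps)
    baseline = rng.normal(0.0, truth.instrument_sd, size=n_sweeps)
    return NoiseSweepSet(peak_currents=peak, baseline_currents=baseline,
                         i=i, true_po=po)
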