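"""Pre-model reductions of raw recordings.

Covers the standard evaluations that precede kinetic modelling of
whole-cell P2X2 currents: the maximal open probability from ensemble
noise at saturating agonist, Hill fits of concentration-activation
relationships, two-Gaussian fits of single-channel amplitude
histograms, and the normalization/truncation of current time courses
(activation cut at the peak to exclude desensitization).

Currents are handled as magnitudes; the inward-current sign convention
of recordings at -50 mV is normalized at ingestion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from lmfit import Model

__all__ = [
    "NoiseSummary",
    "HillFit",
    "AmplitudeFit",
    "po_max_from_noise",
    "hill_fit",
    "gaussian_histogram_fit",
    "normalize_and_truncate",
]


@dataclass
class NoiseSummary:
    """Ensemble-noise evaluation at saturating agonist.

    With N independent two-state channels of unitary current i, the
    current variance around the peak is sigma^2 = i * I_max * (1 - Po),
    so Po,max = 1 - sigma^2 / (i * I_max) after baseline correction.
    """

    sigma2_peak: float  # pA^2
    sigma2_baseline: float  # pA^2
    i: float  # single-channel current, pA
    i_max: float  # peak ensemble current, pA
    po_max: float
    physical: bool  # False if the corrected variance exceeded i*I_max


@dataclass
class HillFit:
    ec50: float  # uM
    hill: float
    ec50_se: float
    hill_se: float
    converged: bool


@dataclass
class AmplitudeFit:
    """Two-Gaussian amplitude-histogram fit; i_s = |i2 - i1|."""

    amplitudes: tuple[float, float]  # A1, A2
    means: tuple[float, float]  # i1, i2 (pA)
    sigmas: tuple[float, float]  # pA
    i_s: float  # single-channel current, pA
    converged: bool


def po_max_from_noise(
    sigma2_peak: float,
    sigma2_baseline: float,
    i: float,
    i_max: float,
) -> NoiseSummary:
    """Maximal open probability from peak-current noise.

    Po,max = 1 - (sigma2_peak - sigma2_baseline) / (i * I_max).
    Values outside (0, 1] are clipped with a warning and flagged.
    """
    i, i_max = abs(i), abs(i_max)
    if i <= 0 or i_max <= 0:
        raise ValueError("single-channel and peak currents must be non-zero")
    corrected = sigma2_peak - sigma2_baseline
    po = 1.0 - corrected / (i * i_max)
    physical = 0.0 < po <= 1.0
    if not physical:
        warnings.warn(
            f"non-physical Po,max={po:.3f} (corrected variance vs i*I_max); clipping",
            stacklevel=2,
        )
        po = float(np.clip(po, np.finfo(float).tiny, 1.0))
    return NoiseSummary(sigma2_peak=sigma2_peak, sigma2_baseline=sigma2_baseline,
                        i=i, i_max=i_max, po_max=float(po), physical=physical)


def _hill(x, ec50, hill):
    return 1.0 / (1.0 + (ec50 / x) ** hill)


def hill_fit(
    concentrations: np.ndarray,
    responses: np.ndarray,
    variances: np.ndarray | None = None,
) -> HillFit:
    """Weighted Hill fit of a normalized concentration-activation relationship.

    I/I_max = 1 / (1 + (EC50/[X])^H), fitted by nonlinear least squares
    with statistical weights 1/sigma per point when variances are given.
    """
    x = np.asarray(concentrations, dtype=float)
    y = np.asarray(responses, dtype=float)
    if x.size < 3:
        raise ValueError("at least 3 concentrations required")
    if np.any(x <= 0):
        raise ValueError("concentrations must be positive")
    weights = None
    if variances is not None:
        v = np.asarray(variances, dtype=float)
        if np.any(v <= 0):
            raise ValueError("variances must be positive")
        weights = 1.0 / np.sqrt(v)

    model = Model(_hill)
    # half-maximum crossing as EC50 start, slope ~1.5 typical for P2X
    ec50_guess = float(np.interp(0.5, np.clip(y, 0, 1), x)) if y.max() > 0.5 else float(np.median(x))
    params = model.make_params(ec50=max(ec50_guess, x.min() * 0.1), hill=1.5)
    params["ec50"].min = 1e-12
    params["hill"].min = 1e-6
    result = model.fit(y, params, x=x, weights=weights)
    return HillFit(
        ec50=float(result.params["ec50"].value),
        hill=float(result.params["hill"].value),
        ec50_se=float(result.params["ec50"].stderr or np.nan),
        hill_se=float(result.params["hill"].stderr or np.nan),
        converged=bool(result.success),
    )


def _two_gauss(i, a1, i1, s1, a2, i2, s2):
    return (a1 * np.exp(-((i - i1) ** 2) / (2 * s1**2))
            + a2 * np.exp(-((i - i2) ** 2) / (2 * s2**2)))


def gaussian_histogram_fit(
    samples: np.ndarray | None = None,
    bin_centers: np.ndarray | None = None,
    counts: np.ndarray | None = None,
    bins: int = 80,
) -> AmplitudeFit:
    """Two-Gaussian fit of a single-channel amplitude histogram.

    Accepts raw amplitude samples (histogrammed internally) or a
    pre-binned histogram.  The difference of the two fitted means is the
    mean single-channel current i_s.  Degenerate single-mode data (the
    two components collapse) is flagged as not converged.
    """
    if samples is not None:
        samples = np.asarray(samples, dtype=float)
        counts, edges = np.histogram(samples, bins=bins)
        bin_centers = 0.5 * (edges[:-1] + edges[1:])
    if bin_centers is None or counts is None:
        raise ValueError("provide samples or (bin_centers, counts)")
    x = np.asarray(bin_centers, dtype=float)
    y = np.asarray(counts, dtype=float)

    # two-means split of the histogram mass for robust starting values
    c1, c2 = np.percentile(np.repeat(x, np.maximum(y.astype(int), 0)), [10, 90]) \
        if y.sum() else (x.min(), x.max())
    for _ in range(50):
        assign = np.abs(x - c1) <= np.abs(x - c2)
        w1, w2 = y[assign].sum(), y[~assign].sum()
        if w1 == 0 or w2 == 0:
            break
        n1, n2 = np.average(x[assign], weights=y[assign]), \
            np.average(x[~assign], weights=y[~assign])
        if np.isclose(n1, c1) and np.isclose(n2, c2):
            break
        c1, c2 = n1, n2
    assign = np.abs(x - c1) <= np.abs(x - c2)
    span = max(np.ptp(x), 1e-6)

    def _wsd(mask, centre):
        w = y[mask]
        if w.sum() <= 0:
            return span / 8
        return max(np.sqrt(np.average((x[mask] - centre) ** 2, weights=w)), span / 100)

    model = Model(_two_gauss)
    params = model.make_params(
        a1=max(y[assign].max(initial=1.0), 1.0), i1=c1, s1=_wsd(assign, c1),
        a2=max(y[~assign].max(initial=1.0), 1.0), i2=c2, s2=_wsd(~assign, c2),
    )
    for name in ("s1", "s2"):
        params[name].min = span / 1e4
    for name in ("a1", "a2"):
        params[name].min = 0
    for name in ("i1", "i2"):  # means stay inside the observed range
        params[name].min = x.min() - span
        params[name].max = x.max() + span
    result = model.fit(y, params, i=x)
    i1 = float(result.params["i1"].value)
    i2 = float(result.params["i2"].value)
    s1 = float(result.params["s1"].value)
    s2 = float(result.params["s2"].value)
    a1 = float(result.params["a1"].value)
    a2 = float(result.params["a2"].value)
    i_s = abs(i2 - i1)
    # genuine two-level data show a dip between the fitted levels; a split
    # single mode does not
    y_mid = _two_gauss(0.5 * (i1 + i2), a1, i1, s1, a2, i2, s2)
    y_peaks = min(_two_gauss(i1, a1, i1, s1, a2, i2, s2),
                  _two_gauss(i2, a1, i1, s1, a2, i2, s2))
    separated = y_peaks > 0 and y_mid < 0.8 * y_peaks
    return AmplitudeFit(
        amplitudes=(float(result.params["a1"].value), float(result.params["a2"].value)),
        means=(i1, i2),
        sigmas=(s1, s2),
        i_s=i_s,
        converged=bool(result.success) and separated,
    )


def normalize_and_truncate(
    times: np.ndarray,
    current: np.ndarray,
    t_on: float,
    smooth_window: int = 5,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Cut the activation segment at the current peak and normalize.

    Activation points after the (smoothed) peak are dropped — they carry
    desensitization, which the kinetic scheme does not model — while the
    deactivation segment (t > t_on) is kept.  The surviving trace is
    divided by its maximum.  Returns (times, normalized current, index
    of the peak sample).
    """
    t = np.asarray(times, dtype=float)
    I = np.abs(np.asarray(current, dtype=float))
    if np.ptp(I) == 0:
        raise ValueError("flat trace: no identifiable peak")
    act = t <= t_on * (1 + 1e-12)
    if not act.any():
        raise ValueError("no activation samples before t_on")
    Ia = I[act]
    if smooth_window > 1 and Ia.size >= smooth_window:
        kernel = np.ones(smooth_window) / smooth_window
        smoothed = np.convolve(Ia, kernel, mode="same")
    else:
        smoothed = Ia
    peak_idx = int(np.argmax(smoothed))
    keep = np.concatenate([np.flatnonzero(act)[: peak_idx + 1], np.flatnonzero(~act)])
    t_out, I_out = t[keep], I[keep]
    return t_out, I_out / I_out.max(), peak_idx
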