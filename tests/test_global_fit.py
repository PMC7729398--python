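"""Weighting scheme, objective assembly, optimizer and standard errors."""

import numpy as np
import pytest

from p2xkin.fitting import (
    CouplingFactors,
    DatasetBundle,
    FitOptions,
    SteadyStateRelationship,
    _covariance_from_jacobian,
    _simulate_trace_po,
    compute_weights,
    fit_global,
    objective,
    residual_vector,
    standard_errors,
    weights_for,
)
from p2xkin.model import ModelVariant, RateConstantSet, effective_rates
from p2xkin.synthetic import GroundTruth, generate_bundle

SMALL_CONC = {
    "wt·ATP": (1.0, 100.0),
    "H319K·ATP": (0.03, 1.0),
    "wt·fATP": (10.0, 300.0),
    "H319K·fATP": (0.3, 10.0),
}


@pytest.fixture(scope="module")
def clean_bundles():
    """Noise-free 4-condition bundles: data equal the model exactly."""
    truth = GroundTruth(noise_scale=0.0)
    return truth, generate_bundle(truth, concentrations=SMALL_CONC,
                                  points_per_segment=30, seed=0)


class TestComputeWeights:
    def test_printed_four_way_example(self):
        w = compute_weights([100] * 47, [6, 4, 7, 11], u=0.1)
        assert w.effective_points == pytest.approx(470.0)
        for s, printed in zip(w.s, (19.59, 29.38, 16.79, 10.68)):
            assert abs(s - printed) <= 0.01

    def test_symmetric_single_case(self):
        w = compute_weights([40], [40], u=1.0)
        assert w.s == (1.0,)

    def test_balance_identity(self, rng):
        for _ in range(20):
            tp = rng.integers(1, 200, size=rng.integers(1, 30)).tolist()
            sizes = rng.integers(1, 30, size=rng.integers(1, 8)).tolist()
            u = float(rng.uniform(0.01, 2))
            w = compute_weights(tp, sizes, u)
            assert sum(s * n for s, n in zip(w.s, sizes)) == pytest.approx(
                u * sum(tp), rel=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            compute_weights([], [5])
        with pytest.raises(ValueError):
            compute_weights([10], [5], u=0.0)


class TestObjective:
    def test_zero_at_generating_parameters(self, clean_bundles):
        truth, bundles = clean_bundles
        w = weights_for(bundles)
        assert objective(truth.rates, truth.factors, bundles, w) == pytest.approx(
            0.0, abs=1e-16)

    def test_manual_assembly(self, clean_bundles):
        """S recomputed point by point from simulated curves and weights."""
        truth, bundles = clean_bundles
        w = weights_for(bundles)
        wrong = RateConstantSet(truth.rates.as_array() * 1.3)
        expected = 0.0
        for k, d in enumerate(bundles):
            eff = effective_rates(wrong, truth.factors, d.variant)
            for tr in d.traces:
                po = _simulate_trace_po(eff, tr)
                ic = po / po[tr.activation_mask()].max()
                expected += w.u * np.sum((tr.current - ic) ** 2 / tr.variance)
            from p2xkin.relax import concentration_po_curve
            poc = concentration_po_curve(wrong, d.variant, truth.factors,
                                         d.steady_state.concentrations).po
            expected += w.s[k] * np.sum(
                (d.steady_state.po - poc) ** 2 / d.steady_state.variance)
        got = objective(wrong, truth.factors, bundles, w)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got > 0

    def test_scales_inversely_with_variance(self, clean_bundles):
        truth, bundles = clean_bundles
        w = weights_for(bundles)
        wrong = RateConstantSet(truth.rates.as_array() * 1.5)
        s1 = objective(wrong, truth.factors, bundles, w)
        doubled = []
        for d in bundles:
            traces = [type(t)(L=t.L, t_on=t.t_on, times=t.times, current=t.current,
                              variance=2 * t.variance) for t in d.traces]
            ss = SteadyStateRelationship(d.steady_state.concentrations,
                                         d.steady_state.po,
                                         2 * d.steady_state.variance)
            doubled.append(DatasetBundle(d.condition, d.variant, traces, ss, d.po_max))
        s2 = objective(wrong, truth.factors, doubled, w)
        assert s2 == pytest.approx(s1 / 2, rel=1e-12)

    def test_invariant_under_dataset_reordering(self, clean_bundles):
        truth, bundles = clean_bundles
        w = weights_for(bundles)
        wrong = RateConstantSet(truth.rates.as_array() * 0.7)
        s1 = objective(wrong, truth.factors, bundles, w)
        shuffled = [bundles[i] for i in (2, 0, 3, 1)]
        w2 = weights_for(shuffled)
        s2 = objective(wrong, truth.factors, shuffled, w2)
        assert s2 == pytest.approx(s1, rel=1e-12)

    def test_unit_factors_reduce_to_shared_f1(self, clean_bundles):
        """With all factors frozen at 1 the coupled objective is just four
        F1 likelihood contributions sharing one rate set."""
        truth, bundles = clean_bundles
        w = weights_for(bundles)
        wrong = RateConstantSet(truth.rates.as_array() * 1.2)
        ones = CouplingFactors()
        s_coupled = objective(wrong, ones, bundles, w)
        relabeled = [DatasetBundle(d.condition, ModelVariant.F1, d.traces,
                                   d.steady_state, d.po_max) for d in bundles]
        s_f1 = objective(wrong, ones, relabeled, w)
        assert s_coupled == pytest.approx(s_f1, rel=1e-14)


@pytest.fixture(scope="module")
def small_fit(clean_bundles):
    """Two-scheme coupled fit from mildly perturbed starts (shared)."""
    truth, bundles = clean_bundles
    two = bundles[:2]
    rng = np.random.default_rng(5)
    init = RateConstantSet(truth.rates.as_array()
                           * np.exp(rng.uniform(-0.2, 0.2, 26)))
    s_init = objective(init, truth.factors, two, weights_for(two))
    fit = fit_global(two, init, truth.factors, FitOptions())
    return truth, s_init, fit


class TestFitGlobal:
    def test_fixed_point_at_truth(self, clean_bundles):
        truth, bundles = clean_bundles
        fit = fit_global(bundles, truth.rates, truth.factors,
                         FitOptions(max_iter=50))
        assert fit.converged
        assert fit.s_value == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(fit.rates.as_array(), truth.rates.as_array(),
                                   rtol=1e-6)

    def test_recovers_mild_perturbation(self, small_fit):
        """A two-scheme coupled fit pulls perturbed parameters back to a
        near-perfect description of noise-free data."""
        truth, s_init, fit = small_fit
        assert fit.converged
        assert fit.s_value < 1e-6 * s_init
        # the H319K flip accelerator is identifiable from the pair of datasets
        assert fit.factors.f == pytest.approx(truth.factors.f, rel=0.05)


class TestStandardErrors:
    def test_linear_model_closed_form(self):
        """One-parameter model y = p x with unit-variance residuals:
        se = 1 / sqrt(sum x^2) from the normal matrix."""
        x = np.array([1.0, 2.0, 3.0])
        J = x[:, None]  # d residual / d p
        cov = _covariance_from_jacobian(J)
        assert cov[0, 0] == pytest.approx(1.0 / np.sum(x**2))

    def test_duplicating_points_shrinks_se_by_sqrt2(self):
        x = np.array([1.0, 2.0, 3.0])
        J1 = x[:, None]
        J2 = np.concatenate([x, x])[:, None]
        cov1 = _covariance_from_jacobian(J1)
        cov2 = _covariance_from_jacobian(J2)
        assert np.sqrt(cov2[0, 0]) == pytest.approx(np.sqrt(cov1[0, 0]) / np.sqrt(2))

    def test_uninfluential_parameter_flagged(self):
        J = np.array([[1.0, 0.0], [2.0, 0.0], [3.0, 0.0]])
        cov = _covariance_from_jacobian(J)
        assert np.isnan(cov[1, 1])
        assert np.isfinite(cov[0, 0])

    def test_report_from_fit(self, small_fit):
        _, _, fit = small_fit
        report = standard_errors(fit)
        assert len(report.names) == len(report.values)
        finite = np.isfinite(report.relative)
        assert finite.any()
        np.testing.assert_allclose(report.se[finite],
                                   (report.relative * np.abs(report.values))[finite])
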