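"""Topology, multiplicities, coupling factors and rate-matrix assembly."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from p2xkin.model import (
    BOUND_LIGANDS,
    STATES,
    CouplingFactors,
    ModelVariant,
    RateConstantSet,
    build_transition_table,
    effective_rates,
    generator_matrix,
    load_model,
    model_from_document,
    model_to_document,
    rescale_pair,
    save_model,
)
from tests.conftest import random_rate_set


def eq6_matrix(k: RateConstantSet, L: float) -> np.ndarray:
    """Independent oracle: the master-equation coefficients transcribed
    term by term from the scheme's differential equations."""
    p = {s: np.zeros(10) for s in STATES}
    for i, s in enumerate(STATES):
        p[s][i] = 1.0
    rows = {
        "C0": k[2] * p["C1"] - L * 3 * k[1] * p["C0"],
        "C1": L * 3 * k[1] * p["C0"] + 2 * k[4] * p["C2"] + k[8] * p["F1"]
              - (k[2] + L * 2 * k[3] + k[7]) * p["C1"],
        "C2": L * 2 * k[3] * p["C1"] + 3 * k[6] * p["C3"] + k[10] * p["F2"]
              - (2 * k[4] + L * k[5] + k[9]) * p["C2"],
        "C3": L * k[5] * p["C2"] + k[12] * p["F3"] - (3 * k[6] + k[11]) * p["C3"],
        "F1": k[7] * p["C1"] + 2 * k[14] * p["F2"] + k[18] * p["O1"]
              - (k[8] + L * 2 * k[13] + k[17]) * p["F1"],
        "F2": k[9] * p["C2"] + L * 2 * k[13] * p["F1"] + 3 * k[16] * p["F3"]
              + k[20] * p["O2"] - (k[10] + 2 * k[14] + L * k[15] + k[19]) * p["F2"],
        "F3": k[11] * p["C3"] + L * k[15] * p["F2"] + k[22] * p["O3"]
              - (k[12] + 3 * k[16] + k[21]) * p["F3"],
        "O1": k[17] * p["F1"] + 2 * k[24] * p["O2"] - (k[18] + L * 2 * k[23]) * p["O1"],
        "O2": k[19] * p["F2"] + L * 2 * k[23] * p["O1"] + 3 * k[26] * p["O3"]
              - (k[20] + 2 * k[24] + L * k[25]) * p["O2"],
        "O3": L * k[25] * p["O2"] + k[21] * p["F3"] - (3 * k[26] + k[22]) * p["O3"],
    }
    return np.vstack([rows[s] for s in STATES])


class TestTransitionTable:
    @pytest.mark.parametrize("src,dst,mult,lig", [
        ("C0", "C1", 3, True),   # three free sites, association
        ("C1", "C0", 1, False),  # one bound ligand leaves
        ("C2", "C1", 2, False),
        ("O3", "O2", 3, False),  # three bound ligands leave the open row
        ("C3", "F3", 1, False),  # isomerization, no multiplicity
        ("F1", "F2", 2, True),
        ("O2", "O3", 1, True),
    ])
    def test_multiplicity_and_ligand_dependence(self, src, dst, mult, lig):
        table = build_transition_table(ModelVariant.F1)
        e = table.entry(src, dst)
        assert e.multiplicity == mult
        assert e.ligand_dependent is lig

    def test_structure(self):
        table = build_transition_table("F1")
        assert len(table.entries) == 26
        # reversible: every edge has its reverse
        directed = {(e.from_state, e.to_state) for e in table.entries}
        assert all((b, a) in directed for a, b in directed)
        # ligand dependence iff the step binds one more ligand
        for e in table.entries:
            gains = BOUND_LIGANDS[e.to_state] == BOUND_LIGANDS[e.from_state] + 1
            assert e.ligand_dependent == gains

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            build_transition_table("F5")


class TestEffectiveRates:
    def base(self):
        return RateConstantSet(np.arange(1.0, 27.0))

    def test_identity_factors_noop(self):
        base = self.base()
        for v in ModelVariant:
            assert effective_rates(base, CouplingFactors(), v) == base

    def test_f2_flip_factors(self):
        base = self.base().replace(k7=10.0)
        eff = effective_rates(base, CouplingFactors(f=11.20, g=0.5), ModelVariant.F2)
        assert eff[7] == pytest.approx(112.0)
        assert eff[9] == base[9] * 11.20
        assert eff[8] == base[8] * 0.5
        assert eff[1] == base[1]  # binding untouched in F2

    def test_f3_binding_and_m(self):
        base = self.base().replace(k1=2.0)
        eff = effective_rates(base, CouplingFactors(h=0.17, j=5.57, m=2.0),
                              ModelVariant.F3)
        assert eff[1] == pytest.approx(0.34)
        assert eff[2] == base[2] * 5.57
        assert eff[7] == base[7] * 2.0  # m accelerates the flips in F3

    def test_f4_excludes_m(self):
        base = self.base()
        eff = effective_rates(base, CouplingFactors(f=2, g=3, h=5, j=7, m=11),
                              ModelVariant.F4)
        assert eff[7] == base[7] * 2  # f only, no m
        assert eff[1] == base[1] * 5
        assert eff[2] == base[2] * 7

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            RateConstantSet(np.zeros(26))
        with pytest.raises(ValueError):
            CouplingFactors(f=-1.0)


class TestGeneratorMatrix:
    def test_matches_equation_oracle(self, rng):
        for _ in range(10):
            rates = random_rate_set(rng)
            L = float(rng.uniform(0, 50))
            Q = generator_matrix(rates, L)
            np.testing.assert_allclose(Q, eq6_matrix(rates, L), rtol=1e-13)

    def test_unit_binding_entry(self):
        rates = RateConstantSet(np.ones(26))
        Q = generator_matrix(rates, 1.0)
        assert Q[STATES.index("C1"), STATES.index("C0")] == pytest.approx(3.0)

    def test_no_binding_at_zero_concentration(self, fixture_rates):
        Q = generator_matrix(fixture_rates, 0.0)
        i = STATES.index("C0")
        assert np.all(Q[:, i] == 0)  # C0 absorbing without ligand

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1), L=st.floats(0, 1000))
    def test_generator_properties(self, seed, L):
        rates = random_rate_set(np.random.default_rng(seed))
        Q = generator_matrix(rates, L)
        off = Q - np.diag(np.diag(Q))
        assert np.all(off >= 0)
        assert np.max(np.abs(Q.sum(axis=0))) <= 1e-12 * max(1.0, np.abs(Q).max())

    def test_negative_concentration_rejected(self, fixture_rates):
        with pytest.raises(ValueError):
            generator_matrix(fixture_rates, -1.0)


def test_factor_application_commutes_with_scaling(rng):
    """Coupling factors are multiplicative: scale-then-apply == apply-then-scale."""
    base = random_rate_set(rng)
    factors = CouplingFactors(f=2.5, g=0.1, h=0.3, j=4.0, m=1.7)
    scaled = RateConstantSet(base.as_array() * 2.0)
    a = effective_rates(scaled, factors, ModelVariant.F4).as_array()
    b = effective_rates(base, factors, ModelVariant.F4).as_array() * 2.0
    np.testing.assert_allclose(a, b, rtol=1e-14)


def test_rescale_pair_preserves_ratio():
    kf, kb = rescale_pair(2.38e11, 9.38e10, 1e8)
    assert kf == pytest.approx(2.38e3)
    assert kb == pytest.approx(9.38e2)
    assert kf / kb == pytest.approx(2.38e11 / 9.38e10, rel=1e-12)


def test_model_document_roundtrip(tmp_path, fixture_rates):
    factors = CouplingFactors(f=11.2, g=5.14e-4, h=0.17, j=5.57, m=15.59)
    for suffix in (".yaml", ".json"):
        path = tmp_path / f"model{suffix}"
        save_model(path, fixture_rates, factors, ModelVariant.F3)
        rates2, factors2, variant2 = load_model(path)
        assert rates2 == fixture_rates
        assert factors2 == factors
        assert variant2 is ModelVariant.F3
    doc = model_to_document(fixture_rates, factors, "F2")
    r3, f3, v3 = model_from_document(doc)
    assert r3 == fixture_rates and v3 is ModelVariant.F2
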