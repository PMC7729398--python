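"""Gibbs free energies and subunit cooperativity from fitted rate constants.

Each reversible step contributes a free-energy difference computed from
the ratio of its bare forward and backward rate constants (statistical
multiplicities excluded, they are notation not energetics):

    binding (association) at reference concentration L:
        dG_A = -RT ln(L * k_fwd / k_bwd)
    flip and closed-open isomerizations:
        dG_E = -RT ln(k_fwd / k_bwd)

How dG_A changes with the degree of liganding quantifies binding
cooperativity (rising dG_A = each bound ligand hinders the next =
negative cooperativity); how dG_E for the flip changes with liganding
quantifies the conformational cooperativity that can overbalance it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from p2xkin.model import (
    CouplingFactors,
    ModelVariant,
    RateConstantSet,
    effective_rates,
)

__all__ = ["R_GAS", "EnergyProfile", "energy_profile", "cooperativity_profile",
           "cycle_energies"]

R_GAS = 8.314  # J / (mol K)

# (label, tier, liganding of the product state, fwd index, bwd index)
BINDING_STEPS = (
    ("C0-C1", "closed", 1, 1, 2),
    ("C1-C2", "closed", 2, 3, 4),
    ("C2-C3", "closed", 3, 5, 6),
    ("F1-F2", "flipped", 2, 13, 14),
    ("F2-F3", "flipped", 3, 15, 16),
    ("O1-O2", "open", 2, 23, 24),
    ("O2-O3", "open", 3, 25, 26),
)
ISOMER_STEPS = (
    ("C1-F1", "flip", 1, 7, 8),
    ("C2-F2", "flip", 2, 9, 10),
    ("C3-F3", "flip", 3, 11, 12),
    ("F1-O1", "open", 1, 17, 18),
    ("F2-O2", "open", 2, 19, 20),
    ("F3-O3", "open", 3, 21, 22),
)


@dataclass
class EnergyProfile:
    """Free energies of all binding and isomerization steps (kJ/mol)."""

    temperature: float  # K
    reference_L: float  # uM
    dG_A: dict[str, float]  # per binding step label
    dG_E: dict[str, float]  # per isomerization label
    tiers: dict[str, str]
    liganding: dict[str, int]

    def binding_series(self, tier: str) -> list[float]:
        """dG_A ordered by liganding degree within one tier."""
        steps = sorted((x, lbl) for lbl, t, x, _, _ in BINDING_STEPS if t == tier)
        return [self.dG_A[lbl] for _, lbl in steps]

    def isomer_series(self, kind: str) -> list[float]:
        steps = sorted((x, lbl) for lbl, t, x, _, _ in ISOMER_STEPS if t == kind)
        return [self.dG_E[lbl] for _, lbl in steps]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for lbl, dg in self.dG_A.items():
            rows.append({"step": lbl, "tier": self.tiers[lbl], "kind": "binding",
                         "liganding": self.liganding[lbl], "dG_kJ_mol": dg})
        for lbl, dg in self.dG_E.items():
            rows.append({"step": lbl, "tier": self.tiers[lbl], "kind": "isomerization",
                         "liganding": self.liganding[lbl], "dG_kJ_mol": dg})
        return pd.DataFrame(rows)


def energy_profile(
    rates: RateConstantSet,
    factors: CouplingFactors | None = None,
    variant: ModelVariant | str = ModelVariant.F1,
    L: float = 1.0,
    T: float = 293.0,
) -> EnergyProfile:
    """Free energies of the 7 binding and 6 isomerization steps.

    L (uM) is the reference ligand concentration entering the binding
    energies only; T defaults to room temperature (293 K).
    """
    if L <= 0:
        raise ValueError("reference concentration must be > 0")
    if T <= 0:
        raise ValueError("temperature must be > 0")
    eff = effective_rates(rates, factors or CouplingFactors(), variant)
    rt = R_GAS * T / 1000.0  # kJ/mol

    dG_A, dG_E, tiers, lig = {}, {}, {}, {}
    for lbl, tier, x, fwd, bwd in BINDING_STEPS:
        dG_A[lbl] = -rt * np.log(L * eff[fwd] / eff[bwd])
        tiers[lbl], lig[lbl] = tier, x
    for lbl, tier, x, fwd, bwd in ISOMER_STEPS:
        dG_E[lbl] = -rt * np.log(eff[fwd] / eff[bwd])
        tiers[lbl], lig[lbl] = tier, x
    return EnergyProfile(temperature=T, reference_L=L, dG_A=dG_A, dG_E=dG_E,
                         tiers=tiers, liganding=lig)


@dataclass
class CooperativityProfile:
    """Successive free-energy differences with qualitative labels.

    ddG > 0 between consecutive liganding degrees means the step becomes
    less favourable as more ligands bind (negative cooperativity);
    ddG < 0 the reverse.  ``dead_band`` (kJ/mol) sets the |ddG| below
    which a step is labelled "none".
    """

    ddG: dict[str, list[float]]  # per tier/kind
    labels: dict[str, list[str]]
    dead_band: float


def _label(d: float, dead_band: float) -> str:
    if abs(d) < dead_band:
        return "none"
    return "negative" if d > 0 else "positive"


def cooperativity_profile(profile: EnergyProfile, dead_band: float = 0.5) -> CooperativityProfile:
    """Per-tier ddG sequences: binding (closed/flipped/open) and isomerizations."""
    ddG: dict[str, list[float]] = {}
    labels: dict[str, list[str]] = {}
    for tier in ("closed", "flipped", "open"):
        series = profile.binding_series(tier)
        diffs = list(np.diff(series))
        ddG[f"binding_{tier}"] = diffs
        labels[f"binding_{tier}"] = [_label(d, dead_band) for d in diffs]
    for kind in ("flip", "open"):
        series = profile.isomer_series(kind)
        diffs = list(np.diff(series))
        ddG[f"isomerization_{kind}"] = diffs
        labels[f"isomerization_{kind}"] = [_label(d, dead_band) for d in diffs]
    return CooperativityProfile(ddG=ddG, labels=labels, dead_band=dead_band)


def cycle_energies(
    rates: RateConstantSet,
    factors: CouplingFactors | None = None,
    variant: ModelVariant | str = ModelVariant.F1,
    T: float = 293.0,
) -> dict[str, float]:
    """Free energy around each elementary 4-cycle of the ladder (kJ/mol).

    Zero for a detailed-balance rate set; reported (not constrained)
    because the fit leaves the rate constants free.
    """
    eff = effective_rates(rates, factors or CouplingFactors(), variant)
    rt = R_GAS * T / 1000.0
    # clockwise products over (fwd indices) / (bwd indices)
    cycles = {
        "C1-C2-F2-F1": ((3, 9, 14, 8), (4, 10, 13, 7)),
        "C2-C3-F3-F2": ((5, 11, 16, 10), (6, 12, 15, 9)),
        "F1-F2-O2-O1": ((13, 19, 24, 18), (14, 20, 23, 17)),
        "F2-F3-O3-O2": ((15, 21, 26, 20), (16, 22, 25, 19)),
    }
    out = {}
    for name, (cw, ccw) in cycles.items():
        ratio = np.prod([eff[i] for i in cw]) / np.prod([eff[i] for i in ccw])
        out[name] = float(-rt * np.log(ratio))
    return out
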