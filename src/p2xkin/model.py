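"""State space, transition topology and rate-matrix construction.

The activation scheme is a three-rung ladder for a trimeric ATP-gated
channel: three sequential binding steps along each conformational tier
(closed C0-C3, flipped F1-F3, open O1-O3), a flip isomerization Cx-Fx at
every liganding degree x >= 1, and a flipped-open isomerization Fx-Ox.
Ligand binding/unbinding runs horizontally, conformational change
vertically.  The reference scheme F1 carries 26 free rate constants
k1..k26; variants F2-F4 (mutant and/or low-affinity ligand) reuse the
same constants modified by dimensionless coupling factors.

Units: concentration in uM, time in s; binding rate constants in
uM^-1 s^-1, all others in s^-1.  Statistical multiplicities (3, 2, 1
free sites for binding; 1, 2, 3 bound ligands for unbinding) are part
of the scheme's notation, not extra parameters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import yaml

__all__ = [
    "STATES",
    "BOUND_LIGANDS",
    "TIERS",
    "N_RATES",
    "StateSpace",
    "RateConstantSet",
    "CouplingFactors",
    "ModelVariant",
    "Transition",
    "TransitionTable",
    "build_transition_table",
    "effective_rates",
    "generator_matrix",
    "rescale_pair",
]

STATES: tuple[str, ...] = ("C0", "C1", "C2", "C3", "F1", "F2", "F3", "O1", "O2", "O3")

BOUND_LIGANDS: dict[str, int] = {
    "C0": 0, "C1": 1, "C2": 2, "C3": 3,
    "F1": 1, "F2": 2, "F3": 3,
    "O1": 1, "O2": 2, "O3": 3,
}

TIERS: dict[str, str] = {
    **{s: "closed" for s in ("C0", "C1", "C2", "C3")},
    **{s: "flipped" for s in ("F1", "F2", "F3")},
    **{s: "open" for s in ("O1", "O2", "O3")},
}

OPEN_STATES: tuple[str, ...] = ("O1", "O2", "O3")

N_RATES = 26
N_SITES = 3  # ATP binding sites in the trimer

# Reversible pairs and their (forward, backward) rate indices.  Forward is
# the direction of increasing liganding (horizontal) or of activation
# (vertical: C->F, F->O).
PAIR_INDEX: tuple[tuple[str, str, int, int], ...] = (
    ("C0", "C1", 1, 2),
    ("C1", "C2", 3, 4),
    ("C2", "C3", 5, 6),
    ("C1", "F1", 7, 8),
    ("C2", "F2", 9, 10),
    ("C3", "F3", 11, 12),
    ("F1", "F2", 13, 14),
    ("F2", "F3", 15, 16),
    ("F1", "O1", 17, 18),
    ("F2", "O2", 19, 20),
    ("F3", "O3", 21, 22),
    ("O1", "O2", 23, 24),
    ("O2", "O3", 25, 26),
)

# Indices of ligand-association rate constants (uM^-1 s^-1).
BINDING_INDICES: frozenset[int] = frozenset({1, 3, 5, 13, 15, 23, 25})
UNBINDING_INDICES: frozenset[int] = frozenset({2, 4, 6, 14, 16, 24, 26})
FLIP_FORWARD: tuple[int, ...] = (7, 9, 11)
FLIP_BACKWARD: tuple[int, ...] = (8, 10, 12)
OPEN_FORWARD: tuple[int, ...] = (17, 19, 21)
OPEN_BACKWARD: tuple[int, ...] = (18, 20, 22)


@dataclass(frozen=True)
class StateSpace:
    """Ordered state labels with liganding degree and conformational tier."""

    states: tuple[str, ...] = STATES
    bound_ligands: Mapping[str, int] = field(default_factory=lambda: dict(BOUND_LIGANDS))
    tier: Mapping[str, str] = field(default_factory=lambda: dict(TIERS))

    def index(self, state: str) -> int:
        return self.states.index(state)


class ModelVariant(str, Enum):
    """The four coupled schemes.

    F1 is the reference (wild type, ATP).  F2 (H319K, ATP) accelerates the
    flips by f and decelerates the back-flips by g.  F3 (wild type, fATP)
    scales all binding constants by h, all unbinding constants by j, and
    accelerates the flips by m.  F4 (H319K, fATP) combines f, g, h, j.
    """

    F1 = "F1"
    F2 = "F2"
    F3 = "F3"
    F4 = "F4"


class RateConstantSet:
    """The 26 free rate constants k1..k26 of the reference scheme.

    Stored 1-indexed to match the conventional naming; ``k[i]`` or
    ``rates.as_array()`` (0-based, length 26) give access.
    """

    __slots__ = ("_k",)

    def __init__(self, values: Iterable[float] | Mapping[int, float]):
        if isinstance(values, Mapping):
            arr = np.array([float(values[i]) for i in range(1, N_RATES + 1)])
        else:
            arr = np.asarray(list(values), dtype=float)
        if arr.shape != (N_RATES,):
            raise ValueError(f"expected {N_RATES} rate constants, got {arr.shape}")
        if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
            raise ValueError("rate constants must be strictly positive and finite")
        self._k = arr

    def __getitem__(self, index: int) -> float:
        if not 1 <= index <= N_RATES:
            raise IndexError(f"rate index {index} out of range 1..{N_RATES}")
        return float(self._k[index - 1])

    def as_array(self) -> np.ndarray:
        return self._k.copy()

    def as_dict(self) -> dict[str, float]:
        return {f"k{i}": float(self._k[i - 1]) for i in range(1, N_RATES + 1)}

    def replace(self, **changes: float) -> "RateConstantSet":
        """New set with ``k<i>=value`` substitutions, e.g. ``replace(k21=2.4e3)``."""
        arr = self._k.copy()
        for name, value in changes.items():
            if not name.startswith("k"):
                raise KeyError(name)
            arr[int(name[1:]) - 1] = value
        return RateConstantSet(arr)

    def __eq__(self, other) -> bool:
        return isinstance(other, RateConstantSet) and np.array_equal(self._k, other._k)

    def __repr__(self) -> str:
        return f"RateConstantSet({self._k.tolist()})"


@dataclass(frozen=True)
class CouplingFactors:
    """Dimensionless multipliers mapping scheme F1 onto F2/F3/F4.

    f accelerates the flips Cx->Fx and g decelerates the back-flips in the
    H319K mutant; h and j scale every binding / unbinding constant for the
    low-affinity fluorescent ligand; m is an extra flip accelerator used
    only in F3.  All ones reproduces F1 exactly.
    """

    f: float = 1.0
    g: float = 1.0
    h: float = 1.0
    j: float = 1.0
    m: float = 1.0

    def __post_init__(self):
        for name in ("f", "g", "h", "j", "m"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"coupling factor {name} must be positive, got {v}")

    def as_dict(self) -> dict[str, float]:
        return {n: float(getattr(self, n)) for n in ("f", "g", "h", "j", "m")}


@dataclass(frozen=True)
class Transition:
    from_state: str
    to_state: str
    rate_index: int
    multiplicity: int
    ligand_dependent: bool


@dataclass(frozen=True)
class TransitionTable:
    """The 26 directed transitions (13 reversible pairs) of the scheme."""

    variant: ModelVariant
    entries: tuple[Transition, ...]

    def entry(self, from_state: str, to_state: str) -> Transition:
        for e in self.entries:
            if e.from_state == from_state and e.to_state == to_state:
                return e
        raise KeyError(f"no transition {from_state}->{to_state}")

    @property
    def pairs(self) -> tuple[tuple[str, str], ...]:
        return tuple((a, b) for a, b, _, _ in PAIR_INDEX)


def _multiplicity(from_state: str, to_state: str) -> tuple[int, bool]:
    """(statistical multiplicity, ligand dependence) of a directed step."""
    nb_from, nb_to = BOUND_LIGANDS[from_state], BOUND_LIGANDS[to_state]
    if nb_to == nb_from + 1:  # association: free sites
        return N_SITES - nb_from, True
    if nb_to == nb_from - 1:  # dissociation: bound ligands
        return nb_from, False
    return 1, False  # flip / open isomerization


def build_transition_table(variant: ModelVariant | str) -> TransitionTable:
    """Assemble the 26-entry directed transition table for a model variant.

    The table is topologically identical across F1-F4 (the coupling
    factors act on rate values, not on the graph); the variant is carried
    so that downstream rate assembly applies the right factors.
    """
    variant = ModelVariant(variant)
    entries = []
    for a, b, fwd, bwd in PAIR_INDEX:
        m_f, lig_f = _multiplicity(a, b)
        m_b, lig_b = _multiplicity(b, a)
        entries.append(Transition(a, b, fwd, m_f, lig_f))
        entries.append(Transition(b, a, bwd, m_b, lig_b))
    return TransitionTable(variant=variant, entries=tuple(entries))


def effective_rates(
    base: RateConstantSet,
    factors: CouplingFactors,
    variant: ModelVariant | str,
) -> RateConstantSet:
    """Apply a variant's coupling factors to the shared rate set.

    F1: identity.  F2: f on k7,k9,k11; g on k8,k10,k12.  F3: h on all
    binding, j on all unbinding, m on k7,k9,k11.  F4: f, g, h, j (no m).
    """
    variant = ModelVariant(variant)
    k = base.as_array()
    if variant is ModelVariant.F1:
        return RateConstantSet(k)
    if variant in (ModelVariant.F2, ModelVariant.F4):
        for i in FLIP_FORWARD:
            k[i - 1] *= factors.f
        for i in FLIP_BACKWARD:
            k[i - 1] *= factors.g
    if variant in (ModelVariant.F3, ModelVariant.F4):
        for i in BINDING_INDICES:
            k[i - 1] *= factors.h
        for i in UNBINDING_INDICES:
            k[i - 1] *= factors.j
    if variant is ModelVariant.F3:
        for i in FLIP_FORWARD:
            k[i - 1] *= factors.m
    return RateConstantSet(k)


def generator_matrix(rates: RateConstantSet, L: float) -> np.ndarray:
    """Infinitesimal generator Q(L) of the master equation dp/dt = Q p.

    Entry (y, x) is the full transition rate x -> y: statistical
    multiplicity times rate constant, times L for association steps.
    Columns sum to zero.
    """
    if not np.isfinite(L) or L < 0:
        raise ValueError(f"ligand concentration must be >= 0, got {L}")
    table = build_transition_table(ModelVariant.F1)
    Q = np.zeros((len(STATES), len(STATES)))
    idx = {s: i for i, s in enumerate(STATES)}
    for e in table.entries:
        r = e.multiplicity * rates[e.rate_index] * (L if e.ligand_dependent else 1.0)
        Q[idx[e.to_state], idx[e.from_state]] += r
    Q[np.diag_indices_from(Q)] = 0.0
    Q[np.diag_indices_from(Q)] = -Q.sum(axis=0)
    return Q


def rescale_pair(k_fwd: float, k_bwd: float, factor: float) -> tuple[float, float]:
    """Divide a forward rate constant by ``factor`` preserving the pair ratio.

    Used to translate an unphysically fast isomerization pair (e.g. a
    fitted F3-O3 step in the 1e11 s^-1 range) into a physically
    interpretable one with the same equilibrium constant.
    """
    if factor <= 0:
        raise ValueError("factor must be positive")
    return k_fwd / factor, k_bwd / factor


# --- serialization -----------------------------------------------------------

def model_to_document(
    rates: RateConstantSet,
    factors: CouplingFactors,
    variant: ModelVariant | str,
) -> dict:
    variant = ModelVariant(variant)
    table = build_transition_table(variant)
    return {
        "states": list(STATES),
        "variant": variant.value,
        "rates": rates.as_dict(),
        "factors": factors.as_dict(),
        "transitions": [
            {
                "from": e.from_state,
                "to": e.to_state,
                "rate_index": e.rate_index,
                "multiplicity": e.multiplicity,
                "ligand_dependent": e.ligand_dependent,
            }
            for e in table.entries
        ],
    }


def model_from_document(doc: Mapping) -> tuple[RateConstantSet, CouplingFactors, ModelVariant]:
    if list(doc["states"]) != list(STATES):
        raise ValueError("document state list does not match the 10-state scheme")
    rates = RateConstantSet({int(k[1:]): v for k, v in doc["rates"].items()})
    factors = CouplingFactors(**doc["factors"])
    return rates, factors, ModelVariant(doc["variant"])


def save_model(path: str | Path, rates, factors, variant) -> None:
    path = Path(path)
    doc = model_to_document(rates, factors, variant)
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(doc, sort_keys=False))
    else:
        path.write_text(json.dumps(doc, indent=1))


def load_model(path: str | Path):
    path = Path(path)
    text = path.read_text()
    doc = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
    return model_from_document(doc)
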