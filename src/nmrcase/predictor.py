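"""Forward chemical-shift prediction interface and the bundled toy oracle.

Any callable object with a ``predict(mol) -> ShiftPrediction`` method and
a ``predictor_id`` string satisfies the forward-model contract: it must
be deterministic, cover every carbon atom and every hydrogen nucleus,
and assign equal shifts to symmetry-equivalent atoms.  Users with a
trained forward model (neural or HOSE/database-based) plug it in here.

The bundled :class:`ToyShiftPredictor` is a deterministic local-topology
oracle built like a two-sphere HOSE model.  A carbon shift is

    base(bonding class) + A1 * u(radius-1 code) + A2 * u(radius-2 code)

where u(.) is a uniform-[0,1) value obtained by hashing the canonical
environment code, the radius-1 code records the atom's own label plus
the elements and bond orders of its immediate neighbors, and A1 >> A2
(the sphere-2 perturbation is ~1 ppm).  Hydrogen shifts are derived the
same way from the heavy atom's label (sphere 0/1), with a ~0.1 ppm
sphere-1 refinement.  This decay mirrors the physical rule that local
structure dominates chemical shifts, and it meshes with the fragment
recombination rules: compatible recombination preserves every carbon's
radius-1 neighborhood, so inherited carbon shifts are at worst ~1 ppm
off near the cut and exact elsewhere.  Because the shift is a pure
function of the local environment, identical environments always get
identical shifts, and distinct radius-2 environments get distinct
values with probability 1.  The absolute values are plausible ppm
ranges, not real chemistry.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

from rdkit import Chem

__all__ = ["ShiftPrediction", "PredictionError", "ToyShiftPredictor", "environment_code"]


class PredictionError(ValueError):
    """Forward model cannot predict this molecule."""


@dataclass(frozen=True)
class ShiftPrediction:
    """Per-atom predicted shifts: carbons by atom index, hydrogens
    grouped under their heavy atom's index (one value per attached H)."""

    c_shifts: dict[int, float]
    h_shifts: dict[int, tuple[float, ...]]

    @property
    def n_carbons(self) -> int:
        return len(self.c_shifts)

    @property
    def n_hydrogens(self) -> int:
        return sum(len(v) for v in self.h_shifts.values())

    def all_h_values(self) -> list[float]:
        return [s for v in self.h_shifts.values() for s in v]


def _bond_char(bond: Chem.Bond) -> str:
    return {
        Chem.BondType.SINGLE: "-",
        Chem.BondType.DOUBLE: "=",
        Chem.BondType.TRIPLE: "#",
        Chem.BondType.AROMATIC: ":",
    }.get(bond.GetBondType(), "?")


def environment_code(mol: Chem.Mol, idx: int, radius: int) -> str:
    """Canonical spherical-environment string of an atom.

    A depth-limited tree walk with lexicographically sorted branches
    (immediate backtracking excluded), in the spirit of HOSE codes.  Two
    atoms related by a graph automorphism always receive equal codes.
    """

    def rec(a_idx: int, prev_idx: int, depth: int) -> str:
        atom = mol.GetAtomWithIdx(a_idx)
        label = f"{atom.GetSymbol()}{atom.GetTotalNumHs()}"
        if atom.GetFormalCharge():
            label += f"{atom.GetFormalCharge():+d}"
        if atom.GetIsAromatic():
            label += "a"
        if depth == 0:
            return label
        branches = sorted(
            _bond_char(bond) + rec(bond.GetOtherAtomIdx(a_idx), a_idx, depth - 1)
            for bond in atom.GetBonds()
            if bond.GetOtherAtomIdx(a_idx) != prev_idx
        )
        return label + "(" + ",".join(branches) + ")"

    return rec(idx, -1, radius)


def _hash_unit(code: str) -> float:
    """Deterministic uniform-[0,1) value from an environment string."""
    digest = hashlib.sha256(code.encode()).digest()
    return int.from_bytes(digest[:8], "big") / 2**64


# base ppm windows (low, spread) per bonding class
_C_CLASSES = {
    "aromatic": (112.0, 38.0),
    "carbonyl": (160.0, 45.0),
    "sp2": (100.0, 55.0),
    "sp": (65.0, 30.0),
    "sp3_O": (50.0, 35.0),
    "sp3_N": (35.0, 30.0),
    "sp3_X": (18.0, 40.0),
    "sp3": (5.0, 45.0),
}
_H_CLASSES = {
    "aromatic": (6.3, 2.2),
    "aldehyde": (9.3, 0.7),
    "sp2": (4.5, 2.5),
    "sp": (1.8, 1.2),
    "sp3_O": (3.2, 1.6),
    "sp3_N": (2.3, 1.2),
    "sp3_X": (2.8, 1.4),
    "sp3": (0.5, 1.7),
    "OH": (1.0, 4.0),
    "NH": (1.0, 4.0),
    "SH": (1.2, 1.0),
}

#: sphere-2 perturbation amplitudes (ppm); small relative to the class
#: windows so that a distant structural change nudges a shift instead of
#: resampling it
FINE_AMPLITUDE_C = 1.0
FINE_AMPLITUDE_H = 0.1

_HALOGENS = {"F", "Cl", "Br", "I"}
_SUPPORTED = {"C", "H", "N", "O", "S"} | _HALOGENS


def _atom_label(atom: Chem.Atom) -> str:
    label = f"{atom.GetSymbol()}{atom.GetTotalNumHs()}"
    if atom.GetFormalCharge():
        label += f"{atom.GetFormalCharge():+d}"
    if atom.GetIsAromatic():
        label += "a"
    return label


def _sphere1_code(mol: Chem.Mol, idx: int) -> str:
    """Radius-1 code over neighbor *elements and bond orders* only.

    Deliberately blind to the neighbors' own substitution so that it is
    invariant under compatible fragment recombination (which preserves
    exactly this neighborhood for carbons).
    """
    atom = mol.GetAtomWithIdx(idx)
    nbrs = sorted(
        _bond_char(b) + b.GetOtherAtom(atom).GetSymbol() for b in atom.GetBonds()
    )
    return _atom_label(atom) + "(" + ",".join(nbrs) + ")"


def _carbon_class(atom: Chem.Atom) -> str:
    if atom.GetIsAromatic():
        return "aromatic"
    nbr_elems = [b.GetOtherAtom(atom).GetSymbol() for b in atom.GetBonds()]
    double_o = any(
        b.GetBondType() == Chem.BondType.DOUBLE
        and b.GetOtherAtom(atom).GetSymbol() in ("O", "S")
        for b in atom.GetBonds()
    )
    if double_o:
        return "carbonyl"
    if any(b.GetBondType() == Chem.BondType.TRIPLE for b in atom.GetBonds()):
        return "sp"
    if any(b.GetBondType() == Chem.BondType.DOUBLE for b in atom.GetBonds()):
        return "sp2"
    if "O" in nbr_elems:
        return "sp3_O"
    if "N" in nbr_elems:
        return "sp3_N"
    if any(e in _HALOGENS for e in nbr_elems):
        return "sp3_X"
    return "sp3"


def _hydrogen_class(heavy: Chem.Atom) -> str:
    sym = heavy.GetSymbol()
    if sym == "O":
        return "OH"
    if sym == "N":
        return "NH"
    if sym == "S":
        return "SH"
    cls = _carbon_class(heavy)
    return "aldehyde" if cls == "carbonyl" else cls


class ToyShiftPredictor:
    """Deterministic environment-keyed shift oracle for offline testing.

    Supports C, H, N, O, S and the halogens.  Shift values are cached
    per environment code — never per molecule, since per-atom index maps
    are only meaningful for one specific atom ordering.
    """

    predictor_id = "toy-hose-v1"

    def __init__(self) -> None:
        self._value_cache: dict[tuple[str, str], float] = {}

    def _value(self, kind: str, code: str, low: float, spread: float) -> float:
        key = (kind, code)
        value = self._value_cache.get(key)
        if value is None:
            value = round(low + spread * _hash_unit(f"{kind}|{code}"), 6)
            self._value_cache[key] = value
        return value

    def predict(self, mol: Chem.Mol) -> ShiftPrediction:
        for atom in mol.GetAtoms():
            if atom.GetSymbol() not in _SUPPORTED:
                raise PredictionError(
                    f"unsupported element {atom.GetSymbol()!r} in "
                    f"{Chem.MolToSmiles(mol)}"
                )

        c_shifts: dict[int, float] = {}
        h_shifts: dict[int, tuple[float, ...]] = {}
        for atom in mol.GetAtoms():
            idx = atom.GetIdx()
            if atom.GetAtomicNum() == 6:
                low, spread = _C_CLASSES[_carbon_class(atom)]
                value = (self._value("Cm", _sphere1_code(mol, idx),
                                     low, spread - FINE_AMPLITUDE_C)
                         + self._value("Cf", environment_code(mol, idx, 2),
                                       0.0, FINE_AMPLITUDE_C))
                c_shifts[idx] = round(value, 6)
            n_h = atom.GetTotalNumHs()
            if n_h:
                low, spread = _H_CLASSES[_hydrogen_class(atom)]
                value = (self._value("Hm", _sphere1_code(mol, idx),
                                     low, spread - FINE_AMPLITUDE_H)
                         + self._value("Hf", environment_code(mol, idx, 1),
                                       0.0, FINE_AMPLITUDE_H))
                # equivalent hydrogens on one heavy atom share a shift
                h_shifts[idx] = (round(value, 6),) * n_h

        return ShiftPrediction(c_shifts=c_shifts, h_shifts=h_shifts)
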