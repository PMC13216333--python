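"""Molecular graph handling: admissibility, symmetry classes, fragmentation
at cleavage bonds, and compatibility-constrained recombination.

Molecules are RDKit ``Mol`` objects throughout; stereochemistry is stripped
on input (the forward model here is 2D).  A *fragment* is a connected
subgraph produced by homolytically unwiring one acyclic heavy-atom bond;
the open valence is represented by a dummy atom (``*``) kept as the last
atom of the fragment, so recombination is a local graph edit.

The cleavage-bond descriptor (retained element, lost element, bond order)
governs which fragments may recombine: a carbon-started cut may only pair
with a cut started by its lost (terminal) element, while non-carbon cuts
pair freely within the same bond order.  Applied symmetrically, these two
rules guarantee that the radius-1 circular neighborhood of every carbon
atom survives recombination unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from rdkit import Chem, RDLogger
from rdkit.Chem import rdMolDescriptors

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "MoleculeError",
    "RecombinationError",
    "CleavageBondDescriptor",
    "Fragment",
    "mol_from_smiles",
    "canonical_smiles",
    "inchikey",
    "molecular_formula",
    "element_set",
    "admissible",
    "symmetry_classes",
    "compatible",
    "fragment_molecule",
    "recombine",
    "recombine_mapped",
    "carbon_radius1_env",
    "read_smiles_file",
    "read_sdf_file",
    "write_smiles_file",
]


class MoleculeError(ValueError):
    """Unparsable or chemically invalid structure."""


class RecombinationError(ValueError):
    """Fragments cannot be joined (incompatible cuts or invalid product)."""


_BOND_FROM_ORDER = {
    1: Chem.BondType.SINGLE,
    2: Chem.BondType.DOUBLE,
    3: Chem.BondType.TRIPLE,
}
_ORDER_FROM_BOND = {v: k for k, v in _BOND_FROM_ORDER.items()}


def mol_from_smiles(smiles: str) -> Chem.Mol:
    """Parse SMILES, sanitize, and strip stereochemistry."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise MoleculeError(f"unparsable SMILES: {smiles!r}")
    Chem.RemoveStereochemistry(mol)
    return mol


def canonical_smiles(mol: Chem.Mol) -> str:
    return Chem.MolToSmiles(mol)


def inchikey(mol: Chem.Mol) -> str:
    return Chem.MolToInchiKey(mol)


def molecular_formula(mol: Chem.Mol) -> str:
    return rdMolDescriptors.CalcMolFormula(mol)


def element_set(mol: Chem.Mol) -> frozenset[str]:
    """Heavy-atom element symbols plus 'H' when any hydrogen is present."""
    elems = {a.GetSymbol() for a in mol.GetAtoms()}
    if any(a.GetTotalNumHs() > 0 for a in mol.GetAtoms()) or "H" in elems:
        elems.add("H")
    return frozenset(elems)


def admissible(mol: Chem.Mol) -> bool:
    """Database admissibility: reject net-charged species, open-shell
    species, isotope-labeled species, and molecules with neither carbon
    nor hydrogen."""
    if Chem.GetFormalCharge(mol) != 0:
        return False
    has_c = False
    has_h = False
    for atom in mol.GetAtoms():
        if atom.GetNumRadicalElectrons() > 0:
            return False
        if atom.GetIsotope() != 0:
            return False
        if atom.GetAtomicNum() == 6:
            has_c = True
        if atom.GetAtomicNum() == 1 or atom.GetTotalNumHs() > 0:
            has_h = True
    return has_c or has_h


def symmetry_classes(mol: Chem.Mol) -> list[list[int]]:
    """Partition atom indices into symmetry-equivalence classes.

    Computed by canonical ranking without tie-breaking (iterated
    neighborhood refinement), which coincides with the automorphism
    orbits at ordinary molecule sizes.
    """
    ranks = list(Chem.CanonicalRankAtoms(mol, breakTies=False))
    groups: dict[int, list[int]] = {}
    for idx, rank in enumerate(ranks):
        groups.setdefault(rank, []).append(idx)
    return [sorted(g) for _, g in sorted(groups.items())]


# ---------------------------------------------------------------------------
# fragmentation / recombination

@dataclass(frozen=True)
class CleavageBondDescriptor:
    """Describes the broken bond from one fragment's point of view."""

    retained_element: str
    lost_element: str
    bond_order: int

    def __str__(self) -> str:  # e.g. "C-O:1"
        return f"{self.retained_element}-{self.lost_element}:{self.bond_order}"


def compatible(d1: CleavageBondDescriptor, d2: CleavageBondDescriptor) -> bool:
    """Symmetric recombination-compatibility predicate.

    Bond orders must match; additionally, a fragment whose retained atom
    is carbon only accepts partners whose retained atom is its lost
    (terminal) element.  Non-carbon-retained fragments accept any partner
    of equal order.  Both fragments' rules must hold.
    """
    if d1.bond_order != d2.bond_order:
        return False

    def one_way(a: CleavageBondDescriptor, b: CleavageBondDescriptor) -> bool:
        if a.retained_element == "C":
            return b.retained_element == a.lost_element
        return True

    return one_way(d1, d2) and one_way(d2, d1)


@dataclass(frozen=True)
class Fragment:
    """Connected subgraph with exactly one attachment point.

    ``mol`` carries a single dummy atom (atomic number 0) as its *last*
    atom, bonded to ``attachment_idx`` with the cleaved bond's order.
    ``parent_atoms[i]`` is the parent-molecule index of fragment atom
    ``i`` (the dummy maps to -1).  Inherited shift annotations are keyed
    by fragment atom index.
    """

    mol: Chem.Mol
    attachment_idx: int
    descriptor: CleavageBondDescriptor
    parent_atoms: tuple[int, ...]
    c_shifts: dict[int, float] = field(default_factory=dict)
    h_shifts: dict[int, tuple[float, ...]] = field(default_factory=dict)
    parent_id: str = ""

    @property
    def smiles(self) -> str:
        return Chem.MolToSmiles(self.mol)

    @property
    def n_heavy(self) -> int:
        return self.mol.GetNumAtoms() - 1  # minus the dummy


def _extract_fragment(
    parent: Chem.Mol,
    work: Chem.Mol,
    keep: tuple[int, ...],
    dummy_old_idx: int,
    attachment_old_idx: int,
    descriptor: CleavageBondDescriptor,
    c_pred: dict[int, float] | None,
    h_pred: dict[int, tuple[float, ...]] | None,
    parent_id: str,
) -> Fragment:
    keep_sorted = sorted(keep)
    # renumber so the dummy lands last
    order = [i for i in keep_sorted if i != dummy_old_idx] + [dummy_old_idx]
    old2local = {old: pos for pos, old in enumerate(keep_sorted)}

    em = Chem.RWMol(work)
    for idx in sorted(set(range(work.GetNumAtoms())) - set(keep_sorted), reverse=True):
        em.RemoveAtom(idx)
    sub = em.GetMol()
    sub = Chem.RenumberAtoms(sub, [old2local[o] for o in order])
    Chem.SanitizeMol(sub)

    new_index = {old: pos for pos, old in enumerate(order)}
    n_atoms = sub.GetNumAtoms()
    parent_atoms = [0] * n_atoms
    for old, new in new_index.items():
        parent_atoms[new] = -1 if old == dummy_old_idx else old

    c_shifts: dict[int, float] = {}
    h_shifts: dict[int, tuple[float, ...]] = {}
    if c_pred is not None:
        for new, old in enumerate(parent_atoms):
            if old in c_pred:
                c_shifts[new] = c_pred[old]
    if h_pred is not None:
        for new, old in enumerate(parent_atoms):
            if old in h_pred and h_pred[old]:
                h_shifts[new] = tuple(h_pred[old])

    return Fragment(
        mol=sub,
        attachment_idx=new_index[attachment_old_idx],
        descriptor=descriptor,
        parent_atoms=tuple(parent_atoms),
        c_shifts=c_shifts,
        h_shifts=h_shifts,
        parent_id=parent_id,
    )


def fragment_molecule(
    mol: Chem.Mol,
    c_shifts: dict[int, float] | None = None,
    h_shifts: dict[int, tuple[float, ...]] | None = None,
    parent_id: str = "",
) -> list[tuple[Fragment, Fragment]]:
    """Cleave every acyclic heavy-atom bond, one pair of fragments per bond.

    Ring bonds are never cleaved (breaking one does not bipartition the
    molecule); bonds to hydrogen never appear because hydrogens are
    implicit.  Shift annotations, when given as per-parent-atom maps, are
    copied verbatim onto each fragment.  A molecule with no cleavable
    bond yields an empty list.
    """
    pairs: list[tuple[Fragment, Fragment]] = []
    for bond in mol.GetBonds():
        if bond.IsInRing():
            continue
        if bond.GetBondType() not in _ORDER_FROM_BOND:
            continue  # acyclic aromatic bonds do not occur in sanitized mols
        order = _ORDER_FROM_BOND[bond.GetBondType()]
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()

        em = Chem.RWMol(mol)
        em.RemoveBond(i, j)
        di = em.AddAtom(Chem.Atom(0))
        em.AddBond(i, di, _BOND_FROM_ORDER[order])
        dj = em.AddAtom(Chem.Atom(0))
        em.AddBond(j, dj, _BOND_FROM_ORDER[order])
        work = em.GetMol()

        frag_sets = Chem.GetMolFrags(work)
        if len(frag_sets) != 2:  # pragma: no cover - guarded by ring check
            continue
        set_i = next(s for s in frag_sets if i in s)
        set_j = next(s for s in frag_sets if j in s)

        elem_i = mol.GetAtomWithIdx(i).GetSymbol()
        elem_j = mol.GetAtomWithIdx(j).GetSymbol()
        frag_i = _extract_fragment(
            mol, work, set_i, di, i,
            CleavageBondDescriptor(elem_i, elem_j, order),
            c_shifts, h_shifts, parent_id,
        )
        frag_j = _extract_fragment(
            mol, work, set_j, dj, j,
            CleavageBondDescriptor(elem_j, elem_i, order),
            c_shifts, h_shifts, parent_id,
        )
        pairs.append((frag_i, frag_j))
    return pairs


def recombine_mapped(
    f1: Fragment, f2: Fragment
) -> tuple[Chem.Mol, list[tuple[int, int]]]:
    """Join two compatible fragments; also return atom provenance.

    Returns ``(mol, prov)`` where ``prov[k] = (slot, frag_idx)`` maps
    product atom ``k`` to slot 0 (``f1``) or 1 (``f2``) and the atom's
    index within that fragment.
    """
    if not compatible(f1.descriptor, f2.descriptor):
        raise RecombinationError(
            f"incompatible cleavage bonds {f1.descriptor} / {f2.descriptor}"
        )
    n1 = f1.mol.GetNumAtoms()
    n2 = f2.mol.GetNumAtoms()
    combo = Chem.CombineMols(f1.mol, f2.mol)
    em = Chem.RWMol(combo)
    # dummies are the last atom of each fragment by construction
    em.RemoveAtom(n1 + n2 - 1)
    em.RemoveAtom(n1 - 1)
    att1 = f1.attachment_idx
    att2 = n1 - 1 + f2.attachment_idx  # shifted down by the removed f1 dummy
    em.AddBond(att1, att2, _BOND_FROM_ORDER[f1.descriptor.bond_order])
    product = em.GetMol()
    try:
        Chem.SanitizeMol(product)
    except Exception as exc:
        raise RecombinationError(f"invalid recombination product: {exc}") from exc
    prov = [(0, k) for k in range(n1 - 1)] + [(1, k) for k in range(n2 - 1)]
    return product, prov


def recombine(f1: Fragment, f2: Fragment) -> Chem.Mol:
    """Join two compatible fragments into a single valence-valid molecule."""
    return recombine_mapped(f1, f2)[0]


def carbon_radius1_env(mol: Chem.Mol, idx: int) -> tuple:
    """Radius-1 circular neighborhood of an atom: its element, total H
    count, and the sorted multiset of (bond order, neighbor element)."""
    atom = mol.GetAtomWithIdx(idx)
    nbrs = sorted(
        (str(bond.GetBondType()), bond.GetOtherAtom(atom).GetSymbol())
        for bond in atom.GetBonds()
    )
    return (atom.GetSymbol(), atom.GetTotalNumHs(), tuple(nbrs))


# ---------------------------------------------------------------------------
# file IO

def read_smiles_file(path: str) -> list[Chem.Mol]:
    """Read one SMILES per line (blank lines and ``#`` comments skipped)."""
    mols = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#")[0].strip()
            if not line:
                continue
            mols.append(mol_from_smiles(line.split()[0]))
    return mols


def read_sdf_file(path: str) -> list[Chem.Mol]:
    supplier = Chem.SDMolSupplier(path)
    mols = []
    for mol in supplier:
        if mol is None:
            raise MoleculeError(f"unparsable SDF record in {path}")
        Chem.RemoveStereochemistry(mol)
        mols.append(mol)
    return mols


def write_smiles_file(path: str, mols: list[Chem.Mol]) -> None:
    with open(path, "w") as fh:
        for mol in mols:
            fh.write(canonical_smiles(mol) + "\n")
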