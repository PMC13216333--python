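"""Deterministic synthetic molecule libraries and solvable elucidation
scenarios.

The library generator combines curated scaffold templates (aromatics,
heteroaromatics, saturated rings, small chains) with substituent
snippets (alkyls, ethers, esters, amides, amines, halides, nitriles)
into admissible, valence-valid, deduplicated molecules, seeded so the
same seed always yields the same library.  Scenario generation then
produces the three study conditions:

* ``in-db``      — the target is a library member (solved by retrieval);
* ``assemblable``— the target is built constructively by recombining
  compatible fragments of two library members and is excluded from the
  database, so it can only be reached by fragment recombination;
* ``reactant-seeded`` — as assemblable, with one parent supplied as a
  known reactant for pool seeding.

Every assemblable scenario is verified solvable at generation time: the
recorded fragment pair recombines to the target, the target is absent
from the database, and both parent molecules rank inside the initial
retrieval pool for the target spectrum — so one recombination from the
starting pool reaches the target.  The retrievability requirement is
the desk-scale analogue of a production-scale database, where any
common building block has many spectrally similar carriers; without it,
a tiny library can pose targets whose only fragment carriers look
nothing like the target and are unreachable by any search.
"""

from __future__ import annotations

import itertools
import json
import random
from dataclasses import dataclass, field

from rdkit import Chem

from . import chem
from .predictor import ToyShiftPredictor
from .spectra import ShiftMultiset, simulate_multiset

__all__ = ["Scenario", "generate_library", "generate_scenario",
           "SCAFFOLDS", "SUBSTITUENTS"]

GENERATOR_VERSION = 1

# scaffold templates: python format strings with one or two substituent
# slots; compositionally distinct ring systems to keep molecular
# formulas discriminative across the library
SCAFFOLDS: tuple[str, ...] = (
    "c1ccc({0})cc1",            # benzene
    "c1ccnc({0})c1",            # pyridine
    "c1cnc({0})nc1",            # pyrimidine
    "c1csc({0})c1",             # thiophene
    "c1coc({0})c1",             # furan
    "c1csc({0})n1",             # thiazole
    "c1cn(C)c({0})c1",          # N-methylpyrrole
    "c1ccc2cc({0})ccc2c1",      # naphthalene
    "c1cc2ccccc2nc1{0}",        # quinoline
    "c1ccc2c(c1)cc({0})o2",     # benzofuran
    "c1cc2c(cc1{0})OCO2",       # benzodioxole
    "Fc1ccc({0})cc1",           # 4-fluorophenyl
    "Clc1ccc({0})cc1",          # 4-chlorophenyl
    "COc1ccc({0})cc1",          # 4-methoxyphenyl
    "C1CCC({0})CC1",            # cyclohexane
    "C1CCC({0})C1",             # cyclopentane
    "C1CCC({0})O1",             # tetrahydrofuran
    "Brc1ccc({0})cc1",          # 4-bromophenyl
    "Ic1ccc({0})cc1",           # 4-iodophenyl
    "c1ccc2[nH]c({0})cc2c1",    # indole
    "c1ccc2sc({0})cc2c1",       # benzothiophene
    "C1CN(C{0})CCO1",           # morpholine (N-CH2 linker)
    "C1CCN(CC{0})C1",           # pyrrolidine (N-CH2CH2 linker)
    "C1CCN(C{0})CC1",           # piperidine (N-CH2 linker)
    "O1CCOC1{0}",               # dioxolane
    "CC(C)({0})C",              # neopentyl-like quaternary core
    "CC(C){0}",                 # isopropyl chain
    "c1ccc({0})cc1{1}",         # disubstituted benzene
    "c1cc({0})cnc1{1}",         # disubstituted pyridine
)

# substituent snippets valid in SMILES branch context, pairwise distinct
# in molecular formula so that formula constraints stay discriminative
SUBSTITUENTS: tuple[str, ...] = (
    "C", "CC", "CCC", "CCCC",
    "O", "OC", "OC(C)C",
    "N", "NC", "N(C)C",
    "F", "Cl", "Br", "I",
    "C=O", "C(C)=O", "C(=O)OC", "C(=O)OCC",
    "C(=O)NC", "C(N)=O", "C(=O)N(C)C",
    "C#N", "C#CC",
    "CO", "CCOC",
    "C(F)(F)F", "CCl",
    "S", "SC", "CSC",
    "C=C", "CC=C",
)


def generate_library(n: int, seed: int) -> list[Chem.Mol]:
    """``n`` distinct admissible molecules, deterministic per seed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = random.Random(seed)
    seen: set[str] = set()
    out: list[Chem.Mol] = []
    attempts = 0
    max_attempts = 400 * n
    while len(out) < n and attempts < max_attempts:
        attempts += 1
        template = rng.choice(SCAFFOLDS)
        n_slots = 2 if "{1}" in template else 1
        subs = [rng.choice(SUBSTITUENTS) for _ in range(n_slots)]
        if n_slots == 2 and rng.random() < 0.5:
            # positional isomers share a formula; keep two-slot products
            # in check so formulas stay discriminative
            continue
        smiles = template.format(*subs)
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            continue
        Chem.RemoveStereochemistry(mol)
        canon = chem.canonical_smiles(mol)
        if canon in seen or not chem.admissible(mol):
            continue
        seen.add(canon)
        out.append(mol)
    if len(out) < n:
        raise RuntimeError(
            f"could only generate {len(out)} distinct molecules; "
            "enlarge the scaffold/substituent sets"
        )
    return out


@dataclass(frozen=True)
class Scenario:
    """One elucidation test case with its construction record."""

    mode: str
    seed: int
    target_smiles: str
    target_h: ShiftMultiset = field(compare=False)
    target_c: ShiftMultiset = field(compare=False)
    database_smiles: tuple[str, ...]
    parents: tuple[str, ...] = ()
    generating_fragments: tuple[str, ...] = ()
    generating_bonds: tuple[str, ...] = ()
    reactant_smiles: str | None = None
    assemblable: bool = True
    generator_version: int = GENERATOR_VERSION

    def to_json(self, indent: int = 1) -> str:
        return json.dumps({
            "mode": self.mode, "seed": self.seed,
            "generator_version": self.generator_version,
            "target_smiles": self.target_smiles,
            "target_h": list(self.target_h.shifts),
            "target_c": list(self.target_c.shifts),
            "parents": list(self.parents),
            "generating_fragments": list(self.generating_fragments),
            "generating_bonds": list(self.generating_bonds),
            "reactant_smiles": self.reactant_smiles,
            "assemblable": self.assemblable,
            "database_smiles": list(self.database_smiles),
        }, indent=indent)


def _assemble_novel(
    library: list[Chem.Mol],
    library_smiles: set[str],
    rng: random.Random,
    predictor,
) -> tuple[Chem.Mol, Chem.Mol, Chem.Mol, chem.Fragment, chem.Fragment] | None:
    """Try once to build a novel molecule from two library members."""
    mol_a, mol_b = rng.sample(library, 2)
    pred_a = predictor.predict(mol_a)
    pred_b = predictor.predict(mol_b)
    frags_a = [f for pair in chem.fragment_molecule(
        mol_a, pred_a.c_shifts, pred_a.h_shifts) for f in pair]
    frags_b = [f for pair in chem.fragment_molecule(
        mol_b, pred_b.c_shifts, pred_b.h_shifts) for f in pair]
    combos = [(fa, fb) for fa, fb in itertools.product(frags_a, frags_b)
              if chem.compatible(fa.descriptor, fb.descriptor)]
    rng.shuffle(combos)
    for fa, fb in combos:
        try:
            product = chem.recombine(fa, fb)
        except chem.RecombinationError:
            continue
        canon = chem.canonical_smiles(product)
        if canon in library_smiles or not chem.admissible(product):
            continue
        # targets must show both nuclei: this is a 1H/13C elucidation tool
        atoms = list(product.GetAtoms())
        if (not any(a.GetAtomicNum() == 6 for a in atoms)
                or not any(a.GetTotalNumHs() for a in atoms)):
            continue
        return product, mol_a, mol_b, fa, fb
    return None


def _parents_retrievable(
    product: Chem.Mol, required: list[Chem.Mol], db, predictor,
) -> bool:
    """Every required parent must make the initial retrieval pool."""
    from .config import SolverConfig
    from .database import retrieve

    config = SolverConfig()
    h_ms, c_ms = simulate_multiset(product, predictor)
    hits = retrieve(db, (h_ms, c_ms), config,
                    k_ann=min(config.k_ann, len(db)),
                    k_final=min(config.pool_size, len(db)))
    pool = {h.record.smiles for h in hits}
    return all(chem.canonical_smiles(m) in pool for m in required)


def generate_scenario(
    library: list[Chem.Mol],
    mode: str,
    seed: int,
    predictor=None,
    db=None,
) -> Scenario:
    """Build one elucidation scenario from a fixture library.

    For the recombination modes a spectral database of the library may
    be passed to avoid rebuilding it per scenario (it is only used for
    the generation-time solvability verification).
    """
    if mode not in ("in-db", "assemblable", "reactant-seeded"):
        raise ValueError(f"unknown scenario mode {mode!r}")
    if len(library) < 2:
        raise ValueError("library too small for scenario generation")
    predictor = predictor or ToyShiftPredictor()
    rng = random.Random(seed)
    library_smiles = {chem.canonical_smiles(m) for m in library}
    db_smiles = tuple(sorted(library_smiles))

    if mode == "in-db":
        target = rng.choice(library)
        h_ms, c_ms = simulate_multiset(target, predictor)
        return Scenario(
            mode=mode, seed=seed,
            target_smiles=chem.canonical_smiles(target),
            target_h=h_ms, target_c=c_ms,
            database_smiles=db_smiles, assemblable=True,
        )

    if db is None:
        from .config import SolverConfig
        from .database import build_db
        db = build_db(library, predictor, SolverConfig())

    # assemblable: both parents must be reachable by retrieval, so the
    # unseeded solver can recover the target in one recombination.
    # reactant-seeded: the seeded parent (mol_a) is handed to the solver
    # directly, so only the other parent needs to be retrievable — this
    # yields targets where seeding genuinely helps.
    built = None
    for _ in range(200):
        candidate = _assemble_novel(library, library_smiles, rng, predictor)
        if candidate is None:
            continue
        required = ([candidate[2]] if mode == "reactant-seeded"
                    else [candidate[1], candidate[2]])
        if _parents_retrievable(candidate[0], required, db, predictor):
            built = candidate
            break
    if built is None:
        raise RuntimeError("could not assemble a novel target from this library")
    product, mol_a, mol_b, fa, fb = built
    h_ms, c_ms = simulate_multiset(product, predictor)
    return Scenario(
        mode=mode, seed=seed,
        target_smiles=chem.canonical_smiles(product),
        target_h=h_ms, target_c=c_ms,
        database_smiles=db_smiles,
        parents=(chem.canonical_smiles(mol_a), chem.canonical_smiles(mol_b)),
        generating_fragments=(fa.smiles, fb.smiles),
        generating_bonds=(str(fa.descriptor), str(fb.descriptor)),
        reactant_smiles=(chem.canonical_smiles(mol_a)
                         if mode == "reactant-seeded" else None),
        assemblable=True,
    )
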