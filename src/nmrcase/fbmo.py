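"""Fragment-based molecular optimization guided by NMR spectral match.

A directed evolutionary loop over a pool of candidate molecules:

1. every pool molecule is cleaved at each acyclic heavy-atom bond into
   fragment pairs that inherit the parent's per-atom predicted shifts;
2. fragment pairs whose *inherited* spectrum (multiset union; encoding
   vectors added elementwise) best matches the target are selected in
   three stages — per-fragment complementary vector search, global
   vector re-rank, set-similarity refinement;
3. selected pairs are recombined under the cleavage-bond compatibility
   rules, freshly re-predicted with the forward model, scored precisely,
   and the best candidates replace lower-ranking pool members.

Shift inheritance is the fast screening surrogate: local environments
away from the cut are untouched by recombination, so inherited shifts
are exact there and the screening ranking closely tracks the precise
one.  The loop terminates at the iteration cap, on a patience stall of
the best score, or when a candidate matches the target perfectly.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

from . import chem
from .config import SolverConfig
from .database import SpectralDB, retrieve
from .predictor import PredictionError, ShiftPrediction
from .similarity import combined_score, set_similarity
from .spectra import ShiftMultiset, encode_full, simulate_multiset

__all__ = [
    "CandidateRecord",
    "PooledFragment",
    "SolveResult",
    "score_candidate",
    "build_fragment_pool",
    "fragment_multisets",
    "inherited_spectrum",
    "select_pairs",
    "iterate",
    "solve",
]

logger = logging.getLogger(__name__)

_PERFECT = 1.0 - 1e-12


@dataclass(frozen=True)
class CandidateRecord:
    """A scored candidate with full provenance."""

    smiles: str
    inchikey: str
    mol: Chem.Mol = field(repr=False, compare=False)
    prediction: ShiftPrediction = field(repr=False, compare=False)
    h_multiset: ShiftMultiset = field(repr=False, compare=False)
    c_multiset: ShiftMultiset = field(repr=False, compare=False)
    score: float = 0.0
    parts: dict = field(default_factory=dict, compare=False)
    provenance: dict = field(default_factory=dict, compare=False)
    iteration: int = 0

    def to_dict(self) -> dict:
        return {
            "smiles": self.smiles, "inchikey": self.inchikey,
            "formula": chem.molecular_formula(self.mol),
            "score": self.score, "parts": self.parts,
            "provenance": self.provenance, "iteration": self.iteration,
        }


def score_candidate(
    mol: Chem.Mol,
    predictor,
    target: tuple[ShiftMultiset | None, ShiftMultiset | None],
    config: SolverConfig,
    provenance: dict | None = None,
    iteration: int = 0,
) -> CandidateRecord:
    """Freshly predict and score one molecule against the target."""
    pred = predictor.predict(mol)
    h_ms, c_ms = simulate_multiset(mol, predictor)
    score, parts = combined_score(target, (h_ms, c_ms), config.spectrum)
    return CandidateRecord(
        smiles=chem.canonical_smiles(mol), inchikey=chem.inchikey(mol),
        mol=mol, prediction=pred, h_multiset=h_ms, c_multiset=c_ms,
        score=score, parts=parts,
        provenance=provenance or {"type": "user"}, iteration=iteration,
    )


# ---------------------------------------------------------------------------
# fragment pool

@dataclass(frozen=True)
class PooledFragment:
    """A deduplicated fragment with inherited multisets and encoding."""

    fragment: chem.Fragment
    smiles: str
    h_shifts: tuple[float, ...]
    c_shifts: tuple[float, ...]  # coalesced (one entry per distinct value)
    encoding: np.ndarray = field(repr=False, compare=False)
    source_smiles: str = ""

    @property
    def descriptor(self) -> chem.CleavageBondDescriptor:
        return self.fragment.descriptor


def fragment_multisets(frag: chem.Fragment) -> tuple[ShiftMultiset, ShiftMultiset]:
    """Inherited shift multisets of a fragment.

    1H keeps one entry per hydrogen; 13C keeps one entry per distinct
    inherited value (the same coalescence convention used for whole
    molecules, where symmetry-equivalent carbons share one signal).
    """
    h_vals = tuple(s for vals in frag.h_shifts.values() for s in vals)
    c_vals = tuple(sorted(set(frag.c_shifts.values())))
    return ShiftMultiset("1H", h_vals), ShiftMultiset("13C", c_vals)


def build_fragment_pool(
    records: list[CandidateRecord], config: SolverConfig
) -> list[PooledFragment]:
    """All single-cleavage fragments of all pool molecules.

    Fragments containing elements outside ``config.allowed_elements``
    are filtered out; duplicates (same structure and same inherited
    shifts) are kept once.  Pool order is deterministic.
    """
    allowed = (set(config.allowed_elements) | {"H"}
               if config.allowed_elements is not None else None)
    cfg = config.spectrum
    seen: dict[tuple, PooledFragment] = {}
    for rec in records:
        pairs = chem.fragment_molecule(
            rec.mol, rec.prediction.c_shifts, rec.prediction.h_shifts,
            parent_id=rec.smiles,
        )
        for f1, f2 in pairs:
            for frag in (f1, f2):
                if allowed is not None:
                    elems = {a.GetSymbol() for a in frag.mol.GetAtoms()
                             if a.GetAtomicNum() > 0}
                    if not elems <= allowed:
                        continue
                smi = frag.smiles
                h_ms, c_ms = fragment_multisets(frag)
                key = (smi, str(frag.descriptor), h_ms.shifts, c_ms.shifts)
                if key in seen:
                    continue
                vec = encode_full(h_ms, c_ms, cfg)
                seen[key] = PooledFragment(
                    fragment=frag, smiles=smi,
                    h_shifts=h_ms.shifts, c_shifts=c_ms.shifts,
                    encoding=vec, source_smiles=rec.smiles,
                )
    return [seen[k] for k in sorted(seen)]


def inherited_spectrum(
    f1: chem.Fragment, f2: chem.Fragment, config: SolverConfig
) -> tuple[ShiftMultiset, ShiftMultiset, np.ndarray]:
    """Estimated spectrum of the recombination of two fragments.

    Multisets are unioned per nucleus (13C with value coalescence, since
    equal inherited values correspond to equivalent environments) and
    the encoding vectors are combined additively — no forward prediction
    is performed.
    """
    if not chem.compatible(f1.descriptor, f2.descriptor):
        raise chem.RecombinationError(
            f"incompatible cleavage bonds {f1.descriptor} / {f2.descriptor}"
        )
    h1, c1 = fragment_multisets(f1)
    h2, c2 = fragment_multisets(f2)
    h_ms = h1.union(h2)
    c_ms = c1.union(c2, coalesce=True)
    cfg = config.spectrum
    vec = encode_full(h1, c1, cfg) + encode_full(h2, c2, cfg)
    return h_ms, c_ms, vec


# ---------------------------------------------------------------------------
# three-stage pair selection

def pair_key(f1: PooledFragment, f2: PooledFragment) -> tuple:
    """Structural identity of an unordered fragment pair."""
    a = (f1.smiles, str(f1.descriptor))
    b = (f2.smiles, str(f2.descriptor))
    return (min(a, b), max(a, b))


def select_pairs(
    fragments: list[PooledFragment],
    v_target: np.ndarray,
    target: tuple[ShiftMultiset | None, ShiftMultiset | None],
    config: SolverConfig,
    exclude: set | None = None,
) -> list[tuple[int, int, float]]:
    """Select fragment pairs whose inherited spectrum matches the target.

    Stage 1: for each fragment F, the ``k_frag`` compatible partners F'
    minimizing ||v_target - v_F - v_F'|| (exact scan).  Stage 2: the
    union of proposed pairs re-ranked globally by the same vector
    objective, top ``m_pairs`` kept.  Stage 3: those re-ranked by set
    similarity between inherited union multisets and the target, top
    ``k_refine`` returned (descending score, ties broken by the pair's
    canonical-structure key).  Returns ``(i, j, score)`` index triples;
    an empty list when no compatible pair exists.

    ``exclude`` holds structural pair keys already recombined in earlier
    iterations; skipping them lets successive iterations explore
    strictly new recombinations instead of re-deriving known offspring.
    """
    n = len(fragments)
    if n == 0:
        return []
    vecs = np.stack([f.encoding for f in fragments])

    # group fragment indices by descriptor, precompute pairwise
    # descriptor compatibility
    desc_of: dict[chem.CleavageBondDescriptor, list[int]] = {}
    for i, frag in enumerate(fragments):
        desc_of.setdefault(frag.descriptor, []).append(i)
    descriptors = sorted(desc_of, key=str)
    partner_idx: dict[chem.CleavageBondDescriptor, np.ndarray] = {}
    for d in descriptors:
        idx = [j for d2 in descriptors if chem.compatible(d, d2)
               for j in desc_of[d2]]
        partner_idx[d] = np.array(sorted(idx), dtype=int)

    # stage 1: per-fragment complementary search.  The pool holds many
    # instances of the same fragment structure (one per inherited-shift
    # provenance); partners are counted by distinct structure — closest
    # instance each — so the k_frag proposals cover k_frag different
    # building blocks rather than copies of one.
    struct_key = [(f.smiles, str(f.descriptor)) for f in fragments]
    proposed: set[tuple[int, int]] = set()
    for i, frag in enumerate(fragments):
        partners = partner_idx[frag.descriptor]
        if partners.size == 0:
            continue
        resid = v_target - vecs[i]
        d2 = np.sum((vecs[partners] - resid) ** 2, axis=1)
        taken: set = set()
        for j in partners[np.argsort(d2, kind="stable")]:
            j = int(j)
            if struct_key[j] not in taken and len(taken) >= config.k_frag:
                continue
            taken.add(struct_key[j])
            # (i, i) pairs two copies of one deduplicated fragment —
            # legitimate, e.g. symmetric dimers
            proposed.add((min(i, j), max(i, j)))
    if not proposed:
        logger.info("no compatible fragment pair exists")
        return []

    # stage 2: global vector re-rank.  Structurally identical pairs
    # (same two fragment structures, different inherited-shift
    # provenance) produce the same offspring, so each structural pair is
    # represented once — by its best-objective instance — before the
    # m_pairs cap; this keeps the cap counting distinct offspring.
    pairs = sorted(proposed)
    if exclude:
        pairs = [(i, j) for i, j in pairs
                 if pair_key(fragments[i], fragments[j]) not in exclude]
    if not pairs:
        return []
    pa = np.array(pairs, dtype=int)
    obj = np.linalg.norm(v_target - vecs[pa[:, 0]] - vecs[pa[:, 1]], axis=1)
    order = np.argsort(obj, kind="stable")
    kept: list[tuple[int, int]] = []
    seen_struct: set = set()
    for o in order:
        i, j = pairs[int(o)]
        key = pair_key(fragments[i], fragments[j])
        if key in seen_struct:
            continue
        seen_struct.add(key)
        kept.append((i, j))
        if len(kept) >= config.m_pairs:
            break

    # stage 3: set-similarity refinement on inherited unions
    cfg = config.spectrum
    t_h, t_c = target
    scored: list[tuple[int, int, float]] = []
    for i, j in kept:
        fi, fj = fragments[i], fragments[j]
        h_ms = ShiftMultiset("1H", fi.h_shifts + fj.h_shifts)
        c_ms = ShiftMultiset("13C", tuple(set(fi.c_shifts) | set(fj.c_shifts)))
        has_common = ((t_h is not None and len(t_h) and h_ms.shifts)
                      or (t_c is not None and len(t_c) and c_ms.shifts))
        if not has_common:
            continue  # e.g. a halogen-halogen pair: nothing to score
        score, _ = combined_score((t_h, t_c), (h_ms, c_ms), cfg)
        scored.append((i, j, score))
    scored.sort(key=lambda t: (-t[2],
                               (fragments[t[0]].smiles, fragments[t[1]].smiles)))
    return scored[: config.k_refine]


# ---------------------------------------------------------------------------
# iteration and the outer loop

@dataclass
class IterationLog:
    iteration: int
    n_fragments: int
    n_pairs_selected: int
    n_recombined: int
    n_rejected: int
    n_duplicates: int
    n_filtered: int
    best_score: float
    median_score: float
    pool: list[str]

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def _formula_ok(mol: Chem.Mol, config: SolverConfig) -> bool:
    if config.formula is not None and chem.molecular_formula(mol) != config.formula:
        return False
    if config.allowed_elements is not None:
        allowed = set(config.allowed_elements) | {"H"}
        if not {a.GetSymbol() for a in mol.GetAtoms()} <= allowed:
            return False
    return True


def _rank(records: list[CandidateRecord]) -> list[CandidateRecord]:
    return sorted(records, key=lambda r: (-r.score, r.inchikey))


def iterate(
    pool: list[CandidateRecord],
    target: tuple[ShiftMultiset | None, ShiftMultiset | None],
    v_target: np.ndarray,
    config: SolverConfig,
    predictor,
    iteration: int,
    tried_pairs: set | None = None,
    seen_products: set | None = None,
) -> tuple[list[CandidateRecord], IterationLog]:
    """One optimization step: fragment, select, recombine, re-score, update.

    ``tried_pairs`` / ``seen_products`` are cross-iteration memories
    (mutated in place) so the search explores new recombinations rather
    than regenerating earlier offspring.
    """
    fragments = build_fragment_pool(pool, config)
    selected = select_pairs(fragments, v_target, target, config,
                            exclude=tried_pairs)

    known = {rec.inchikey for rec in pool}
    if seen_products is not None:
        known |= seen_products
    survivors: list[CandidateRecord] = []
    n_recombined = n_rejected = n_duplicates = n_filtered = 0
    for i, j, _screen_score in selected:
        fi, fj = fragments[i], fragments[j]
        if tried_pairs is not None:
            tried_pairs.add(pair_key(fi, fj))
        try:
            mol = chem.recombine(fi.fragment, fj.fragment)
        except chem.RecombinationError:
            n_rejected += 1
            continue
        n_recombined += 1
        key = chem.inchikey(mol)
        if key in known:
            n_duplicates += 1
            continue
        known.add(key)
        if seen_products is not None:
            seen_products.add(key)
        if not _formula_ok(mol, config):
            n_filtered += 1
            continue
        provenance = {
            "type": "recombined",
            "parents": [fi.source_smiles, fj.source_smiles],
            "fragments": [fi.smiles, fj.smiles],
            "cleavage_bonds": [str(fi.descriptor), str(fj.descriptor)],
        }
        try:
            rec = score_candidate(mol, predictor, target, config,
                                  provenance, iteration)
        except PredictionError as exc:
            logger.info("dropping candidate after prediction failure: %s", exc)
            n_rejected += 1
            continue
        survivors.append(rec)

    new_pool = _rank(pool + survivors)[: config.pool_size]
    scores = [r.score for r in new_pool]
    log = IterationLog(
        iteration=iteration, n_fragments=len(fragments),
        n_pairs_selected=len(selected), n_recombined=n_recombined,
        n_rejected=n_rejected, n_duplicates=n_duplicates,
        n_filtered=n_filtered,
        best_score=scores[0] if scores else 0.0,
        median_score=float(np.median(scores)) if scores else 0.0,
        pool=[r.smiles for r in new_pool],
    )
    return new_pool, log


@dataclass
class SolveResult:
    """Final ranking plus the per-iteration trajectory and provenance."""

    ranked: list[CandidateRecord]
    trajectory: list[IterationLog]
    config: SolverConfig
    n_iterations: int
    converged: bool

    @property
    def best(self) -> CandidateRecord:
        return self.ranked[0]

    def rank_of(self, smiles: str) -> int | None:
        """1-based rank of a canonical SMILES in the final pool."""
        for pos, rec in enumerate(self.ranked, start=1):
            if rec.smiles == smiles:
                return pos
        return None

    def iteration_solved(self, smiles: str) -> int | None:
        """First iteration at which ``smiles`` led the pool (0 = by
        retrieval alone); None if it never reached rank 1."""
        for log in self.trajectory:
            if log.pool and log.pool[0] == smiles:
                return log.iteration
        return None

    def report(self) -> dict:
        return {
            "n_iterations": self.n_iterations,
            "converged": self.converged,
            "candidates": [r.to_dict() for r in self.ranked],
            "trajectory": [t.to_dict() for t in self.trajectory],
        }

    def to_json(self, indent: int = 1) -> str:
        return json.dumps(self.report(), indent=indent)


def solve(
    target: tuple[ShiftMultiset | None, ShiftMultiset | None],
    db: SpectralDB,
    config: SolverConfig,
    predictor,
    reactants: list[Chem.Mol] | None = None,
    candidates: list[Chem.Mol] | None = None,
) -> SolveResult:
    """Elucidate a structure from target 1H/13C shift multisets.

    The initial pool is the database retrieval augmented with seeded
    reactants and user-supplied candidates; the pool then evolves by
    fragment recombination until the iteration cap, a patience stall, or
    a perfect spectral match.
    """
    t_h, t_c = target
    if (t_h is None or len(t_h) == 0) and (t_c is None or len(t_c) == 0):
        raise ValueError("empty target: no peaks in either nucleus")

    hits = retrieve(db, target, config,
                    k_ann=min(config.k_ann, len(db)),
                    k_final=min(config.pool_size, min(config.k_ann, len(db))))
    # seeded reactants and user candidates are integrated into the pool
    # unconditionally; retrieved hits fill the remaining slots
    seeded_map: dict[str, CandidateRecord] = {}
    for mol, kind in ([(m, "seeded-reactant") for m in reactants or []]
                      + [(m, "user") for m in candidates or []]):
        rec = score_candidate(mol, predictor, target, config,
                              {"type": kind}, iteration=0)
        seeded_map.setdefault(rec.inchikey, rec)
    retrieved_map: dict[str, CandidateRecord] = {}
    for hit in hits:
        if hit.record.inchikey in seeded_map:
            continue
        mol = chem.mol_from_smiles(hit.record.smiles)
        rec = score_candidate(mol, predictor, target, config,
                              {"type": "retrieved"}, iteration=0)
        retrieved_map.setdefault(rec.inchikey, rec)
    seeded = _rank(list(seeded_map.values()))[: config.pool_size]
    n_slots = config.pool_size - len(seeded)
    pool = _rank(seeded + _rank(list(retrieved_map.values()))[:n_slots])
    if not pool:
        raise ValueError("empty initial pool")
    v_target = encode_full(t_h, t_c, config.spectrum)

    trajectory = [IterationLog(
        iteration=0, n_fragments=0, n_pairs_selected=0, n_recombined=0,
        n_rejected=0, n_duplicates=0, n_filtered=0,
        best_score=pool[0].score,
        median_score=float(np.median([r.score for r in pool])),
        pool=[r.smiles for r in pool],
    )]

    best = pool[0].score
    stall = 0
    converged = best >= _PERFECT
    n_iter = 0
    tried_pairs: set = set()
    seen_products: set = set()
    while not converged and n_iter < config.max_iterations:
        n_iter += 1
        pool, log = iterate(pool, target, v_target, config, predictor, n_iter,
                            tried_pairs=tried_pairs,
                            seen_products=seen_products)
        trajectory.append(log)
        if log.best_score > best + 1e-12:
            best = log.best_score
            stall = 0
        else:
            stall += 1
        if best >= _PERFECT or stall >= config.patience:
            converged = best >= _PERFECT
            break

    return SolveResult(ranked=pool, trajectory=trajectory, config=config,
                       n_iterations=n_iter, converged=converged)
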