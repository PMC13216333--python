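"""Fragment pool, inherited spectra, staged pair selection, and the
optimization loop."""

import numpy as np
import pytest

from nmrcase import chem
from nmrcase.config import SolverConfig
from nmrcase.database import build_db
from nmrcase.fbmo import (
    build_fragment_pool, fragment_multisets, inherited_spectrum, iterate,
    pair_key, score_candidate, select_pairs, solve,
)
from nmrcase.fixtures import generate_scenario
from nmrcase.similarity import set_similarity
from nmrcase.spectra import ShiftMultiset, encode_full, simulate_multiset


def records_for(smiles_list, predictor, config, target):
    out = []
    for smiles in smiles_list:
        mol = chem.mol_from_smiles(smiles)
        out.append(score_candidate(mol, predictor, target, config))
    return out


@pytest.fixture(scope="module")
def small_target(predictor):
    mol = chem.mol_from_smiles("CCOC(=O)c1ccccc1")
    return simulate_multiset(mol, predictor)


class TestFragmentPool:
    def test_pool_of_one_molecule_yields_two_fragments_per_bond(
            self, predictor, config, small_target):
        (rec,) = records_for(["CCOC(=O)c1ccccc1"], predictor, config,
                             small_target)
        n_bonds = sum(1 for b in rec.mol.GetBonds() if not b.IsInRing())
        pool = build_fragment_pool([rec], config)
        assert len(pool) == 2 * n_bonds  # all fragments distinct here

    def test_element_filter_drops_foreign_fragments(self, predictor,
                                                    small_target):
        config = SolverConfig(allowed_elements=("C", "H", "O"))
        recs = records_for(["CCOC(=O)c1ccccc1", "CN(C)c1ccccc1"],
                           predictor, config, small_target)
        pool = build_fragment_pool(recs, config)
        for frag in pool:
            elems = {a.GetSymbol() for a in frag.fragment.mol.GetAtoms()
                     if a.GetAtomicNum() > 0}
            assert "N" not in elems

    def test_fragment_encoding_matches_inherited_multisets(
            self, predictor, config, small_target, library100):
        recs = records_for([chem.canonical_smiles(m) for m in library100[:10]],
                           predictor, config, small_target)
        pool = build_fragment_pool(recs, config)
        for frag in pool:
            h = ShiftMultiset("1H", frag.h_shifts)
            c = ShiftMultiset("13C", frag.c_shifts)
            np.testing.assert_allclose(
                frag.encoding, encode_full(h, c, config.spectrum), atol=1e-12)

    def test_empty_pool_gives_empty_fragment_pool(self, config):
        assert build_fragment_pool([], config) == []


class TestInheritedSpectrum:
    def test_self_recombination_reproduces_parent_spectrum(
            self, predictor, config, library100):
        """The union of a partition's inherited multisets equals the
        parent's own simulated spectrum."""
        for mol in library100[:15]:
            pred = predictor.predict(mol)
            h_own, c_own = simulate_multiset(mol, predictor)
            for f1, f2 in chem.fragment_molecule(mol, pred.c_shifts,
                                                 pred.h_shifts):
                h_ms, c_ms, _ = inherited_spectrum(f1, f2, config)
                assert h_ms.shifts == h_own.shifts
                assert c_ms.shifts == c_own.shifts

    def test_proton_cardinality_is_additive(self, predictor, config,
                                            library100):
        mol = library100[0]
        pred = predictor.predict(mol)
        f1, f2 = chem.fragment_molecule(mol, pred.c_shifts, pred.h_shifts)[0]
        h1, _ = fragment_multisets(f1)
        h2, _ = fragment_multisets(f2)
        h_ms, _, _ = inherited_spectrum(f1, f2, config)
        assert len(h_ms) == len(h1) + len(h2)

    def test_encoding_is_additive(self, predictor, config, library100):
        """v_M = v_F1 + v_F2 equals a fresh encoding of the union when no
        cross-fragment signal coalescence occurs."""
        mol = chem.mol_from_smiles("CCOC(=O)c1ccccc1")
        pred = predictor.predict(mol)
        f1, f2 = chem.fragment_molecule(mol, pred.c_shifts, pred.h_shifts)[0]
        h1, c1 = fragment_multisets(f1)
        h2, c2 = fragment_multisets(f2)
        assert not set(c1.shifts) & set(c2.shifts)  # no coalescence here
        h_ms, c_ms, vec = inherited_spectrum(f1, f2, config)
        np.testing.assert_allclose(
            vec, encode_full(h_ms, c_ms, config.spectrum), atol=1e-9)

    def test_incompatible_fragments_rejected(self, predictor, config):
        mol = chem.mol_from_smiles("CCOC(=O)c1ccccc1")
        pred = predictor.predict(mol)
        frags = [f for p in chem.fragment_molecule(mol, pred.c_shifts,
                                                   pred.h_shifts) for f in p]
        f_c = next(f for f in frags if f.descriptor.retained_element == "C"
                   and f.descriptor.lost_element == "O")
        with pytest.raises(chem.RecombinationError):
            inherited_spectrum(f_c, f_c, config)

    def test_screening_fidelity_of_inherited_spectra(self, predictor, config,
                                                     library100):
        """Inherited spectra are a faithful screening surrogate: exactly
        1.0 similarity whenever every atom's local environment survives
        the cut, and >= 0.95 on average over random recombinations (the
        weak cases are tiny products whose every atom sits at the cut)."""
        import random
        rng = random.Random(23)
        frags = []
        for mol in library100[:60]:
            pred = predictor.predict(mol)
            for pair in chem.fragment_molecule(mol, pred.c_shifts,
                                               pred.h_shifts):
                frags.extend(pair)
        fidelities = []
        n_clean = 0
        while len(fidelities) < 80:
            f1, f2 = rng.sample(frags, 2)
            if not chem.compatible(f1.descriptor, f2.descriptor):
                continue
            try:
                product, prov = chem.recombine_mapped(f1, f2)
            except chem.RecombinationError:
                continue
            atoms = list(product.GetAtoms())
            if (not any(a.GetAtomicNum() == 6 for a in atoms)
                    or not any(a.GetTotalNumHs() for a in atoms)):
                continue  # fidelity is about 1H/13C-observable products
            h_inh, c_inh, _ = inherited_spectrum(f1, f2, config)
            h_new, c_new = simulate_multiset(product, predictor)
            s_h = set_similarity(h_inh, h_new,
                                 config.spectrum.sigma_match_h).score
            s_c = set_similarity(c_inh, c_new,
                                 config.spectrum.sigma_match_c).score
            fidelity = 0.5 * (s_h + s_c)
            fidelities.append(fidelity)

            fresh = predictor.predict(product)
            preserved = all(
                fresh.c_shifts[idx] == (f1, f2)[slot].c_shifts[k]
                for idx, (slot, k) in enumerate(prov)
                if k in (f1, f2)[slot].c_shifts
            ) and all(
                fresh.h_shifts[idx] == (f1, f2)[slot].h_shifts[k]
                for idx, (slot, k) in enumerate(prov)
                if k in (f1, f2)[slot].h_shifts
            )
            if preserved:
                n_clean += 1
                assert fidelity == pytest.approx(1.0, abs=1e-12)
        assert sum(fidelities) / len(fidelities) >= 0.95


class TestSelectPairs:
    def test_constructed_pair_is_found_with_high_score(self, predictor,
                                                       config, small_target):
        """A target assembled from two pool fragments surfaces in the
        stage-3 output with near-perfect screening score."""
        recs = records_for(
            ["CCOC(=O)c1ccccc1", "CCOC(C)=O", "COc1ccccc1"],
            predictor, config, small_target)
        pool = build_fragment_pool(recs, config)
        v_target = encode_full(*small_target, config.spectrum)
        selected = select_pairs(pool, v_target, small_target, config)
        assert selected
        top_i, top_j, top_score = selected[0]
        product = chem.recombine(pool[top_i].fragment, pool[top_j].fragment)
        assert chem.canonical_smiles(product) == "CCOC(=O)c1ccccc1"
        assert top_score > 0.99

    def test_exhaustive_config_matches_oracle(self, predictor, library100,
                                              small_target):
        """With k_frag = M = K = everything, the output equals a direct
        exhaustive enumeration: every compatible structural pair, scored
        through its best vector-objective instance, ranked by inherited
        set similarity."""
        import itertools
        import numpy as np
        from nmrcase.similarity import combined_score

        config = SolverConfig(k_frag=10_000, m_pairs=100_000, k_refine=100_000)
        recs = records_for([chem.canonical_smiles(m) for m in library100[:8]],
                           predictor, config, small_target)
        pool = build_fragment_pool(recs, config)
        v_target = encode_full(*small_target, config.spectrum)
        selected = select_pairs(pool, v_target, small_target, config)

        best_instance = {}
        for i, j in itertools.combinations_with_replacement(
                range(len(pool)), 2):
            fi, fj = pool[i], pool[j]
            if not chem.compatible(fi.descriptor, fj.descriptor):
                continue
            obj = np.linalg.norm(v_target - fi.encoding - fj.encoding)
            key = pair_key(fi, fj)
            if key not in best_instance or obj < best_instance[key][0] - 1e-12:
                best_instance[key] = (obj, i, j)
        expected = []
        for _, i, j in best_instance.values():
            fi, fj = pool[i], pool[j]
            h = ShiftMultiset("1H", fi.h_shifts + fj.h_shifts)
            c = ShiftMultiset("13C", tuple(set(fi.c_shifts) | set(fj.c_shifts)))
            if not h.shifts and not c.shifts:
                continue
            score, _ = combined_score(small_target, (h, c), config.spectrum)
            expected.append((i, j, score))
        expected.sort(key=lambda t: (-t[2], (pool[t[0]].smiles,
                                             pool[t[1]].smiles)))
        got_scores = [round(s, 10) for _, _, s in selected]
        want_scores = [round(s, 10) for _, _, s in expected]
        assert got_scores == want_scores

    def test_no_compatible_pair_yields_empty_list(self, predictor, config,
                                                  small_target):
        # lone C-O fragment: its partner rule demands an O-started cut
        recs = records_for(["COC(F)(F)F"], predictor, config, small_target)
        pool = build_fragment_pool(recs, config)
        keep = [f for f in pool if str(f.descriptor) == "C-O:1"]
        v_target = encode_full(*small_target, config.spectrum)
        assert select_pairs(keep, v_target, small_target, config) == []

    def test_excluded_pairs_are_skipped(self, predictor, config, small_target):
        recs = records_for(["CCOC(=O)c1ccccc1", "CCOC(C)=O"],
                           predictor, config, small_target)
        pool = build_fragment_pool(recs, config)
        v_target = encode_full(*small_target, config.spectrum)
        first = select_pairs(pool, v_target, small_target, config)
        tried = {pair_key(pool[i], pool[j]) for i, j, _ in first}
        second = select_pairs(pool, v_target, small_target, config,
                              exclude=tried)
        assert not ({pair_key(pool[i], pool[j]) for i, j, _ in second} & tried)


class TestLoop:
    def test_true_molecule_stays_rank_one(self, predictor, config,
                                          small_target, library100):
        smiles = ["CCOC(=O)c1ccccc1"] + \
            [chem.canonical_smiles(m) for m in library100[:6]]
        pool = sorted(records_for(smiles, predictor, config, small_target),
                      key=lambda r: (-r.score, r.inchikey))
        assert pool[0].score == 1.0
        v_target = encode_full(*small_target, config.spectrum)
        new_pool, _ = iterate(pool, small_target, v_target, config,
                              predictor, iteration=1)
        assert new_pool[0].smiles == "CCOC(=O)c1ccccc1"
        assert new_pool[0].score == 1.0

    def test_best_score_is_non_decreasing(self, predictor, config,
                                          library100):
        target = simulate_multiset(chem.mol_from_smiles("CCOC(=O)c1ccc(Br)cc1"),
                                   predictor)
        pool = sorted(records_for([chem.canonical_smiles(m)
                                   for m in library100[:20]],
                                  predictor, config, target),
                      key=lambda r: (-r.score, r.inchikey))
        v_target = encode_full(*target, config.spectrum)
        best = pool[0].score
        for it in range(1, 4):
            pool, log = iterate(pool, target, v_target, config, predictor, it)
            assert log.best_score >= best - 1e-12
            best = log.best_score

    def test_formula_constraint_is_sound(self, predictor, library500, db500):
        """No reported candidate violates a supplied formula."""
        target_mol = chem.mol_from_smiles("CCOC(=O)c1ccccc1")
        target = simulate_multiset(target_mol, predictor)
        formula = chem.molecular_formula(target_mol)  # C9H10O2
        config = SolverConfig(formula=formula, max_iterations=2)
        result = solve(target, db500, config, predictor)
        for rec in result.ranked:
            if rec.provenance["type"] == "recombined":
                assert chem.molecular_formula(rec.mol) == formula


class TestSolve:
    def test_target_in_db_needs_no_recombination(self, predictor, config,
                                                 library500, db500):
        mol = library500[123]
        target = simulate_multiset(mol, predictor)
        result = solve(target, db500, config, predictor)
        assert result.best.smiles == chem.canonical_smiles(mol)
        assert result.best.score == 1.0
        assert result.n_iterations == 0 and result.converged

    def test_assemblable_scenario_solved_and_replayable(
            self, predictor, config, library500, db500):
        """The solver reaches a perfect match within 3 iterations, ranks
        the true structure first, and its provenance chain replays to
        the same molecule."""
        scenario = generate_scenario(library500, "assemblable", seed=77,
                                     predictor=predictor, db=db500)
        target = (scenario.target_h, scenario.target_c)
        result = solve(target, db500, config, predictor)
        assert result.best.smiles == scenario.target_smiles
        assert result.best.score >= 0.99
        assert result.n_iterations <= 3

        prov = result.best.provenance
        assert prov["type"] == "recombined"
        replayed = _replay(prov, predictor)
        assert chem.canonical_smiles(replayed) == scenario.target_smiles

    def test_score_trajectory_non_decreasing(self, predictor, config,
                                             library500, db500):
        scenario = generate_scenario(library500, "assemblable", seed=78,
                                     predictor=predictor, db=db500)
        result = solve((scenario.target_h, scenario.target_c), db500,
                       config, predictor)
        bests = [log.best_score for log in result.trajectory]
        assert bests == sorted(bests)

    def test_empty_target_rejected(self, predictor, config, db500):
        with pytest.raises(ValueError):
            solve((ShiftMultiset("1H", ()), ShiftMultiset("13C", ())),
                  db500, config, predictor)

    def test_reactant_is_integrated_into_pool(self, predictor, config,
                                              library500, db500):
        scenario = generate_scenario(library500, "reactant-seeded", seed=79,
                                     predictor=predictor, db=db500)
        reactant = chem.mol_from_smiles(scenario.reactant_smiles)
        result = solve((scenario.target_h, scenario.target_c), db500, config,
                       predictor, reactants=[reactant])
        seeded = [r for log in result.trajectory[:1] for r in log.pool]
        assert scenario.reactant_smiles in seeded
        assert result.rank_of(scenario.target_smiles) == 1


def _replay(provenance, predictor):
    """Rebuild the winning molecule from its recorded parents and
    fragment structures."""
    frag_smiles = provenance["fragments"]
    picked = []
    for parent_smiles, wanted in zip(provenance["parents"], frag_smiles):
        mol = chem.mol_from_smiles(parent_smiles)
        pred = predictor.predict(mol)
        frags = [f for p in chem.fragment_molecule(mol, pred.c_shifts,
                                                   pred.h_shifts) for f in p]
        picked.append(next(f for f in frags if f.smiles == wanted))
    return chem.recombine(*picked)
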