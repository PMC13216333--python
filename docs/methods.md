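# Methods

This note records the model assumptions, the numerical conventions, the
design choices that were genuinely open, and what the synthetic test
conditions do and do not establish.

## Spectrum representation and conventions

A spectrum is an unordered multiset of chemical shifts per nucleus.

* **¹H** — one entry per hydrogen nucleus. Literature peak lists encode
  integration by repeating the representative shift (range peaks use
  the midpoint of the reported range); multiplicity labels ride along
  as optional tags. The multiset cardinality therefore equals the total
  integrated proton count.
* **¹³C** — one entry per distinct carbon resonance. Symmetry-equivalent
  carbons receive identical predicted shifts under any deterministic,
  symmetry-respecting predictor, so "averaging equivalent carbons into
  one signal" is implemented as exact-value coalescence of the per-atom
  predictions. This convention makes the inherited union of two
  fragment spectra *exactly* consistent with a fresh simulation of the
  recombined molecule whenever the atomic environments survive the cut,
  including the case where recombination creates new symmetry across
  the junction. A side effect is that non-equivalent carbons whose
  radius-2 environments happen to coincide (e.g. interior methylenes of
  long chains) also coalesce — chemically reasonable, since such
  carbons resonate at indistinguishable positions.

Degenerate inputs: an empty multiset encodes to the zero vector; set
similarity against an empty multiset is 0 by convention (with a
warning), since the 1/√(mn) normalization is undefined there.

## Encoding and similarity parameters

| parameter | default | why |
|---|---|---|
| ¹H window | −2 … 16 ppm | covers the conventional proton range with margin |
| ¹³C window | −10 … 230 ppm | covers the conventional carbon range |
| grid points per nucleus | 128 | fixed-length 256-dim full encoding |
| σ (encoding), ¹H / ¹³C | 0.2 / 2.0 ppm | ≈ one grid spacing (0.14 / 1.9 ppm), so adjacent samples overlap smoothly |
| σ (set similarity), ¹H / ¹³C | 0.1 / 1.0 ppm | commensurate with typical forward-prediction error on each scale |
| nucleus weights w_H, w_C | 0.5 / 0.5 | renormalized over the nuclei present in both spectra |

Encoded vectors are **not** normalized — additivity under multiset
union is the basis for estimating recombined spectra by vector sums.
The retrieval index stores L2-normalized copies separately for its
cosine scan. Shifts outside the window still contribute their Gaussian
tails (no clipping). Grid convention: inclusive endpoints, uniform
spacing.

The optimal assignment is computed with `scipy.optimize.
linear_sum_assignment` directly on the rectangular kernel matrix; with
a strictly positive kernel this is equivalent to allowing unmatched
elements, so no dummy padding is needed.

Multiplicity weighting is a hook, off by default: compatible or missing
tags weigh 1.0, contradictory defined tags weigh λ = 0.5, and the
catch-all multiplet "m" is compatible with everything (a large share of
literature peaks are multiplets). The weighting scheme is a placeholder
for spectroscopically calibrated weights.

## Fragmentation and recombination

Cleavable bonds are acyclic bonds between two heavy atoms; ring bonds
are excluded because breaking one does not bipartition the molecule
into two single-attachment fragments, and bonds to hydrogen never
appear (hydrogens are implicit). Aromatic bonds are ring bonds and are
therefore never cleaved. Stereochemistry is stripped on input — the
bundled predictor is 2D and stereo-aware scoring is out of scope.

The compatibility predicate implements two rules, applied symmetrically
(both fragments' rules must hold — the directionality is not fully
pinned down in the field's informal descriptions, and the symmetric
reading is the one that keeps the guarantee below provable):

1. bond orders must match;
2. a fragment whose retained atom is carbon accepts only partners whose
   retained atom equals its lost element; non-carbon-retained fragments
   accept any partner of equal order.

Under these rules every carbon's radius-1 circular neighborhood
(element multiset of bonded neighbors with bond orders) is invariant
under recombination — asserted by direct graph comparison in the test
suite. The permissible-pairing table is exactly these rules; users
needing a finer-grained table can extend `compatible`.

Self-recombination (re-joining fragments of one parent, or pairing two
copies of one fragment structure) is allowed; it regenerates known
molecules, which deduplication removes, and legitimately produces
symmetric dimers.

Symmetry classes are computed by canonical ranking without tie-breaking
(iterated neighborhood refinement), validated against a full VF2
automorphism enumeration on all fixture molecules up to 10 heavy atoms.

## The toy forward predictor

The bundled oracle assigns

    shift = base(bonding class) + A₁·u(radius-1 code) + A₂·u(radius-2 code)

where u(·) is a deterministic uniform-[0,1) hash of the canonical
environment code. The radius-1 code records the atom's own label plus
neighbor *elements and bond orders only* — precisely the neighborhood
that compatible recombination preserves for carbons — while the
radius-2 code is the full two-sphere HOSE-style string. Amplitudes:
A₂ = 1.0 ppm for ¹³C and 0.1 ppm for ¹H, small against the class
windows (aromatic C ≈ 112–150 ppm, carbonyl ≈ 160–205 ppm, aliphatic
≈ 5–60 ppm; aromatic H ≈ 6.3–8.5 ppm, etc.). Hydrogen shifts are keyed
on the heavy atom's codes, so equivalent hydrogens on one heavy atom
share a value.

This hierarchy mirrors the physical rule that local structure dominates
chemical shifts with rapidly decaying long-range effects, and it yields
the two properties the optimization loop relies on:

* **inheritance exactness** — after a compatible recombination, every
  atom at graph distance ≥ 2 from the attachment point keeps its
  parent's shift exactly; atoms nearer the cut move by at most A₂
  (¹³C) when their radius-1 neighborhood is preserved, i.e. shifts are
  nudged, never resampled;
* **discriminativeness** — distinct radius-2 environments receive
  distinct values with probability 1 (hash resolution 10⁻⁶ ppm), so
  distinct structures essentially never share an exact spectrum.

Known identifiability limit: environments identical to radius 2 are
identical to the oracle. Rare isomer pairs exist whose radius-2
environment multisets coincide globally (e.g. swapping a cyclopentyl /
cyclohexyl pair between the two sides of an amide); such pairs have
*exactly* equal toy spectra, both score 1.0, and the ranking between
them is decided by the deterministic InChIKey tie-break. This is the
toy analogue of genuinely NMR-ambiguous structures.

Hydrogens on non-carbon attachment atoms (e.g. an O–H at an O-started
cut that pairs with a different partner element) can move by more than
A₁ under recombination, because the non-carbon pairing rule does not
preserve the partner element. This is the main source of inherited-
versus-fresh discrepancy beyond tiny molecules.

## Database and retrieval

Build: inadmissible molecules (net charge, radicals, isotope labels,
neither C nor H) are dropped with logged reasons; duplicates are
removed by InChIKey; records are sorted by InChIKey so the build is
independent of input order. The on-disk format is a directory with a
metadata JSON (including a hash of the encoding configuration and
predictor identity — stale databases are refused on load), a TSV of
records, and a raw little-endian float32 vector file.

Retrieval: stage 1 is an exact cosine scan over normalized encodings
returning `k_ann` = 200 records; stage 2 re-ranks them by combined set
similarity and returns `k_final` = 20 (ties broken by InChIKey). The
vector-index interface (`top_k(query, k)`) accepts approximate
backends; none is bundled, and the exact scan is the default at desk
scale.

## The optimization loop

Defaults: k_frag = 10 complementary structures per fragment, M = 500
pairs after the global vector re-rank, K = 50 pairs refined by set
similarity, pool size P = 50, at most T = 5 iterations with patience 2,
plus an early stop on a perfect score (scores plateau within the first
two iterations in practice, so small T suffices). All config-exposed.

Design choices that were genuinely open:

* **Initial pool** — the top P retrieved records; seeded reactants and
  user candidates are integrated unconditionally (they carry
  information the spectrum alone may not support, which is their
  point), with retrieved hits filling the remaining slots.
* **Instance vs structure** — fragments with identical structure but
  different inherited shifts (different parents) are distinct screening
  objects producing identical offspring. Stage 1 counts complementary
  partners by distinct structure; stage 2 represents each structural
  pair by its best vector-objective instance before the M cap, so M
  and K count distinct offspring. Without this, duplicate instances
  crowd out structural diversity and symmetric-dimer targets are
  missed.
* **Cross-iteration memory** — the solver remembers structural pair
  keys already recombined and product InChIKeys already evaluated, so
  successive iterations explore strictly new recombinations instead of
  re-deriving earlier offspring. Without memory the deterministic
  selection re-picks the same top-K pairs and the loop stalls.
* **Pool update** — global top-P replacement by combined score (ties by
  InChIKey), rather than per-lineage replacement.
* **Stage-1 partitioning** — fragments are grouped by cleavage-bond
  descriptor and each fragment scans only its compatible groups;
  functionally equivalent to post-filtering a global scan.
* **Mutations** — none; candidates arise from single-cut crossover
  only, so every offspring forms exactly one new bond. Multi-fragment
  assembly and ring-forming recombination are out of scope.
* **Screening approximation** — stages 1–2 use additive fragment
  encodings (exact for ¹H; for ¹³C they overcount when signals from the
  two fragments would coalesce); stage 3 and final scoring use exact
  multisets, and every surviving candidate is re-predicted with the
  forward model, so the approximation only influences which pairs get
  refined.
* **Constraints** — element filters apply to fragments at pool build
  time (cheap pruning); the molecular-formula constraint applies at the
  final candidate filter, where the complete molecule exists.

Candidates failing sanitization after recombination, and candidates the
predictor cannot handle, are dropped and counted in the iteration log,
never fatal.

Determinism: for a fixed database, configuration, and predictor the
solver is fully deterministic — every ranking stage has an explicit
structural tie-break — so repeated runs are byte-identical. The
configured seed only enters fixture/scenario generation.

## Synthetic test conditions

The fixture generator builds libraries from ~29 curated scaffold
templates (benzenoid, heteroaromatic, fused-ring, saturated-ring and
chain cores) × ~32 substituents, seeded and deduplicated. Substituent
formulas are pairwise distinct and two-slot scaffolds are subsampled so
a 500-molecule library carries ≥ 400 distinct molecular formulas,
keeping formula constraints discriminative. Default study sizes: a
500-molecule library/database, 50-scenario recovery suites, and paired
seeded/unseeded runs on 25–50 scenarios.

Scenario modes: `in-db` (target sampled from the library; solvable by
retrieval alone), `assemblable` (target constructed by recombining
fragments of two library members, excluded from the database), and
`reactant-seeded` (assemblable with one parent supplied as a known
reactant). Every assemblable scenario is verified at generation time:
the recorded fragment pair recombines to the target, the target is
novel, the target exhibits both nuclei, and the parents required for an
unseeded solve rank inside the initial retrieval pool. The last check
is the desk-scale analogue of a production-scale database in which any
common building block has many spectrally similar carriers; without
it, a 500-molecule library poses targets whose only fragment carriers
are unreachable by any pool-based search. In reactant-seeded mode only
the non-seeded parent must be retrievable — the seeded parent is
handed to the solver — which yields exactly the scenarios where
reactant knowledge demonstrably reduces iterations to solution.

What passing these suites shows: the representation, similarity,
screening, and search machinery are internally consistent and can
recover structures whose spectra the forward model explains. What it
does not show: performance on experimental spectra, where forward-model
error, solvent/temperature effects, overlapping multiplets, and peak-
picking noise dominate — the toy oracle models none of these, and its
absolute shift values are not real chemistry.

## Known limitations

* Single-cut crossover cannot form or break rings; targets differing
  from all database molecules by ring rearrangement are unreachable.
* The ¹³C coalescence convention merges accidentally degenerate
  resonances; intensity information within ¹³C spectra is not used.
* J-couplings are parsed and preserved but never scored.
* The multiplicity weighting hook is a placeholder, not calibrated.
* Radius-2-identical isomer pairs are indistinguishable to the toy
  oracle (exact score ties, broken deterministically).
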