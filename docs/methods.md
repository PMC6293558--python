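# Methods

## Code models and representations

A genetic code is a total map from the 64 RNA codons (canonical order:
lexicographic in U<C<A<G, the code-table order) to the 20 amino acids plus
stop. The stop codons UAA, UAG and UGA are pinned in every code, so the
mutable part is the assignment of the 61 sense codons and the structural
distance d_str — the Hamming count of sense codons with different meanings —
has maximum 61.

* **BS (block structure)**: the SGC's 20 sense-codon blocks are fixed and a
  bijection places one amino acid on each block. A "block" is the complete
  codon set of one SGC amino acid, so split families (Ser UCN + AGY, Leu,
  Arg) count as single 6-codon blocks; the block-size multiset is
  {6,6,6,4,4,4,4,4,3,2,…,2,1,1}. Internally BS codes are 20-element
  permutations expanded to the 64-codon map on demand.
* **US (unrestricted)**: any surjective assignment of the 61 sense codons to
  the 20 amino acids. Random US codes are drawn by placing each amino acid
  on one distinct uniformly chosen sense codon (a uniform random injection,
  guaranteeing surjectivity without rejection) and assigning the remaining
  41 codons independently and uniformly. The sampling distribution over
  surjections is a design choice — the construction is simple, rejection-free
  and reproducible; it mildly over-represents balanced codes relative to the
  uniform distribution over all surjections, which does not matter for any
  quantity computed here because optimized archives, not the initial
  distribution, carry the results.

Serialization is a 64-character string of one-letter amino-acid codes with
`*` for stop, in canonical codon order; the reader revalidates all
invariants (totality, surjectivity, fixed stops, and for BS codes the block
partition).

## Objectives

Each of the eight AAindex scales (BLAM930101, BIOV880101, MAXF760101,
TSAJ990101, NAKH920108, CEDJ970104, LIFS790101, MIYS990104 — the
representatives of an eight-cluster consensus clustering of >500 published
scales) yields a 20×20 cost matrix of squared value differences divided by
the largest squared difference, so all matrices share the [0, 1] scale with
maximum exactly 1. Constant scales produce an all-zero matrix flagged as
degenerate. The objective F_i(code) sums the cost over the 263 sense–sense
single-substitution codon pairs; pairs containing a stop codon are excluded
because stops carry no property value and are immutable in both models, and
each unordered pair counts once (doubling would rescale every objective and
leave all ratio measures unchanged).

### Packaged index data

The scales ship on the max-normalized scale v/max(v) (signed maximum). Cost
matrices are invariant to any positive rescaling of a scale, and the
deviation analytics below normalize by the maximum anyway, so this storage
choice changes no computed quantity. The packaged values were
cross-validated against the packaged reference deviation table: each scale
reproduces all twenty tabulated per-amino-acid deviations at the tabulated
3-decimal precision (this validation is an executable test). Three of the
eight scales (NAKH920108, CEDJ970104, MIYS990104) are stored as
reconstructions from that deviation profile — the sign pattern of
(value − mean) is fixed by requiring the signed deviations to sum to zero
(residuals ≤ 0.003 against a rounding budget of 0.01) and the positive-side
maximum to reach 1 after normalization, with the biochemically expected
pattern (e.g. Leu/Ile/Val/Phe-rich membrane-protein composition for NAKH,
negative partition energies for the hydrophobics in MIYS) confirming the
choice; their records say so in the description line.

### Deviation analytics

For each scale the values are normalized by the (signed) maximum and the
absolute deviation from the mean of the normalized values is tabulated per
amino acid, with a row-average column across scales. Amino acids with
near-average properties (Thr has the smallest row average, 0.130) are cheap
to substitute; cost-minimizing codes therefore assign them many codons,
which shows up as a negative Spearman rank correlation (average ranks on
ties; scipy's implementation) between codon counts and deviation averages.

## The evolutionary engine

The multi-objective search is SPEA2 with the canonical formulas for
everything the loop needs:

* strength S(i) = number of pool members i dominates; raw fitness R(j) =
  Σ S(i) over the dominators i of j; density D(i) = 1/(σ_i^k + 2) with
  σ_i^k the Euclidean distance in objective space to the k-th nearest
  neighbour, k = round(√(M + N_max)); fitness F = R + D, lower is better.
  Non-dominated members are exactly those with fitness < 1.
* Environmental selection copies all non-dominated members of P_t ∪ A_t to
  the archive; at overflow an iterative truncation repeatedly removes the
  member with the lexicographically smallest sorted-distance profile
  (exact duplicates, at distance 0, go first); at underflow the best
  dominated members fill up by ascending fitness.
* **Elitist guard**: the members attaining the per-objective minima are
  exempt from truncation. Canonical SPEA2 can, rarely, truncate a boundary
  point; the guard (at most k of N_max slots) makes the archive's ideal
  point provably monotone across generations, which the test suite asserts.
* Mating: M binary tournaments with replacement on the archive, copying the
  lower-fitness contestant, ties uniform. A fitness-proportional variant
  (win probability f_other/(f_a+f_b)) is available behind
  `EngineConfig.tournament="proportional"`; the deterministic tournament is
  the default because it is the operative rule of the algorithm's step list.
* Variation, in order: each pool member mutates with probability p_m
  (defaults 0.9); the pool is then paired in uniformly shuffled order and
  each pair crosses over with probability p_c (default 0.3), unpaired or
  uncrossed members passing through. For US runs a mutation event applies
  the point mutation or the amino-acid swap with equal probability (no
  published split exists; equal rates keep both neighbourhoods active).
* Termination after T generations returns the non-dominated subset A* of
  the final archive.

Maximization runs negate the cost matrices internally (the objective is
linear in the costs, so F(−C) = −F(C)) and re-negate on output; a
maximizing run and a minimizing run on negated costs are bit-identical
under equal seeds.

The single-objective variant keeps the same loop but replaces dominance
with scalar order: the archive is the top N_max codes by objective value in
the configured direction and doubles as the fitness used by the tournament.

### Operators

* BS swap mutation exchanges the amino acids of two uniformly chosen
  distinct blocks (the stop block is not selectable).
* BS crossover is position-based: each block of offspring 1 independently
  keeps parent 1's amino acid with probability 0.5; the remaining blocks
  are filled scanning parent 2's amino acids in canonical block order,
  skipping those already present (offspring 2 symmetric). The 0.5 keep
  rate maximizes mixing; the operator reduces to cloning for identical
  parents.
* US point mutation reassigns one uniformly chosen sense codon to a
  uniformly chosen different amino acid; if the codon is the sole codon of
  its amino acid the operation is an applied-but-identity event (no
  resampling), preserving surjectivity.
* US amino-acid swap samples codon pairs until they encode two different
  amino acids and exchanges the complete codon sets.
* US crossover starts from parent copies and processes the 20 amino acids
  once each in shuffled order: codons shared by both parents stay; differing
  codons are paired in shuffled order and exchanged as within-offspring
  meaning swaps (count-preserving by construction); an unpaired leftover is
  transferred, taking the focal amino acid in one offspring and the
  displaced amino acid in the other, skipped whenever it would empty an
  amino acid's codon set. Codons that are the sole codon of their amino
  acid in a parent are frozen in the corresponding offspring.

### Randomness and reproducibility

One `numpy` PCG64 generator per run, seeded from `EngineConfig.seed` and
consumed in a fixed order, makes runs bit-reproducible; repeats r = 1..R use
seeds seed+1..seed+R and their archives are aggregated by union (20·700 =
14,000 codes at the published multi-objective scale, 50·700 = 35,000 for
single-objective runs).

## Measures

m_s, m_min and m_mean are ratios on [0, 100] as defined in the README;
Euclidean distances are taken on the objective vectors exactly as produced,
since the per-index max-normalization already puts all objectives on a
common cost scale. The d_str summary reports min/median/max; for even-sized
sets the median is the lower of the two middle order statistics so that the
reported value is an attained integer distance. The dominance-count
histogram buckets archive members by how many objective components are
strictly smaller than the SGC's. The best/worst sets entering the measures
are always the unions of archives across repeats, not per-run archives.

## Problem sizes and what the tests show

The published scale (M = 2800, N_max = 700, T = 3000, 20–50 repeats) is the
package default but the test suite runs desk-scale searches — population
300, archive 50, 300 generations, 5 repeats per direction under the BS
model — chosen so a full suite completes in minutes on one CPU. At that
scale the stochastic measure values are reproducible only directionally, so
the suite asserts the <50% claims (the SGC closer to best than to worst)
rather than point values; the deterministic statistics (combinatorics,
deviation table, rank correlations, d_str bound) are asserted at printed
precision. Engine correctness is established by property tests instead of
full-scale replication: operator invariants over 10⁴ applications,
fitness equivalence against a literal brute-force SPEA2 implementation,
objective equivalence against direct neighbour enumeration for 100 random
codes, archive ideal-point monotonicity and bit-exact rerun determinism.

The synthetic index generator (uniform / constant / two-level schemes)
exists so the whole pipeline runs without the real scales; it reproduces
the format and degeneracy branches of real data but not the correlation
structure among real amino-acid properties, so synthetic-index runs say
nothing about the SGC's actual optimality — the packaged validated scales
do that.

## Known limitations

* The sampling scheme for random US codes is one reasonable choice among
  several; only optimized archives are interpreted.
* Exact duplicate archive vectors are removed in bulk (keeping the first)
  before iterative truncation; this matches the removal order implied by
  zero nearest-neighbour distances but fixes one particular tie-break.
* Desk-scale runs under-explore the US space relative to the BS space;
  multi-objective US measures at desk scale are noisier than BS ones.
* The discriminant-analysis visualization of best/worst/SGC code clouds is
  out of scope, as is any statistic defined relative to random-code
  ensembles.
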