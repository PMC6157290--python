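# Methods

## Discretization and the composition table

All mass arithmetic is done on integers: a mass `m` (Da) maps to
`round(m · scale)` with `scale = 100` by default and half-away-from-zero
rounding, so 113.084 → 11308 and 114.04 → 11404. The 20 standard
monoisotopic residue masses (G 57.02146 … W 186.07931) give 19 distinct
integers — leucine and isoleucine both map to 11308. Database matches are
reported with the database's original letters, so L/I identity is preserved
in output even though the search cannot distinguish them.

The composition table realizes C(e): for every integer mass up to
`α·scale + tol` it knows all ordered residue strings with that exact mass
sum. Counts per (mass, length) are computed eagerly by dynamic programming
(a convolution per length over the 19 symbol masses); string lists are
materialized lazily per queried mass and cached, because near 350 Da a
single mass bin can hold thousands of strings. A mass-tolerance lookup for
an edge labeled `m` is the union of the exact sets for `|m′ − m| ≤ tol`,
with `tol = round(ε·scale)` (2 integer units at the ε = 0.02 Da default).
The tolerance is applied independently at each edge; it does not accumulate
along a path by construction, although the total mass error of a k-edge
match can reach k·tol.

The expansion factor `r = max_{m,j} |C(m, j)|^(1/j)` is defined on the
zero-tolerance counts; at scale 100 and masses up to 35000 it evaluates to
2.913 (attained at m = 34315, j = 4, 72 strings). With out-degree d = 3 and
alphabet size g = 19 this keeps `2rd < g`, the regime in which the expected
number of surviving search states grows sublinearly with database size.

## Spectra, noise filtering and scoring

A deconvoluted spectrum is a precursor mass plus mass-sorted fragment
(mass, intensity) pairs. The noise filter keeps a fragment only if it ranks
in the top λ intensities among all fragments within ±100 Da of its own mass
(λ = 8 by default; λ = ∞ disables filtering). Equal intensities are ranked
by ascending mass — the tie rule is a package choice made for determinism;
any fixed rule would do. The filter is idempotent and monotone in λ.

Three per-fragment scores are available: mass count (1 per fragment), log
intensity (`log2(2h/b)` with `b` the spectrum's minimum intensity), and rank
(`1 + i/k`, most intense fragment scoring exactly 2). A path's score is the
sum of its node scores, which reduces to the node count under the mass-count
scheme.

## Interval selection and reversal

Candidate windows of width δ are anchored at each observed fragment mass
(`[x, x + δ]`); this finite candidate set attains every achievable mass
count, so the greedy maximum is the true maximum. Greedy selection reports
the best-count candidate (ties: smallest lower bound), suppresses candidates
whose overlap ratio with any reported interval reaches ρ, and stops at γ
intervals or when candidates run out; only intervals with ≥ 6 masses are
reported. For ρ = 0 the suppression rule is "any positive overlap
disqualifies": suppressing overlap ≥ 0 literally would also remove disjoint
candidates and reduce every selection to a single interval, which
contradicts the method's own multi-graph regime.

Reversal maps an interval `[m_l, m_r]` with masses `b_i` to
`[M − m_r, M − m_l]` with masses `M − b_i`, exactly as printed, with an
optional additive offset (default 0) left for ion-type chemistry; the shift
between the plain `M − b` arithmetic and true b/y chemistry is absorbed by
the extended-score mass shift, so it does not affect ranking.

## Spectrum graphs and terminal sets

One node per interval mass; a candidate edge (u, v) exists when the integer
mass difference is positive, at most `α·scale + tol`, and has at least one
composition within tol. Each node then keeps its d smallest-label out-edges
(ties: lower-mass target), capping the out-degree as the complexity analysis
requires. Because labels are node-mass differences they telescope: all paths
between two nodes carry the same total mass. Terminal sets are therefore
computed from mass differences alone: V_s contains nodes within β Da of the
lightest node, V_t those within β Da of the heaviest. This deliberately
admits nodes not reachable from the lightest node (disconnected components
remain searchable); a literal shortest-path reading would exclude them and
silently drop matches in sparse graphs.

## The search

The restricted search from a start node s propagates per-node hash sets B_i
mapping suffix-tree cursors to the best (path score, node count) reaching
them. A cursor pinpoints a tree position one symbol at a time, also inside
compressed edges. Extending a cursor across an edge labeled e is a
depth-first walk of the tree constrained by the remaining mass: branches
whose accumulated mass exceeds `e + tol` are pruned, and positions with
accumulated mass within tol of `e` are accepted. This enumerates exactly the
intersection of C(e) with the spellings present in the database — the
identifiable prefix strings — without materializing C(e) per edge.
Separators between proteins are unique negative symbols, so no match can
span two proteins. Matches are read off cursors at nodes of V_t: subtree
leaf positions give text offsets, which map back to (protein, offset,
residues). The full search runs the restricted search once per start node in
V_s and deduplicates by (protein, offset, residues), keeping the best path
score. A brute-force counterpart (path enumeration plus per-position
partition matching) is kept as the reference implementation for equivalence
testing.

## Scoring and ranking

Per protein, the similarity score is the maximum path score over all matches
from all of the spectrum's graphs. The extended similarity score fixes one
mass shift from the best match's first path node (experimental node mass
minus theoretical prefix mass at the match offset), shifts the whole
theoretical cleavage ladder by it, and counts — once each — the experimental
fragment masses within ε of a shifted value; for reversed-orientation
matches the spectrum is first mirrored through the precursor mass, which
brings its suffix ladder into the prefix frame. The extended mass-count
score is the default ranking score; ties break by similarity score, then
database order. Only the single best-match shift is used; per-node shifts
are out of scope.

## Synthetic data

The fixture generator emulates deconvoluted top-down CID spectra: fragment
masses are plain residue-mass prefix sums (no proton/water terms — matching
the reversal arithmetic above), the precursor is the residue total plus
water (18.010565 Da, the molecular-mass convention; configurable), peaks are
dropped independently with probability `miss_prob`, `n_noise` uniform noise
masses span the ladder range, PTMs add their mass to every cleavage at or
downstream of the modified residue, and intensities are log-normal
(μ = 3, σ = 1 on the log scale — an arbitrary but realistic two-decade
spread). Optionally the suffix ladder (`M − prefix`) is emitted as well to
exercise reversed intervals. Databases are uniform-random sequences over the
20 residues. Default study conditions for end-to-end evaluation: 50 proteins
of 40–80 residues; an "easy" condition with 20% missing peaks and 5 noise
masses, and a "hard" condition with 30% missing peaks, 5 noise masses and
two PTMs (+79.966, +42.011 Da).

What passing these fixtures shows — and does not. Random sequences lack
homology, low-complexity runs and shared domains, so candidate separation is
easier than on a real proteome; real deconvolution also produces correlated
harmonics and charge-state errors that the uniform noise model does not
imitate. The fixtures validate the algorithmic contracts (search
correctness, monotonicity, ranking plumbing), not proteome-scale filtration
efficiency.

## Numerical choices and limitations

- Rounding is half-away-from-zero everywhere a mass is discretized.
- All tolerances are absolute Da (ε), not ppm.
- Degenerate inputs: spectra with < 6 usable masses yield an empty ranking
  (not an error); intervals with < 2 nodes yield no graphs; empty databases
  and non-positive parameters raise immediately.
- Composition tables are refused above a size cap (≈ 5·10⁶ cells) with
  advice to lower α; at the defaults the table is ~2 MB.
- Problem sizes used by the test suite (50-protein databases, ≤ 10-node
  graphs for oracle equivalence, 100 trials per end-to-end condition) were
  chosen so the whole suite runs in well under a minute while still
  exercising every code path; the method itself has no such limits.
- ε-monotonicity of the match set holds for the search proper; with the
  out-degree cap active a wider tolerance can admit a new small-label edge
  that evicts another from a node's top-d list, so the property is verified
  with the cap relaxed.
- Out of scope: spectral alignment, E-values and FDR control, PTM
  localization, ppm tolerances, modified or non-standard residues
  (B/Z/J/X/U/O break matchable runs), and upstream deconvolution.
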