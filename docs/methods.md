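# Methods

This note documents the models, algorithms, and numerical choices behind
`seedsearch`, and what the synthetic benchmarks do and do not show.

## Alignment kernels

Both search modes are affine-gap Smith–Waterman over a position × residue
profile: sequence–sequence search uses a profile of substitution-matrix rows
(BLOSUM62 by default, taken from Biopython's copy of the NCBI matrix),
profile search uses the PSSM's integer scores directly. The recurrence is
the classic three-matrix formulation; a gap of length *L* costs
`gap_open + L·gap_extend` (defaults 11/1, the BLAST protein defaults). The
kernel is JIT-compiled with numba; an independent, deliberately naive
pure-Python DP in the test suite checks it exhaustively on short sequences
and on random pairs in both modes.

Determinism: the best cell is the first maximum in row-major order, and the
traceback prefers an aligned pair, then a gap in the subject, then a gap in
the query; within a gap state, closing the gap beats extending it. These
tie-breaks fix the reported alignment completely, so identical inputs give
bit-identical output.

Alignments are encoded as BTOP strings (match-run integers plus two-letter
edit tokens, query letter first, `-` for a gap) in BLAST-style commented
tabular files. The decoder validates token letters against the sequences,
so a BTOP that does not belong to its coordinates is rejected rather than
silently misinterpreted.

## E-value statistics

Significance follows the extreme-value model `E = K·m·n·exp(−λS)` with *m*
the query length and *n* total database residues. Iteration 1 (plain
BLOSUM62/11/1 search) uses the published gapped Karlin–Altschul constants
λ = 0.267, K = 0.041. Every PSSM iteration is calibrated empirically on its
own search: a maximum-likelihood Gumbel fit to the per-subject best scores,
iteratively censoring scores whose fitted E-value falls below 1 (the
candidate homologs) and refitting, at most five rounds. The first fit is
initialized from the lower 80% of the scores; without that, a heavy homolog
tail (a fifth of this package's benchmark databases are genuine homologs)
flattens the initial fit so badly that censoring never identifies the tail.
K is anchored so a score at the fitted location has expectation ≈ 1 per
average-length subject. Degenerate inputs (constant scores, fewer than 50
values) raise a fit error and the driver keeps the previous iteration's
calibration.

On 10,000 simulated Gumbel scores the fitted λ is within 5% of truth
(typically well under 1%); the acceptance script recomputes this.

## PSSM construction

Given the (optionally seeded) query-anchored MSA, with the query always row
one at full span:

- **Weights.** Henikoff position-based sequence weights over all rows; a
  column with *r* distinct symbols gives a row showing a symbol seen *s*
  times a contribution `1/(r·s)`; gaps count as a symbol type.
- **Observed frequencies.** Weighted residue frequencies per column; gap
  characters and `X` contribute nothing.
- **Pseudocounts.** `Q = (α·f + β·g)/(α+β)` with `α = n_eff − 1`, where
  `n_eff` is the column's number of distinct residue types, β the
  pseudocount weight (default 10), and `g = C·f` the substitution-matrix
  conditional mixture. The conditionals `C[a|b]` and background `p` are
  derived from the score matrix itself: λ_ungapped is the root of
  `sum(exp(λS)⁻¹·1) = 1`, the solution vector is the background, and
  `q_ab = p_a·p_b·exp(λS_ab)` gives the implied target frequencies. For
  BLOSUM62 this reproduces the canonical implicit composition (Trp ≈ 0.013,
  Leu ≈ 0.099) without embedding any table.
- **Scores.** `S_i(a) = round(2·log2(Q_i(a)/p_a))` (half-bit integers);
  unrounded values and frequencies are retained. A column with no residue
  observations at all falls back to the matrix row of the query residue.

Two consequences worth knowing. With β → ∞ the PSSM converges to the
background log-odds of `g` (tested in closed form). And because α counts
residue *types*, query-seeding changes a column's scores only when the
column carries at least one observation discordant with the query — which
is exactly the situation in creeping over-extension, where a few rows carry
foreign residues and the rest are gaps. There, seeded fills outvote the
sparse observations; unseeded columns hand them the whole frequency mass.

## Seeding and boundary policies

`fill_gaps` implements four modes — `none`, `query_seed`, `x_fill`,
`random_fill` (background-distributed, seeded RNG) — over two scopes,
internal gaps only or internal plus end gaps. The shipped default is
query-seeding over both scopes, so every subject row becomes full-length
and the model's effective depth is constant across columns. The subject
library (each row's non-gap text, fills included) is emitted alongside the
MSA.

Boundary policies trim a hit before it enters the MSA. `current` keeps the
alignment as found. `history` clamps it, via the BTOP walk, to the query
span recorded the first time the subject scored at or below the inclusion
threshold (write-once registry); an empty intersection excludes the hit.
`domain` clamps it to the annotated query region with the highest
sub-alignment score density among the regions the hit overlaps.
Sub-alignment scoring partitions the raw score exactly across regions —
each aligned column to the region of its residue, each gap run to the
region of its first column — so low score-density over-extended segments
are directly visible.

## The driver

Iteration 1 is a sequence search; each later iteration selects the previous
iteration's included subjects (E ≤ 0.002 by default), applies the boundary
policy, builds and fills the MSA, constructs the PSSM, re-searches, and
recalibrates E-values. One alignment (the best) per query–subject pair per
iteration; subject residues inserted relative to the query are dropped from
the MSA row and kept as row metadata. The loop stops early at a fixed
point: the included subject set *and* every included alignment's
coordinates unchanged between consecutive iterations. An id-only test was
considered and rejected because it declares convergence while alignment
spans are still creeping — that is, while the model is still moving — which
is precisely the regime this tool exists to study. A reporting threshold
(E < 0.001 by default) governs what the evaluation layer scores.

## Benchmarking

Queries are genuine domains embedded in random flanks of
`floor(domain_length/2)` residues per side (a 200-residue domain gives a
400-residue query), so any alignment outside the domain is non-homologous
by construction. A reported hit is a true positive only if its query span
overlaps the embedded domain interval (≥ 1 residue by default, exposed as
`min_overlap`) *and* the subject positions aligned to that overlap — via
the BTOP walk restricted to it, not the full hit span — overlap a subject
domain of the same family or clan. Everything else reported is a false
positive; for full-length (non-embedded) queries, hits outside the scored
domain interval are ignored instead. Sensitivity is family coverage
TP/(TP+FN); FDR is FP/(TP+FP), 0 when nothing is reported; multi-query
summaries weight each query equally. Over-extension is the number of
aligned query positions outside the domain interval; quartile statistics
(median over-extension, bottom-quartile percent identity) use
linear-interpolation quantiles.

## Synthetic data

The generator draws ancestral domain sequences i.i.d. from a background
(uniform over the 20 residues by default; any composition can be supplied),
then derives family members by point substitutions sampled in proportion to
the matrix-implied exchange probabilities `P(b|a, b≠a)`, plus occasional
indels (Poisson events at 0.01 per position, geometric lengths of mean 2).
Identity targets may be single values (realized within ±2%, with the
substitution budget compensating for planned indel columns) or ranges
sampled per instance — heterogeneous families are what make discovery
gradual across iterations, as in real iterative searches. Multi-domain
proteins concatenate mutated instances and random linkers; architecture
items may slice the ancestor (variable-boundary instances) or override the
family identity. Annotations record every instance; a truth manifest
records ancestors, architectures, and family membership. Everything is
deterministic under the spec's seed.

### The contamination benchmark

The fixed study condition mimics the classic multi-domain failure mode.
Family A (160 residues, members 55–85% identical to the ancestor) appears
in two architectures: 35 proteins carry only positions 1–150, and 25 carry
the full-length instance followed immediately by a "B module" — a weakly
conserved 20-residue edge segment (35–55%) and a tightly conserved
120-residue B domain (88–96%). Thirty B-only proteins (edge + B, no A) are
the contamination sentinels, and 200 random 260-residue decoys pad the
database (290 sequences, ~72k residues). The query is a 40%-identity
family-A member truncated to positions 1–150 and embedded in 75-residue
random flanks.

The geometry is deliberate. Subject A domains continue 10 residues past the
query's domain, so alignment ends jitter into a homologous continuation;
without seeding, a handful of over-extended rows dominate those MSA columns
(gap rows contribute nothing), the model learns the continuation and then
the weak edge, and within a few iterations it reaches the conserved B
domain — at which point all B-only proteins flood in at once. With seeding,
the filled query residues outvote the sparse over-extensions and the creep
stalls. The A-only majority exists precisely to supply those fills.

At this scale the cascade is stochastic: across 20 replicate seeds,
unseeded runs pick up B-only decoys within five iterations in roughly three
quarters of replicates and seeded runs in roughly a quarter, while seeded
FDR ≤ unseeded FDR in every replicate examined. The acceptance tests assert
the comparison at that strength (contamination in a majority of the five
fixed replicates; FDR ordering in at least four of five; strictly fewer
decoy-domain inclusions with seeding on average). The effect at realistic
scale — thousands of library sequences per family, order-of-magnitude FDR
reductions — needs a database orders of magnitude larger; what passes here
shows the direction and mechanism of the effect, not its magnitude.

### What the generator does not model

No phylogenetic structure (members are independent draws from the
ancestor), no composition bias or low-complexity regions, no correlated
indels, sharp domain boundaries, and a single substitution process for all
sites. Real-sequence effects that depend on those — compositional false
positives, repeat-driven over-extension, psiblast's composition-based
statistics — are out of reach of these tests.

## Problem sizes and runtime

Test and acceptance runs use the 290-sequence benchmark with 5 iterations
and 5 replicates, a 20-query evaluation benchmark over an 80-sequence
database, exhaustive oracle sweeps over 4-letter sequences up to length 3
plus 600 random oracle comparisons, and 10,000-score calibration fits. The
full pytest suite runs in well under a minute after JIT warm-up; the
acceptance script in a few minutes.
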