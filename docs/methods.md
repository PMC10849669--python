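# Methods

## Data model

A catalog is a samples × channels matrix of nonnegative integer mutation
counts over a fixed channel schema. The built-in SBS96 schema uses the
pyrimidine-strand convention: 6 substitution classes (C>A, C>G, C>T, T>A,
T>C, T>G) × 16 flanking contexts, ordered substitution-major and then
context-lexicographically (`A[C>A]A`, `A[C>A]C`, …, `T[T>G]T`) — the de-facto
ordering of COSMIC-style signature matrices. Purine-reference labels are
rejected rather than strand-folded, because correct folding needs the
underlying variant calls, which this package deliberately does not consume
(it starts from count matrices). Genome build is carried only as metadata.

Catalogs are read from wide CSV (`sample,<label>,…`), long CSV
(`sample,mutationType,mutations`, absent channels zero) or a portal-style
JSON array of `{sample, profile, matrix, mutationType, mutations}` records.
The JSON field names are an **emulation** of a portal API payload, chosen
here as a stable dialect; records whose `profile`/`matrix` disagree with the
requested schema are rejected. An empty record array is an error, not an
empty catalog — silence would hide a failed upstream query.

## NNLS refitting

Exposures are estimated per sample by minimizing ‖Sx − m‖² over x ≥ 0 with
the Lawson–Hanson active-set algorithm, implemented in `refit.nnls_solve`:

- the entering variable is the one with the largest dual component
  w = Sᵀ(m − Sx); exact ties go to the lowest index, making the solver fully
  deterministic on rank-deficient or duplicated designs;
- dual feasibility is tested against `10·eps·max(|Sᵀm|_∞, 1)` — machine
  precision on the scale of the initial gradient;
- the outer loop is budgeted at 3·k iterations and raises an explicit
  convergence error beyond that (never observed on well-posed inputs);
- the inner feasibility loop steps back to the boundary and drops any
  coefficient at (numerical) zero.

The reported r-norm is the **sum of squared residuals** (not the residual
2-norm). Refitting defaults to raw counts, so exposures carry mutation-count
units and the r-norm is in squared counts; `normalize_input=True` refits the
normalized spectrum instead (exposures then sum to ≈1). The count-scale
default is the convention documented throughout the outputs; the flag exists
because either scale can be argued for and cosine-based comparisons are
unaffected. No sparsity pruning or signature selection is applied — the
estimate is plain NNLS, nothing more.

Degenerate inputs: a zero count vector yields zero exposures and r-norm 0;
duplicate signature columns are handled by the deterministic tie-break and
can only lower, never raise, any sample's r-norm.

## Similarity and clustering

Cosine similarity of nonnegative vectors lies in [0, 1] and is invariant to
positive rescaling, so counts and spectra give identical distances; distance
is defined as 1 − similarity. An all-zero vector has similarity 0 to
everything (maximally distant) with a logged warning — erroring would abort
batch runs over catalogs that contain empty samples.

UPGMA merges the closest pair of clusters; the merged cluster's distance to
any other is the size-weighted arithmetic mean of its parts' distances
(equivalently, the flat mean over all member leaf pairs of the original
matrix — the test oracle recomputes it that way), and the new node sits at
half the merging distance. Equal-distance pairs merge in lexicographic order
of their (creation-index) pair, so the output is deterministic. The result
is ultrametric: heights are non-decreasing and the cophenetic distance
between leaves is twice their LCA's height.

Sample trees annotate each internal node with (a) the cosine similarity
between the two child clusters' **summed raw count vectors** — summing is
the aggregate chosen here; under cosine it is scale-invariant, so large
samples dominate a cluster's direction exactly as they dominate its pooled
spectrum — and (b) the total mutation count beneath the node, which sums
bottom-up by construction. Double clustering runs UPGMA independently on
exposure rows and columns and reports both trees plus their left-to-right
leaf orders; leaf order is the natural merge order without optimal-leaf-
ordering rotation. Newick export encodes branch length as parent height −
child height (leaves at height 0) with internal labels = node similarity to
4 decimals; branch lengths are printed to 10 significant digits so heights
round-trip through a standard Newick parser to well under 1e-9.

## Summary statistics

Per-sample summaries report the total and per-substitution-class subtotals,
at both per-channel and per-class granularity (the tables carry full channel
resolution; classes are sums over their 16 contexts). Two-sample comparison
tables list both spectra and their difference per channel, with the cosine
similarity and the residual sum of squares of the difference.

Grouped boxplots use log10 of the per-sample total (the log base is a
package convention), linear-interpolation quantiles, and Tukey whiskers at
the most extreme observation within 1.5×IQR of the box, clamped to the box
when every observation on one side is an outlier (a whisker may not sit
inside the quartile box). Zero-total samples have no logarithm and are
excluded with a warning rather than failing the whole plot.

## Synthetic catalogs

The simulator defines the conditions every recovery claim is tested under:
50 samples, 5 signatures, 3 active signatures per sample, lognormal burden
with mean 5000 and coefficient of variation 1 (heavy right tail, mimicking
the orders-of-magnitude spread of real per-sample mutation counts), Poisson
counting noise, seed 20240119. Signature profiles are symmetric
Dirichlet(0.1) draws over the 96 channels — a small concentration gives the
spiky, nearly disjoint profiles characteristic of reference signatures;
per-sample relative weights are Dirichlet(1). Noise modes: independent
Poisson per channel (default), multinomial with the rounded burden as total
(row sums then equal the burden exactly), or none (rounded expectations).

Randomness uses one root seed with fixed-offset substreams (one for the
signatures, one per sample), so identical specs are bit-identical and adding
samples never reshuffles earlier ones.

For exact-recovery checks, `generate_noiseless_catalog` quantizes profiles
to a 1/1000 grid (the column remainder absorbed by the largest entry) and
draws exposures as integer multiples of 1000, so expected counts are
integers computed in exact integer arithmetic: the catalog equals
signatures · exposures with *no* rounding, and a correct solver must refit
it to zero residual. Plain `noise="none"` rounds real-valued expectations
and therefore leaves a small, irreducible rounding residual — it is not the
tool for exactness claims.

What the simulator does **not** emulate: trinucleotide opportunity weighting
by genome content, inter-signature correlation structure, cohort-level
covariates, or sequencing-artifact signatures. Passing recovery tests shows
the estimator is correct under the stated generative model, not that real
tumors decompose this cleanly; flat or highly collinear signature sets
(large Dirichlet concentration) will recover worse, as for any refitting
method.

## Problem sizes and numerics

The test suite and the acceptance script run at the sizes stated above
(200 solver instances with ≤6 channels × ≤4 signatures against grid
search, 100-sample noiseless and 50-sample Poisson catalogs, 100 random
distance matrices with n ≤ 8 against the naive UPGMA reference, 100 random
boxplot groups), which keeps a full run within seconds while exercising
every branch of the algorithms. The grid-search oracle is exhaustive for
k ≤ 2 and cyclic coordinate descent on the same 0.01 grid for k ≥ 3 (the
objective is convex, so sweeps converge to the per-axis grid optimum).

## Known limitations

- No de-novo signature extraction (NMF): only refitting against a fixed set.
- No variant-file (VCF/MAF) ingestion; catalogs are the entry point.
- Heatmap rendering, force-directed layout and dimension reduction are out
  of scope; the package emits the sorted matrices, trees and plot-ready
  tables and leaves drawing to the consumer.
- UPGMA is O(n³) as implemented — ample for cohort-scale sample counts
  (hundreds), not for tens of thousands of leaves.
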