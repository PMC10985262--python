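# Methods

## Scope and data model

`danpkit` analyses expert influence panels over a two-level factor system:
ordered *dimensions*, each an ordered list of *criteria*. The flat criterion
order of the configuration file is semantic — it is the canonical row/column
order of every matrix in the pipeline, and the contiguous runs of criteria
belonging to one dimension define the block structure used by the supermatrix
construction. Criterion codes are normalised (uppercased, whitespace and
typographic markup stripped) so configs, CSV headers and published tables
compare cleanly. Each dimension must contain at least two criteria, because
block normalisation divides by within-block row sums.

The bundled system is a work-from-home mental-health factor model with three
dimensions — work-related stressors (7 criteria), non-work stressors (6),
communication issues (5) — 18 criteria in total.

## Pipeline

**Aggregation.** Expert matrices are integer 0–4 with a zero diagonal;
self-influence is undefined on the scale, so a non-zero diagonal is rejected
rather than silently zeroed, and incomplete long-format matrices are rejected
rather than imputed. The direct-influence matrix `A` is the entrywise panel
mean.

**Normalisation.** `δ` is the larger of the maximal row sum and maximal
column sum of `A`, and `D = A/δ`. Every row and column sum of `D` is then at
most 1, with equality on the arg-max line. An all-zero `A` (degenerate panel)
is an error. A useful consequence: multiplying every rating by the same
positive constant changes `δ` but leaves `D`, `T` and all downstream weights
untouched.

**Total influence.** `T = D(I − D)⁻¹`, the closed form of the geometric
series of direct and indirect influence. It is computed by a linear solve on
`(I − D)` rather than an explicit inverse; the solve is refused when the
reciprocal condition number (1-norm) falls below 1e−12, which catches
normalisations whose influence series does not converge (e.g. a row-stochastic
`D`). `T_D`, the dimension-level matrix, takes the arithmetic mean of each
(dimension, dimension) block of `T`; dimension-level indices are computed from
`T_D`, not from sums of criterion indices — the two differ by the block-size
normalisation, and the block-mean convention matches the magnitudes of
published dimension rows.

**Indices and INRM.** Give `u` = row sums, receive `r` = column sums,
center `u + r`, net `u − r`. A factor is in the cause group only when its net
is strictly positive; net = 0 is assigned to the effect group so the
partition is deterministic at the boundary. The INRM places factors at
`(center, net)` and keeps an arrow `i → j` when `t_ij` is at or above the
threshold. No universal threshold convention exists; the default is the mean
of the off-diagonal entries of the matrix in use (evaluated per map), and any
numeric cutoff can be supplied. The dimension map uses `T_D`; criteria maps
are drawn per dimension from the diagonal blocks of `T`. Raising the
threshold can only remove edges; a threshold that removes all of them yields
a node-only map with a warning, not an error.

**Supermatrices.** The unweighted supermatrix `W` normalises each row
segment of each block of `T` to sum 1 and transposes the result, so every
block-column of `W` is stochastic. A zero within-block row sum means a
criterion exerts no influence on an entire dimension; this is reported (with
the criterion and dimension codes) instead of patched, since the resulting
column would be undefined. The weighting matrix `Q` is the transposed
row-normalised `T_D`; scaling block `(o, p)` of `W` by `Q[o, p]` yields the
weighted supermatrix `V`, whose columns sum to 1 by construction. The code
verifies this to 1e−6 and then renormalises columns exactly, so the
convergence loop starts from a machine-precision stochastic matrix; a larger
deviation indicates an upstream defect and is an error.

**Limiting weights.** The limit of `V^ρ` is computed by repeated squaring
(cap 64 squarings) until the iterate stops changing (1e−10). Convergence is
declared when the columns of the power agree; a chain that stops changing
while its columns still disagree is either periodic — period 2, resolved by
the Cesàro average of consecutive powers, which is the stationary
distribution of an irreducible periodic chain — or reducible, in which case
the weights would depend on initialisation and the run fails loudly rather
than averaging silently. The limiting column is renormalised to sum exactly
1. Dimension weights are defined as the sums of their member criteria's
limiting global weights (a separate limit of `Q` would be a second source of
truth and does not reproduce the `global = dimension × local` identity);
local weights divide global weights by the dimension weight, so the identity
holds to machine precision before any rounding.

**Ranking.** Rank 1 is the largest weight; ties are broken by canonical
factor order, so ranks are always a permutation of 1..k and re-runs are
bitwise reproducible. Ranking happens on full-precision values; rounding is
display-only.

**Consensus gap.** For a panel of ϑ experts,
`gap = (1/(n(n−1))) Σ_{i≠j} |a^{(ϑ)}_{ij} − a^{(ϑ−1)}_{ij}| / a^{(ϑ)}_{ij}`,
where `a^{(ϑ)}` averages all experts and `a^{(ϑ−1)}` the first ϑ−1.
Off-diagonal cells with `a^{(ϑ)}_{ij} = 0` contribute 0: a zero mean over all
experts forces a zero mean over the first ϑ−1, so the cell is perfectly
stable. The statistic deliberately depends on expert order — it measures the
marginal perturbation by the most recently added respondent, the quantity
behind the conventional "gap < 5%" stopping rule. Other panel-stability
definitions exist; users with a different convention can compute their own
from the per-expert matrices.

## Display rounding

Published influence tables round to 3 decimals. Machine outputs (CSV, JSON)
carry full precision so conservation identities (global weights summing
to 1, give/receive grand-sum equality) survive a file round trip; 3-decimal
rounding appears only in the plain-text report, half-away-from-zero so
positive and negative net values are treated symmetrically.

## Synthetic panels

The generator emulates a briefed expert panel rating a known latent
structure:

* **Ground truth** `A*`: each (dimension, dimension) block gets a mean
  intensity on the 0–4 scale (default 2.5 — moderate coupling), plus
  entrywise uniform jitter of half-width 0.5 so criteria are distinguishable;
  designated cause criteria get +0.7 on their outgoing rows, making the sign
  of their net influence known by construction. Per-criterion row/column
  overrides allow extreme cases (e.g. a pure source). Entries are clipped to
  [0, 4]; diagonal zero.
* **Experts**: `e_ij = clip(round(A*_ij + N(0, σ)), 0, 4)`, diagonal forced
  to 0, experts independent, everything reproducible from one seed. The
  default σ = 0.5 is about half a scale step of disagreement; the default
  panel size 33 mirrors the survey the bundled factor system comes from.

What this does *not* emulate: correlated experts (shared background, herding),
demographic strata, systematic response styles (acquiescence, scale
compression), and missing responses. Rounding and clipping bias the panel
mean near the scale edges (an entry at 4 can only be under-reported), so
recovery guarantees are stated for interior entries; at σ = 0.5 the rounding
bias on interior entries is far below the sampling noise. Passing recovery
tests therefore show the pipeline inverts its own response model — they do
not certify behaviour under real panel pathologies.

## Test instance model and problem sizes

Property tests run on random 18-criterion instances (the bundled block
structure) and on small hand-built systems. For checks that compare the
closed-form `T` against the 60-term partial sum of the influence series to
1e−8, instances draw per-row intensity factors from U(0.2, 1): factors in
real panels differ in overall influence strength, and the resulting spread of
row sums keeps the spectral radius of `D` near 0.65, where 60 series terms
resolve `T` to well below the tolerance. (A perfectly homogeneous random
matrix drives the spectral radius toward the 0.74 boundary at which 60 terms
no longer suffice — such panels, where every factor influences everything
equally, are also the least informative for the method.)

Recovery checks use panels of 100 experts (ranking recovery, Spearman ≥ 0.95
against ground-truth weights) and 500 experts (aggregate recovery within 0.1
on interior entries); the study-sized end-to-end fixture uses 33 experts and
completes in well under a second. The full suite runs in a few seconds on one
CPU.

## Known limitations

* One aggregation rule (arithmetic mean) and one crisp 0–4 scale; no fuzzy or
  grey DEMATEL variants, and no Saaty pairwise-comparison ANP input mode —
  DANP replaces it by construction.
* Factor systems are strictly two-level; criteria cannot be shared across
  dimensions.
* The consensus gap is one of several panel-stability conventions in use;
  published figures computed under a different convention will not match it
  exactly.
* Reducible influence networks (isolated factor clusters) are rejected, not
  analysed per component.
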