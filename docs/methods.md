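# Methods

This note documents the models and procedures the package implements,
the defaults that matter, what the synthetic-data generators do and do
not emulate, and the numerical choices made where the design was open.

## TSS consolidation

Raw CAGE peaks are merged per gene by a single left-to-right pass over
peaks sorted by their strand-aware 5′ point (interval start on `+`,
`end − 1` on `−`). A peak joins the open cluster iff (i) its 5′ point is
within `max_dist_bp = 100` (inclusive) of the nearest member's point and
(ii) the Pearson correlation between its tissue-sample vector and the
cluster's *current summed* tissue vector is ≥ `min_corr = 0.7`.
Correlation uses tissue-category samples only; a zero-variance tissue
vector is assigned r = 0 and therefore never merges. Merged profiles are
per-sample sums, so total TPM is conserved; merged spans are interval
unions. The single-pass-vs-summed-profile rule was chosen because only a
pairwise criterion is given by the underlying method description; the
pass is deterministic and, on typical data, idempotent (re-merging the
merged output changes nothing, which the tests assert on the hand-traced
fixture — it is not a theorem for adversarial inputs).

Filtering keeps a promoter iff max tissue TPM ≥ 1 **or** max
primary-cell TPM ≥ 5 **or** max cell-line TPM ≥ 5 (all inclusive).
Naming sorts promoters of a gene by total TPM over **all** samples,
descending, ties broken by ascending start coordinate, and assigns pA,
pB, …, pZ, pAA spreadsheet-style.

Expression classes partition promoters: `noise` (max tissue TPM < 1),
`low` (< 5), otherwise `broad` when more than `broad_n = 10` tissues
exceed 5 TPM and `specific` when at most 10 do (exactly 10 is therefore
specific; the source rule leaves n = 10 unstated). Rather than forcing a
hard "same organ" requirement into the specific call, the class carries
`dominant_organ` (largest share of summed tissue TPM), its share, and a
`multi_organ` flag — known biology includes organ-spanning specific
promoters, so no hidden reclassification is applied.

Novelty calling matches a promoter's 5′ point against same-strand
annotated starts point-to-point within ± 50 bp; equidistant candidates
resolve to the 5′-most one (lower coordinate on `+`, higher on `−`).

Domain-composition grouping (activation domain AD, DNA-binding domain
DBD, domains B and C, dimerization domain DIM): group 1 = all five,
group 2 = all but AD, group 3 = DBD only, group 4 = no DBD, anything
else = `other` (an explicit catch-all added because the four named
groups do not cover the composition space).

## PWM scanning

From a 4×L count matrix, column probabilities are
`p(b,j) = (n(b,j) + κ·q(b)) / (N_j + κ)` with background `q` (uniform by
default) and pseudocount `κ = 0.8` distributed by background — the
common JASPAR-ecosystem convention; the scanner the original analysis
relied on does not publish its exact pseudocount, so κ is configurable.
Scores are `log2(p/q)` sums; the relative score normalizes by the
achievable range `[S_min, S_max]` (sums of per-column minima/maxima).
Both strands are scored at every start position (reverse strand via the
reverse-complemented matrix); windows containing N are skipped entirely
rather than scored against background, avoiding threshold artifacts at
masked bases. All overlapping hits are reported; no greedy masking.
A `≥` comparison with a 1e-12 guard keeps hits that sit exactly at the
threshold despite float rounding.

The exact score distribution uses dynamic programming on the integer
lattice obtained by rounding each matrix entry to `granularity = 1e-3`:
column distributions under the background are convolved, and
P(S ≥ s) is read off the tail. The reported tail point is exact for the
rounded matrix; relative to the unrounded score the error is bounded by
L·granularity in score units (the tests bracket the DP value between
exhaustive-enumeration tails shifted by ± L·granularity).

## Positional enrichment

Hit offsets (5′-most base of the match, TSS-relative) from foreground
windows and from a 10× background are binned at 50 bp over
−5000…+2000 (140 bins) and converted to hits/window/bp, so total hit
counts are conserved. Bin-then-smooth was chosen over kernel density
because it matches density-frequency plotting and gives the smoother a
well-defined per-bin error model.

Smoothing is loess: at each grid point the nearest ⌈0.75·n⌉ points are
fit by weighted least squares on a local quadratic with tricube weights;
the pointwise band is fit ± t₀.₉₇₅,ν · SE with ν = n_local − 3, where
SE² = σ̂²·‖l‖² from the local linear smoother and σ̂² is the weighted
residual variance with an n_local/ν small-sample correction. Constants
and exact quadratics are reproduced to machine precision with zero-width
bands. Known limitation: as with any loess interval, coverage of the
*true* curve degrades when curvature is large relative to the span
(smoothing bias); at the gentle curvatures of TSS-relative density
profiles, simulated coverage of the 95% bands is ≈ 94%.

Window calling: the **robust** window is the longest contiguous run
(≥ 2 bins, suppressing single-bin artifacts) where the foreground lower
band strictly exceeds the background upper band — enrichment direction
only, band-separated depletion is never called. The **permissive**
window extends the robust run outward to the last grid point where the
fitted foreground–background difference is still positive before a sign
change, or to the span edge (flagged, since "curves touching without
crossing" is otherwise ambiguous). One window pair is reported;
secondary separated runs do not widen the permissive bound.

## TFBS over-representation

Foreground promoter windows (−5000/+2000) and enhancer windows (± 200 bp
of midpoints) are pooled; overlapping foreground intervals are merged
before counting so clustered TSS cannot double-count the same sequence.
Scannable positions are counted as 2·(len − L + 1) per sequence minus
N-skipped windows — the denominator the z-score needs.

The background is sampled 10-fold from a pool, matched on GC fraction
(N-free numerator and denominator) in 0.05-wide bins; exhausted bins
spill to the nearest non-empty bin, ties to the lower-GC bin, with a
logged warning. The z-score is the continuity-corrected binomial
`z = (x_fg − p·N_fg − ½) / √(N_fg·p·(1−p))` with `p` the background hit
rate; σ = 0 degenerates to z = 0 with a warning. Calling uses the mean
and sample (n−1) standard deviation of all profile z-scores with a
strict `z > m + 2·sd` threshold. Under a shared foreground/background
generative law the z distribution is approximately standard normal
(simulated: |mean| ≲ 0.2, sd ≈ 1.1), and the m + 2·sd rule calls ≈ 2.3%
of null profiles, matching the normal tail.

## Co-expression clustering

Distances are 1 − Pearson r between expression rows (constant rows are
excluded with a warning; in the correlation matrix they carry r = 0 off
the diagonal). The UPGMA tree is built in-package so the tie-break is
fully specified — ties in the minimum distance resolve to the pair whose
lexicographically smallest member labels sort first — making the tree
invariant to row input order; heights match an independent
`scipy.cluster.hierarchy` recomputation in the tests.

Bootstrap support resamples *sample columns* with replacement (the
clustered objects are profiles over samples) at scales
ρ ∈ {0.5, 0.6, …, 1.4}, rebuilding the tree `nboot` times per scale.
Clade identity is the exact leaf set. BP is the recovery frequency at
ρ = 1; AU comes from the weighted least-squares fit of
z(ρ) = −Φ⁻¹(BP_ρ) to d√ρ + c/√ρ with weights nboot·φ(z)²/(BP(1−BP)),
AU = 1 − Φ(d − c); scales with BP ∈ {0, 1} are dropped from the fit, and
clades never/always recovered get AU = BP = 0/1 without fitting. Note
that AU deliberately exceeds BP for most unstable clades — that bias
correction is its purpose — so the two are not expected to agree
numerically away from the endpoints. The conventional 0.5–1.4 scale grid
is adopted; the original analysis does not state its grid.

## Enhancer linking

Candidates are all same-chromosome enhancers whose midpoint
(left-of-center base for even lengths) lies within ± 500 kb (inclusive)
of a promoter's TSS point; reported distances are strand-oriented.
Spearman rho uses average ranks; the two-sided p-value uses the
t-approximation t = ρ√((n−2)/(1−ρ²)) (cross-checked against
`scipy.stats.spearmanr`). Benjamini–Hochberg q-values are pooled over
*all* tested pairs (global pooling; per-promoter correction would be the
alternative) and significance is strict q < 0.05, with a relative float
guard so q-values equal to the threshold up to rounding are excluded.
Correlation spans all samples by default (configurable to a category).
Negative links are flagged significant too, not dropped — the direction
is part of the result.

## qPCR quantification

Within a biological replicate, technical Cts are averaged on the Ct
scale before any exponentiation; per-gene ratios are `E_g^(ΔCt_g)` with
ΔCt = Ct(scr) − Ct(test), so knockdown-induced up-regulation gives
fc > 1; the target ratio is divided by the geometric mean of the
reference ratios (two-reference generalization of the
efficiency-adjusted ratio method). Significance is a two-tailed
one-sample t-test of log₂(fc) against 0 — fold changes are
multiplicative, so the log scale is the natural test scale; a
two-sample alternative against a control fc group is available via
`fc_significance(..., control_fc=...)`. Reported summaries are the
geometric-mean fc and a delta-method SEM on the fc scale. Fewer than 3
replicates or zero variance yield a missing p-value with a warning,
never a fabricated one.

## Synthetic data: what it emulates, and what it does not

Defaults mirror the scale of a large CAGE atlas study of an 8-member TF
family: 135 tissue samples across six organ systems, 170 primary-cell
and 255 cell-line samples; ~33 raw TSS with planted broad / specific /
low / noise archetypes and seven same-promoter peak pairs placed within
100 bp; −5000/+2000 promoter windows over an i.i.d. background (GC 0.5)
with motif instances planted Poisson(rate) at configurable positional
laws (default normal(0, 300 bp), rate 2 per foreground window vs 0.5
uniform in a 10× background); annotation starts at a fixed cycle of
signed offsets (5/8 within ± 50 bp, echoing the roughly 60% annotation
match rate such studies report); 13 enhancers, alternately
copula-correlated at ρ = 0.8 and independent, some beyond ± 500 kb as
negative controls; and Ct tables with 6 biological × 3 technical
replicates, efficiencies 1.9–2.0 and Ct noise sd 0.1 cycles.

Specific points worth knowing:

- TPM noise is multiplicative log-normal (σ = 0.5) with exact zeros for
  zero means; merge-partner peaks are *proportional copies* (factor 0.5)
  of their primary peak's realized profile, modelling the near-identical
  profiles of CAGE peaks of one promoter and making the planted merges
  deterministic ground truth.
- "Specific" archetypes are expressed in 8 tissues of one organ so the
  broad/specific boundary (> 10 tissues) is actually exercised on both
  sides under noise.
- Planted motif instances are sampled from the PFM's per-column
  frequencies (not consensus), so the 80% relative-score threshold
  genuinely filters them. The synthetic X-box profile is a 14-column
  imperfect inverted repeat; random panel profiles use Dirichlet(0.2)
  columns, i.e. information contents comparable to curated vertebrate
  profiles.
- Enhancer profiles use a Gaussian copula on the paired TSS profile's
  normal scores with r = 2·sin(πρ_s/6), achieving the target Spearman
  within ± 0.1 at n ≥ 50; ρ = 1 degenerates to an exact monotone
  transform.
- Each generator draws from its own `default_rng([seed, stream])`, so
  outputs are byte-identical under a fixed seed and independent of call
  order, and every generator emits a truth table sufficient to score its
  downstream stage.

Not emulated: donor replicates and time courses, chromatin context,
dinucleotide or isochore sequence structure, mappability, and any real
genome/annotation/motif release. Passing tests therefore demonstrate
the *algorithms* behave as specified under controlled conditions; they
do not certify performance on real CAGE data, where heavy-tailed
expression, correlated backgrounds and annotation idiosyncrasies are
harsher than the generators here.

## Problem sizes used by the test suite and acceptance script

Simulation sizes were chosen as the smallest that make the statistical
assertions stable: positional recovery uses 200 foreground / 2000
background windows over 20 seeds; z-score calibration uses 50 profiles
over 50/500 windows of 500 bp; bootstrap support uses nboot = 500 at 8
rows (the CLI default remains nboot = 1000); link calibration uses 400
pairs × 50 simulations; qPCR recovery uses 100 simulations. The
end-to-end smoke run uses the default synthetic configuration
(33 raw TSS, 330 background windows, 50-profile panel).
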