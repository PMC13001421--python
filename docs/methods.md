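# Methods

This note records the models, estimators and design choices behind
`somaclock`, in the order the pipeline runs them.

## The clock model

Each post-mitotic cell is assumed to carry somatic mutations from two
processes: *clonal* (developmental) mutations acquired on the branches of a
cell-division lineage before the cell's terminal division, shared by all
cells descending from the same branch; and *private* mutations acquired
after the terminal division at a constant annual rate. For a cell whose
lineage became post-mitotic at time `t_term` (years from the zygote) in a
donor of age `A`,

    E[private burden] = β₀ + β₁ · (A − t_term),

with `β₁` the annual accumulation rate and `β₀` the mutations present at the
start of the ageing clock. Because `t_term` is small relative to adult ages,
regressing per-cell burden on donor age recovers `β₁` with the intercept
absorbing `β₀ − β₁·t̄_term`. Counts are extrapolated genome-wide before
fitting: `burden = n_calls / callable_fraction`, where the callable fraction
is the portion of the genome in which the genotyper could have detected a
variant in that cell.

### Rate estimation

With one donor per age — the usual cross-sectional design — per-cell errors
are perfectly confounded with donor-level effects: no estimator can separate
subject random intercepts from residual structure. `fit_rate` therefore runs
OLS on subject-mean burdens with `t` inference on `n_subjects − 2` degrees of
freedom, which is valid whether or not donor-level effects exist (subject
means are independent across donors either way), and logs a notice. When
subjects outnumber distinct ages, a random-intercept linear mixed model on
per-cell burdens is used instead. An earlier candidate — per-cell OLS with
cluster-robust errors — was rejected because with ~4 clusters its variance
estimate is too noisy to give nominal CI coverage; the package's own coverage
check (95% CI covering the true rate in ≥90% of replicates) drove the choice.

`compare_rates` fits one pooled model over subject-mean burdens with a
per-celltype intercept and slope (cell-means coding) and reports each
pairwise slope difference with a studentized-range (Tukey) adjusted p-value,
`p = SR_sf(|t|·√2; k, df)` with `k` cell types and residual degrees of
freedom from the pooled fit. SNV and indel families are corrected
separately.

## Spectra

SBS96 channels follow the canonical pyrimidine-centred convention: a
substitution whose reference base is a purine is reverse-complemented
(context and alternate allele) before classification, giving six
substitution classes × 16 flanking contexts in fixed COSMIC column order.
ID83 channels encode indel type, size (1–5+, strand-collapsed C/T motif for
1 bp events), homopolymer/tandem-repeat context and, for non-repetitive
deletions ≥2 bp, flanking microhomology length. Every indel is trimmed to a
parsimonious representation and left-aligned against the reference before
classification, so VCF dialect differences in anchor placement cannot change
a channel. Events that are neither pure insertions nor pure deletions after
trimming are tagged `unclassifiable`: they are excluded from spectra but
still counted in burdens (burden is a count of calls; a spectrum is a
classification).

Spectrum similarity is the cosine of raw count vectors — scale-invariant, in
[0, 1].

## Signature refitting

Exposures solve the non-negative least-squares problem
`min ‖spectrum − C·x‖₂, x ≥ 0` over the active catalog columns (columns sum
to 1, so `x` is in mutation counts). Signature selection is forward
stepwise: starting from a clock-like base set ({SBS1, SBS5} for SNVs, empty
for indels), repeatedly add the signature with the largest
reconstruction-cosine gain while the gain is ≥ `threshold` (default 0.01),
then prune any signature whose removal costs < `threshold/2`, iterating to a
fixed point. Ties break on signature id, making selection deterministic and
invariant to catalog column order. The gain criterion is the field-standard
refitting heuristic; the threshold is exposed because the trade-off between
sparsity and fit is genuinely data-dependent.

Per-mutation attribution uses the channel posterior
`P(sig | channel) ∝ exposure_sig · catalog[channel, sig]` over the sample's
selected set, with MAP ties broken by id order and zero-mass channels
labelled `unattributed`.

The packaged catalog is **synthetic**: a CpG-concentrated C>T column
("SBS1"), a flat mildly T>C-tilted column ("SBS5") and seeded Dirichlet
columns tilted toward one substitution class each, plus 1-bp-channel indel
columns ("ID1", "ID2", "ID5", "ID9"). The familiar names make mixtures read
naturally, but the columns are constructed, not measured; analyses of real
data should load a real catalog TSV.

## Enrichment

Expected counts come from relocating every mutation to a random callable
position, `n` times (default 1,000, seeded). Two modes: `uniform`, and
`context-matched`, where the destination's collapsed trinucleotide must
equal the source context — the default for substitutions because
trinucleotide composition differs systematically between genic and
intergenic sequence and would otherwise masquerade as enrichment. Records
whose context has no callable site fall back to uniform with a logged count.
The enrichment ratio is `observed / mean(permuted)`; the two-sided empirical
p is `(1 + #{|perm − mean| ≥ |obs − mean|}) / (n + 1)`; Benjamini–Hochberg
q-values are reported across classes within a track. Ordered (quantile)
tracks get a trend test: Pearson correlation of the mean per-subject
obs/exp ratio against bin rank. Functional-impact labels are consumed, not
computed; impact fractions are compared across cell types with two-tailed
Mann-Whitney tests on per-cell fractions.

## Lineage reconstruction and MRCA dating

Variant identity is `(chrom, pos, ref, alt)`. A variant is a shared marker
when carried by ≥ `min_cells` cells (default 2) or present in the bulk
clonal table (and carried by ≥2 cells); carrier sets with ≥ `min_support`
markers (default 2 — singleton support is amplification-artifact-prone)
become candidate clades. Candidates violating laminarity are resolved
greedily: order by support, then cell count, then lexicographic cell ids,
and accept a candidate only if it nests with everything accepted so far
(conflicts are logged). Surviving clades nest into a rooted tree; every
shared variant is assigned to the smallest clade containing all its
carriers, private variants to their cell's leaf. Branch length is the
assigned variant count. The disjoint-paths invariant (no variant on two
branches of one root-to-leaf path) is asserted on every built tree.

A clade's MRCA is dated from its descendants' extrapolated private sSNV
burdens:

    t = A − (center(burdens) − offset) / β₁,

with `center` the mean (median available), `offset` defaulting to the fitted
intercept (mutations not attributable to post-MRCA ageing) and a
delta-method CI combining the burden-mean standard error with the slope and
intercept standard errors. Estimates beyond the donor age are clipped and
flagged. This estimator targets the time the clade's cells became
post-mitotic; when divisions continue after the clade's founding the true
founding time is earlier, so dates are upper bounds in that regime. Indels
are excluded from the dating burden — the clock is the sSNV rate. The time
axis has the zygote at 0; birth is at the fertilisation offset (0.75 yr), a
configurable constant.

## Intermixing tests

For a clade partitioned into subclusters `s` (its immediate child clades,
unclustered leaves as singletons), the region-mixing deviation index is

    D = Σ_s (n_s / N) · |f_CH(s) − f_CH(clade)|,

zero exactly when every subcluster mirrors the clade's CH:V ratio. The
nearest-neighbour statistic is the mean fraction of each cell's `k` nearest
tree neighbours (path length in branch variants, private branches included;
ties broken by cell id; default `k = 3`, reported in output) sharing its
region. Both grow with segregation, so permutation tests are one-sided
(`p = (1 + #{null ≥ obs}) / (n + 1)`) against uniform label shuffles that
preserve marginal counts — within the tested clade for the deviation index,
tree-wide for neighbour match. Neighbour lists do not depend on labels and
are computed once per test. Degenerate (single-region) label sets return
p = 1 with a flag.

## The synthetic-data generator

What it emulates: an i.i.d.-base genome at a configurable GC fraction
(default 0.41, human-like); layered annotation tracks (genic/intergenic with
internal UTR/exon/intron structure, expression deciles over genes,
replication-timing and accessibility window quantiles); a timed
developmental lineage (division schedule → tips → cells) with
Poisson(`clonal_mu`) mutations per branch from a developmental signature
mixture and Poisson(`β₀ + β₁·(A − t_term)`) private mutations per cell from
an ageing mixture; SBS placement at genome sites whose collapsed
trinucleotide matches the drawn channel (sampled without replacement per
channel, so truth sets never collide); 1-bp indel placement at homopolymer
runs matching the drawn ID83 channel; CH/V region labels assigned per
top-level clade and flipped per cell with probability `region_mixing/2`
(0 = perfect segregation, 1 = i.i.d. labels); and per-cell detection
thinning with probability `detect_sensitivity[depth] ×
callable_fraction[depth]`, so that dividing surviving counts by the callable
fraction is unbiased at sensitivity 1.

Key defaults mirror the aged-cerebellum study design: ageing rate 27
sSNV/yr over intercept 100 and 1.86 sIndel/yr; donor age 82.7 with 64 cells;
postnatal division schedule ending around one year with `clonal_mu = 60`
(tens of mutations per early postnatal branch, consistent with a ~27/yr
clock running over months-to-years of expansion); depth classes {30X, 10X}
with the 10X sensitivity an explicitly free knob (no published value
exists); `region_mixing = 1.0`, matching the finding that anatomical labels
are statistically indistinguishable from random mixing. A single seed
drives everything, with per-subject substreams so subject simulations are
order-independent.

What it does not emulate — and hence what passing recovery tests do not
show: amplification artifacts and allelic dropout structure, repeats and
realistic chromatin (the genome is i.i.d.), CNVs/SVs, read-level error,
multi-bp repeat/microhomology indel *placement* (the classifier handles all
83 channels; the generator places the 1-bp homopolymer channels its
synthetic indel catalog uses), and correlated detection between nearby
variants. Recovery on synthetic data demonstrates the estimators are
correct under the stated model, not that the model captures every failure
mode of real single-cell data.

## Numerical and degenerate-input choices

- NNLS via `scipy.optimize.nnls`; unselected exposures are exactly 0.
- Probability vectors validated to 1 ± 1e-9; catalog columns to 1 ± 1e-6.
- Empirical p-values use the add-one convention, never 0.
- Saturated designs (2 subjects, 2 ages) report zero-width CIs rather than
  dividing by zero residual degrees of freedom.
- Zero spectra: aggregation returns empty groups silently; cosine raises.
- Context-matched permutation falls back to uniform (logged) for contexts
  with no callable site; classes never hit by any permutation are flagged
  unreliable.
- Tree tie-breaks (conflict resolution, MAP attribution, neighbour ties) are
  all lexicographic, making every pipeline stage deterministic given seeds.

## Validation problem sizes

The validation battery (`somaclock.validation`, driven by
`tests/test_acceptance.py` and `scripts/acceptance.py`) uses: 100 replicate
4-donor cohorts (ages 20/42/59/83, 25 cells each) for rate coverage; 50,000
mutations for the 60/25/15 stepwise-selection experiment; one 32-cell
two-mixture lineage for the clonal/private split; one 64-cell five-division
lineage (62 true clades) for tree fidelity at sensitivities 1.0 and 0.9; 50
replicates of a 24-cell three-clade donor (terminal times 0.5/1/2 yr) for
MRCA coverage; 1,000 permutations on a 1 Mb genome for enrichment
calibration (10,000-mutation null, 200-window p-uniformity, 10× forced
concentration); and 100 replicates per condition (region_mixing 0 and 1,
64 cells, young donors to keep burdens small) with 199 permutations for
intermixing power and size. All sizes are the package's own choices to keep
the battery in the minutes range on one core.

## Known limitations

- The stepwise criterion is a documented stand-in for the cited refitting
  method's unpublished stopping rule; exposure percentages are sensitive to
  the catalog version supplied.
- With one donor per age, donor-level confounders (postmortem interval,
  amplification quality) are statistically inseparable from age; the
  estimator is honest about this (subject-level inference) but cannot fix it.
- MRCA offsets: the default `offset = fitted intercept` is one defensible
  correction; the original model-based correction is not public, and the
  offset is exposed as a flag.
- The greedy laminarity resolution is simple and deterministic but not
  optimal; heavily conflicting data (low sensitivity, high artifact rates)
  would warrant probabilistic phylogeny methods, which are out of scope.
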