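# Methods

## The evaluation model

Salt tolerance is treated as a latent, quantitative property of an
accession that expresses itself across many correlated traits. The
pipeline's estimand is an ordering of accessions, not an absolute
tolerance scale, and every stage is built around that:

**Salt-tolerance coefficient.** `STC(i,j) = mean_salt / mean_control`
per accession × trait, computed as a ratio of treatment means rather
than a mean of per-replicate ratios: dishes and pots are independent
between treatments, so per-replicate pairing would be artificial. The
ratio cancels units and baseline genetic differences; all 22 registry
traits are scored higher-is-better, so no trait is inverted before
evaluation. Control means must be strictly positive (a zero-control
trait is not evaluable as a ratio); salt means may be zero, e.g. total
germination failure. Missing cells are a hard error by default; an
opt-in `trait_mean` imputation fills a missing cell with the trait's
mean STC and is recorded in the run manifest.

**Correlation screen.** Pearson r with the two-sided t-test p-value
(df = n − 2) for every trait pair. The pruning rule — drop a trait
with fewer than 2 significant positive correlations at p < 0.01 —
codifies the verbal practice of discarding traits uncorrelated with
the rest of the battery; negative correlations never count toward
retention, since a trait moving against the battery is disqualifying
rather than supporting evidence. No multiple-testing correction is
applied by default, matching the per-pair reporting convention of this
assay literature; a Bonferroni switch exists. Both the threshold and
alpha are configurable, and the screening report states the rule and
the per-trait reason for every decision.

**PCA on the correlation matrix.** Traits live on wildly different
scales (cm, g, counts, percentages), so the decomposition acts on
standardized STCs (sample sd, n − 1). Components with eigenvalue
above 1 (Kaiser rule; configurable) are retained; if none qualifies,
the first component is retained with a warning rather than failing.
Eigenvector sign is arbitrary in any eigendecomposition; each loading
column is oriented so its sum is non-negative (tie broken by making
the largest-magnitude loading positive). Because all traits are
higher-is-better, this orientation makes a higher composite score mean
more tolerant and renders D well-defined and invariant under row and
column permutations of the input.

**Membership, weights, D.** Fuzzy membership
`u = (F − min)/(max − min)` per retained component (so each component
always has one accession at 0 and one at 1; the degenerate all-equal
case maps to 0.5 everywhere rather than erroring). Weights are
contribution rates renormalized over the retained components only.
`D = Σ w_k u_k ∈ [0, 1]`; ranking is descending with ties sharing the
minimum rank ("1, 1, 3"), display order tie-broken by accession id.
Membership is computed per retained component, not per original trait:
the retained components are the mutually independent composite
indicators the method is built on.

## Germination indices

The day-count indices use the standard agronomic forms:
`rate = 100·ΣG_t/n_seeds`, `vigor = 100·Σ_{t≤d}G_t/n_seeds` with the
vigor day d defaulting to 5 (configurable — assay protocols vary, and
for courses shorter than d the whole window is counted),
`GI = Σ G_t/t` (1-based days, so earlier germination strictly
increases GI), `VI = GI × mean radicle length`, and root-bud ratio =
radicle/embryo length. The observation window is 12 days. Moldy seeds
are recorded and validated (germinated + moldy ≤ seeds sown) but enter
no index.

## The synthetic cohort generator

The generator exists to give every downstream stage a testbed with a
known answer; it emulates the screening design, not any particular
dataset. A single latent factor τ_i ~ U(0.2, 0.95) per accession
drives all 22 registry traits through power sensitivities
s_j ~ U(0.5, 1.5): the salt/control mean ratio is
`clip(τ^s_j + ε, 0.01, 1.2)` with ε ~ N(0, σ_e = 0.08). Control means
are `baseline_j · (1 + g_i)` with g_i ~ N(0, 0.1) modelling intrinsic
size differences (which the STC must cancel). Replicates are normal
with CV 0.05, truncated at zero. The upper clip at 1.2 permits
occasional STC > 1, as seen in hormesis-like responses. Defaults (57
accessions, 3 replicates, 50 seeds, 12 days) are the design constants
of the assay.

Two **decoy traits** (`decoy_ratio_1/2`) get salt/control ratios drawn
U(0.6, 1.1) independently of τ. They emulate the behaviour of
ratio-type traits like root-bud ratio or average root diameter that
real screens find uncorrelated with the battery, giving the screening
stage something it should drop. With 57 accessions the sampling sd of
a chance correlation is ≈ 0.13, so a decoy occasionally draws a real
correlation with τ and survives the screen; across seeds both decoys
are dropped in ≈ 95% of cohorts, which is the behaviour the validation
asserts rather than per-seed certainty.

Germination courses are drawn multinomially per dish over days 1..12
from a discrete logistic hazard (control: plateau 0.92, midpoint day
3; salt: plateau 0.92·τ, midpoint 3 + 4(1 − τ), shallower slope), so
tolerant accessions germinate more, earlier. The trait table samples
all traits directly from the latent model rather than deriving the
germination-stage traits from these counts: count-derived indices are
integer-granular and would break the exact noise-off identity
STC = τ that the validation relies on. The courses are a parallel,
qualitatively consistent dataset for exercising the index formulas.

What the generator does *not* emulate: genotype-by-trait interaction
structure beyond one factor, non-normal replicate error, spatial or
batch effects, dormancy, and trait-specific measurement floors.
Passing tests therefore demonstrate that the pipeline recovers a
latent ordering under its own model assumptions — not that any real
cohort satisfies those assumptions.

## Physiology statistics

RWC = 100(FW − DW)/(TW − DW); REL = 100·C1/C2 — both dimensionless
and unit-invariant. Group comparisons use classical one-way ANOVA
(with the 0/0 no-variation case defined as F = 0) and Tukey HSD
p-values from the studentized range distribution; the compact letter
display uses the insert-and-absorb algorithm with letters assigned
from the largest mean downward, so "a" always marks the top group.
The two-sample t-test defaults to Welch degrees of freedom (equal
variances are not assumable across genotypes under stress); the
classical pooled test remains available. Assay-kit concentrations
(MDA, proline, soluble protein/sugar) are treated as given data; no
standard-curve arithmetic is implemented. The physiology generator
produces linear trends over days 1/5/9/13 of treatment — damage
markers rising, water status falling, osmolytes accumulating, each
effect doubled (or halved, for protective markers) in the sensitive
genotype — which is sufficient structure for testing the letter
displays, not a physiological model.

## qPCR quantification

Livak 2^−ΔΔCt with replicates averaged on the Ct scale and
amplification efficiency fixed at 2.0 (no efficiency correction).
ΔCt = mean Ct_target − mean Ct_reference per condition;
ΔΔCt = ΔCt_treatment − ΔCt_control; fold = 2^−ΔΔCt. Exactly one
reference gene is required; Ct values are validated to (0, 45).
A constant plate offset added to any sample set cancels in ΔCt, which
the tests assert. The qPCR/RNA-seq concordance is the R² of an OLS fit
between log2 fold-change vectors: fold changes are multiplicative, so
the log scale is the natural regression scale.

## Numerical choices

- Eigendecomposition via symmetric `eigh`; eigenvalues clipped at 0
  (tiny negatives are roundoff). The test suite cross-checks against
  an independent oracle built from the Faddeev–LeVerrier
  characteristic polynomial, companion-matrix root finding and shifted
  inverse iteration, to 1e−8 on matrices up to 7 × 6, plus the
  two-trait closed form λ = 1 ± r.
- Constant trait columns are errors at standardization (named in the
  message) and NaN-flagged in correlation output.
- Result CSVs are written at fixed `%.10g` precision so identical
  configurations produce byte-identical files.
- All randomness flows from one config seed through
  `numpy.random.default_rng`; stage-local generators derive from it.

## Validation problem sizes

The acceptance script uses the design-scale cohort (57 × 24 × 2 × 3)
throughout: 50 cohorts for the recovery median, 100 for the decoy drop
rate, 200 random matrices for the eigen oracle, 1000 three-group null
datasets for Tukey calibration and 20 000-permutation oracles for the
Welch comparison — sizes chosen so the whole validation completes in
about a minute on one CPU while keeping Monte-Carlo error well inside
the asserted margins.

## Known limitations

- The screening rule is a codified convention; real studies describe
  the outcome of trait pruning, not an explicit criterion, and other
  reasonable rules (e.g. mean-|r| thresholds) exist. The rule and its
  parameters are surfaced in every screening report.
- D values are relative to the evaluated cohort (membership rescales
  within-cohort); scores are not comparable across cohorts.
- With near-degenerate eigenvalues the component ordering — and hence
  weights — can be sensitive to perturbation; the sign-orientation
  rule guarantees determinism but not stability of near-ties.
- The borderline "both decoys dropped" rate (~95%) is a property of
  chance correlation at n = 57, not a tunable of the screen.
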