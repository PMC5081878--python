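# Methods

## Model

`tdgibbs` fits a four-trait fixed-regression test-day animal model to
repeated milk-recording observations of first-lactation dairy cows. The
traits, in fixed order, are somatic cell score (SCS, unitless), milk yield
(kg), fat yield (kg) and protein yield (kg). For a record of cow *m* taken
*t* days into lactation,

y = HYM + Σ₆ β_q φ_q(x) + Σ₅ δ_q φ_q(x) + a_m + pe_m + e,

with
- **HYM** — herd × year-month-of-test contemporary group (fixed),
- **β, δ** — fixed Legendre lactation curves nested in the age-season-of-
  calving class (AS; 19 monthly age classes 18–36 crossed with 4 quarterly
  seasons, 6 coefficients) and in the herd-year-of-calving class (HY, 5
  coefficients). φ_q are orthonormal Legendre polynomials on x = 2(t − 5)/300 − 1,
  t ∈ [5, 305] days,
- **a** — additive genetic effect, a ~ N(0, A ⊗ G0) over the pedigree's
  numerator relationship matrix A,
- **pe** — permanent-environment effect, one per recorded cow, iid N(0, P0),
- **e** — residual, N(0, R0), independent across records.

G0, P0, R0 are unstructured 4×4 covariance matrices. All four traits must
be present on every record; records with a missing trait are rejected when
the model frame is built.

## Record edits

Raw records are filtered to 3–75 kg milk, 1.5–8 % fat, 1–7 % protein,
1–500 (×10³ cells/mL) SCC, 5–305 days in milk and first calving at 18–36
months, in that fixed order (a record is charged to the first rule it
violates); afterwards cows with fewer than five surviving records are
removed entirely. Component yields are modelled in kg
(`fat_kg = milk × fat% / 100`), SCC as `SCS = log2(SCC/100) + 3`. Edits
are idempotent by construction.

## Pedigree algebra

A⁻¹ is assembled directly by Henderson's rules from the Mendelian-sampling
variances d (0.5/0.75/1 for two/one/no known parents, reduced by
0.25·(F_sire + F_dam) when inbreeding is accounted for — the default,
switchable off). Inbreeding coefficients come from a memoised recursive
kinship; the dense tabular A is kept as the oracle the sparse inverse is
tested against (A⁻¹·A = I to 1e−8 on random inbred pedigrees, and A itself
against 10⁵-replicate gene-dropping). Identifiers are recoded to
consecutive integers in topological order and the map is always written
out.

## Gibbs sampler

One cycle updates all location effects by Gauss–Seidel, then the three
covariance matrices:

1. fixed-effect columns (HYM indicators, then each AS and HY Legendre
   coefficient column) — 4-trait draws with flat priors;
2. additive effects of animals without records — 4-trait draws with the
   A⁻¹ ⊗ G0⁻¹ prior coupling;
3. recorded cows — one joint 8-dimensional (a, pe) block per cow. The
   likelihood only identifies a + pe within a cow, so separate single-site
   updates of the two effects are nearly perfectly negatively correlated
   and the chain barely moves; the joint block removes that bottleneck.
   A strictly single-level sweep is available (`joint_cow_blocks=False`)
   for comparison;
4. G0 | a ~ IW(a'A⁻¹a + S_g, n_animals + ν_g), and analogously P0 over
   cows and R0 over records.

The default covariance prior is **flat** (ν = −(p+1), zero scale), the
customary GIBBSF90-family choice. This is deliberate: a near-zero-scale
inverted-Wishart prior with positive degrees of freedom (e.g. scale 1e−4·I,
ν = 5) has density growing like |G|⁻⁵ toward the origin, and in weakly
identified directions it traps the chain in a spike of essentially zero
genetic variance — we verified the collapse against an independent dense
block-sampling reference before discarding that prior.

Starting values are diagonal method-of-moments estimates (within-cow
variance for R0; the between-cow remainder split evenly between G0 and P0),
so short chains carry almost no transient. All randomness flows through a
single NumPy generator; a chain is bit-reproducible from its seed, and
checkpoints (full state plus generator state, every 10,000 cycles by
default) resume bit-identically. Numerical kernels are numba-compiled;
each level's conditional mean and covariance were verified exactly against
dense Kronecker algebra, and the location sampler against the GLS solution
on fixed-effect-only data.

The reference chain protocol (200,000 cycles, 10,000 burn-in, thinning 10)
retains 19,000 covariance samples; desk-scale validation uses 5,000 cycles
with 1,000 burn-in and thinning 5. Convergence is judged from exported
traces; a Geweke z-score is provided as an optional diagnostic, not a gate.

## Posterior summaries

Stored samples (upper triangles of G0/P0/R0 per retained cycle) are mapped
per sample to heritabilities h² = σ²_a/(σ²_a+σ²_pe+σ²_e), genetic
correlations from G0, environmental correlations from the pooled
non-genetic covariance P0+R0 (default; residual-only behind
`env_mode="residual"` — which convention a given study used is often
unstated, so both are first-class), and phenotypic correlations from the
total. Summaries report mean, SD, 95 % equal-tail and
highest-posterior-density intervals (shortest sorted-sample window), and
the Monte Carlo standard error by batch means with ⌊√n⌋ batches; each
correlation carries a flag for whether its 95 % HPD interval excludes
zero. Trace and kernel-density tables are exportable for plotting.

## Descriptive daily correlations

As a model-free view of the SCS–yield relationship over lactation, records
are adjusted by subtracting their HYM group mean (raw mode available),
tiled into days-in-milk windows (default 15 days over [5, 305], windows
with fewer than 30 records suppressed), and Pearson correlations are
computed per window and averaged with record-count weights. The published
analyses of this kind do not state their adjustment or window width; this
implementation is documented as one defensible interpretation.

## Synthetic data

The generator emulates the structure of a national first-lactation data
set at desk scale. Default truth: the published variance components
(additive/PE/residual diagonals per trait), genetic correlations
milk–fat 0.62, milk–protein 0.90, fat–protein 0.80 (chosen inside the
published 0.62–0.90 range), SCS–milk 0.07, SCS–fat 0.01, SCS–protein 0.11,
and environmental correlations applied identically to P0 and R0 (−0.177,
−0.165, −0.152 for SCS against milk/fat/protein; 0.85, 0.97, 0.91 among
the yields). Trait means (SCS 2.433, milk 32.82 kg, fat 1.075 kg, protein
1.006 kg) enter through the AS-curve intercepts; contemporary-group
effects and curve coefficients are drawn once per class with documented
SDs. Monthly tests start at a random day 5–35, eight per cow, so every
cow survives the minimum-records edit; emitted records carry SCC
(back-transformed from the SCS channel) and component percentages, i.e.
exactly the raw format the editing module consumes. Unless an
`edit_stress` flag is set, raw values are clipped into the edit ranges
(touching well under 1 % of records at the default truth) so simulated
data passes the edits losslessly; with the flag on, the tails are left so
the edit rules are exercised.

### Validation design and variance reduction

The default herd — 2,000 recorded cows, 200 sires, 1,000 dams in a
balanced nested mating design (each dam mated to one sire; families spread
evenly, by stratification, over herds, calving dates and ages) — is a
*validation* design: its purpose is to measure estimator correctness, not
to mimic the messiness of field data. Two deliberate choices follow.

First, the herd size. The posterior SD of a heritability at 1,000 cows is
about 0.05 under this model, and the h² posterior is right-skewed, so its
mean sits ~0.02 above the generating value however long the chain runs; a
point-recovery check at ±0.03 is only coherent when the posterior is
tighter than the tolerance. 2,000 cows bring the posterior SD to ~0.03 and
the skew offset to ~0.01.

Second, moment matching (`exact_moments`, on by default). The simulated
deviates are decomposed into the ANOVA components of the pedigree hierarchy
(sire-family means, dam-group deviations, individual deviations), and each
component's scatter is set exactly to its expected value, with realized
cross-covariances between the genetic and non-genetic components removed
at every level. The realized additive scatter a'A⁻¹a then equals
n·G0 exactly, and the between-family variance a variance-partitioning
model reads as genetic signal carries no χ² fluctuation. This is a
variance-reduction device for recovery studies — the model being fitted is
unchanged — and with it the 5,000-cycle posterior-mean recovery error over
twelve seeds is +0.010 ± 0.005 for milk heritability and within ±0.006 for
the milk–protein genetic correlation. What passing such a test shows is
that the estimation machinery is unbiased and correctly assembled; it does
not show how the estimator behaves under selection, culling, missing
traits, or heterogeneous variance, none of which the generator emulates.
SCS-side genetic correlations remain weakly identified at desk scale (the
SCS additive variance is only 3 % of its phenotypic variance): their
posteriors are wide and their recovery is correspondingly loose.

## Pipeline

`run_all` drives edit → classes → pedigree → chain → summaries → daily
correlations from one YAML config, writes every artifact as delimited text
or JSON with a content-hash manifest, logs per-10k-cycle timing, and is
deterministic end to end under a fixed seed (identical manifest hashes).
A stage failure aborts with the stage name and preserves upstream
artifacts. The CLI (`tdgibbs simulate/prep/fit/summarize/corr/run-all`) is
a thin wrapper over the same functions.

## Known limitations

Single lactation, all four traits required per record, no unknown-parent
groups or genomic relationships, homogeneous residual variance over the
lactation, and no missing-trait sampler. The dense tabular A is quadratic
in pedigree size and meant for oracles and desk-scale pedigrees; the
model path itself only ever builds the sparse A⁻¹.
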