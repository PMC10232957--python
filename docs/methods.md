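# Methods

## Data model

The package operates on three containers. Replicated trial data are long
(tidy) records `(genotype, season, replicate, treatment, trait, value)` so
unbalanced designs are representable; balance is validated (every
genotype × season × replicate cell present), not assumed. Pooled
genotype-mean tables hold the fourteen canonical traits plus an optional
grain-type label; missing phenotype cells are errors because every
downstream analysis assumes complete means. Marker matrices hold one
allele call (band-size class) per genotype per locus, with `-` as the
missing token; the panel is inbred landraces scored from gel bands, so
heterozygote handling is out of scope. Genotype labels are
whitespace-normalized and matched case-insensitively across files.

The packaged reference panel (`data/genotype_means_table4.csv`) is the
pooled two-season mean table of 119 genotypes (115 landraces and the check
varieties FR13 A, IR42, CO 43, CO 43 Sub1). Its AVI column was computed by
the original analysts from replicate-level data; for low-germination
genotypes it exceeds `AGP × (SL + RL)` applied to the pooled means
(averaging a product is not the product of averages), so the formula is
asserted only where the two coincide (e.g. the maximum-vigor row).

## Classification rules

Tolerance classes partition AGP with half-open interior bounds — ≥ 90
tolerant, (70, 90) moderately tolerant, (40, 70] moderately susceptible,
≤ 40 susceptible — so fractional AGP values (granularity 100/30 with five
seeds × three replicates × two seasons) always classify. The grain-type
rule is: kernel length ≥ 6 mm is *long*, split *slender*/*bold* at
LBR ≥ 3; shorter kernels are *medium–slender* for LBR in [2.5, 3),
otherwise *short–bold*, with short–slender merged into short–bold by
default (both short groups are small in practice). These thresholds
reproduce 118/119 of the panel's printed labels; the single disagreement
(*Edakkal*, KL 5.0, LBR 2.50, labelled long–bold) is inconsistent with any
simple KL/LBR rule and is treated as a data-entry anomaly. All thresholds
are configurable via `GrainTypeRule`.

The response index defaults to the per-genotype difference of mean shoot
lengths; a per-replicate variant exists but pooled tables carry one value
per genotype.

## Variance components and variability parameters

ANOVA follows the method of moments on the balanced RCBD: within a season
σ̂²e = MS_error and σ̂²g = (MS_g − MS_e)/r; pooled over seasons, replicates
are nested within season (the seasons were independently conducted
screenings), σ̂²ge = (MS_g×s − MS_e)/r and σ̂²g = (MS_g − MS_g×s)/(rs),
with genotype tested against MS_g×s and the interaction against the pooled
error. Negative moment estimates are clamped to zero and flagged; raw
values remain available. No REML — the moment estimators are the method
the screening literature reports, and they are exactly unbiased before
truncation (verified by Monte-Carlo recovery in the test suite at the
study scale, 100–119 genotypes × 2 seasons × 3 replicates).

Genetic advance defaults to `GA = k·h²·σg` (k = 2.06, 5% selection
intensity). Reverse-engineering the published per-trait table shows this
σg form reproduces its GA column (e.g. AGP: 2.06·0.8204·29.90 = 50.53; KL:
2.06·0.9719·1.0702 = 2.143), while the textbook `k·h²·σp` form does not;
both are exposed via `ga_basis`. One published row (RI) prints GA and GAM
exactly 10× the values its own GCV and mean imply — an apparent
decimal-place slip — so tests assert the internally consistent values
there. The phenotypic-variance basis is configurable (`plot`,
`entry_mean`, `single_env`; default `single_env` for one season, `plot`
otherwise) because the original report's basis is not recoverable: its
pooled variance components are not numerically reconcilable with its
GCV column under any single textbook formula, so component magnitudes are
never asserted, only formula-level behavior. SED is reported as
√(2·MS_e/r); the source's exact SED formula is unstated, so its SED column
is not asserted either.

Category cutoffs (GCV/PCV and GAM: <10 low, 10–20 moderate, >20 high;
h²bs: <30/30–60/>60) are the community conventions.

## Newman–Keuls letters

The SNK test sorts group means descending and tests each span of p
adjacent means against q(α, p, df_error), skipping sub-spans of accepted
spans. Unequal group sizes (the real case: 63/24/13/19 grain-type groups)
use the Tukey–Kramer-style standard error √(MSe/2·(1/nᵢ+1/nⱼ)) on the span
endpoints. Homogeneous spans are contiguous, so letters label maximal
accepted intervals. Studentized-range quantiles come from
`scipy.stats.studentized_range` (well within 1e-3 over the used range) and
are memoized because repeated `ppf` calls dominate simulation cost.
Letters are computed on genotype means (one observation per genotype),
which reproduces the published group means exactly and the published
letter patterns; groups of size one are reported but excluded from the
letter computation, and zero within-group variance with unequal means
yields all-distinct flagged letters. Familywise null behavior is checked
by simulation (4 groups, n = 25, 1,000 replicates: the rate of rejecting
complete homogeneity stays ≤ 0.10 at α = 0.05).

## Multivariate analysis

PCA standardizes with divisor n (population variance), mirroring the
FactoMineR convention; at n = 119 the n vs n−1 choice shifts eigenvalues
far below reporting tolerance. Eigenvector signs are fixed by making each
component's largest-magnitude loading positive. Gower distance excludes
zero-range traits with a warning. Ward.D2 clustering runs
`scipy.cluster.hierarchy.linkage(method="ward")` on the precomputed
condensed distance matrix, which implements exactly the Lance–Williams
update above (equivalent to R's `hclust(..., "ward.D2")` on a `dist`
object); a tiny independent Lance–Williams agglomerator serves as the
oracle in tests. The cluster count k is a user input (6 for phenotype and
4 for markers in the reference analysis); no automatic selection is
offered. The clustering trait set is configurable — default all fourteen,
with an `ag_traits` preset (the ten submergence-phase traits) since the
original clustering was based on AG-potential traits without an explicit
list; published cluster means are therefore reproduced conditionally on
imposed memberships, not by de-novo clustering. Dendrograms export as
Newick with branch lengths from merge heights.

## Markers

PIC defaults to the Botstein form (the convention of PowerMarker-style
software); plain expected heterozygosity `1 − Σp²` is available via flag,
as printed rounding cannot distinguish the two in the reference tables.
Three genotype distances are provided: Nei–Li band sharing
`1 − 2·n_shared/(n_x+n_y)`, shared-allele proportion, and the unnormalized
mismatch count — the last documented as the likely source of
published "Nei distance" values exceeding 1. Single-marker association
keeps allele classes with ≥ 2 genotypes and requires ≥ 2 such classes;
p-values are reported raw (the reference behavior) plus
Benjamini–Hochberg adjusted as an extension. Raw marker scores behind the
published diversity tables are unavailable, so marker statistics are
validated on closed forms and synthetic data with known frequencies only.

## Synthetic data

`simulate_trial` draws `y = μ + gᵢ + sⱼ + (gs)ᵢⱼ + b_k(j) + ε` with
independent normal effects; defaults (μ = 50, σ²g = 100, σ²ge = 30,
σ²b = 5, σ²e = 25, 119 × 2 × 3) give heritability around 0.65 on a plot
basis, typical of seedling screening traits. The default simulated trait
is RI, the one sign-unconstrained trait, so unbounded normal draws never
violate range validation. Germination adds a Binomial(5, pᵢ) layer per
replicate, placing pooled AGP on the 100k/30 lattice that the reference
panel's AGP values occupy. Marker calls are i.i.d. categorical draws. What
the generators do not emulate: non-normal or heteroscedastic errors,
correlated traits within genotype, spatial block structure, and selection
of landraces by collectors — so passing recovery tests demonstrates
correctness of the estimators under the design assumptions, not
robustness to their violation. `recovery_experiment` (500 replicates at
g = 100 in the acceptance suite, smaller in unit tests, sized to keep the
default run inside a few seconds) reports bias, RMSE and 2-SE coverage
for the components and downstream GCV/h².

## Numerical choices

Trial CSVs are written with `%.17g` and read with pandas'
`float_precision="round_trip"` so write/read round-trips are bit-exact.
Sums of squares are computed from marginal means on the pivoted cell
array; additivity against the total SS holds to 1e-8 relative on random
data. Degenerate inputs: constant data give σ̂² = 0 with the F-statistic
reported as undefined (`None`); a single replicate or season raises a
design error naming the remedy. The pipeline funnels all randomness
through one seed and stamps outputs with a hash of the configuration.
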