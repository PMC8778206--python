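# Methods

## Analysis model

The unit of analysis is the genotype × year mean over replicates of a
balanced randomized-complete-block trial (g genotypes × y years × r
replicates; the default design is 135 × 2 × 4). All correlation and
regression work happens at that level; the ANOVA consumes the
replicate-level table.

### Correlation screen

For each year, each element's genotype means are correlated (Pearson)
with the covariate panel: grain yield (g/m²), protein content (%),
thousand-kernel weight (g) and the macroelement concentrations Ca, K,
Mg, P, S (µg/g). Significance uses the two-sided t transform
`t = r·sqrt((n−2)/(1−r²))` with n−2 degrees of freedom at α = 0.05.
No multiple-testing correction is applied: the screen deliberately
mirrors per-cell starring, because its product is a gating set, not an
inferential claim. A macroelement is never correlated with itself;
such cells are undefined and excluded from all tallies. Constant
traits produce undefined cells with a warning rather than an error.

### Covariate adjustment

Each element-year whose screen row has at least one flag is regressed
(OLS with intercept) on exactly the flagged covariates; the adjusted
genotype mean is `ȳ + (yᵢ − ŷᵢ)`. The "mean + residual" form is used
rather than bare residuals so adjusted data remain on the original
concentration scale with the original mean; with an intercept the mean
is preserved exactly and the genotype-mean variance can only shrink
(residual SS ≤ total SS), by the model's R² share. Replicate-level
adjusted values subtract the genotype's fitted offset `ŷᵢ − ȳ` from
every replicate of that genotype-year, which preserves within-genotype
replicate structure so the factorial ANOVA can be rerun on adjusted
data. Fitting on genotype-year means (rather than plots) keeps the
regression consistent with the screen's analysis unit; this is a
design choice, documented here because fitting on plot values would
weight within-plot noise into the slopes.

### Variance components and heritability

Balanced method-of-moments ANOVA only; no REML. One-way per year:
`σ̂²_g = (MS_g − MS_e)/r`. Factorial genotype × year:
`σ̂²_e = MS_e`, `σ̂²_gy = (MS_gy − MS_e)/r`,
`σ̂²_g = (MS_g − MS_gy)/(r·y)`. Negative estimates are clamped to zero
before any ratio is formed (standard practice; it introduces a small
upward bias at H² near 0 and a downward bias via the interaction at low
genotype variance). Broad-sense heritability defaults to the
entry-mean basis — `σ²_g/(σ²_g + σ²_gy/y + σ²_e/(r·y))` factorial,
`σ²_g/(σ²_g + σ²_e/r)` single-year — with a plot basis
(`σ²_g/(σ²_g + σ²_gy + σ²_e)`) behind a flag, because published H²
values in this magnitude range are consistent with either convention
and the choice should be explicit rather than implicit. F tests use
MS_e as denominator (fixed-effects convention); a random-model option
tests genotype against MS_gy. Blocks are not modelled separately from
residual. LSD at level α is `t(1−α/2, df_e)·sqrt(2·MS_e/n)`.

### Suitability index

Mid-rank (average-rank) tie handling everywhere: tied values share the
mean of the positions they span, so every rank column over n elements
sums to n(n+1)/2 regardless of ties. CV% and H² rank descending
(highest = 1), the correlation count ranks ascending (fewest = 1); the
rank sum is ranked ascending again for the final order. The three
criteria are deliberately unweighted. The correlation count is the
element's number of flagged cells across both years and all eight
covariates; the H² criterion uses the factorial ANOVA of the
*original* (unadjusted) data, since the index is meant to describe the
trait as the breeder encounters it.

The published reference criteria shipped in
`grain_ionome.reference` contain two internal inconsistencies (the
printed count-rank for P/S and the printed Cu/K entries do not follow
from mid-ranking the displayed values, presumably because the
underlying unrounded values differ); the recomputed mid-ranks are
taken as the reference behaviour, and validation asserts only the
elements whose printed sums are self-consistent.

### Selection

Superior sets per element are the k = 15 genotypes at the favorable
end of the adjusted two-year-mean ranking: high for macro- and
microelements, low for the toxic trace elements (Cd, Co, Ni) *and* the
other trace elements (Mo, Rb, Sr). Treating Mo as favorable-low
follows the trial's own selection rule even though Mo is a
micronutrient in parts of the literature; the direction is
per-element configuration, not hard-coded. Ties in the ranking are
broken by genotype id for determinism and annotated. Group summaries
report per-group means of two-year genotype means with standard error
sd/√(n genotypes) (undefined for single-genotype groups) and percent
difference against the designated check genotype's own mean.

## Synthetic-trial generator

Every trait follows `value_ijk = µ + G_i + Y_j + GY_ij + ε_ijk` with
independent zero-mean Gaussian components. Genotype effects of the
elements are `σ_G·(w_p·F_prot,i + w_m·F_macro,i + w_u·U_i)` with two
shared standard-normal latent genotype factors; protein loads entirely
on the protein factor and yield negatively on it (genotype-mean
correlation −0.45), which reproduces the empirical pattern of protein
correlating with most elements, Mg/P/S being inter-correlated, and
Co/Rb correlating with nothing. Correlation targets are specified on
the genotype-mean scale and converted to loadings by dividing out the
heritability attenuation `sqrt(h²_e·h²_prot)`; targets implying
`w_p² + w_m² > 1` (negative element-specific variance) raise a
configuration error.

Per element the user sets the mean µ (µg/g), the factorial entry-mean
heritability target h², and the residual CV%. The genotype variance is
solved from `σ²_G = h²·σ²_e/(r·y·(1 − h²(1 + γ/y)))` with interaction
ratio γ = σ²_GY/σ²_G (default 0.2), which makes the true factorial H²
equal the target exactly — the basis of the parameter-recovery tests.
Year effects are drawn once per year per element with sd 5% of the
mean. Default means, CVs and heritabilities are calibrated to a
published two-year 135-genotype spring-wheat trial (Cd the most
variable at CV ≈ 36%, Mg the least at ≈ 9%; H² spanning 0.27–0.87);
the residual CV is back-solved so the realised within-year
genotype-mean CV lands on the calibration value. Group composition
defaults to the same trial's seven germplasm groups
(37 CIMMYT synthetics, 8 Japan synthetics, 14 USA, 15/42/17 KASIB
early/intermediate/late, 2 checks). Concentrations are clipped at 0
with a logged count (relevant only for the most residual-heavy trace
elements at ~1–3% of plots).

What the generator does **not** emulate: spatial field structure and
block effects, non-Gaussian (e.g. right-skewed) concentration
distributions, environment-driven covariance between elements beyond
the genotype level, year-specific correlation structure, and
measurement error correlated within ICP-MS batches. Tests passing on
this generator therefore demonstrate correctness of the estimators and
the pipeline contracts under the stated model, not robustness to those
real-data features.

## Numerical choices and problem sizes

Negative variance components clamp to 0; H² is clipped to [0, 1].
Rank-deficient covariate matrices are rejected with the offending
columns named. A perfectly fitting adjustment (adjusted values
constant) reports an undefined original–adjusted correlation rather
than an arbitrary value. Determinism: one `numpy` Generator seeded
from the configuration drives all draws in a fixed trait order, so a
seed fixes the trial bit-for-bit; pipeline outputs are byte-identical
across reruns.

Simulation-backed checks use the full 135 × 2 × 4 design where the
claim concerns that design (heritability recovery over 20 seeds per
level, screen type-I error over 200 null screens) and a reduced
30-genotype × 2-replicate design where only the algebraic contracts
are exercised (adjustment mean/variance contract over 100 panels);
`scripts/acceptance.py` uses 10 seeds per heritability level and 100
null screens. These sizes give Monte-Carlo standard errors comfortably
inside the asserted tolerances (±0.07 for H² recovery, ±0.01 for the
type-I rate).

## Known limitations

- Strict balance is required by the ANOVA; the permissive reader drops
  incomplete genotype-year units rather than imputing.
- Method-of-moments components can be noisy for low-H² traits at small
  g; the clamping bias is visible below H² ≈ 0.3.
- The screen's gating (no multiplicity control) is faithful to its
  purpose but means ~5% of null cells gate a spurious covariate; the
  adjustment is mean-preserving and variance-non-inflating regardless.
- The correlation structure of the generator lives entirely in the
  genotype effects, so realised genotype-mean correlations attenuate
  with falling heritability; configured targets above
  `sqrt(h²_e·h²_prot)` are rejected rather than silently missed.
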