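# Methods

This note documents the models, conventions and design choices behind the
package, in the spirit of a statistical-software methods appendix. Nothing
here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Stoichiometric [2H] balance

The balance is pure bookkeeping over daily end-product rates. Coefficients
(signed mol [2H] per mol of product; positive = produced):

| product | coefficient |
|---|---|
| acetate | +2 |
| propionate | −1 |
| butyrate | +2 |
| valerate | −1 |
| caproate via propionyl-CoA (pathway 1) | −4 |
| caproate via acetyl-CoA (pathway 2) | +2 |
| methane | −4 |

Both caproate scenarios are always computed; they bracket the truth when
the actual route is unknown. Two identities follow directly and are
enforced as property tests: production(pathway 2) − production(pathway 1)
= 2 × caproate mmol/d, and utilization(pathway 1) − utilization(pathway 2)
= 4 × caproate mmol/d.

**Iso-acids.** Isobutyrate and isovalerate are measured in Rusitec work but
excluded from the balance by default, since the classic production and sink
lists name only the straight-chain acids. A configuration switch
(`StoichiometricTable(include_iso_acids=True)`) adds them with the
coefficients of their straight-chain analogues; branching does not change
the redox bookkeeping. Minor products (formate, heptanoate) are likewise
excluded by default but can be added to the coefficient table.

**Gas-law conversion.** CH4 volume is converted to moles with PV = nRT
(R = 8.3145 J mol⁻¹ K⁻¹; kPa·mL / (J mol⁻¹ K⁻¹ · K) yields mmol directly).
Published balance tables in this area rarely state the T/P used. Our
default is the incubation temperature of the sample's thermal treatment
(312.65 K or 315.15 K) at one standard atmosphere (101.325 kPa), both
overridable per dataset and per record (`temperature_k` column). Note that
back-calculating from published paired values (e.g. 87.3 mL/d ↔ 13.8 mmol
[2H]/d) can imply a CH4 molar volume near 25.3 L/mol, matching neither
39.5 °C/1 atm (25.66) nor 25 °C/1 atm (24.47); rather than guess an
undocumented convention we expose T and P as configuration and document the
default. Recomputed CH4 [2H] terms may therefore differ from published ones
by a few percent while all within-table identities hold exactly.

**Degenerate inputs.** Recovery with zero production is reported as NaN
(missing), not an exception: degenerate synthetic rows must not abort a
batch. Comparisons against printed tables round half away from zero to the
table's decimals (`round_half_away`); internal math is full precision.

## Gas metrics

Total gas = CH4 + CO2 + O2. O2 is part of the total but often unreported;
a missing `o2_ml` column defaults to 0 with a warning. Apparent
disappearance is feed-in minus residue-out per nutrient, with `out > in`
rejected as a unit mix-up rather than clamped. The methane conversion rate
needs an energy density for CH4; the package defaults to 39.54 kJ/L
(standard combustion value at ~0 °C, 1 atm) and takes gross-energy intake
as an input since diet composition varies by study. Both are configurable.
Disappearance is computed per record; averaging across residue-pooling
windows is left to the statistics layer.

## Diversity

* **Filtering:** OTUs with fewer than 10 reads total across all samples are
  removed (strictly-below threshold; an OTU at exactly 10 reads is kept).
* **Rarefaction:** uniform subsampling without replacement (multivariate
  hypergeometric) to a fixed depth, default 41,921; shallower samples are
  dropped with a warning. An explicit integer seed is mandatory — there is
  no silent global RNG state anywhere in the package.
* **Alpha diversity:** observed richness; singles (OTUs seen exactly once);
  Shannon −Σ p log₂ p in bits (base configurable — analysis suites differ,
  and published index values near 4.6–4.8 at this richness do not
  discriminate between bases, so the convention is explicit rather than
  inferred); Simpson reported as 1 − D (matching the 0.90–0.91 range such
  tables print; D and 1/D available); ACE with the conventional
  rare/abundant cutoff of 10. When every rare read is a singleton the ACE
  coverage term is zero and the estimator is undefined; the package falls
  back to bias-corrected Chao1 with a warning instead of aborting.
* **Weighted UniFrac:** the raw (unnormalized) variant
  d(A,B) = Σ_b len(b)·|p_A(b) − p_B(b)| by default, with the
  denominator-normalized variant behind a flag. The implementation is a
  single postorder accumulation of per-branch relative-abundance mass; it
  is cross-checked against scikit-bio's implementation in the tests.
* **PCoA:** Gower double-centering B = −½·J·D²·J and symmetric
  eigendecomposition; coordinates are eigenvectors scaled by √λ over the
  positive eigenvalues, explained percentages use the positive eigenvalues
  only, and the count of negative eigenvalues (non-Euclidean input) is
  reported on the result rather than corrected.
* Whether singles are counted before or after rarefaction is a genuine
  ambiguity in the field; this package computes alpha metrics on the
  rarefied table in the pipeline (configurable by calling `alpha_frame`
  on the unrarefied table).

## Factorial statistics

The experiment is a 2 × 2 × 3 factorial (osmolality × temperature ×
betaine) replicated over 6 runs. The classical analysis uses a mixed model
with run as a random effect; this package fits OLS with run as a **fixed
block** (`y ~ run + osmolality*temperature*betaine`). For a balanced
design the treatment LS means and contrasts are identical between the two
parameterizations (the tests verify LS-mean invariance to the block term);
what is lost is the REML partition of variance components, which is out of
scope. F tests use type-III sums of squares with sum-to-zero contrasts.
LS means are model predictions averaged with equal weight over the levels
of the other factors and over runs; contrasts carry t-based CIs on the
residual degrees of freedom. Daily repeated measures of a fermenter are
always averaged into one value per fermenter before fitting (no repeated-
measures covariance structure is modelled). P ≤ 0.05 is labelled
significant and 0.05 < P ≤ 0.10 a tendency, kept as distinct labels. No
multiple-testing correction is applied, matching field practice for these
tables. Correlation tables are plain Pearson r with two-sided t tests.

A constant response (zero total variance) is reported as "all effects null"
(F = 0, P = 1) rather than the 0/0 F-statistics OLS would produce.

## Synthetic data generator

The generator exists to exercise the pipeline and validate it by parameter
recovery; it makes no claim to model rumen biology. Its defaults are the
study conditions it emulates.

**Fermentation:** value = baseline + Σ additive treatment shifts + run
effect N(0, σ_run) + residual N(0, σ), truncated at 0 with a logged count.
Baselines are the normal-osmolality treatment means (e.g. CH4 87.3 mL/d,
acetate 29.95 mmol/d back-computed from its [2H] mean, GE intake 211.8
kJ/d back-computed from the printed MCR); shifts are the published LS-mean
differences (e.g. CH4: −38 mL/d for hyperosmolality, +43.6 for high
betaine). Residual σ defaults to 5 mL/d for CH4 and 5 % of baseline for
other variables; run σ is 3 % of baseline. Because CH4 and the SCFA
baselines come from the same internally consistent table, stoichiometric
[2H] recovery of simulated data lands in the observed 35–55 % band without
any coupling term.

**Community:** per-sample genus proportions are Dirichlet
(concentration 150, i.e. moderate overdispersion; `None` gives the
infinite-concentration limit) around phase-specific means — liquid:
Methanobrevibacter 0.49, Vadin CA11 0.303, Methanosphaera 0.043, …, with
trace Methanosaeta present only in the liquid phase; solid: 0.45 / 0.27 /
0.13 / …. Treatment effects are applied as logit-scale shifts derived from
the per-level published means. Reads (Gaussian depth around 66,139,
truncated at 42,000 so every sample survives rarefaction at 41,921) are
allocated multinomially to 3,016 OTUs; OTU counts per genus are
proportional to (mean abundance)^0.25 with a minimum of 3, and within-genus
base weights follow a geometric series with ratio 0.985 — chosen once so a
rarefied sample shows on the order of 1,600 observed OTUs, ~300 singletons
and ACE near 1,900, the realistic order for this system, so ACE and singles
are genuinely exercised. The tree joins random coalescent-style clades per
genus (exponential branch lengths, scale 0.05 within and 0.2 between
clades); its only adequacy criterion is that UniFrac separates treatments
when injected effects are large.

**What the generator does not emulate:** sequencing error, chimeras and
clustering noise; compositional coupling between SCFA species; day-to-day
autocorrelation; overdispersed (non-multinomial) read allocation within
genus; phylogenetic signal in treatment responses. Passing recovery tests
therefore demonstrates the correctness of the pipeline's arithmetic and
statistics under the stated generative model, not robustness to every
feature of real amplicon data.

**Randomness:** every stream derives from the single config seed via
numbered `SeedSequence` children (universe/tree, fermentation, liquid
community, solid community), so the two phases share one OTU universe and
identical seeds give byte-identical datasets and pipeline outputs.

## Problem sizes

The default simulated experiment is the full study scale: 6 runs × 12
fermenters × 5 sampling days (360 fermentation records) and 144 community
samples (72 fermenters × 2 phases) × 3,016 OTUs at ~66k reads. The complete
pipeline runs in a few seconds on one CPU; the recovery experiment in the
acceptance script uses 200 independent replicates of the fermentation
simulation and factorial fit. Unit tests use down-scaled configurations
(2 runs, 200 OTUs, ~5k reads) where full scale adds nothing to the property
being checked.

## Known limitations

* Run is a fixed block, not a REML random effect: SEs of LS means are not
  the mixed-model SEs (point estimates and contrasts agree under balance).
* The [2H] balance consumes already-computed daily production rates; outflow
  accounting upstream of mmol/d is out of scope.
* PCoA percentages from published ordinations of the real sequencing data
  cannot be reproduced without the deposited reads; diversity correctness
  is instead established against an independent reference implementation
  and hand-computed cases.
* The OTU-table reader validates cell-by-cell in Python; it is comfortable
  at this study's scale (3,016 × 144) but not engineered for much larger
  tables.
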