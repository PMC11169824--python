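# Methods

This note documents the models implemented in `phenogs`, the synthetic
data they are exercised on, and the numerical and design choices a
maintainer or reviewer would want spelled out.

## Synthetic breeding trials

The generator produces complete trial suites with known ground truth. It
is deliberately simple — every feature exists to make a downstream claim
testable, and everything is a pure function of `(config, seed)`.

**Genotypes.** Unlinked biallelic SNPs: per-marker allele frequencies
uniform on a configurable MAF range (default 0.05–0.5), line dosages
Binomial(2, freq). No linkage disequilibrium, pedigree structure,
dominance or epistasis. Markers are assigned round-robin to 21
chromosomes with 1-based positions.

**Genetic values.** Infinitesimal model: marker effects for the t traits
are iid across markers, multivariate normal with covariance proportional
to the configured genetic correlation matrix. Breeding values are the
centered dosage matrix times the effects, rescaled exactly so each
trait's genetic variance equals its heritability target. The
multivariate-normal effect model matches the GBLUP assumptions, so
recovery tests are well posed rather than model-misspecification tests.

**Heritability convention.** `h2` targets are *entry-mean* broad-sense
heritabilities, `H2 = sg2/(sg2 + se2/nRep)`. With total entry-mean
phenotypic variance fixed at 1 per trait, the plot residual variance is
derived per trial as `se2 = nRep * sg2 * (1 - h2)/h2`. Defaults: GY 0.5,
TW 0.7, GPC 0.4 (test weight the most heritable, protein the least, as
is typical for hard winter wheat); genetic correlations default to
GY–TW +0.3, GY–GPC −0.3, TW–GPC +0.1 (the familiar yield–protein
trade-off).

**Field designs.** RCBD trials place every line once per replicate with
randomized within-replicate order; augmented trials place unreplicated
test lines across blocks with every check in every block. The default
advanced suite mirrors a breeding program's layout: ELITE 36 lines x 3
replicates and AYT 126 x 2 at two locations; the preliminary nursery is
augmented with 7 checks over 22 blocks (which yields 590 + 154 = 744
plots under the every-check-every-block rule). Plot values add a
location main effect (sd 0.5), a genotype-by-location deviation (sd
0.3), a replicate/block effect (sd 0.3) and the derived residual, all on
the standardized scale, then map affinely to field units (GY 4500 ± 600
kg/ha, TW 76 ± 2, GPC 12 ± 0.8%). Heritabilities and correlations are
affine-invariant.

**Canopy reflectance.** Per plot and flight, a latent canopy vigor

    v = loading(stage) * (z_GY + location effect) + baseline(stage) + noise

where `z_GY` is the line's standardized yield breeding value. Bands are
fixed affine maps of the logistic squash `s = sigma(v)` — NIR = 0.25 +
0.35 s (increasing), red = 0.25 − 0.18 s (decreasing), green/blue/red
edge gentle affine maps — clipped to [0, 1]. Consequently NDVI-type
indices correlate with yield with stage-controlled strength. Default
loadings 0.4 / 0.8 / 0.8 / 0.6 for Feekes 6/8/10/11 encode the weak
early-season and strong mid-season signal seen in wheat canopies; vigor
noise sd is 0.5. The location effect enters vigor because a site's
productivity is visible in its canopy; this is also what makes
multi-location training meaningful — without it, site differences would
sit in the target but be invisible in the features, structurally biasing
any cross-site experiment against pooled training.

**What the generator does not emulate.** Real spectra carry soil
background, illumination drift, atmospheric effects, band-specific noise
and genuine multivariate canopy physiology (TW and GPC influence
reflectance only through their genetic correlation with yield here). LD
and family structure are absent, so genomic accuracies at a given panel
size run lower than GBS data would give. Passing tests therefore
demonstrate the *machinery* — estimators recover planted truth, schemes
rank as theory predicts — not field-level accuracy values.

## Phenotype analysis

BLUEs fit genotype as fixed and replicate/incomplete block as random;
heritability swaps genotype to random with the replicate stratification
fixed. Both reduce to one mixed model with a single random effect,
solved by profile REML: the variance ratio is optimized by bounded
scalar search over log-lambda in [−12, 12] (xatol 1e−8) after one
eigendecomposition of ZZ', with a GLS back-solve for fixed effects.
Negative variance estimates truncate at the lambda→0 boundary with a
warning. The implementation is cross-checked against statsmodels
MixedLM in the tests. Single-replicate tables degenerate to raw plot
means and are flagged unreliable. Multi-location inputs for genomic
selection default to fitting each location and averaging the per-line
BLUEs; a pooled fit with location fixed is available. `nRep` in H2 is
the mean plot count per line.

## Vegetation indices

The 20-index catalog is an explicit, user-extensible registry; each
entry records its closed-form formula and literature citation (NDVI
Rouse 1974, GNDVI Gitelson 1996, GCI Gitelson 2003, ARI/ARI_2 Gitelson
2001, PSRI Merzlyak 1999, IKAW Kawashima 1998, NDWI McFeeters 1996,
SAVI Huete 1988, EVI_2 Jiang 2008, MCARI Daughtry 2000, TCARI/OSAVI
Haboudane 2002, and so on). Where the literature has competing variants
the registry pins one: RVI = NIR/Red, RVI_2 = NIR/Green, SAVI_2 =
NIR/(Red + 0.5). Denominators with |d| < 1e−9 yield a missing-value
flag rather than an infinity. Band order is fixed to the Altum-PT
sensor (blue, green, red, red_edge, nir). Zonal statistics over gridded
images use labeled-region means (scipy.ndimage); rasters are plain
numpy grids. Feature columns are named `INDEX@STAGE`.

## Genomic prediction

**QC.** Strict thresholds as worded: a marker at exactly 30%
missingness or exactly 5% MAF survives. Removal counts are attributed
by rule priority (missingness, MAF, unmapped) so they sum to the input
count. Mean imputation replaces the external haplotype-imputation step,
which is out of scope.

**GRM.** `G = XX'/p` over centered columns scaled by their observed
standard deviation, giving diagonal mean exactly 1; the VanRaden
`2*sum(p q)` denominator is an option. Monomorphic markers are rejected
by id. G is symmetric to 1e−10 and invariant to allele-coding flips.

**Samplers.** Both Gibbs samplers rotate into the eigenbasis of G
(`G = U diag(lam) U'`), where the genetic values decouple across
eigencomponents: the single-trait update is a vectorized scalar draw
per component, the multi-trait update a batched t-variate normal with
precision `Sigma^-1/lam_j + R^-1`. This is algebraically identical to
the naive sweep and makes full-length chains (25,000 iterations)
run in under a second at n ≈ 100–200. Eigenvalues are floored at 1e−8
(a standardized GRM with n > p is singular); matrices indefinite beyond
−1e−8 are rejected. Priors are weakly informative in the BGLR/MTM
tradition: scaled-inverse-chi-square with df 5 and scale set so the
prior mode assigns half the phenotypic variance to each component (ST
and the MT residuals), and inverse-Wishart with df = t + 4 and scale
set so the prior mean assigns half the phenotypic variance to genetics
(MT). Thinning defaults to 5. Missing phenotypes are imputed by data
augmentation each sweep; residual-variance updates use observed cells
only. Chains are bit-reproducible from the config seed; non-finite
draws or non-positive-definite scale matrices abort with diagnostics.

**Cross-validation.** Training size is floor(0.8 n); test sets below 3
lines are rejected. Replicate splits derive from spawned children of
the scheme seed, so a CVResult is a pure function of (inputs, scheme),
and ST-CV1/MT-CV2 runs sharing a scheme seed are split-paired — this
pairing is a deliberate variance-reduction deviation from re-drawing
splits independently per scheme. Inside CV loops chains shorten to
6,000/2,000 (the oracle tests show posterior means stabilize well
before that); full-length chains remain available. Note that paired
splits resolve mean-ability differences of a few hundredths, so
"schemes agree" checks are equivalence bounds at the Monte-Carlo scale
rather than null-hypothesis tests.

## Phenomic deep network

Hidden layers are dense → batch normalization → ReLU → dropout, in that
order, with a linear output unit; the reference architecture is
64-128-256-512-1024 with dropout 0.3. Where the hidden activation and
the output description conflict, the rectifier belongs to the hidden
layers and the identity to the regression output. One single-output
model per trait is the default; a multi-output head is available
through `n_outputs`. Features and the target are z-scored with
parameters learned on training data only; predictions map back to trait
units. Training is plain Adam (lr 1e−3 default, grid-searchable) on
shuffled minibatches for a fixed epoch count — no early stopping, so
the epoch grid (50–250, with batch sizes 16/24/32/64) is meaningful.
The 70/30 plot split is simple random, not stratified. Evaluation
freezes batch-norm running statistics and disables dropout. RMSE uses
the n−1 denominator throughout, and relative RMSE is RMSE/mean(y)x100,
flagged undefined at zero mean. The implementation is a compact
float64 numpy network with hand-written backpropagation; with a fixed
seed (weights, dropout masks, batch order all flow from one generator)
runs are bit-identical on a given machine. Forward prediction trains on
all advanced-trial plots with no internal split and applies the frozen
standardization to the preliminary-trial matrix.

## Problem sizes in the test and acceptance runs

The suites use the sizes at which the statistical claims are stated:
sampler-vs-oracle at n = 100 lines / 500 markers; multi-trait recovery
at n = 200 / 1000 over 20 seeds; heritability recovery at 200 lines x 3
replicates over 50 seeds; scheme comparisons at n = 200 with 30 paired
replicates; the deep-network checks at 500 plots; forward prediction
with the full advanced layout (360 plots per location) and a 200-line
preliminary nursery over 20 seeds. The acceptance script runs the
end-to-end suite at 162 advanced lines / 2000 markers with 10 CV
replicates per scheme. These sizes keep full runs in the minutes range
on one CPU while leaving every estimate's Monte-Carlo error small
relative to the tolerances asserted.

## Known limitations

- Unlinked markers understate realistic genomic accuracy at a given
  panel size; accuracies here should be read relative to each other,
  not as field forecasts.
- Only yield drives canopy vigor, so phenomic prediction of TW and GPC
  on synthetic data works only through genetic correlation and is
  correspondingly weak.
- The REML stage handles one random effect; no spatial row/column or
  autoregressive field-trend corrections.
- No genotype-by-environment covariance modeling in the genomic models
  (the generator's G×L deviations act as extra noise there).
- The multi-trait sampler's unstructured Sigma scales to a handful of
  traits comfortably (batched t x t solves); hundreds of covariate
  traits would want a factor-analytic structure it does not implement.
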