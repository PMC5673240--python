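# Methods

`genephys` implements a discovery→validation analysis relating cell-type-level
gene expression to intrinsic electrophysiological (ephys) properties of
neurons. This note documents the statistical model behind each stage, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the numerical choices made where the design was open.

## The analysis problem

Two data modalities are paired at the level of *cell types*, never single
cells: (a) expression profiles — pooled-cell microarray intensities on a log2
scale for the discovery side, or single-cell RNA-seq TPM summarized per
transgenic (cre) line for the validation side — and (b) intrinsic ephys
properties curated from intracellular-recording literature or measured with
standardized patch-clamp protocols. Eleven properties are analysed (closed
registry): resting potential `Vrest`, input resistance `Rin`, membrane time
constant `Tau`, capacitance `Cm`, action-potential amplitude `APamp`,
half-width `APhw`, threshold `APthr`, afterhyperpolarization amplitude
`AHPamp`, rheobase `Rheo`, maximal firing rate `FRmax`, and spike-frequency
adaptation `SFA` (first / mean inter-spike interval; values near 0 mean
strong adaptation). The strictly positive, right-skewed set
{`Rin`, `Tau`, `APhw`, `Cm`, `Rheo`, `FRmax`} is log10-transformed before any
modeling; `Cm` can also be derived as τ/R_in (ms/MΩ = nF, reported in pF).

## Expression preprocessing

* **Quantile normalization** forces all samples' empirical distributions onto
  the cross-sample mean of order statistics; ties receive the average of the
  tied positions' targets, so identical inputs are a fixed point.
* **Probe collapse** keeps, per gene, the probe with the largest across-sample
  variance (ties: first in input order, logged).
* **Cell-type summarization** is the arithmetic mean per gene over a type's
  samples.
* **Gene filtering** computes per-gene mean μ_g and (n−1) standard deviation
  σ_g *across cell types* and keeps genes with μ_g > mean(μ) and
  σ_g > mean(σ). The derived thresholds are returned and can be fixed
  externally, under which the filter is idempotent. Downstream statistics are
  rank-based, so any strictly increasing rescaling of expression leaves the
  screen unchanged.
* **Single-cell aggregation** summarizes TPM by mean within line and drops
  lines sampled by fewer than `min_cells_per_line` (default 10) cells in
  either modality.

## Cross-study ephys normalization

Literature measurements mix species, electrode types, junction-potential
(LJP) conventions, animal ages and recording temperatures. After filtering
(acute slice only; mouse/rat/guinea pig; age > 2 days; age ranges collapsed
to their geometric mean; missing age/temperature median-imputed; explicit LJP
corrections reverted on absolute voltages `Vrest`/`APthr` and marked
`post_corrected`), each property is modelled additively on its modeling
scale:

    value ~ NeuronType + Species + JxnPotential + ElectrodeType
            + bs(log10(age), df=5) + bs(temperature, df=5)

The cubic B-spline bases use two internal knots at the observed terciles
(inverted-CDF quantiles, so duplicating records cannot move them) and
boundary knots at the observed range; out-of-range covariates are clamped to
the boundary and flagged. **Cell-type terms are unpenalized fixed effects**:
the target and every condition column are centered within cell type
(Frisch–Waugh), and the elastic net (mixing weight 0.99, 100-value penalty
path, penalty by article-grouped cross-validation) is fit on the within-type
variation only. This choice is deliberate: with a single shared penalty over
all terms, the weakly penalized splines can absorb genuine between-type
biology (cell types are confounded with age), which in simulation made the
adjustment *worse* than no adjustment in a third of runs.

Adjustment moves each record to reference conditions on the modeling scale
(`adjusted = observed − (predicted_at_observed − predicted_at_reference)`)
and back-transforms. Reference conditions are the most frequent level per
categorical term and the median temperature; the **age reference is each
cell type's own median age**, because developmental stages are curated as
distinct cell types and within-type age variation is too small to identify
the spline away from its fitting region — a global age reference extrapolates
wildly. Records carrying a categorical level unseen at fit time are left
unadjusted and logged. Models serialize fully (coefficients, levels, knot
vectors, references) to JSON.

Summarization then takes the mean within article and the median of article
means across articles, per (cell type, property).

## Harmonization

Expression and ephys cell types are paired through an explicit curated
mapping table, never string matching. When both sides of a pair are
age-annotated, the pair is kept only if the ages agree within ±2.5 days
(configurable); unmatched labels are recorded in provenance. Gene universes
of two datasets are intersected in sorted order, column-aligned.

## Univariate screen and cross-dataset consistency

Per gene and property, an average-rank Spearman correlation is computed over
the cell types with that property observed (pairwise complete; properties
with fewer than `min_celltypes_per_property` = 5 complete types are skipped;
zero-variance genes are excluded, not imputed). Two-sided p-values use the
t approximation `t = r√((n−2)/(1−r²))` on n−2 df, matching the reference
implementation's tie behavior; |r| = 1 reports the smallest positive float.
Benjamini–Hochberg adjustment is applied **within property only** — the 11
properties are mutually correlated, and no correction is made across them.

Consistency between a discovery screen and a validation dataset is measured
as (1) the Spearman correlation of the two full r_s vectors over the common
genes and (2) among discovery hits (p_adj < 0.05), the percentage whose
validation correlation matches in sign with |r_s| > 0.3. Both get one-sided
permutation p-values by re-pairing the validation ephys rows with its
expression rows (1000 shuffles by default) with add-one smoothing,
`p = (1 + #{null ≥ observed}) / (B + 1)`, so an observation above every null
reports 1/1001 ("< 0.001"). Shuffling permutes only the link between
modalities, preserving each modality's internal correlation structure;
permutations act on the complete-case cell types of the property under test.
Because the replication percentage is a discrete statistic, its permutation
p is mildly conservative when few genes are discovered; with a realistically
sized discovery set (hundreds of hits) the p-values are near-uniform under
the null.

## Sparse multivariate models

Each property is predicted from z-scored expression by a two-stage elastic
net (mixing 0.99, 100-value path): stage 1 is fit over all genes with the
penalty chosen by internal cross-validation (seeded 10-fold, the glmnet cv
default; leave-one-out when n < 12) and its nonzero-coefficient genes become
the selected set; stage 2 repeats the penalized CV procedure on the selected
genes, with leave-one-out penalty selection, whose lower-variance error
curve is affordable at a handful of predictors. A constant or never-selected
target yields an intercept-only model. Gene scaling statistics are stored so
the model can transform new data.

Evaluation is leave-one-cell-type-out cross-validation with both stages and
all scaling recomputed inside every fold;
`R² = 1 − SSE/SST` over the pooled held-out predictions (the unity-line
definition; can be negative). The shuffled-label null re-pairs the target
with the expression rows and re-runs the full LOOCV. The bootstrap resamples
expression samples within each cell type and ephys articles within each
(type, property) stratum — so every cell type survives every replicate —
rebuilds the paired dataset through the standard summarization pipeline, and
re-runs LOOCV (default 100 replicates).

For transfer, the discovery model is fit on a z-scored target; validation
expression is mapped to log2(TPM+1) and z-scored per gene *within the
validation dataset*, validation ephys is registry-transformed then z-scored
within dataset, and predictions are compared on that shared standardized
scale. Two R² forms are reported: squared Pearson correlation (the headline,
tolerant of affine miscalibration across datasets) and the unity-line
1 − SSE/SST form.

## The synthetic-data generator

The generator provides paired discovery/validation datasets with known
ground truth. Per cell type it draws a latent value of each property from
realistic distributions (e.g. Vrest ~ N(−65, 7) mV, log10 Rin ~ N(2.2, 0.45));
planted genes' per-type mean expression is linear in the standardized latent
with the requested sign — monotone, which is all Spearman needs — with the
Pearson loading calibrated through the exact finite-sample expectation of
Spearman's statistic for a bivariate Gaussian,
`E[r_s] = 6/(π(n+1))·((n−2) asin(ρ/2) + asin(ρ))`, and compensated for
replicate-mean noise; unattainable targets raise. Null genes sit at the
background floor (6.0 log2 units, per-type SD 0.3) and are independent of
every latent; optional co-expression blocks share a latent factor. Article-
level ephys measurements add per-article metadata (species, preparation,
electrode, LJP status with explicit offsets on corrected voltages, age with
occasional ranges, bimodal room/physiological temperatures, 5% missingness)
and configurable additive condition effects on the modeling scale. Defaults:
34 cell types × 3 replicates, 3000 genes, 3–8 articles per (type, property),
80% of (type, property) cells observed.

The validation mode reuses the realized latents for a subset of lines
(default 12): single-cell TPM is exponentiated from the latent log2 signal
(TPM = 2^(x − background)) with per-cell noise (SD 1.0 log2) and zeros
injected at the dropout rate (default 0.5), and a disjoint set of cells
carries per-cell ephys values around the same latent means. All randomness
flows through named substreams of one seed, so adding genes does not perturb
ephys draws and identical configurations are byte-identical. Ground truth
(planted effects, lab effects, realized latents) is serialized alongside.

What the generator does **not** emulate: platform-specific noise spectra,
gene-length or GC biases, real gene identifiers, cellular contamination,
correlated property latents (each property's latent is drawn independently,
unlike the strong empirical correlations between e.g. Cm and Rin), or
heterogeneous per-article protocols for derived features. Passing tests
therefore demonstrate statistical correctness and recoverability under the
stated generative assumptions, not robustness to every artefact of real
microarray or scRNA-seq data.

## Problem sizes used in the test suite

The statistical acceptance checks run at: 2000 genes × 30 cell types × 50
seeds for null FDR control; 45 planted genes × 10 seeds for screen recovery;
1000 random vectors per oracle check; 50 seeds for condition-normalization
recovery; 100 meta-replicates × 100 simulations × 300 shuffles for
permutation calibration (with a discovery set of ~1000 associations over
2603 genes, matching the scale of a real screen); and 25 seeds × (2000
genes, 30 types) for predictive-model recovery and transfer. In the
predictive check the five signal genes are planted at |r_s| ≈ 0.95 so each
is individually detectable above the maximum-null-correlation floor
(√(2 ln p / n) ≈ 0.63 at p = 2000, n = 30), with target noise calibrated per
seed so the block's attainable R² is 0.8; weaker per-gene loadings probe
identifiability limits rather than estimator quality (verified against an
independent R glmnet implementation, which scores the same hard draws the
same way).

## Numerical choices and degenerate inputs

* Elastic-net solver: coordinate descent, tol 3e-4 / 3000 iterations for the
  gene models (the CV error curve is far flatter than this tolerance) and
  tol 1e-6 / 100000 for the small condition models.
* Quantile normalization requires ≥ 2 samples; gene filtering ≥ 2 cell
  types and errors if nothing survives; condition models require ≥ 2 cell
  types, ≥ 10 records and ≥ 2 articles; predictive models require ≥ 8 cell
  types; permutation tests require ≥ 4 cell types and ≥ 100 shuffles.
* Ties: probe-collapse variance ties keep the first probe; max-rate sweep
  ties keep the first sweep; both are logged.
* Zero-variance inputs: undefined correlations are excluded pairwise and
  logged; constant targets give intercept-only models; constant covariates
  drop their model terms with a warning.
* All counts, drops and exclusions are logged through the `genephys` logger.

## Known limitations

* The condition model assumes additive, cell-type-independent study effects;
  interactions (e.g. temperature sensitivity differing by type) are neither
  modelled nor emulated.
* Per-type age referencing means cross-age normalization *within* a type is
  local; the pipeline is not designed to compare the same label across
  widely separated ages (those should be distinct types).
* With ~30 cell types, LOOCV R² is itself a noisy estimate; single-property
  conclusions should lean on the bootstrap spread.
* The permutation p for the replication percentage is conservative for small
  discovery sets (discreteness); interpret p near a threshold accordingly.
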