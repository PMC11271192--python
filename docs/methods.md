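# Methods

## Problem and scope

`metscore` turns a serum NMR panel — quantified metabolites (mmol/L)
and lipoprotein subclass parameters (mg/dL; particle numbers nmol/L;
ratios dimensionless) — into a continuous risk score for metabolic
syndrome (MetS).  MetS status is encoded as a 4-bit risk profile in the
fixed factor order (diabetes, obesity, dyslipidemia, hypertension); the
built-in WHO rule calls MetS when the diabetes bit is set together with
at least two of the other three, i.e. profiles {1011, 1101, 1110,
1111}.  Other consensus definitions (EGIR, NCEP, IDF, …) are not
hard-coded — their exact profile sets are not enumerated here — but can
be registered as explicit code sets via
`profiles.register_definition`.

## Pipeline

### Univariate profile contrasts

For each variable, an OLS model regresses the standardized variable
(sample SD, n−1 denominator, used consistently everywhere) on the risk
profile as a categorical factor with 0000 as reference, plus gender and
age group as unordered categorical covariates.  Age groups use the
boundaries [18,25), [25,35), [35,45), [45,55), [55,64), [64,70),
[70,81), [81,105].  Profile coefficients are effect sizes in SD units;
p-values are classical two-sided t-tests (robust errors are not used).
Benjamini–Hochberg adjustment runs within each variable-type family
(serum metabolites, serum lipoproteins, urine bins), pooling all
profiles in a family; adjusted p < 0.05 counts as significant.
Profiles absent from the data are dropped from the design, not
imputed; a missing 0000 or a rank-deficient design is an error (the
message names the aliased columns).  All variables share one design
matrix, so the stage is computed as a single multi-response least
squares; the per-variable statsmodels-style path
(`fit_profile_regression`) is retained and tested for exact agreement.

The heatmap view truncates effects to [−1, 1], orders variables and
profiles by complete-linkage Euclidean dendrograms, and marks cells
with stars at adjusted p < 0.05 / 0.01 / 0.001 / 0.0001.

### Variable selection

Variables are clustered per dataset type with distance d = 1 − ρ
(Spearman).  The signed (not absolute) correlation is used, so
anti-correlated variables never merge — a deliberate choice where the
convention is ambiguous, keeping e.g. protective HDL components out of
atherogenic clusters.  Linkage is average; the tree is cut on the
cophenetic height scale at 0.5 for both serum types and 0.85 for urine
bins (bins are more mutually correlated); both heights are config keys.
Ties and input order are neutralised by sorting variables by name.

The cascade then runs in fixed order, and each variable receives
exactly one provenance flag:

1. **manual_discard** — regex patterns; defaults remove particle-number
   parameters (collinear with Apo-B) and the Ca-/K-EDTA adduct
   signals.  The "reduced model", independent of the clinical
   definitions of diabetes and dyslipidemia, adds glucose and the
   members of the HDL/LDL clusters (HDLs 1-3 noTGs, HDLs 4 noTGs,
   LDLs 6, HDLs 1-3 TGs, LDLs 4-5) to the exclusion list.
2. **near_zero_variance** — discard iff frequency ratio of the two most
   common values > 19 *and* unique-value fraction < 10%; constant
   vectors have infinite ratio and are discarded.
3. **effect_filtered** — a variable survives only if some single
   profile row is significant (adjusted p < 0.05) with |effect| ≥ 0.5
   SD; both conditions in the same row.
4. **non_representative / kept** — survivors are grouped by cluster and
   one representative is kept per cluster: the member with the largest
   Σ|effect| over all 15 non-reference profiles (all profiles, not
   only significant ones; ties broken alphabetically).

### O-PLS-DA

Concentrations are log-transformed (per-variable offset of half the
smallest positive value when zeros occur, else 0 — concentrations are
nonnegative by contract) and autoscaled with training means/SDs frozen
for projection.  With a single centred binary response y the PLS weight
is closed form, w ∝ Xᵀy, so the orthogonal-signal-correction scheme
needs no iteration (the NIPALS tolerance 1e-10 / 500-iteration cap is
retained in the API for generality):

1. w = Xᵀy / ‖Xᵀy‖; t = Xw; p = Xᵀt/(tᵀt);
2. orthogonal weight w⊥ = p − (wᵀp)w, normalised; t⊥ = Xw⊥;
   p⊥ = Xᵀt⊥/(t⊥ᵀt⊥); deflate X ← X − t⊥p⊥ᵀ;
3. refit the predictive component on the filtered matrix; store all
   vectors and the response loading c.

One predictive and one orthogonal component are fixed (no CV over
component number).  If the loading is already collinear with w
(‖w⊥‖ < 1e-8, e.g. exactly rank-1 data) the orthogonal component is
skipped rather than fabricated.  Sign convention: t_pred is positively
associated with class 1, which makes label swapping flip t_pred
exactly.  Projection of new samples applies the stored preprocessing,
removes the stored orthogonal variation, then scores t_pred = x·w.
Variable influence is the predictive loading, ranked by magnitude and
signed by direction of association.

### Threshold, calibration, assessment

The decision threshold maximises Youden's J over midpoints between
consecutive distinct scores (sentinels beyond the range included; ties
resolved toward the smallest threshold, so the rule prefers
sensitivity at lower scores).  MetSCORE is a logistic sigmoid of
t_pred fitted by weighted GLM with class weights inversely proportional
to class frequency (the asymptomatic class outnumbers MetS ~50:1 at
realistic prevalence); the slope must come out positive, and the
intercept is then replaced by −slope·threshold so
MetSCORE(threshold) = 0.5 holds exactly by construction rather than
approximately.  Under perfect separation the GLM slope diverges; the
calibration then falls back to a steep finite slope (10 / median
|t − threshold|, capped at 1e6), preserving monotonicity and centring.

AUROC is the tie-aware Mann–Whitney statistic; its 95% CI uses
DeLong's structural-components variance (the method is a package
choice — no method is prescribed by the protocol).  The full protocol
is: 80/20 unstratified split → fit on train → evaluate on test → final
refit on all samples assessed by 10 × stratified 5-fold CV plus a
100-permutation test.  Folds are stratified by the MetS label because
unstratified folds can lose the rare class entirely at ~2% prevalence.
Labels are permuted once per replicate before folding; each permutation
runs one repetition of k-fold CV and its statistic is the mean fold
AUROC; p = (1 + #{perm ≥ observed}) / (n_perm + 1), so p ≥ 1/101 at 100
permutations.  Selection runs inside every training fold;
`repeated_cv_permutation` raises if handed a variable set chosen on the
full data (a dedicated test demonstrates the optimistic bias that guard
prevents), unless explicitly forced for demonstration.

### Self-organizing map

A batch Kohonen SOM on a rectangular grid (default ≈ 5√n cells,
near-square — grid size and schedule are package defaults, exposed in
config) with Gaussian neighbourhood decaying geometrically from
max(rows, cols)/2 to 0.5 over 20 epochs; codebooks are initialised from
a seeded sample of the data.  Inputs are autoscaled like the model's.
Cells whose neighbourhood weight mass is zero in an epoch keep their
codebook.  The per-epoch trace records mean *squared* sample-to-BMU
deviation — the quantity the update provably never increases once the
neighbourhood has shrunk to the k-means limit; the mean Euclidean
quantization error is available as a method.  Codebooks are grouped by
Ward linkage (Ward.D2 on Euclidean distances) cut to exactly 6 groups;
per-cell statistics report count, MetS fraction and mean score, with
empty cells flagged rather than zero-filled.

### Urine spectral binning

Spectra are reduced to 290 bins of 0.03 ppm: 140 over [0.5, 4.7) and
150 over [5.0, 9.5], skipping the 4.7–5.0 water window.  Intervals are
half-open [lo, hi) with the final bin closed, giving disjoint,
exhaustive coverage (edge handling is not prescribed anywhere, so this
is a package decision); bin centres derive from the segment starts and
bins are named by centre with 3 decimals.  Bin intensity is the sum of
spectral point intensities inside the interval, so binning conserves
the retained-region total to machine precision.  Total-intensity
normalisation is computed over the retained region only — the water
region is discarded from analysis, so including it in the total would
let an artefact rescale every bin; whether normalisation precedes or
follows water exclusion is ambiguous in the protocol's phrasing, and
this choice is ours.

## Synthetic cohort generator

No patient-level data is distributable, so the generator emulates the
three structural features the pipeline depends on:

* **Blocks.**  112 lipoprotein parameters in the 7 empirically reported
  cluster themes (VLDLs+IDLs, LDLs 1-3, LDLs 4-5, LDLs 6, HDLs 1-3
  noTGs, HDLs 1-3 TGs, HDLs 4 noTGs) and 41 metabolites (branched-chain
  amino acids and ketone bodies as 3-member blocks, the rest
  singletons, including the Ca-/K-EDTA discard targets and
  particle-number parameters).  Within-block equicorrelation comes from
  a shared latent Gaussian factor, default ρ = 0.9 (Pearson; the
  implied Spearman for a Gaussian copula is ≈ 0.89) — the simplest
  structure that makes average-linkage clustering recover blocks
  exactly at the 0.5 cut.  Optionally 290 urine bins in 15 contiguous
  blocks.
* **Effects.**  The (variable × profile) mean-shift matrix is built
  from additive per-risk-factor loadings in SD units, mirroring the
  qualitative serum pattern: glucose +2.0 on diabetes; VLDL/IDL +1.0
  and dense LDL +0.9 on dyslipidemia; TG-rich HDL +0.7 and LDL-6 +0.6;
  light HDL −0.8 and light LDL −0.5; BCAAs, alanine, proline,
  phenylalanine, sarcosine, ketones at 0.3–0.7 on their factors.  The
  magnitudes are a package choice (only effect directions and the ≥0.5
  SD selection threshold are externally anchored), set so that
  informative clusters clear the selection threshold at n = 2000 while
  several variables (lactate, tyrosine, creatinine at 0.3–0.4) fall
  below it and exercise the filter.
* **Covariates and demographics.**  Mild gender shifts (±0.3 SD on
  VLDL/light-HDL, +0.4 on creatinine) and age slopes (+0.015 SD/yr on
  atherogenic particles); age ~ N(44.7, 10.3²) clipped to [18, 90];
  37.9% female; profile prevalences from the reference population
  counts (asymptomatic 68.5%, WHO-MetS ≈ 2% combined).

Values are reported as baseline + latent value (baseline 10 SD units),
i.e. a positive, concentration-like scale that keeps every moment
calculation linear — so configured shifts are exactly recoverable in
SD units — while remaining strictly positive for the log transform.
What the generator does **not** emulate: NMR lineshapes, J-coupling,
baseline artefacts, batch/instrument effects, non-Gaussian tails,
missingness, or any dependence of profile on age/gender (independent
unless configured).  Passing tests therefore demonstrate correctness of
the algorithms under the assumed covariance/effect structure, not
clinical performance on real cohorts.

## Problem sizes and reproducibility

The reference analyses run at n = 2000 samples × 153 variables (the
summary-prevalence check uses n = 20,000; null-behaviour checks
n = 4000–5000); cross-validated permutation checks use 2 repetitions of
5-fold CV with 100 permutations on an informative cohort of n = 1200 —
sizes chosen so the whole suite completes in about a minute while every
statistical property remains well-powered.  A single global seed fans
out to per-stage seeds through `numpy.random.SeedSequence(seed,
spawn_key=(stage_index,))`, so the split, CV and SOM stages are
independently reproducible and artifacts embed the seed and a SHA-256
config hash.

## Known limitations

* The exact O-PLS deflation variant differs subtly between published
  implementations; the scheme above (orthogonalised-loading weights,
  single-response closed form) is the one implemented and tested.
* The DeLong CI is asymptotic and degenerates when AUROC saturates at
  1.0 (zero variance); the interval is clipped to [0, 1].
* Registered MetS definitions are membership sets only; no rule
  grammar.
* Risk-factor flags are inputs; assigning them from raw biochemistry
  (clinical cut-offs) is out of scope.
* The SOM is a visual grouping device; it performs no prediction, and
  no U-matrix diagnostics are provided.
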