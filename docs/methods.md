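# Methods

`noddinorms` implements a pipeline for deciding what counts as normal versus
abnormal gray- and white-matter microstructure on ROI-level NODDI metrics
(NDI, the neurite density index, and ODI, the orientation dispersion index,
both dimensionless fractions in (0, 1)), and for asking whether those
metrics add diagnostic information beyond CSF amyloid/tau biomarker status.
This note records the model, the defaults and why they were chosen, the
numerical decisions, and what the synthetic data can and cannot show.

## Robust normative model

For every (ROI, metric) cell, the normative reference is an ordinary
least-squares regression fitted in a "presumed non-neurodegeneration"
group — cognitively unimpaired (CU) participants negative on both CSF
amyloid and tau (A−T−):

    predicted = b0 + b_age · (age − age_center) + b_sex · sex
    z         = (observed − predicted) / RMSE

with sex coded 0 = male, 1 = female. The procedure is *robust* in the
internal-norms sense: after an initial fit, any normative participant whose
z falls **at or below −1.5** in *any* of the 24 (ROI, metric) cells is
removed in a single pass, the regressions are refit on the reduced set, and
the refit coefficients and RMSE are frozen and applied to every participant.
The exclusion is one-sided by design — only low values signal
neurodegeneration-like abnormality; ODI elevation in some white-matter
tracts of impaired groups therefore never triggers exclusion.

Decisions taken where the procedure was open:

- **RMSE denominator**: residual root-mean-square with `n − 3` in the
  denominator (three estimated coefficients); a plain `1/n` variant is
  available (`rmse_denominator="n"`). The choice shifts z by a factor
  `sqrt((n−1)/(n−3))` ≈ 0.5% at n ≈ 200 and does not move any conclusion.
- **Age centering**: the mean age of the normative fitting set, frozen
  inside the serialized `NormativeModel` so applying saved norms to new
  data is reproducible.
- **Single pass**: exclusion runs remove-once-then-refit; `iterate=True`
  repeats to convergence but is off by default.
- **Boundary**: "1.5 or more SD below" is inclusive (z ≤ −1.5 flags).

On the final normative subset the per-cell z-scores have mean 0 (an OLS
residual identity, machine precision) and SD `sqrt((n−3)/(n−1))` ≈ just
below 1 — the acceptance band [0.95, 1.05] reflects this.

## A/T classification and sample selection

Amyloid positivity: CSF Aβ42/Aβ40 ratio **strictly below 0.046**. Tau
positivity: p-Tau181 **at or above 24.8** (assay units, pg/mL semantics).
Both cutoffs are config fields (`CutoffConfig`) and the boundary semantics
are taken literally. The analysis-sample filter retains CU participants in
A−T−/A+T−/A+T+ and impaired (MCI/AD) participants only when amyloid
positive; A−T+ participants fall outside the amyloid-first AD continuum and
are dropped with a ledgered reason, as are amyloid-negative impaired
participants.

## Group comparisons

Per (ROI, metric) cell: Kruskal–Wallis omnibus across group levels
(tie-corrected H, chi-square p with k−1 df), Benjamini–Hochberg FDR within a
family, and pairwise two-group Kruskal–Wallis follow-up **only** for cells
passing the omnibus gate at α. Effect sizes are Cliff's delta
(P(X>Y) − P(X<Y)) with a 95% CI from the consistent unbiased variance
estimate (row means, column means, and individual dominance indicators) and
a normal approximation, truncated to [−1, 1].

Open choices: the FDR family defaults to the 6 ROIs within each
metric × tissue-class block (matching how the results tables are organised);
`family="all"` adjusts across all 24 cells jointly. Which of the two a given
study used is often unstated, so both are supported and the default is
documented rather than inferred. Ties take average ranks everywhere.

## Firth-penalized logistic model suite

Ten models predict clinical status (CU = 0 vs MCI/AD = 1), all containing
age and sex: (0) base; (1) + ordinal CSF A/T status coded 1 = A−T−,
2 = A+T−, 3 = A+T+; (2–5) + the six **raw** bilateral ROI means of one
metric × tissue block (WM NDI, WM ODI, GM NDI, GM ODI); (6–9) A/T status
plus each block. With ~11 impaired cases the data are close to (sometimes
completely) separated, so coefficients are estimated by maximizing the
Jeffreys-penalized likelihood l*(β) = l(β) + ½ log det I(β) (Firth
correction), which keeps estimates finite under separation.

Numerics: modified-score Newton iterations (the score augmented by
h_i(½ − p_i) with h the hat diagonal), step-halving up to 10 times when the
penalized likelihood would decrease, convergence at penalized-score norm
< 1e-8. Design columns are internally rescaled to unit spread purely for
conditioning (the objective is equivariant; results are reported in raw
units). Because the Fisher information omits the penalty's curvature, the
iteration is only linearly convergent when the penalty dominates (tiny n or
heavy separation); the default iteration cap is therefore 200, and a
BFGS polish on the penalized objective (whose exact gradient is the
modified score) runs if the cap is hit.

Model assessment, per model: in-sample ROC AUC via the rank (Mann–Whitney)
formula with ties counted ½ and a DeLong structural-components 95% CI;
AIC = −2·(penalized log-likelihood) + 2k — the penalized likelihood is an
approximation to the likelihood-based AIC, flagged as such; and
PLR = 2·(pll_model − pll_reference) with the reference configurable
(default: the age+sex base model). The PLR is defined explicitly this way
because published PLR columns often leave the reference and sign convention
implicit. AUC is in-sample with no cross-validation, matching the procedure
being modelled; in-sample AUCs of models with ~12 covariates at n ≈ 300
carry optimism of roughly +0.05–0.10 under the null, which is why the null
simulation accepts AUC up to 0.65 rather than 0.5 exactly.

## Voxel-level extraction

On co-registered volumes (registration itself is out of scope — a
grid-equality check stands in for warping): GM fraction = clamp(1 − WM −
CSF, 0, 1) (the raw subtraction can go negative where WM + CSF > 1; the
clamp enforces physical bounds); pseudo-T1 = 0·CSF + 1·WM + 2·GM, a
synthetic structural contrast used upstream to drive registration; GM ROI
means are unweighted over voxels with a matching label **and** GM fraction
≥ 0.7 (threshold inclusive — the boundary convention is an assumption,
configurable); WM tract means weight each voxel by its tract probability
over the p > 0 support, so zero-probability voxels contribute nothing. GM
values are extracted per hemisphere and averaged; WM probability maps come
as left/right pairs averaged after extraction (symmetric with GM; a single
bilateral map is also accepted).

## Synthetic data: what it emulates, what it does not

The cohort generator is first-class, tested code and defines the study
conditions. Defaults:

- **Cell counts** mirror the 296-participant cohort: CU 231/26/28 across
  A−T−/A+T−/A+T+, MCI 0/1/5, AD 0/1/4. (One source paragraph prints CU
  A+T− = 16 against the table's 26; the default follows the table and both
  are configurable.)
- **Ages**: normal, truncated to [45, 95] years; CU 65.10 ± 7.81,
  MCI 71.77 ± 9.73, AD 71.36 ± 2.52. **Female fractions** 0.65/0.83/0.40,
  sampled per participant.
- **CSF analytes**: log-normal within each A/T cell, truncated by
  inverse-CDF sampling to the cutoff side of the cell, so classification
  from the generated analytes reproduces the assigned cell with probability
  one. Locations (A− ratio median 0.070, A+ 0.034; T− p-Tau median 16.5,
  T+ 33.0; Aβ40 median 15000) are plausible assay-scale values chosen once.
- **ROI values**: baseline + b_age·(age − 65) + b_sex·sex + shift·SD +
  noise, clipped to (0, 1). Age slopes are small and negative for NDI
  (−0.0010 to −0.0015/yr) and small positive for ODI; residual SD 0.03.
- **Planted group effects**, in residual-SD units: impaired groups get
  −1.0 on GM ODI in all six ROIs, −0.9 on GM NDI in hippocampus,
  parahippocampus and posterior cingulate, −0.9 on WM NDI in ILF and both
  cingulum segments, and the bidirectional WM ODI pattern (+1.0 uncinate,
  +0.9 cingulum-hippocampus, −0.8 ILF); CU A+T+ gets milder −0.45/−0.5 ODI
  reductions in posterior cingulate, inferior parietal + precuneus and
  forceps major. Magnitudes were chosen once to produce Cliff's deltas in
  the 0.4–0.6 range at the impaired-group sizes.
- **Residual correlation**: cell residuals share a participant-level
  component carrying 60% of the variance (`residual_correlation = 0.6`),
  emulating the strong within-person correlation of microstructure metrics
  across regions.

Known fidelity limits. Real ROI metrics are correlated across regions far
more strongly (and with richer structure) than a single shared component
can express: under independent cell noise the "any cell ≤ −1.5" rule would
flag ~80% of a 231-person normative set, and even ρ = 0.95 leaves the
expected exclusion fraction near 14%, versus single-digit percentages in
real cohorts. The default ρ = 0.6 yields ~30–40% excluded. Consequently the
synthetic runs validate the *mechanics* of the procedure (who gets flagged
and why, the z identity after refit, frozen-model application) but not the
real-data exclusion *rate*. Scanner/site effects, longitudinal structure,
and voxel-level realism of the phantom (cubic ROI blobs, Gaussian tract
blobs on a 32³ grid) are likewise not modelled; passing tests say nothing
about registration quality or NODDI fitting, which are upstream and out of
scope.

## Problem sizes and determinism

The test suite and acceptance checks run simulations at deliberately modest
sizes chosen to estimate each property well: normative cohorts of 120–500,
50 seeds for the exclusion-fidelity check, 200 replicates for slope
recovery, 1000 replicates for DeLong coverage, 12,000 null omnibus tests
for type-I calibration, and 20-seed model-suite orderings. Every stochastic
path flows from explicit integer seeds (numpy `default_rng`); identical
seeds give byte-identical CSV outputs, which the end-to-end determinism
test asserts literally.
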