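# Methods

This note records the model, the numerical choices, and the limits of what
the synthetic experiments can show. Everything quantitative stated here is
recomputed by the test suite or by `scripts/acceptance.py`; nothing is quoted
from elsewhere.

## Model and assumptions

The package works on ROI-mean linear attenuation coefficients μ (1/cm) at a
pair of virtual monoenergetic energies, default (50, 200) keV. Nothing in the
math depends on the literal energies; they label the two channels and any
`EnergyPair` with 0 < e_low < e_high is accepted.

Core assumptions, in decreasing order of importance:

* **Linearity.** Attenuation of a mixture is the volume-fraction-weighted sum
  of constituent attenuations at each energy. This holds for ideal mixing;
  volume excess on mixing real solutions, temperature-driven volume changes
  and K-edge effects inside the measured spectrum all violate it slightly and
  are out of scope.
* **Volume conservation.** Fractions sum to 1. This supplies the third
  equation of the three-material system and the renormalization logic of the
  extra-material correction.
* **Histology area ≈ volume.** The reference modality reports area fractions
  on thin sections; the package treats them as volume fractions without
  correction. This is an assumption, not a theorem, and is inherited by every
  downstream number.
* **Additive Gaussian measurement noise** (synthetic data only, see below).

## The extra-material correction

Histology sees three materials; the CT point also contains up to two
"extra" materials (contrast agent, fixative). Writing μ^Histo for the
attenuation of the histology composition, each extra k defines a path vector
μ_k − μ^Histo, and the fitted point is μ^Histo shifted by Σ f̃_k·(μ_k − μ^Histo).
The cost is the squared Euclidean distance between the shifted point and the
measured point, minimized over f̃_k ≥ 0, Σf̃_k ≤ 1 − ε.

This is a 1- or 2-variable constrained linear least squares. It is solved
**exactly** by enumerating active constraint sets (each variable free or at
zero; sum constraint active or not) and solving the small equality-constrained
system for each — no iterative optimizer, no convergence tolerance. When the
unconstrained two-path solution would need a negative fraction, the active-set
solution automatically re-fits with that extra at zero; such specimens are
corrected by a single path and generically retain a nonzero matching error,
whereas two independent paths reach any interior point of the plane exactly
(cost 0). Collinear path vectors with two extras degrade the geometry to one
dimension; the fit warns and returns the better single-path solution.

Numerical choices: ε = 1e−6 keeps c_s = 1/c_a finite; the matching error is
defined per energy as 100·|μ_opt − μ_meas|/μ_meas (the relative form; the
choice is used consistently everywhere); reports round fractions to 3 decimals
and concentrations to mg/ml with 3 decimals while JSON output keeps full
precision.

## Basis-factor calibration

For contrast-free fixed specimens, the assumed 2×3 basis attenuation matrix is
corrected entrywise by factors c_m (m = 1..6) while each specimen carries an
unknown formalin fraction f̃_4,j removed via
μ'_j = (μ_CT,j − f̃_4,j·μ_formalin)/(1 − f̃_4,j). The joint cost — summed
squared residuals of (μ'_j, 1) against the corrected matrix times the
histology composition — is bilinear in (c, f̃_4) and therefore non-convex with
a famously flat curved valley.

Solver design (the genuinely open part of the design):

* **Profiled global stage.** For fixed f̃_4 the cost is an ordinary bounded
  linear least squares in c, solved exactly (BVLS). The global search
  (simplicial homology, sobol sampling, default 128 points / 2 iterations)
  therefore runs only over the formalin fractions — 4 dimensions for a
  4-specimen group instead of 8 — which makes it cheap and reliable.
* **Joint polish.** Candidate starts are polished by a bounded trust-region
  least-squares solve over (free c, f̃_4) on the residual vector. On
  noiseless data this reaches machine-precision cost where simplex or
  quasi-Newton descent on the scalar cost stalls in the flat valley (observed
  stalls at ~1e−13 versus ~1e−31 after the switch).
* **Bounds.** c ∈ [0.25, 5] per free factor — wide enough for near-unity
  density corrections and for the several-fold factors that arise when a
  material was seeded from a badly wrong chemical assumption (e.g. treating
  red cells as hemoglobin solution at MCHC density). f̃_4 ∈ [0, 0.999].
* **Convention.** WBC factors are frozen at 1 by default (`{"WBC": 1.0}`):
  WBC is close to generic soft tissue, contributes little, and freezing it
  keeps the per-group problem identifiable.
* **Determinism.** All stages are deterministic for a fixed configuration;
  there is no stochastic sampling in the optimizer.

Identifiability: a group of n specimens supplies 2n equations for
4 + n unknowns (4 free factors + n formalin fractions), so n ≥ 4 is required
for a unique noiseless optimum; with n < 4 the zero-cost set is a continuum
and results are start-dependent. The package enforces only n ≥ 2 (the math is
defined) but the tests and the shipped defaults use 4, and users should too.

Group aggregation uses weights ∝ 1/cost, normalized — the absolute scale of
the cost (raw, per-mille display, per-specimen) cancels. A vanishing cost is
floored at 1e−300 purely to avoid division by zero, which makes an exactly
fitting group weight-dominant, as it should be. A per-mille display
(`cost_per_mille`) is provided for factor-table-style reports; the raw value
is what is stored.

## Dilution-series regression

Endpoint determination is implemented as two independent OLS fits of μ
against concentration, evaluated at the stock concentration — the only
reading under which "endpoints" carry per-parameter relative standard errors
(reported as |SE/estimate|·100). Water is never fitted; it enters only as the
theoretical zero-concentration crossing checked by the diagnostic, which
reports per-material intercept offsets and the scatter of pairwise line
intersections in the (μ_low, μ_high) plane and never raises: disagreement
there is a data-quality signal (volume excess, temperature drift), not a
programming error. Errors-in-variables regression is deliberately out of
scope.

## Synthetic phantoms: what they emulate and what they do not

The generator produces two cohort types with exact ground truth:

* **Aqueous tubes** — pipetted volumes of eosin (40 mg/ml stock), iomeprol
  (20 mg/ml), NaCl (200 mg/ml) and water; volumes → fractions → attenuation
  by forward mixing. The shipped recipes mirror laboratory practice
  (0.005–1.0 ml volumes in 1.5 ml tubes).
* **Clot-like specimens** — histology triples drawn from a two-mode Dirichlet
  sampler (fibrin-dominant and RBC-dominant clusters, reflecting the regional
  clustering of real clot constituents), WBC capped at 0.15 by rejection;
  hidden formalin (default U(0.05, 0.35)) and iomeprol (default U(0, 0.065),
  i.e. up to ~1.3 mg/ml at the 20 mg/ml stock) shift the measured point along
  their paths; optionally the generating basis attenuations are scaled by
  known correction factors so calibration has a recoverable truth.

Noise is additive, independent, Gaussian per energy in μ-space, applied to
measurements only. The default σ = 0.002 1/cm is illustrative — chosen so
that sub-mg/ml contrast concentrations sit near the recovery limit, which is
where the interesting behavior lives. Real scanner noise is neither Gaussian
in μ nor energy-independent, and ROI means also average spatial
heterogeneity; the phantoms model none of that. Consequently, passing tests
demonstrate the correctness of the *algorithms* (inversions, recoveries,
calibration) under the stated model, not the accuracy achievable on any
particular scanner.

The detection-limit experiment quantifies the single-path correction under
noise: with a roughly constant absolute concentration error set by the noise
level, the relative error grows as concentration falls (at the default noise,
means of roughly 25–30% at 0.66 mg/ml, ~11% at 1.66 mg/ml, ~4% at 5 mg/ml
over 300 replicates). The experiment reproduces the qualitative concentration
dependence of accuracy; the absolute limit depends entirely on the configured
noise and is not a scanner statement.

## Shipped constants

`demix.materials` ships example attenuation values: aqueous endpoints in the
style of dilution-series regressions, NIST-style water values, a formalin
solution slightly above water, calibrated-style clot constituents, and a
deliberately wrong "initial" clot basis (RBC seeded several-fold low) for
calibration demonstrations. All are illustrative defaults, not measured
ground truth; real use replaces them via the YAML material files.

## Degenerate inputs and tie-breaks

* Three-material solve refuses condition numbers above 1e8 (configurable) —
  that ceiling separates linearly dependent bases from merely similar ones.
* Fractions outside [0, 1] from the solver are returned as computed with an
  out-of-gamut flag; clamping would destroy the geometry the correction
  relies on.
* Active-set ties in the correction (equal cost) resolve to the smaller total
  extra fraction.
* Histology rows must sum to 1 within 5e−3 (3-decimal table convention) and
  are renormalized exactly; full-precision compositions use 1e−6.
* HU below −1000 (negative μ) is an error unless explicitly overridden.

## Known limitations

* Table 1-style printed fractions are rounded to 3 decimals; concentrations
  computed from rounded fractions can disagree with concentrations computed
  from full-precision fractions in the last digit (e.g. 0.0333…·20 = 0.667
  vs 0.033·20 = 0.66). The package computes from the fraction it is given and
  leaves the rounding policy to the report layer.
* No voxelwise decomposition: the unit of analysis is the ROI mean.
* No polychromatic, detector-response or beam-hardening modeling; inputs are
  assumed to be proper virtual monoenergetic values.
* The inverse-cost weighting is exactly reproducible only when cost values
  are known at full precision; aggregating from costs rounded to one decimal
  shifts weighted means at the 1e−3 level.
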