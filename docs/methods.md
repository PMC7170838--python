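# Methods

## The analysis in one paragraph

An ORA measurement is a 400-sample applanation signal with two peaks.  Each
eye is measured three times; measurements with vendor quality index ≤ 7.5
are discarded (strict "greater than" cutoff) and the survivors averaged
pointwise into one trace per eye.  From each trace we locate the two
applanation peaks and the inter-peak trough, compute **Monot1-2** (the
summed movement against the expected descend-then-ascend profile between
the peaks) together with 37 surrogate versions of the classical waveform
descriptors, and regress the peripapillary retinal arteries angle (PRAA,
degrees) on 41 predictors: age, AL, SERE, CH, CRF, the 35 descriptors that
are not exact rescalings of others (h11 = ⅔·h1 and h21 = ⅔·h2 are
excluded), and Monot1-2.  Lasso screening reduces the 41 columns to 20
candidates; an exhaustive best-subset search over all 2^20 candidate
subsets picks the minimum-AICc model; the chosen model is refit by OLS and
compared against the same model with Monot1-2 removed (or added, if the
search excluded it) by the F-form nested ANOVA.  A 2-D-latent variational
autoencoder trained on the traces provides denoising reconstruction and the
latent-traversal animation along the PRAA-associated direction.

## Monot1-2

With peak indices `p1 < t < p2` (trough `t` = earliest minimum of the raw
trace strictly between the peaks),

    Monot1-2 = Σ_{i=p1..t-1} max(0, y[i+1] − y[i])
             + Σ_{i=t..p2-1}  max(0, y[i] − y[i+1]).

Properties used as tests: non-negativity; zero exactly on monotone-V
segments; invariance to vertical translation; positive homogeneity of
degree 1; exact agreement with a brute-force adverse-increment oracle.
"Total length of retrogressive movement" is read as summed adverse
*vertical increments*; an arc-length variant (`hypot(1, Δy)` per adverse
step) is available via `monot12(..., method="arclength")` but is not the
default, since the magnitudes the statistic is reported in are signal
units.

Peak detection: moving-average smoothing (window 9), the two most prominent
smoothed maxima at least 40 samples apart, a parabolic apex refinement over
±7 samples of the smoothed trace, then a snap to the nearest raw local
maximum within ±5 samples.  The parabolic step is needed for the detector
to hold its ±3-sample localisation under 2%-of-peak noise; a plain smoothed
argmax wanders by more in roughly one draw in ten.

## Surrogate descriptors

The vendor's 37-parameter algorithms are unpublished, so the package
defines documented surrogates with the same names and qualitative meaning
(heights above a baseline = median of the first 50 samples; widths, areas
and sample counts at a 75% height cut, "1"-suffixed variants at 50%; flank
slopes between height fractions; max 1-step and 3-step rises; Aindex/Bindex
counting down from 10 per adverse flank step; Aplhf = 10× the power ratio
of the window-9 high-frequency residual over the inter-peak segment).
Numerical agreement with the vendor software is explicitly *not* claimed;
only scaling behaviour, degeneracy handling and internal consistency are
tested.

The design matrix has 41 columns.  The published variable list is
ambiguous about keratometry versus SERE (the abstract names keratometry,
the methods and the regression table name SERE); the package follows the
methods/table reading — SERE in, keratometry out — and exposes
`include_keratometry=True` to append keratometry as a 42nd column.

## The VAE

Architecture 400 → 40 → 20 → (μ, log σ²) ∈ R² and mirrored decoder; ReLU
hidden layers, linear outputs; diagonal Gaussian posterior; reparameterised
sampling; Adam (rate 1e-3), batch 16, 500 epochs by default; all randomness
from one seed, so training is bit-reproducible.  Traces are normalised by a
single constant (the training-set maximum) to preserve relative peak
heights.

The loss is reconstruction + β·KL with β = 1 and a Gaussian decoder of
fixed observation sd `recon_sigma` (default 0.01 on the normalised scale,
the order of the instrument's high-frequency jitter):
`recon = ‖x − x̂‖²/(2σ²)` per trace, KL in closed form
`½Σ(e^l + μ² − 1 − l)`.  The observation sd matters: with σ of order 1 on
unit-scale data the KL term dominates and the posterior collapses toward
the prior, erasing between-eye variation (for a linear VAE the per-direction
shrinkage is l/(l+σ²), which is ≈ 0 for every waveform mode at σ = 1).
Setting σ to the noise scale makes the bottleneck — not the KL weight — do
the denoising.

**What the 2-D bottleneck keeps.**  On this package's synthetic cohorts the
two dominant variation modes are the (correlated) peak heights, and the
retrogressive component is independent of them by construction.  A 2-D
latent therefore reconstructs the heights and filters the retrogressive
movement *out*: Monot1-2 measured on reconstructions is uninformative about
the planted magnitude.  This is an information constraint, not a training
failure.  Consequently the pipeline's default measures features on the
triplicate-averaged raw trace (averaging is the denoiser), and the VAE
serves the roles it can serve: per-trace denoising toward the clean
waveform (verified on held-out data at 4%-of-peak noise) and the
latent-traversal visualisation that motivated the statistic in the first
place.  `feature_source="reconstructed"` switches the measurement path to
reconstructions for users who want the other reading.

The PRAA latent axis is this package's construction: least squares
PRAA ≈ intercept + w·μ over the cohort's posterior means; direction w/‖w‖,
slope ‖w‖ (degrees per latent unit).  Traversal decodes
z(s) = center + s·direction for s equally spaced in [−span, span]
(span default: 2 sd of the projected training latents) and orders frames by
decreasing predicted PRAA.

## Model selection

AICc uses the parameter count p = (#slopes) + 2, counting the intercept and
the residual variance, i.e. the convention of the usual statistical
environments, so ΔAICc values line up with Gaussian log-likelihood
comparisons.  The exhaustive search walks subsets in Gray-code order with
Goodnight's sweep operator on the cross-product matrix of standardised
columns (RSS is scale-invariant); one toggle costs O(k²), so the full 2^20
search takes seconds.  Sweep RSS values match naive per-subset least
squares to ~1e-12 at p = 12 (tested, tolerance 1e-8).  Subsets with
n − p − 1 < 1 are skipped and counted.  The winner is refit by OLS on the
raw columns for reportable coefficients, SEs and p-values.

Lasso screening standardises columns, computes the regularisation path on
an explicit 200-point log-spaced penalty grid (down to 1e-4 of the maximal
penalty), takes the largest penalty at which ≥ k coefficients are active
and returns the k features with largest absolute coefficients there, ties
broken by earlier path entry then column order — exactly k names always.
How the original analysis tuned its penalty to land on 20 candidates is not
stated anywhere; this path-based rule is the package's construction.

The nested comparison is the F-test form of ANOVA:
F = [(RSS_s − RSS_l)/Δdf]/[RSS_l/(n − p_l)], p from the F distribution.
Its type-I error at the 5% level is calibrated within ±2 points over 2000
null simulations (tested).

## The synthetic cohort generator

The generator emulates the published study conditions; its defaults are the
published moments and are not tuning knobs:

| quantity | default | source of the value |
|---|---|---|
| eyes × replicates | 54 × 3 | study sample; replicate count from the triplicate design |
| covariates (age, AL, SERE, keratometry, CH, CRF) | 51.0±21 y, 24.6±1.7 mm, −1.91±4.1 D, 8.2±0.5 mm, 10.26±1.0, 9.85±1.3 mmHg | published cohort table |
| absolute peak heights h1, h2 | 611.54±63.00, 526.29±73.74 | published descriptor table |
| peak-height correlation | 0.8 | package choice: both peaks reflect common signal strength |
| retro magnitude | max(0, N(31.55, 25.97)) | published Monot1-2 moments, left-clipped |
| quality index | N(8.81, 0.6) truncated to [0,10] | published; `qi_low_fraction` plants sub-7.5 records for filter tests |
| sample noise sd | 2.0 signal units (~0.3% of h1) | package choice, see below |
| planted PRAA model | 202.6 − 2.37·AL − 0.31·Monot1-2 + N(0, 11.7) | published optimal-model slopes; intercept/noise solved so PRAA ≈ 134.5±14.8° |

Geometry: baseline 100 + two Gaussian bumps (centers 120/280, width 25
samples).  The retrogressive component is four raised-cosine bumps
(half-width 14, at 0.37/0.45/0.55/0.63 of the inter-peak interval) whose
common scale is solved by root-finding so the noise-free trace's Monot1-2
equals the requested magnitude within 1% (in practice to 1e-9).  Two shape
choices deserve their rationale:

* *Smooth, broad retro bumps.*  Retrograde corneal motion is a slow
  mechanical deflection, not sensor jitter.  Narrow kinked deflections
  would put the retro energy into the window-9 high-frequency band, making
  the Aplhf surrogate a near-duplicate of Monot1-2 and the two
  interchangeable under selection — a generator artifact, not a property of
  the method.  The bumps also sit clear of the peak flank regions used by
  the width/slope/Aindex descriptors.
* *Noise sd 2.0.*  The study treats Monot1-2 as a reliable per-eye
  measurement (every measurement passed the quality gate).  At sd 2 the
  triplicate-averaged measurement tracks the planted magnitude with slope
  0.98 and error sd ≈ 4.5 against a between-eye spread of 26 — a reliable
  instrument.  At several-fold higher noise the adverse-increment sum
  acquires a large noise-induced bias and the statistic stops being
  measurable at all, contradicting the study conditions.  The denoising
  experiment deliberately uses much heavier noise (4% of h1) to stress the
  VAE.

What the generator does **not** emulate: correlation between covariates and
waveform shape (age/AL/SERE are drawn independently of the trace, whereas
in real eyes axial length correlates with corneal biomechanics); vendor
pressure-channel outputs (CH/CRF are covariates, not derived from the
trace); between-eye variation in peak positions and widths (fixed
geometry, so width-type descriptors vary only through noise); and
left/right-eye or subject-level clustering.  Passing tests therefore show
that the *pipeline machinery* recovers planted structure under realistic
noise — not that the clinical effect sizes themselves generalise.

## Validation experiments (the quantities `scripts/acceptance.py` recomputes)

* Monot1-2 equals an independent brute-force oracle on 1000 random
  segments (exact); the worked 9-sample segment scores 2.
* Closed-form KL matches numerical quadrature on 100 random codes (≤1e-6).
* Sweep-based subset search matches naive refits for all 2^12 subsets
  (≤1e-8 on RSS) and a full 2^20 search completes in seconds.
* Planted-coefficient recovery: twenty 500-eye cohorts with planted
  AL = −2.37 and Monot1-2 = −0.31; both predictors selected in ≥90% of
  seeds and mean estimates within 20% of truth.  The repeated experiment
  screens to k = 12 candidates (2^12 subsets per seed) — the full k = 20
  search is exercised separately — and measures features on averaged
  traces.
* Denoising: after seeded training on 500 single-replicate traces at
  4%-of-peak noise, held-out reconstructions are on average L2-closer to
  the clean truth than the noisy inputs (ratio ≈ 0.3).
* Nested-ANOVA null calibration: rejection rate 0.05 ± 0.02 at n = 2000.
* Structure: 400-point encoder input, 2-D latent, 41 design columns,
  exactly 20 Lasso candidates, quality cutoff 7.5.

## Numerical choices and degenerate inputs

* Trough = earliest global minimum strictly between the peaks.
* Baseline = median of the first 50 samples; smoothing window 9 for both
  peak detection and the Aplhf residual.
* Widths use linear interpolation of the level crossings and are floored at
  1 sample; slope denominators are floored at 0.5 samples.
* The sweep search standardises candidate columns for conditioning (RSS is
  invariant); a near-zero pivot aborts with a collinearity error rather
  than returning garbage; constant columns are dropped (screening) or
  flagged (univariate scan).
* `aicc` refuses rss ≤ 0 (saturated fits) and n − p − 1 < 1.
* Eyes losing all replicates to the quality filter are dropped with a
  warning and listed in the averaging metadata; design assembly names eyes
  with missing covariates or PRAA.
* Pipeline seeds for the simulator, VAE initialisation, training and the
  repeated-seed experiments are all derived from the single run seed (kept
  below 2^31), so a rerun with the same configuration is bit-identical.

## Known limitations

* The surrogate descriptors are not the vendor's; analyses that depend on
  their exact clinical scaling do not transfer.
* A 2-unit latent cannot represent more than two independent waveform
  modes; cohorts with richer variation need a larger `latent_dim` before
  reconstruction-based feature measurement becomes meaningful.
* The generator's independence assumptions (above) make decoy predictors
  easier to reject than in clinical data, where collinearity between
  biomechanical descriptors is strong.
* AICc-based exhaustive search intentionally tolerates false inclusions;
  selection frequencies, not single-run subsets, are the interpretable
  output of the recovery experiment.
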