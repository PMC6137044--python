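# Methods

## Coordinate and unit conventions

One convention is stated once and used everywhere: `x` is the column
direction, `y` the row direction, the origin is the *center* of pixel
(0, 0), frame indices are 0-based, physical coordinates are micrometers,
and diffusion coefficients are µm²/s. Pixels appear only inside
image-processing internals. This removes the classic half-pixel
disagreement between detection, rendering and distance computation.

## Drift quantification

The movement of an immobilized cell between consecutive frames is the
integer shift maximizing the circular cross-correlation of the two frames
(or of a rectangular ROI around one cell), computed as
`ifft2(fft2(b)·conj(fft2(a)))`. Choices:

- **Mean subtraction, no windowing.** Each frame is mean-subtracted before
  the FFT to suppress the DC peak; this is the minimal preprocessing that
  makes the estimator robust to additive noise. Whether the original
  analyses windowed or background-subtracted is unknown; this choice is
  ours and is documented as such.
- **Integer pixels by design.** Movement is reported in whole pixels — the
  question being answered is "does the cell move at the camera's
  resolution", not "register to 0.01 px". No sub-pixel interpolation, and
  no drift *correction* is applied downstream.
- **Tie-break.** If several correlation pixels share the maximum, the
  lexicographically smallest signed (dy, dx) wins — deterministic on
  degenerate synthetic inputs. Shifts are reported signed in (−N/2, N/2].
- Constant frames have no correlation peak and are rejected rather than
  returning an arbitrary argmax.

The drifting-cell generator uses periodic (circular) translation by
default, which makes the FFT estimator *exact* and turns generator ground
truth into a sharp oracle; a zero-padded mode exists for realism. ROI
correlation of non-periodic content is accurate to the extent the content
dominates the wrap-around edge, which is the usual situation for a cell
well inside its ROI.

## Spot detection and localization

- **Discoidal averaging filter**, inner radius 1 px, outer radius 3 px
  (pixel-center distances, reflected borders): mean over the inner disk
  minus mean over the annulus. This band-pass matches the scale of a
  diffraction-limited spot at 80 nm pixels.
- **Detection threshold** is expressed in robust background standard
  deviations of the filtered frame (1.4826·MAD, falling back to the plain
  SD for noise-free synthetic frames). The default of 5σ gives ≲1 false
  positive per 100 blank 32×32 frames.
- **Sub-pixel refinement** is an intensity-weighted centroid over a
  (2·r_outer+1)² raw-image window with the window minimum subtracted. A
  centroid is deterministic and accurate to ≪0.1 px on rendered spots;
  the localizer is isolated behind one operation so a Gaussian MLE fitter
  could be swapped in without touching anything else.
- Maxima closer than r_outer are merged keeping the brighter response —
  two emitters under ~1 px apart are one detection, by design.

## Trajectory linking

Greedy frame-to-frame nearest-neighbor linking, resolved globally per frame
pair by ascending distance, with a hard step cap (`max_step_um`) and
optional gap bridging (`max_gap_frames`). Greedy linking is correct in the
sparse regime the emulated experiments operate in (inter-particle spacing
≫ typical step); it makes no attempt at globally optimal assignment.
Step-size extraction at lag k only uses index pairs with *all* intermediate
frames present, so bridged gaps never contaminate the step distribution.

## Two-population CPD fit

For 2D Brownian motion, P(step² ≤ r² at lag t) = 1 − exp(−r²/(4Dt)); a
mobile/immobile mixture gives

    P(r², t) = 1 − α·e^(−r²/(4D₁t)) − (1−α)·e^(−r²/(4D₂t)),  D₁ ≥ D₂.

Numerical choices:

- **Unbinned CPD.** The empirical CPD is evaluated at the sorted squared
  sample steps (P = i/n), avoiding any bin-width parameter. The fit is
  plain least squares of the model against these ordinates with bounds
  α ∈ [0, 1], D₁, D₂ ≥ 0; the mobile-first convention is restored by
  swapping after the fit if needed.
- **Initialization** from the tails: D₁ from the 90th percentile of r²,
  D₂ from the 10th, α = 0.5. On the presets the optimizer is insensitive
  to the start; fitting the model's own tabulated curve returns the
  parameters to better than 4 significant figures.
- **Localization error is absorbed into apparent D** (per-step variance
  4Dt + 4σ²), which is what experiments report. Consequently the packaged
  tracking presets generate at the reported apparent coefficients with no
  extra coordinate noise; the image-level pipeline exercises real
  localization error separately.
- **Uncertainties** by bootstrap over steps (default 200 resamples,
  seeded), restarted at the point estimate. At n = 5000 steps this gives
  σ(α) ≈ 0.009 — consistent with the per-seed scatter of the recovery
  tests.
- **Immobile coefficient.** "Immobile" means at the detection limit, not
  zero; the preset value 1·10⁻⁵ µm²/s (20 nm rms step at 10 s lag) keeps
  the mixture non-degenerate. With α pinned at 1 the fit reduces exactly
  to the single-population closed form.
- Only lag 1 feeds the headline fit (consecutive frames); other lags are
  available through `step_sizes(..., lag_frames=k)`.

## Eisosome distance mapping

Blink localizations of the marker are condensed by single-linkage
clustering with a radius parameter (components of the ≤radius graph),
keeping clusters with ≥ `min_points` members and taking the mean position
— the simplest deterministic rule, isolated behind one operation.
Distances are plain 2D Euclidean nearest-centroid distances (exhaustive
`cdist` + argmin; ties to the lowest index), with no membrane-surface
correction or channel registration. Histograms are left-closed
right-open from 0 with a default 50 nm bin width — finer than the 20–50 nm
localization accuracy would be meaningless — and all population labels
share one set of edges.

## FRAP analysis

Traces are normalized by the mean of the pre-bleach samples (20 by
default), fixing F_pre = 1 rather than co-fitting it. The post-bleach
samples are fitted with F(t) = F₀ + (F∞ − F₀)(1 − e^(−ln2·t/t½)),
parameterized directly in t½ so the headline quantity is a fit parameter;
bounds keep 0 ≤ F₀, F∞ − F₀ and F∞ ≤ 1.2. The mobile fraction is
(F∞ − F₀)/(1 − F₀). A flat (no-recovery) model is compared by AIC and a
warning flag is set when it wins, catching non-monotone traces. No
acquisition-bleaching correction is applied (the emulated protocol has no
reference ROI).

**Halftime → D.** D = γ·w²/(4·t½) with γ = 0.88 (uniform circular beam)
and w the bleach-spot radius, both explicit inputs. With the nominal
1-µm-diameter spot and t½ = 196 ms this relation yields ≈ 0.28 µm²/s,
several-fold below typical published liquid-disordered lipid mobility
(~1.2 µm²/s). The discrepancy cannot be resolved without knowing the
effective bleach radius of the original optics, so the package does not
bake in any correction: the self-consistency of the round trip
D → t½ → fit → D is what is tested (exact to <2%), and absolute D values
should be interpreted with the chosen (γ, w) stated alongside.

## Synthetic data: what it emulates, and what it does not

The generators state one world and keep it fixed:

- 80 nm pixels, 100 ms standard frame interval, 10 s tracking interval,
  50 ms FRAP sampling with 20 pre-bleach frames — the emulated acquisition
  settings.
- Tracking presets: `aptes_yeast` α = 0.57, D₁ = 5.1·10⁻⁴ µm²/s;
  `cona_yeast` α = 0.59, D₁ = 5.4·10⁻⁴ µm²/s; D₂ = 1·10⁻⁵ µm²/s both.
- FRAP preset `frap_guv_ld`: 82% mobile, t½ = 196 ms, bleach depth 0.6,
  measurement noise σ = 0.02 (normalized units).
- Free choices, fixed up front because the emulated experiments do not
  state them: emitter integrated intensity 2000 counts, additive Gaussian
  camera noise σ = 5 counts, PSF σ = 1.3 px.

Not emulated: photophysics (blinking/bleaching of tracked emitters),
Poisson/EMCCD noise statistics (Gaussian additive noise only), membrane
curvature (all motion is planar 2D), diffusion during the bleach pulse
(bleach is instantaneous and uniform), and cell morphology (drift movies
contain generic smooth blobs). A green recovery test therefore
establishes that the estimators are unbiased and correctly implemented
*under the stated model*, not that the model captures every feature of
real movies; the oracle-equivalence tests (brute-force correlation,
double-loop filter and distance oracles, DKW band against the analytic
CDF) establish exactness of the deterministic computations independently
of any model assumption.

## Determinism

Every generator is a pure function of (config, seed), using
`numpy.random.default_rng`. Pipeline runs expand one global seed into
per-stage child seeds through a fixed stage-id table
(`SeedSequence([seed, stage_id])`), so adding a stage never perturbs
existing streams; manifests record SHA-256 hashes of every artifact and
identical config + seed reproduces identical hashes.

## Known limitations

- Greedy linking degrades at high particle density or fast diffusion
  (steps comparable to spacing); no motion-model or global assignment.
- The centroid localizer carries a small bias toward the window center on
  structured backgrounds; it is accurate on the sparse TIRF-like images it
  is meant for.
- The two-population model cannot represent anomalous diffusion or more
  than two mobility states; residual structure in the CPD fit is the
  diagnostic to watch.
- The single-exponential FRAP form is an empirical recovery description;
  it is not the Soumpasis reaction–diffusion solution, and D conversion
  inherits the (γ, w) caveat above.
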