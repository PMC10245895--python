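# Methods

This note records the models implemented in `cordmotion`, the
parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic validation does and does not
demonstrate about real data.

## Movie model and conventions

Movies are `T x Y x X` tensors, floating point internally, 0-based,
pixel units. Invalid pixels (outside a warp's support, behind
registration borders, division guards) are NaN and are propagated, never
filled: any interpolation stencil touching a missing pixel yields a
missing pixel. The rostrocaudal axis defaults to image rows (`rc_axis =
"y"`) and is configurable; nothing in the maths depends on the choice.
Transforms map moving-frame coordinates to fixed-frame coordinates
(`p_fixed = A p_moving + t`); warping resamples by inverse mapping with
linear interpolation. Displacement fields live on the fixed grid: the
corrected image is `moving(y + u_y, x + u_x)`.

## Preprocessing

* **Detrend** (photobleaching): a polynomial of order 1 or 3 is fit to
  the per-frame mean intensities; the fit is subtracted from every pixel
  and the grand mean added back, so values stay in the original range
  and never go systematically negative. Idempotent to 1e-9.
* **Spatial bandpass divide**: each frame is divided by its own
  low-pass version, keeping 0–10 cycles per field of view. The mask
  shape was open; we use a radially symmetric FFT mask with a
  raised-cosine rolloff over 2 cycles to suppress ringing. Operates on
  raw (not log) intensity; frames must be strictly positive.
  Denominators below 1e-12 become missing.
* **Registration normalization**: mean subtraction; subtract a
  pillbox-averaged version (disk radius = one tenth of the smaller
  frame dimension — FFT convolution above radius 7); smooth with a
  3 px disk; optionally complement (max − pixel) so dark vessels become
  the brightest structures. "Cross-correlation with a circular
  averaging filter" is implemented as convolution (identical for
  symmetric kernels).
* **ΔF/F**: F₀ is the pixelwise temporal mean or the pixelwise bottom
  0.1 % of values over time ("soft minimum"). Non-positive F₀ marks the
  pixel missing.
* **8-bit export**: soft min/max at the 1st / 99.99th percentiles, then
  `Mf = round(255 (0.01 + 0.99 M1))` — the printed source formula for
  this step is typographically garbled; this version satisfies its
  stated intent (values shifted upward so no frame is fully dark, which
  degrades feature tracking).
* **Borders**: after registration a fixed border of
  `min(ceil(max motion), 14)` px is masked on every frame.
* **Down-sampling**: spatial 2× / 4× bilinear; temporal 4× by linear
  interpolation of each pixel's time series at T/4 points spanning the
  original endpoints.

## LD-MCM: control-point rigid correction

Feature tracks (any tracker emitting per-frame `x, y, likelihood`; the
pose-estimation 3-row-header CSV dialect is read and written) are gated
at likelihood > 0.99 per record. The per-frame transform is **rigid**
(rotation + translation, no scale/skew): large shifts must be removed
while preserving image mass; residual non-rigid motion is handled by
the next tier.

The robust fit runs 1,000 seeded trials; each trial fits the closed-form
rigid transform to a random pair of correspondences and scores all
points with a truncated quadratic (`min(r, 20 px)^2`, i.e. MSAC). MSAC
rather than raw inlier counting is a deliberate deviation from plain
consensus counting: with 50 % contamination and a generous 20 px gate, a
candidate that loosely absorbs a gross outlier can win a count tie
against the tight true consensus; truncated-quadratic scoring prefers
the tight set, and Monte-Carlo recovery at 50 % gross contamination of
8 points is then ≥ 99.9 % (0 failures in 6,000 seeded problems). The
winner is refined by iterated Procrustes refit / re-gating plus a robust
(3 × MAD, floor 3 px) trim.

Because field-of-view motion is shared by all true landmarks, a frame
whose consensus covers fewer than half of its gated features (or fewer
than 2) is treated as a tracking failure: it inherits the nearest
corrected frame's transform and is flagged `interpolated`, and the
residual pass — phase correlation against the reference frame on an
automatically selected subregion (maximal spatial contrast / temporal
variance over ≥ 90 %-valid pixels, the "most stable" patch) — supplies
the actual correction there. On normal frames residual estimates above
5 px are rejected as occluder captures; on flagged frames the bound is
the 20 px inlier gate.

Feature QC computes the Spearman correlation matrix between the
features' per-frame rostrocaudal displacement series and drops features
whose mean correlation falls below threshold — a feature tracking a
withering vessel or an occluder decorrelates from the ensemble.

## NR-MCM: constrained diffeomorphic demons

The demons solver is written in numpy/scipy: multiscale (3 levels,
factor 2), image-force updates `u = d ∇m / (|∇m|² + d²)` on
intensity-standardized frames, fluid smoothing of the update (σ = 1 px),
compositional accumulation `φ ← φ∘(id + u) + u`, and Gaussian smoothing
of the accumulated field with σ = 1.5 px each iteration. Iteration
budgets (2000/400/100 coarse-to-fine) are upper bounds: a level stops
once the mean-squared mismatch stops improving by 1e-5 relative for 10
iterations. "Accumulated field smoothing of 1.5" is interpreted as the
Gaussian σ in pixels. A SimpleITK diffeomorphic-demons run serves as an
independent cross-check in the test suite, never as the implementation.

The mediolateral constraint is applied **inside the solver**: the ML
component is zeroed after every iteration, so the RC component only
absorbs motion it can genuinely explain, and every emitted field
satisfies `max |u_ml| == 0` exactly. The cost of the constraint is
documented by test: a purely mediolateral synthetic warp is left
essentially uncorrected (a free 2-D field removes most of it).

Fields are estimated on registration-normalized frames but applied to
the analysis movie (typically the bandpass-divided one) — the two-track
flow is explicit in the API (`apply_to=`). Frames are registered to a
single fixed template; a residual translation pass on the interior
(cropped by the maximal field magnitude, since NaN borders bias phase
correlation) finishes the tier.

**Known limitation**: frames containing strong activity transients can
acquire activity-driven distortions in the free (RC) component — the
same confound that motivates zeroing the ML component. The non-rigid
validation therefore runs on quiescent-tissue movies; on active data the
practical mitigations are a quiescent template and the rigid tier first.

## CS-MCM: cross-session alignment and cell matching

Mean frames are padded to a common shape with NaN (not zero) so pads
never enter correlations or costs. Initial large shifts come from user
offsets, landmark pairs, or masked phase correlation — the masked
(Padfield) variant is essential once frames carry large invalid regions.
The affine refinement is a two-stage constrained fit on Gaussian
pyramids (6 levels): translation + per-axis scale, then + rotation;
skew is never estimated. The per-level blur is `smoothing_px / 16`
(σ ≈ 2 px for the 30 px neighborhood parameter): heavy blurring at the
finest level was tried first and discards so much structure on small
fields of view that the smoothed cost prefers wrong optima; the pyramid
already supplies coarse-scale context. Powell minimization of the
masked MSE with bounds (±15 % of the frame in translation, scale
0.8–1.25, ±0.2 rad) and a sloped low-overlap penalty keeps the search
on the support.

Cell matching: footprints are warped into reference coordinates; the
first session seeds a registry; subsequent sessions match greedily by
ascending centroid distance, gated at 5 px (or 15 px for drifted
preparations) and footprint Pearson correlation > 0.6; unmatched cells
open new global IDs. Additional rounds re-center each registry entry on
the mean centroid of its matches and re-match. Left/right hemicords can
be matched separately by splitting the maps, since differential growth
shifts the two cell strips.

## Vessel diameter

Per frame: min-max normalization, histogram matching to a reference
frame, ×150 scaling; multiscale Frangi vesselness; thresholding; local
thickness; mean over an ROI. Notes:

* The **Frangi response is computed directly** in its classic
  parameterization (σ²-scaled Hessian eigenvalues; blobness
  `exp(-Rb²/2β₁²)` with β₁ = 0.5; structureness `1 − exp(-S²/2β₂²)`
  with β₂ = 15; scales σ = 1–20 step 2; polarity flag for bright/dark
  ridges). The β₂ = 15 contrast constant and the downstream mask
  thresholds are defined on that scale, for images normalized to
  0–150; a library implementation with a different internal response
  scaling silently changes what these constants mean. The response is
  made exactly invariant to additive offsets by subtracting the frame
  mean (truncated derivative kernels otherwise leak a DC term). At
  β₁ = 0.5 a perfect blob retains `exp(-2) ≈ 13.5 %` of the ridge
  response, so the ideal tube/blob separation is about 7×.
* **Local thickness** — `thickness(p)` is the diameter (2 × EDT radius)
  of the largest inscribed disk covering `p` — is computed by painting
  inscribed disks in descending radius order, and agrees exactly with a
  brute-force all-pairs search on every mask up to 64×64. On a pixel
  grid this convention reads a 9-px strip as 10 and a radius-10 disk as
  20.1; geometric phantoms are recovered within ±1 px.
* The mask combines the printed low gate (response > 0.03) with the
  thickness-stage threshold on the ×150 scale. The classic response
  **saturates inside a vessel** and falls through ≈ 0.9 at the edge of
  a steep-walled (super-Gaussian) profile, so the near-saturation
  threshold 135 (0.9) is the calibration for **absolute** widths —
  synthetic vessels of 5/9/15 px are recovered within ±1 px. The
  printed default 40 (0.27) produces dilated masks; those are adequate
  for the **relative**, baseline-normalized diameter series the method
  is used for in practice, and that distinction is stated in the API.
  Histogram matching assumes the vessel under study is a small part of
  a stable frame histogram (true in real fields of view, where the
  dorsal vein and venules anchor it); in degenerate two-level phantoms
  it pins apparent width to the reference frame.
* Diameter–fluorescence coupling is an ordinary least-squares line per
  declared epoch, reported as R².

## Behavioral and physiological formulas

* **Wheel encoder**: channels A/B are binary per-sample pulse
  indicators; `CW = (A > B) > ΔA`, `CCW = −[(B > A) > ΔB]`,
  `v = |CW + CCW|`, converted by `Cp = 2πr/600 = 0.0691 cm/pulse` at
  r = 6.6 cm, times the sample rate. First sample defined 0. The
  synthetic trace generator integrates a signed speed profile and emits
  single-sample pulses with carry, so decoding round-trips within
  one-pulse quantization.
* **Pose-track speed**: Euclidean displacement between consecutive
  frames over the mean inter-frame interval, converted by a px/cm
  factor; records with likelihood ≤ 0.1 are excluded (NaN); first frame
  0; optional NaN-aware moving mean (5 s ≙ 100 frames at 20 Hz) that
  preserves the area under the curve.
* **von Frey**: SUDO `PWT = 10^(0.24 (F ± 0.5) − 1.54)` gf (−0.5 if the
  final filament evoked a response, +0.5 if not); classical up-down
  `T₅₀ = 10^(log₁₀ F + k D)`. The k lookup table is user data
  (`load_k_table`): it is published with the classical up-down
  literature and is not restated here, to avoid shipping unverified
  constants.
* **Microglia asymmetry**: `R = (F_ipsi − F_contra)/(F_ipsi +
  F_contra)`, bounded in [−1, 1], antisymmetric under side exchange;
  optional normalization subtracts the mean over baseline sessions.
* **Stimulus response maps**: mean ΔF/F over a post-stimulus window
  (default 3 s — the source does not print its window), median filtered;
  contours by marching squares, "outermost" = largest enclosed area per
  threshold.
* **Profiles / cameras**: bead profiles min-max normalized to [0, 1]
  exactly (affine invariant); per-camera intensity normalization divides
  each session by its own camera's mean, so each camera's normalized
  mean is exactly 1.

## Synthetic data

The generator renders bright tissue (Gaussian-filtered texture) crossed
by a dark meandering dorsal vein with venule branches (super-Gaussian
cross-sections), two lateral strips of Gaussian-blob neurons with
Poisson-event / exponential-decay transients (τ = 1.5 s, a slow
indicator-like constant), rigid motion (a smoothed random walk scaled to
reach the configured maximal rostrocaudal shift exactly, default 120 px
≈ 660 µm at 5.5 µm/px, plus per-frame jitter), a smooth rostrocaudal
sinusoidal deformation whose amplitude follows a seeded smooth random
trace in [0, 8] px, a bright occluding layer drifting independently,
exponential bleaching, and Poisson + read noise. Everything is a pure
function of (config, seed); the returned ground truth (shifts,
deformation profiles, traces, footprints, widths, bleach trend, true
landmark positions) is exact. Landmark tables derived from it can add
localization jitter, dropout (likelihood below the 0.99 gate), and
gross outliers that keep high likelihood — the worst case for
registration; the first frame is exempt, modeling the manually
annotated reference frames a tracker is trained on.

What passing these tests shows: the estimators recover known geometry
under the nuisances the generator models, at the stated tolerances.
What they do not show: performance under optical aberrations, PSF
blurring, slow vessel remodeling, breathing-locked non-sinusoidal
deformation, or tracking failure modes of any specific deep-learning
tracker — real-data properties the generator does not emulate.

## Validation problem sizes

The shipped validation (`scripts/acceptance.py`, `tests/`) uses a
256×256×500 movie for the large-displacement tier (shifts to 120 px,
occluder, 30 % outliers), 128×128×300 for the non-rigid tier
(8 px deformation, quiescent tissue), three 256×256 sessions (shifts to
100 px, 2° rotation) for the cross-session tier, 1,000 Monte-Carlo
problems for the consensus estimator, and 64×64 masks for the
exhaustive local-thickness oracle — sizes chosen so the full suite
completes in minutes on a single CPU while exercising the
large-displacement regime the methods exist for.
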