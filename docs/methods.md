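# Methods

This note documents the models, algorithms and numerical choices behind
`octcycle`: what the one-cycle workflow computes, what the synthetic phantom
emulates (and deliberately does not), and which defaults matter.

## The one-cycle model

The method assumes ocular tissue in a fixed imaging plane repeats periodically
with the heart beat, so frames acquired at the same cardiac phase are
repeated noisy observations of the same scene. Three ingredients make the
assumption workable in practice:

1. **Phase wrapping.** Systolic peaks are detected on the pulse trace
   (prominence-based local maxima with a refractory period, default
   `min_period_s = 0.33 s` ≈ a 180 bpm ceiling; prominence threshold 0.25 of
   the trace's amplitude range). A frame at time *t* between consecutive
   peaks maps to phase `(t − t_k)/(t_{k+1} − t_k)` and bin
   `⌊phase·B⌋` with `B = 100`. Frames before the first or after the last
   peak have no defined period and are discarded rather than extrapolated.
   Frame and pulse clocks are assumed common; a constant offset can be
   applied externally before binning.

2. **Two-step registration.** Within a bin, every frame is registered to the
   bin's first frame: a global integer-pixel translation from plain FFT
   cross-correlation, then a per-A-scan axial tilt correction — the lag in
   `[−max_lag, max_lag]` (default `max_lag = H/10`) maximising the zero-mean
   normalised cross-correlation between reference and moving A-scans,
   sampled every 20 columns, with an ordinary least-squares line fitted over
   (column, lag) and subtracted per column. Shift and lag *estimation* runs
   on lightly Gaussian-smoothed copies (σ = 1 px for the frame translation;
   σ = 1.5 px axially plus a ±2-column average for A-scans): smoothing
   suppresses the speckle term of the correlation without biasing the peak,
   and the estimated correction is applied to the raw frames. Plain (not
   phase-normalised) cross-correlation is essential here — spectral
   whitening weights all frequencies equally and locks onto speckle on
   smooth or averaged frames. Columns whose best correlation falls below
   0.3 are excluded from the tilt fit; subpixel translation refinement
   exists behind a flag but integer shifts are the default. After
   averaging, the per-bin frames are registered to the first bin's average
   with the same two-step workflow.

3. **Outlier rejection.** The MMI of every registered frame against its bin
   reference is pooled over the whole movie and split with Otsu's
   threshold. The split is acted on only when it is decisive — inter-class
   variance ≥ 0.85 of the total. The threshold sits deliberately above the
   ~0.63–0.77 ratio that a *unimodal* sample produces at its own Otsu split
   (measured on Gaussian and uniform clusters), and below the >0.95 of a
   genuinely contaminated set, so homogeneous bins lose nothing. Removal is
   additionally capped at 20% of a bin and the reference is always kept, so
   a bin never empties.

Averaging is a plain pixel-wise arithmetic mean in float64, cast back to the
input dtype; intensities are never renormalised, so metric comparisons
before/after denoising are fair. Empty bins (possible in short recordings)
are dropped with a warning.

## Quality metrics

* **MMI** is evaluated from the joint histogram (default 64 equal-width bins
  over the pooled range of the pair; natural log). An explicit
  `intensity_range` argument makes values comparable across pairs; under a
  fixed binning the data-processing inequality MMI(X,X) ≥ MMI(X,Y) holds
  exactly (it does not between histograms built on different ranges — the
  property tests pin this down). A full Parzen-windowed estimator was not
  implemented; the plain histogram is the default evaluation of the metric's
  defining sum.
* **SNR/CNR** are exact formula evaluations from ROI statistics.
  `roi_stats(..., erode_px=k)` shrinks masks before measuring — recommended
  on registered/averaged frames, whose borders contain zero fill.
* The **FFT noise metric** uses the unwindowed magnitude spectrum (matching
  the metric's plain definition); the resolution ellipse has semi-axes
  `k = N·px/res` in FFT bins and the geometry is rejected when the cut-off
  exceeds Nyquist (an undersampled axis makes the metric meaningless).
* The **layer counter** smooths each sampled A-scan (σ = 2 px), takes the
  vertical gradient magnitude, and counts peaks with prominence ≥ 0.5 of the
  column's gradient SD and ≥ 5 px separation, every 4th column, with the
  mask span padded by 4 px so the boundary interfaces (ILM, Bruch's
  membrane) fall inside the profile. Interfaces (gradient peaks) are
  counted, not bands.

## Movement preservation

The benchmark induces a purely axial Gaussian displacement bump
(`amplitude = 5 px`, `σ = 20 px`, centred on the choroid centroid) on the
second frame of each consecutive pair, recovers the deformation with demons
registration, and reports the median |vector difference| between induced and
recovered fields over the retina, averaged over 100 pairs. On one-cycle
videos the pairing closes cyclically (last frame with first) — cardiac phase
is periodic — giving exactly B pairs from B frames. A variant normalised by
the true displacement magnitude (where > 0.5 px) exists behind a flag.

Demons runs as a **multi-resolution pyramid** (downsampling factors 4, 2, 1;
50 iterations of SimpleITK's fast symmetric-forces filter per level, update
smoothing σ = 2 px, each level initialised by the upsampled previous field).
Multi-resolution is load-bearing: at full resolution the demons force term
saturates under strong speckle (large intensity differences suppress the
update), so single-scale demons recovers almost nothing on raw frames —
neither the induced bump nor genuine eye motion — which would make raw
frames look spuriously "accurate". Coarse levels average speckle away and
capture coherent motion; the benchmark then behaves as intended: errors on
raw speckled pairs are several times those on denoised pairs, and the
recovery on clean frames is ≈0.01 px.

## The synthetic phantom

The generator emulates the statistical structure the pipeline relies on, at
the acquisition's stated operating point: 30 s at 100 Hz (3000 frames),
1536×1024 px, 1.95/5.9 µm pixels, 6.3/20 µm optical resolution, a ~1 Hz
heart beat, a retina of 11 interfaces delimiting ~50 µm layers.

Anatomy per column, top to bottom: vitreous (0), alternating-contrast
retinal layers (first = RNFL, last = bright RPE band), textured choroid
(smoothed Gaussian random field), homogeneous sclera, dark background strip.
The whole stack is offset by a smooth parabolic curvature (5% of frame
height) and a few Gaussian vessel shadows attenuate everything below the
inner surface (stopping at the sclera, which stays strictly homogeneous so
noise statistics can be read off it). Curvature and shadows are not
decoration: a laterally uniform stripe phantom makes transverse registration
ill-posed, which no real B-scan is. Finally the ideal frame is blurred to
the instrument resolution (Gaussian with FWHM = optical resolution), since
no interface can be sharper than the PSF.

Per-frame transforms, in order: cardiac axial displacement of the
retina/choroid boundary region (Gaussian depth profile centred on the
boundary, σ = 8% of frame height), scaled by the pulse waveform value at the
frame timestamp; global translation jitter (i.i.d. Gaussian, SD 2 px);
cumulative linear A-scan tilt (edge-column shift growing 0.005 px/frame).
Speckle is fully developed multiplicative noise: `I = I_clean · S`,
`S ~ Gamma(L, 1/L)` i.i.d. per pixel, mean 1 (L = 1 ⇒ exponential intensity,
the standard surrogate; analytic moments make the variance tests exact).
The pulse trace is a raised-cosine systolic bump (40% of the cycle) centred
on each peak, with optional per-cycle period jitter; the same waveform
drives the tissue displacement, so trace and motion are synchronised by
construction. Amplitudes (pulsation 3 px ≈ 12 µm, jitter 2 px, tilt
accumulating to ~15 px across a 30 s recording) are plausible for ONH video
OCT; they are config fields, not constants.

A desk-scale preset (256×256 px, 10 s, 100 Hz) samples the same physical
anatomy at a 2× coarser axial pitch (3.9 µm/px), because 11 interfaces of
50 µm need ≈256 rows at 1.95 µm/px and would not fit a 256-row frame
together with the other bands. Tests use still smaller geometries
(~160–224 rows, 96–128 columns, 5–30 heart cycles) chosen so the full
pipeline, including 200 demons registrations, runs in about a minute.

**What the phantom does not model:** OCT physics (interferometric speckle
correlation, sensitivity roll-off, shadow cones cast by vessels onto deeper
*moving* tissue), vasculature and flow, log-compressed display intensities,
3-D volume effects, eye-tracker behaviour, and non-periodic physiology.
Passing tests therefore demonstrate the pipeline's correctness under its own
assumptions (periodic motion, mean-one multiplicative noise, rigid +
linear-tilt frame misalignment), not clinical performance.

## Numerical choices and degenerate inputs

* Warps use linear interpolation; out-of-frame pixels are zero-filled in the
  phantom and registration path ("vitreous-like"), nearest-edge-filled in
  the benchmark warp. Zero fill slightly contaminates mask borders of
  averaged frames — hence `erode_px`.
* Constant frames cannot be registered (`DegenerateInputError`); constant
  pulse traces or <2 peaks raise `InsufficientCyclesError`; a tilt fit with
  <2 usable columns raises `FitError` and the pipeline then skips the tilt
  step for that frame rather than aborting the bin.
* A constant image pair has MMI 0 by convention; CNR of equal means is −∞
  (sentinel); zero background SD raises rather than returning infinity.
* Ties in the A-scan correlation argmax resolve to the smallest lag index
  (`np.argmax` semantics); integer lags quantise the tilt fit, bounding the
  recoverable slope to ~2/W per frame width W.
* Determinism: every stochastic element draws from
  `numpy.random.default_rng` seeded from the config (`SeedSequence` children
  per component), so identical configs give bit-identical outputs.

## Known limitations

* The second registration pass cannot remove sub-pixel inter-bin offsets
  left by integer-lag tilt fits; residual frame-to-frame displacement of a
  denoised motion-free phantom is ~0.4–0.7 px (visible in the
  consecutive-displacement benchmark, and consistent with its expected
  "order of a pixel" scale).
* The outlier scheme assumes outliers are a minority with *lower* MMI; a
  majority-corrupted bin would invert the split.
* The tilt model is linear across columns by construction; higher-order
  intra-frame distortion is not corrected.
* With very short recordings some bins receive one frame (no averaging) or
  none (dropped with a warning); the one-cycle video then has fewer than B
  frames.
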