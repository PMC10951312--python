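# octcycle

Cardiac-gated **one-cycle denoising** of OCT B-scan videos, with the image-quality
and movement-preservation metrics needed to evaluate it — plus a synthetic
layered-retina phantom so the whole pipeline runs and tests itself without any
patient data.

## The problem

Dynamic OCT imaging of the retina and optic nerve head (e.g. 30 s of B-scans at
~100 Hz) is the raw material for pulsatile biomarkers — tissue displacement,
strain, vessel dynamics. Speckle noise, which is multiplicative and intrinsic to
coherent imaging, ruins individual frames; yet naive temporal averaging erases
exactly the pulsatile motion one wants to measure.

Ocular tissue moves quasi-periodically with the heart beat. If a pulse-oximeter
trace is recorded synchronously with the video, every frame can be
**phase-wrapped** to the cardiac cycle: for a frame at time *t* between systolic
peaks *t<sub>k</sub>* ≤ *t* < *t<sub>k+1</sub>*,

    phase = (t − t_k) / (t_{k+1} − t_k),    bin = ⌊phase · B⌋,   B = 100 bins.

Frames in the same bin show the same tissue at the same cardiac instant, so they
can be averaged **without blurring motion**. A 3000-frame video becomes a
100-frame "one-cycle" video where each frame averages ~30 independent speckle
realisations (variance ↓ ~30×), while pulsation survives.

The pipeline per bin: register every frame to the bin's first frame with a
two-step scheme — (1) global translation by FFT cross-correlation, (2) A-scan
tilt correction (the axial lag maximising the normalised cross-correlation
between A-scans is sampled every 20 columns and a line is fitted over
(column, lag)) — then reject outlier frames by Otsu-splitting the pooled Mattes
mutual information (MMI) values, average the survivors, and finally register
the averaged frames to each other with the same two-step workflow.

Evaluation metrics:

* **MMI** (Eq. form: Σ P(x,y) log[P(x,y)/(P(x)P(y))] over a joint intensity
  histogram), **SNR<sub>dB</sub> = 20·log₁₀(μᵢ/σ_b)** and
  **CNR<sub>dB</sub> = 20·log₁₀(|μᵢ−μ_b|/σ_b)** for ROI *i* vs background *b*;
* mean FFT magnitude outside the instrument's **resolution ellipse**
  (semi-axes k = N·px/res; signal beyond the optical resolution is noise);
* region metrics: sclera intensity SD (→0), vitreous mean/SD (→0), and the
  number and spacing of retinal interfaces counted as peaks of the vertical
  intensity gradient (11 interfaces, ~50 µm layers in a clean scan);
* a **movement-preservation benchmark**: induce a known Gaussian expansion of
  the choroid (5 px amplitude, 20 px SD), recover it with multi-resolution
  demons registration, and score the median |induced − recovered| in the
  retina over 100 consecutive-frame pairs.

## Worked example

```python
from octcycle import (PhantomConfig, make_phantom, denoise, DenoiseParams,
                      roi_stats, cnr_db, sclera_uniformity, vitreous_stats)

cfg = PhantomConfig.desk(rng_seed=0, frame_height=192, frame_width=128,
                         duration_s=10.0, n_interfaces=6, layer_thickness_um=60.0)
ph = make_phantom(cfg)                     # speckled video + pulse trace + masks
oc = denoise(ph.video, ph.pulse, DenoiseParams(n_bins=100))

raw, den = ph.video.frames[0], oc.frames[0]
print(f"frames in           : {ph.video.n_frames}")
print(f"one-cycle frames    : {oc.n_frames}  (mean {oc.frames_per_bin.mean():.1f} sources/frame)")
print(f"CNR (RPE)  raw      : {cnr_db(roi_stats(raw, ph.masks, 'rpe', erode_px=4)):.1f} dB")
print(f"CNR (RPE)  one-cycle: {cnr_db(roi_stats(den, ph.masks, 'rpe', erode_px=4)):.1f} dB")
print(f"sclera SD  raw      : {sclera_uniformity(raw, ph.masks):.3f}")
print(f"sclera SD  one-cycle: {sclera_uniformity(den, ph.masks):.3f}")
print(f"vitreous SD raw     : {vitreous_stats(raw, ph.masks)[1]:.4f}")
print(f"vitreous SD onecycle: {vitreous_stats(den, ph.masks)[1]:.4f}")
```

prints (numbers from this exact run):

```
frames in           : 1000
one-cycle frames    : 100  (mean 9.8 sources/frame)
CNR (RPE)  raw      : 33.1 dB
CNR (RPE)  one-cycle: 46.6 dB
sclera SD  raw      : 0.559
sclera SD  one-cycle: 0.132
vitreous SD raw     : 0.2170
vitreous SD onecycle: 0.0199
```

i.e. the 1000-frame speckled acquisition collapses to a 100-frame one-cycle
video; RPE contrast-to-noise rises by ~13 dB and the SD in the homogeneous
sclera and the optically empty vitreous drops roughly as 1/√N, while the
choroid's cardiac displacement is preserved (see `tests/test_denoise.py`).

The same stages are scriptable from a shell:

```bash
octcycle simulate --out sim --preset desk --seed 0
octcycle denoise  --video sim/video.tif --timestamps sim/timestamps.csv \
                  --pulse sim/pulse.csv --out onecycle.tif --report report.csv
octcycle metrics  --video onecycle.tif --timestamps onecycle.phase.csv \
                  --masks sim/masks.tif --labels sim/labels.json --out metrics.json
```

## Conventions

Axis 0 is axial (depth z, downward), axis 1 is transverse (x); 0-based
indexing; metrics operate on linear intensity as stored (no implicit
log-compression). Videos are multi-page float32 TIFFs with a
`*_timestamps.csv` sidecar; masks are labelled TIFFs with a JSON label map.

See `docs/methods.md` for the model, parameter defaults and limitations.
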