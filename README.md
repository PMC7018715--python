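# granuloscope

Image processing and nanostructure quantification for volume electron
microscopy of granule-in-matrix biological composites — built around the
mussel byssus cuticle, a hard yet extensible metal-crosslinked protein
coating whose micron-scale granules contain a bicontinuous network of
~20 nm lamellae, pre-organised inside phase-separated secretory vesicles.

The package is for microscopists and image analysts who need a tested,
scriptable version of the classic FIB-SEM processing chain and of the
structural metrics used to characterise such materials:

* **preprocess** — serial-section stack alignment (Fourier-shift or ECC
  translation registration), Fourier destriping of FIB "waterfall"
  curtains, 3D total-variation denoising (Chambolle's dual projection,
  weight 0.07, eps 0.001), contrast inversion, Sauvola local thresholding
  (window 11, k = 0.005, r = 1.7), inclusive 40-voxel size filtering and
  radius-1.5 3D median filtering, assembled into documented `tissue` and
  `thread` presets.
* **segment** — connected components, magic-wand-style seeded region
  growing, and three-phase (crescent / proto-granule / proto-matrix)
  splitting of vesicle interiors by maximal between-class variance.
* **metrics** — per-vesicle phase volume fractions with cross-instance
  dispersion; spherically averaged autocovariance with support-overlap
  correction; local layer thickness by the largest-inscribed-sphere
  transform; mean lamellar orientation and anisotropy from the 3D
  structure tensor (evaluated spectrally).
* **eds** — STEM-EDS count-map analysis: uncalibrated relative weight
  fractions, line transects, phase-conditioned element statistics with
  Poisson confidence intervals, and interface transition widths.
* **phantoms** — synthetic specimens with exact ground truth: bicontinuous
  granules (oriented band-pass Gaussian random fields with controlled
  layer thickness, volume fraction, tilt and anisotropy), packed
  three-phase secretory vesicles, per-element Poisson EDS maps, and a
  FIB-SEM degradation model (per-slice jitter, curtaining stripes, noise,
  contrast inversion).

Key quantities recovered end-to-end on the reference phantom: the modal
thickness t of the lightly-staining lamellae (largest inscribed sphere,
2·max{r : x ∈ B(c,r) ⊆ phase}), the angle θ = arccos |n·a| between the
mean layer normal n (leading structure-tensor eigenvector) and the fiber
axis a, and the pg/pm element rate ratio with its delta-method CI.

## Worked example

Build the native-granule reference phantom (20 nm layers tilted 45° to the
fiber axis at the thread acquisition voxel size 10.5 × 4.8 × 4.8 nm),
degrade it with the default FIB-SEM artefact model, run the full thread
preprocessing preset, and measure the recovered structure:

```python
import dataclasses
from granuloscope.phantoms import (NATIVE_GRANULE, DegradationConfig,
                                   degrade_stack, make_granule_phantom)
from granuloscope.preprocess import THREAD_PRESET, apply_shifts, run_pipeline
from granuloscope.metrics import lamellar_orientation, layer_thickness

cfg = dataclasses.replace(NATIVE_GRANULE, shape_voxels=(96, 128, 128), seed=1234)
truth = make_granule_phantom(cfg)
stack = degrade_stack(truth, DegradationConfig(seed=1234))
result = run_pipeline(stack, THREAD_PRESET)

# evaluate the recovered mask in the aligned frame
net = truth.shifts_px + result.shifts
ls = result.mask & apply_shifts(truth.support_mask, net)

thick = layer_thickness(ls, cfg.voxel_size_nm)
orient = lamellar_orientation(ls, cfg.voxel_size_nm, fiber_axis="y")
print(f"modal layer thickness: {thick.modal_thickness_nm:.1f} nm "
      f"(mean {thick.mean_thickness_nm:.1f} nm)")
print(f"layer normal at {orient.angle_to_fiber_axis_deg:.1f} deg to the fiber axis "
      f"(anisotropy index {orient.anisotropy_index:.2f})")
```

Output:

```
modal layer thickness: 21.5 nm (mean 29.3 nm)
layer normal at 45.2 deg to the fiber axis (anisotropy index 0.60)
```

The phantom was built with 20 nm layers at 45°: after jitter, curtaining,
noise, registration, destriping, denoising, thresholding and filtering,
the modal thickness is recovered within the generator's ±15% contract and
the lamellar tilt within a degree.  The mean thickness runs above the mode
because junctions between layers admit larger inscribed spheres.

The same steps are available from the shell:

```sh
granuloscope phantom granule --preset native-granule --seed 1234 --degrade --out ph/
granuloscope preprocess run --preset thread --in ph/stack.tif --out-dir out/
granuloscope metrics thickness --mask out/mask.tif --voxel 10.5,4.8,4.8
granuloscope metrics orientation --mask out/mask.tif --voxel 10.5,4.8,4.8 --fiber-axis y
```

Every run writes a provenance record (parameters, stage checksums,
timings); identical configurations reproduce identical checksums.

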