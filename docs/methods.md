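# Methods

## The volumetry model

A CT voxel spanning two materials reports the occupancy-weighted mean
of their attenuations.  For a region of interest (ROI) that contains
only an object material of uniform density `HU_obj` and a background
material of uniform density `HU_bg`, the ROI mean `HU̅` determines the
object's area fraction exactly:

    f = (HU̅ − HU_bg) / (HU_obj − HU_bg)

and, from per-slice ROI areas `A_i` (mm²) and slice thickness `T`
(mm), the object volume

    V [cm³] = T/1000 · Σ_i A_i · f_i .

The model's assumptions, and therefore the method's domain of
validity:

* exactly two materials inside every ROI, each of uniform density;
* the object fully contained in the background (no ROI edge cuts the
  object);
* the imaging chain is *linear* in attenuation, so averaging over a
  voxel, a slice, or an ROI commutes with the mixture.

Everything the acquisition does linearly (partial-volume averaging,
slice averaging, pixel binning, reformats, zero-mean noise in
expectation) leaves `Σ A_i f_i` invariant; that is the entire reason
the method is robust, and the package's tests are mostly assertions of
this invariance.

`f` is deliberately **not clamped** to [0, 1]: under noise a slice
mean can stray past either pure density, and clamping would rectify
that noise into a positive volume bias.  The count of out-of-range
slices is reported as a diagnostic (`VolumetryResult.n_out_of_range`).

## The digital phantom

The generator emulates a physical validation phantom: a conglomerate
of PMMA spheres (`HU_obj = 119.9`) embedded in petroleum jelly
(`HU_bg = −149.7`), densities chosen to bracket parenchymal organ and
fat attenuation.

**Packing.** Random sequential addition of non-overlapping spheres in
an axis-aligned box, with candidate positions biased toward the lower
center of the box (beads settled into a concave scoop) and large beads
placed first; the bias relaxes as rejections accumulate so crowded
packs still complete.  Tangency is allowed (contact tolerance
10⁻⁶ mm).  Placement is deterministic given the seed.

**Bead sizes.** Nominal diameters {3.2, 4.0, 4.8, 5.6, 6.4} mm with
weights {0.32, 0.28, 0.22, 0.11, 0.07}.  The range matches the bead
stock; the weights are the one free choice, set so the expected volume
per bead is 47.34 mm³ and a 750-bead pack lands at 35.5 cm³ — the
physical pack's water-displacement volume.  A uniform diameter law
would give ≈48 cm³ for 750 beads, so the skew toward small beads is
forced by the recorded total.  Ground truth is **always** the pack's
analytic sphere-volume sum `Σ (4/3)πr³`, never the nominal 35.5 cm³.

**Voxelization.** Per-voxel occupancy is the fraction of
`supersampling³` regular sub-voxel points (default 4³ = 64) inside any
sphere; HU is the convex combination `o·HU_obj + (1−o)·HU_bg`.  At the
default 0.273 mm pixels the occupancy-sum volume of a single sphere
agrees with the closed form to ≲0.1% (the test bound is 0.5%); this
voxelization bias is the floor under all noise-free accuracy numbers.
The grid extends the container by a pure-background margin on all
sides (the jelly fills the whole grid) and rounds the slice count to a
multiple of 8 so the 0.625 mm native stack reslices evenly to 2.5 and
5.0 mm.

**Acquisition emulation.** All reconstruction physics is reduced to
linear operations plus two non-linearities chosen for their documented
effect:

* *slice thickness*: non-overlapping block averaging of native slices
  (no helical slice-sensitivity profile; the factor must be an integer
  and divide the stack, with background-only edge slices cropped —
  verified against ground truth — when it does not);
* *reformats*: lossless axis transposition (coronal stacks along y,
  sagittal along x) followed by reslicing; because the new stacking
  axis carries the 0.273 mm pixel spacing, a requested 5 mm output is
  snapped to the nearest multiple (18 px = 4.92 mm) — harmless, since
  V is thickness-invariant;
* *pixel size / FOV*: area-weighted in-plane averaging (exact block
  mean at integer ratios); 30 cm and 50 cm fields of view are emulated
  as 30/14 ≈ 2.14× and 50/14 ≈ 3.57× pixel coarsening of the 14 cm
  reconstruction, not as re-reconstruction;
* *noise*: i.i.d. zero-mean Gaussian, injected at the measurement
  slice thickness.  Defaults 4.6 HU (low-dose-equivalent "standard"
  scan) and 22.3 HU (10 mA high-noise scan), the two measured noise
  indicators.  Real CT noise is spatially correlated and kernel-shaped;
  white noise is a stated simplification — it averages out *faster*
  with ROI size than correlated noise would, so noise-driven error
  bounds here are optimistic in that one respect;
* *edge-enhancing ("Lung") kernel*: in-plane unsharp mask
  `out = in + s·(in − G_r(in))`, default strength 1.5 and Gaussian
  radius 0.8 mm, applied after noise so it sharpens noise texture too.
  Flat regions are preserved exactly; edges overshoot.  This
  reproduces qualitatively the HU and noise alteration near boundaries
  that sharp kernels cause, which is the attributed mechanism of their
  volumetry error;
* *adherent-air artifact* (off by default): tiny air spheres
  (r = 0.3 mm, −1000 HU) at bead near-contact points, displacing
  background only.  It exists to demonstrate the direction of the
  residual bias such air would cause — measured volume drops while the
  truth is unchanged — not to reproduce its magnitude.

## ROIs and calibration

Per-slice mixture ROIs are built from ground truth: the slice's object
support dilated by a 2 mm margin (elliptical footprint on anisotropic
grids).  The margin is large enough to tolerate through-plane blur at
5 mm slices and small enough to keep the background share — and hence
noise sensitivity — low.  ROIs may not touch the grid edge (pixels
beyond it are not guaranteed to be phantom).  The area-doubled variant
grows each ROI by one-pixel dilations until the raster area reaches
2× (achieved factor recorded; overshoot ≤ one dilation ring).  In
noise-free data any growth that adds only background leaves `A·f`
unchanged — the doubled-ROI error observed in practice is a noise and
inhomogeneity interaction, not a property of the formula.

Polygon ROIs (the user-facing input format) are rasterized by the
pixel-center even-odd rule, chosen because it matches common raster
conventions and admits a trivial brute-force oracle.

Calibration mirrors the workstation procedure: background density from
one ~10 cm² ROI of pure background on a thin slice; object density as
the **unweighted mean of per-ROI means** over ten random beads, each
measured by a small interior disk (half the bead radius, shrunk to
stay clear of the partial-volume rim) on the slice where the bead is
widest.  ROI standard deviations are population SDs (ddof = 0, what
workstations display); the SD convention affects diagnostics only,
never the volume.

## Sensitivity to reference-density error

Reference-density misspecification enters the closed form directly, so
the scenario grid recomputes volumes from the *recorded* per-slice
measurements with offset references — no re-simulation.  Four classes
(object-only, background-only, opposite-sign, same-sign) at ±2/±5/±10
HU give 24 scenarios; each is checked against an independent rerun
with a manually edited material pair.  Because the phantom's ROIs are
mostly background, a background-density error of given size moves the
volume more than an equal object-density error; the grid reproduces
that asymmetry.

## Problem sizes and numerical choices

* Quick/experiment scale (used by the test suite and the acceptance
  script): 150-bead target pack in a 42×42×30 mm box, 14 mm background
  margin, 0.2734 mm pixels (14 cm FOV / 512), 0.625 mm native slices,
  supersampling 4, three replicate seeds.  Full scale (750 beads,
  70×70×45 mm, 20 mm margin) is available through `FULL_PHANTOM` /
  `--full`.  Accuracy statements transfer because ground truth is
  analytic at every scale.
* Replicate seeds drive packing directly; per-variation noise streams
  are derived from (seed, variation index) so variations are
  independent but reproducible.  Identical seeds give bit-identical
  outputs.
* Degenerate inputs fail loudly: equal reference densities, empty
  ROIs/measurement sets, non-positive thickness, spheres outside the
  grid, non-integer reslice factors, ROI growth past the grid edge,
  perturbations that collapse the material contrast (tolerance
  1e−9·contrast).
* Presentation rounding (0.1 cm³, 0.1%) is applied only when printing
  summary tables; all computation and serialization keep full
  precision.

## What passing tests do and do not show

The simulator honors the exact two-material mixture premise, so the
noise-free pipeline inverts it to voxelization accuracy — the <1%
noise-free bounds test the *implementation*, not the clinical method.
The noisy bounds (≤3% axial, ≤4% reformats) test robustness to the
emulated degradations only.  Not modelled, and therefore not validated
here: correlated noise texture, helical interpolation, beam hardening,
iterative-reconstruction nonlinearity, material inhomogeneity, and
operator variability in freehand ROI drawing.  The small negative
residual bias physical bead phantoms show — attributed to sub-visible
air adherent to bead surfaces — does not appear in the clean
simulation; the optional air-pocket artifact demonstrates its
direction only.
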