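# Methods

## The tracking model

The pipeline follows the model-evolution paradigm: each cell owns a single
mean-shift kernel that is carried from volume to volume, and the
trajectory is the sequence of its convergence points. Robustness does not
come from the tracker itself but from two surrounding mechanisms: (i)
every volume is reduced to smooth correlation blobs by matched filtering
with a cell template, so the kernels climb wide, artifact-free gradients;
and (ii) every distinguishable object is forced to carry a tracker at all
times, which turns the failure mode "kernel drifts onto a neighboring
cell" into an observable event — two kernels converging to the same point
— that can be handled by explicit rules instead of silently corrupting
trajectories.

Assumptions: cells are sparsely seeded relative to the detection
neighborhood; inter-frame motion rarely exceeds a cell radius; a cell's
correlated peak, after per-volume rescaling to 8 bits, normally exceeds
the noise threshold. Identity is deliberately *not* preserved through
contact: when two cells touch, both trajectories end, a fresh tracker
follows the conjoined object, and new trajectories start at parting. No
probabilistic re-linking of fragments is attempted.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| voxel spacing | (0.78, 0.78, 8) | µm | anisotropic acquisition geometry; used for physical features only |
| frame interval | 4 | min | time base for µm/h rates |
| contrast percentiles | (0.01, 0.99) | — | clip window of the 8-bit stretch |
| detection neighborhood | 20×20×10 | voxels (x,y,z) | one cell volume; conjoined cells merge into one object |
| softThresh | 5 | 8-bit levels | leniency of the local-maximum mask |
| noiseThresh | 120 | 8-bit levels | minimal correlated cell-peak intensity |
| kernel size | 7 | voxels/side | flat mean-shift kernel; 3–9 give equivalent convergence |
| stop tolerance | 0.01 | voxels | mean-shift convergence criterion |
| max iterations | 100 | — | termination guarantee on pathological inputs |
| boundary margins | 10 XY / 5 Z | voxels/slices | trackers stop when a cell nears a face |
| collision distance | 3.5 XY / 2 Z | voxels | per-axis proximity that defines "same point" (half a kernel in XY, scaled for Z anisotropy) |
| parasite max lifetime | 5 | frames | short-lived collider removed without stopping the long trajectory |
| minimum follow-up | 45 | frames | 3 h; below this, duration-normalized features are outlier-prone |

softThresh and noiseThresh are calibrated to the intensity distribution of
the *correlated* volumes. Because both the contrast stretch and the
correlation rescale are per-volume percentile/min–max mappings, their
effect depends on what fraction of the volume is occupied by cells: in
very sparse fields the stretch amplifies background texture and local
background maxima can cross noiseThresh. On such data the thresholds (or
the contrast percentiles) must be re-tuned; the built-in benchmark density
(~20 cells per 225×225×224 µm field) is within the calibrated regime.

## Numerical choices

**Correlation** is plain (unnormalized, un-centered) cross-correlation,
evaluated as a zero-padded linear FFT convolution cropped to the input
shape; circular wrap-around would join opposite faces and create spurious
peaks. The result is min–max rescaled to [0, 255] per volume and kept in
floating point to preserve smooth gradients.

**Max filter** windows are truncated at the faces (implemented as
replicate-edge padding, which is exactly the truncated-window maximum);
an even extent places its extra voxel toward lower indices. Components
are labeled with 26-connectivity so peaks merged by the soft-max window
stay one object.

**Mean-shift kernel placement.** The flat kernel is a cube of side 7
voxels centered on the *continuous* tracker position: voxels straddling
the kernel face contribute in proportion to their overlap. An earlier
variant that snapped the window to the nearest integer voxel has a severe
failure mode on wide, pedestal-raised blobs: the window only re-centers
when the mean crosses a rounding boundary, and since the per-window pull
is ~0.1 voxel the tracker freezes a few voxels short of the peak,
permanently lagging its cell and flooding the run with duplicate
spawn/collision cycles. Continuous placement makes the kernel mean a
continuous function of position, whose only fixed points are genuine
weighted centroids; the convergence loop returns the position whose own
kernel mean moved less than the tolerance, so every converged position is
a fixed point to within 0.01 voxel by construction.

**Order within a frame**: converge → boundary stops → collision
resolution → commit positions → detect → associate → spawn. Stopped
trajectories end at the previous frame; a tracker spawned at frame *t*
holds the object centroid at *t* and first converges at *t* + 1. If a
(rare, non-convex) component's rounded centroid falls outside its own
voxel set, the spawned tracker is placed on the component's peak voxel so
the all-objects-tracked invariant holds identically. A tracker that
converges onto background (its object dipped below noiseThresh) is kept
alive and logged; the cell is re-detected when its peak recovers.
Collision lifetimes are counted in recorded frames; ties (several members
within the parasite lifetime) stop the whole group, since no unique
parasite can be identified.

## The synthetic scene generator

The generator emulates exactly the image structure the pipeline exploits,
not phase-contrast optics:

- **Cell appearance**: at slice offset `dz` from the focal plane, a
  Gaussian annulus whose radius grows linearly with `|dz|` (a disk at
  focus, radius ~7.5 voxels) and whose amplitude decays from the focal
  peak (200) toward the cone tips over 12 slices — the "two squashed
  cones" geometry. Halos are additive and positive, whereas real
  phase-contrast has negative lobes; only peak geometry matters to
  correlation and detection, and halo sign is configurable for stress
  tests.
- **Background**: seeded band-limited noise (Gaussian-smoothed white
  noise, correlation length ~1 voxel in XY), amplitude 15 on a base level
  of 30 — sub-cell-scale texture standing in for collagen fibers. Texture
  at cell scale would itself respond to the matched filter.
- **Motion**: per-axis Gaussian random walk (σ_xy = 0.8 voxels/frame,
  σ_z = 0.12 slices/frame — inter-frame steps well under a cell radius,
  ~10 µm/h in XY), optional drift in µm/h, reflection at the volume
  borders.
- **Events** are scripted deterministically on top of the walk: crossings
  steer a pair to a meeting point (nudged away from bystander cells) and
  apart again; divisions insert a daughter that separates at 2.5
  voxels/frame; entries insert a path at a face placed ≥ 50 voxels from
  residents; exits walk a cell out through the nearest face. Keeping
  scripted events clear of bystanders ensures the benchmark measures the
  scripted scenarios rather than accidental multi-cell pile-ups.
- **Default benchmark**: 20 cells, 100 frames, 288×288 XY × 28 slices,
  two crossings, two entries, one division. Full acquisition-scale
  volumes (1600×1190×60, hundreds of frames) behave identically per
  frame; the benchmark size keeps a full tracking run around a minute on
  one CPU.

What passing on synthetic data does **not** show: robustness to real
phase-contrast halo polarity, to structured collagen artifacts at
cell-like scales, to cell-shape changes (elongation, blebbing), or to
density/intensity regimes outside the calibrated thresholds. The
supplied scenario fixtures (two-cell crossing with a 1.0/0.8 brightness
asymmetry so the conjoined tracker deterministically follows the brighter
cell; a two-frame artifact 24 voxels from a tracked cell whose spawned
tracker is removed as a parasite) verify the collision-management logic,
not its real-data error rate.

## Scoring

A trajectory point matches a ground-truth cell within 5 XY voxels and 2
slices; recall is the fraction of truth points covered, precision the
fraction of trajectory points on a true cell. A trajectory counts as an
identity switch if its matched cell changes between *unambiguous* points
(exactly one candidate in range) — while two cells are conjoined, both are
in range and the nearest-id assignment flips arbitrarily, and following a
conjoined pair is correct behavior, not an error.

## Known limitations

- Per-volume adaptive rescaling couples detection thresholds to scene
  density (see above); a sequence-global scaling option is exposed for
  data where per-volume scaling drifts.
- Conjoined cells are one object by design; no watershed splitting, no
  morphology, no re-identification after parting.
- The average speed uses inter-frame path length and is therefore biased
  upward by localization jitter; MRDO, being displacement-based, is
  nearly jitter-free. Comparisons across conditions tracked with the same
  settings are unaffected.
- A weaker cell within the detection neighborhood of a much brighter one
  (peak difference > softThresh) is temporarily undetected; its tracker,
  if alive, still follows it, and detection resumes when the cells
  separate.
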