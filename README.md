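# celltrack3d

Automated detection and tracking of large populations of **unlabeled cells**
in time-lapse **3D phase-contrast** volume sequences, with duration-normalized
migration descriptors for comparing cell populations across experimental
conditions (e.g. drug doses or matrix compositions in 3D gel assays).

Cells imaged label-free at low magnification in gel appear as a bright focal
disk with off-focus cone-like halos, on top of collagen background texture —
conditions under which per-cell segmentation is hopeless but template
matching is robust. The pipeline:

1. **Contrast boost** — percentile-clip linear stretch to 8-bit, suppressing
   gel texture.
2. **Template correlation** — each volume `I` is cross-correlated with a
   small subvolume `T` cropped around one isolated cell:
   `I_c(v) = Σ_k I(v + k − c) · T(k)` (computed by FFT). Every cell becomes a
   smooth correlation blob peaked on the cell center.
3. **Soft-max detection** — `max = max-filter(I_c, N)` over an anisotropic
   neighborhood `N` (20×20×10 voxels), `mask = (max − I_c ≤ softThresh)`,
   `softMax = I_c · mask`, `segmented = softMax ≥ noiseThresh`
   (softThresh = 5, noiseThresh = 120 on the 8-bit scale); 26-connected
   components are the detected objects (conjoined cells merge into one).
4. **Mean-shift tracking** — each cell carries a flat kernel (7 voxels per
   side) iterated to the intensity-weighted mean of `I_c` under it until the
   shift falls below 0.01 voxel. Trackers stop within 10 voxels (X/Y) or
   5 slices (Z) of a volume face.
5. **Collision management** — trackers converging to the same point signal
   touching cells or duplicate detections: all members stop (their
   trajectories end at the previous frame) unless exactly one is ≤ 5 frames
   old, in which case that "parasite" is removed and the established
   trajectory continues. Every detected object without a tracker receives a
   fresh one at its geometric center, so *all* cells stay tracked.
6. **Trajectory descriptors** — after discarding follow-ups shorter than
   45 frames (3 h at 4 min/frame): average speed (path length / duration,
   µm/h) and MRDO rate (maximum relative distance covered from the origin /
   duration, µm/h), computed with anisotropic voxel spacing
   (0.78, 0.78, 8) µm. Distributions across conditions are compared with the
   Kruskal–Wallis rank test.

A first-class synthetic-scene generator renders ground-truthed sequences
(double-cone cell appearance, band-limited gel texture, random-walk motion,
scripted crossings / divisions / entries / exits) so every stage is testable
without microscopy data.

## Worked example

```python
from celltrack3d import synthetic as syn
from celltrack3d.pipeline import PipelineConfig, run_pipeline

scene = syn.default_benchmark_scene(seed=1)          # 20 cells, 100 frames
sequence = syn.render_sequence(scene)                # 288x288x28-voxel stacks
template = syn.make_template()                       # synthesized cell template
result = run_pipeline(sequence, template, PipelineConfig())
metrics = syn.score_against_truth(result.trajectories, scene)
print(len(result.trajectories), len(result.features))
print({k: round(v, 3) for k, v in metrics.items() if isinstance(v, float)})
```

prints

```
53 26
{'recall': 0.987, 'precision': 0.872, 'id_switch_fraction': 0.0}
```

i.e. the run produced 53 trajectories of which 26 survive the 45-frame
filter; 98.7% of ground-truth cell positions are covered by a trajectory
point (within 5 XY voxels / 2 slices), 87.2% of trajectory points lie on a
true cell, and no trajectory ever changes which cell it follows. The
trajectory, metadata and feature tables are pandas DataFrames
(`result.trajectory_table()`, `result.features_table()`), and
`result.write(out_dir)` emits them as CSV plus an events JSONL and a run
report embedding the fully resolved config.

The same flow is available from the shell:

```bash
celltrack3d simulate  --spec scene.yaml --seed 1 --out scene/
celltrack3d track     --input scene/ --template-stack scene/frame_0000.tif \
                      --template-center 53 57 14 --out run/
celltrack3d benchmark --seed 1 --out bench/
celltrack3d features  --trajectories ctrl ctrl/features.csv \
                      --trajectories dose dose/features.csv
```

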