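# pcls4d

Multiscale quantification of osmotic stress in precision-cut liver
slices (PCLS) from 4D multichannel confocal recordings — and a
synthetic 4D benchmark generator with full ground truth to validate
every stage of the measurement chain.

## The problem

A 300–500 µm liver slice mounted on chamber glass and exposed to an
anisosmotic bath (or a permeating cryoprotectant such as DMSO) responds
on three coupled scales:

* the **whole slice** shrinks or swells as water leaves or enters;
* **nuclei** are carried by the local tissue strain — upward
  (toward the exposed face) under hyposmotic swelling, downward under
  hyperosmotic or CPA-driven shrinkage, and more strongly near the
  exposed periphery than in the diffusion-limited core, which makes
  them usable as in-situ probes of local osmotic stress;
* **individual cells** follow volume kinetics set by membrane water
  (and solute) transport: slow swelling that equilibrates in minutes
  under hyposmotic stress, faster shrinkage under hyperosmotic stress,
  and the classic shrink–swell excursion under a permeating solute,
  with regulatory volume decrease/increase (RVD/RVI) returning cells
  toward their initial volume.

`pcls4d` measures all three from a `(t, c, z, y, x)` stack with
membrane / cytoplasm / nuclei channels: whole-tissue surface
segmentation and volumetry, nuclei spot detection (multiscale LoG) with
gated optimal-assignment tracking and periphery/core stratification,
seeded-watershed 3D cell instance segmentation with per-cell
morphometrics, and volume-kinetics analytics (mean ± SEM aggregation,
LOESS smoothing, equilibration time under a 5%-of-plateau criterion,
shrink–swell metrics).

Because raw recordings of such experiments are not publicly available,
the package also ships a physics-based generator
(`pcls4d.synthetic`): sphere-packed hepatocyte-like cells (20%
binucleate) in a slab, an interstitial reaction–diffusion solute field
(backward Euler, exact discrete maximum principle), a two-solute
membrane transport model with a regulatory leak

    Mi = M0 (n+s)/w,   dw/dt = k_w (Mi − Me − Se)/M0,
    ds/dt = k_s (Se − M0 s/w)/M0,   dn/dt = −k_r (v−1),
    v = b + (1−b) w,

strain-advected nuclei (`λ = v^{1/3}`, glass-anchored), and a renderer
with anisotropic PSF and Poisson/read noise. Ground truth (per-cell
volume trajectories, nuclei trajectories, field snapshots, instance
labels) is recorded exactly, so accuracy claims are testable. See
`docs/methods.md` for the model, parameter defaults and calibration.

## Worked example

Run the calibrated hyperosmotic benchmark (1,215 mOsm/kg bath switch at
t = 0, ~950 cells, 33 frames over 480 s; a few minutes on one CPU):

```python
from pcls4d.pipeline import run_benchmark

summary = run_benchmark("hyper1215", seed=1, scale="default")
print(round(summary["equilibration_s"], 1))                  # 149.5
print(round(summary["tissue_dv_final"], 3))                  # -0.513
print(round(summary["displacement"]["mean_axial_um"], 1))    # -15.0
print(round(summary["recovery"]["median_volume_error"], 3))  # 0.062
print(round(summary["recovery"]["link_accuracy"], 3))        # 0.966
```

Reading the numbers: the aggregate cell-volume curve (V/V₀, mean over
~500 quality-controlled cell tracks) settles to within 5% of its
plateau 150 s after the bath switch — hyperosmotic equilibration is
fast because the water efflux rate scales with the bath osmolality.
The whole imaged tissue block loses half its volume; nuclei move
down (toward the glass) by 15 µm on average, riding the accumulated
shrinkage strain of the tissue below them. Against the generator's
ground truth, the median per-cell volume error is 6.2% and 96.6% of
frame-to-frame track links are correct. The same call with
`"hypo80"` gives slow swelling (equilibration near 300 s, upward
nuclear drift); `"dmso1molal"` gives the shrink–swell excursion.

The same pipeline runs from the shell:

```bash
pcls4d benchmark --condition hyper1215 --seed 1 --outdir out/
pcls4d simulate --condition dmso1molal --seed 2 --outdir sim/   # stack + truth
pcls4d analyze --stack sim/stack.tiff --outdir results/         # any Stack4D tiff
```

`out/` holds per-timepoint tissue volumetry, the nuclei track table
(position, volume, velocity, acceleration, region), the per-cell
morphometrics table, the aggregate V/V₀ curve and a JSON summary with
a checksum manifest.

## Layout

    src/pcls4d/synthetic/   generator: geometry, field, transport,
                            displacement, renderer, benchmarks
    src/pcls4d/io.py        TIFF / CSV / YAML readers and writers
    src/pcls4d/tissue_volume.py      whole-slice segmentation + volumetry
    src/pcls4d/cell_segmentation.py  LoG seeds, watershed, size filter
    src/pcls4d/nuclei_tracking.py    linking, kinematics, periphery/core
    src/pcls4d/kinetics.py  aggregation, LOESS, equilibration, shrink-swell
    src/pcls4d/pipeline.py  orchestration + ground-truth comparison
    src/pcls4d/cli.py       `pcls4d` command-line interface
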