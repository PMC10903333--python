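"""Standard calibrated benchmark conditions.

Three named conditions reproduce the exposure experiments this package
emulates (a 300 µm liver slice on chamber glass, isosmotic baseline of
300 mOsm/kg):

* ``hypo80``      bath switched to 80 mOsm/kg non-permeating at t = 0;
* ``hyper1215``   bath switched to 1,215 mOsm/kg non-permeating;
* ``dmso1molal``  1 mol/kg (~1,000 mOsm/kg) permeating DMSO added to
  isosmotic bath.

The benchmark grid is a 192 µm lateral window of the slice imaged at
2 µm laterally and 10 µm z-steps, 33 frames at 15 s — large enough for
several hundred cells per frame while keeping a full pipeline run at
desk scale.  ``scale="small"`` is a faster variant used for the
many-seed direction checks (same window, 60 s at 15 s frames).
"""

from __future__ import annotations

import numpy as np

from .config import SimConfig, SolutionProtocol, TransportParams
from .truth import GroundTruth, simulate_ground_truth

CONDITIONS = ("hypo80", "hyper1215", "dmso1molal")

#: bath (non-permeating, permeating) osmolality after the switch, mOsm/kg
BATHS = {
    "hypo80": (80.0, 0.0),
    "hyper1215": (1215.0, 0.0),
    "dmso1molal": (300.0, 1000.0),
}


def benchmark_config(seed: int = 0, scale: str = "default") -> SimConfig:
    if scale == "default":
        shape, lateral = (44, 96, 96), 2.0   # 440 µm of z: headroom for swelling
    elif scale == "small":
        shape, lateral = (40, 96, 96), 2.0
    else:
        raise ValueError(f"unknown scale {scale!r}")
    return SimConfig(shape=shape, voxel_size=(10.0, lateral, lateral),
                     slab_thickness=300.0, seed=seed)


def benchmark_protocol(condition: str, scale: str = "default") -> SolutionProtocol:
    if condition not in BATHS:
        raise ValueError(f"unknown condition {condition!r}; know {CONDITIONS}")
    me, se = BATHS[condition]
    if scale == "default":
        duration, frame = 480.0, 15.0
    else:
        duration, frame = 60.0, 15.0
    return SolutionProtocol(baseline_mosm=300.0,
                            switches=((0.0, me, se),),
                            duration=duration, frame_interval=frame)


def make_benchmark(condition: str, seed: int = 0, *,
                   scale: str = "default",
                   params: TransportParams | None = None) -> GroundTruth:
    """Simulate the ground truth of one named benchmark condition."""
    cfg = benchmark_config(seed=seed, scale=scale)
    protocol = benchmark_protocol(condition, scale=scale)
    params = params if params is not None else TransportParams()
    return simulate_ground_truth(cfg, protocol, params, lateral_bc="neumann")


def ground_truth_mean_volume(truth: GroundTruth) -> np.ndarray:
    """Mean normalized cell volume per frame (the generator's own aggregate)."""
    return truth.cell_v.mean(axis=1)
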