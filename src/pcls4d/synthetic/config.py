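"""Configuration types for the synthetic 4D liver-slice benchmark.

The generator emulates confocal time-lapse recordings of a precision-cut
liver slice (PCLS) mounted on chamber glass and exposed to anisosmotic
bath solutions.  All lengths are in micrometres, times in seconds and
osmolalities in mOsm/kg.  Axes are ordered ``(t, c, z, y, x)`` with z
index 0 at the chamber bottom; "upward" means increasing z, toward the
exposed top face of the slice.
"""

from __future__ import annotations

from dataclasses import dataclass, fields


class ConfigError(ValueError):
    """A configuration value is out of its documented range."""


def _check(cond: bool, key: str, msg: str) -> None:
    if not cond:
        raise ConfigError(f"{key}: {msg}")


@dataclass(frozen=True)
class SimConfig:
    """Geometry, optics and noise of a synthetic acquisition.

    Defaults mirror the acquisition this package emulates: 10 µm z-steps
    through a 300 µm slab, 2 µm lateral pixels, hepatocyte-like cells of
    24 ± 3 µm diameter with 8 µm nuclei and a 20% binucleate fraction.
    """

    shape: tuple[int, int, int] = (30, 256, 256)          # (nz, ny, nx)
    voxel_size: tuple[float, float, float] = (10.0, 2.0, 2.0)  # (dz, dy, dx) µm
    slab_thickness: float = 300.0                          # µm
    cell_diameter_mean: float = 24.0                       # µm
    cell_diameter_sd: float = 3.0                          # µm
    nucleus_diameter: float = 8.0                          # µm
    binucleate_fraction: float = 0.2
    packing_fraction: float = 0.5
    photon_scale: float = 50.0     # expected counts at unit intensity; 0 = noise-free
    read_noise_sd: float = 2.0     # counts
    seed: int = 0

    def __post_init__(self) -> None:
        _check(len(self.shape) == 3 and all(int(n) > 0 for n in self.shape),
               "shape", "must be three positive voxel counts (nz, ny, nx)")
        _check(all(v > 0 for v in self.voxel_size),
               "voxel_size", "all voxel sizes must be > 0")
        _check(0 < self.slab_thickness <= self.shape[0] * self.voxel_size[0],
               "slab_thickness", "must be positive and fit the grid (<= nz*dz)")
        _check(self.cell_diameter_mean > 0, "cell_diameter_mean", "must be > 0")
        _check(self.cell_diameter_sd >= 0, "cell_diameter_sd", "must be >= 0")
        _check(0 < self.nucleus_diameter < self.cell_diameter_mean,
               "nucleus_diameter", "must be positive and smaller than the cell diameter")
        _check(0.0 <= self.binucleate_fraction <= 1.0,
               "binucleate_fraction", "must lie in [0, 1]")
        _check(0.0 <= self.packing_fraction <= 1.0,
               "packing_fraction", "must lie in [0, 1]")
        _check(self.photon_scale >= 0, "photon_scale", "must be >= 0")
        _check(self.read_noise_sd >= 0, "read_noise_sd", "must be >= 0")

    # -- derived geometry ---------------------------------------------------
    @property
    def extent(self) -> tuple[float, float, float]:
        """Physical size of the grid (Lz, Ly, Lx) in µm."""
        return tuple(n * d for n, d in zip(self.shape, self.voxel_size))

    def voxel_volume(self) -> float:
        dz, dy, dx = self.voxel_size
        return dz * dy * dx


@dataclass(frozen=True)
class SolutionProtocol:
    """Time-stamped bath composition during a recording.

    The bath carries a non-permeating osmolality ``Me`` (salts) and a
    permeating osmolality ``Se`` (e.g. DMSO).  Both are piecewise
    constant: ``switches`` holds ``(time_s, Me, Se)`` triples applied
    instantaneously at the switch time (real solution exchange finishes
    within a few seconds, well under one frame interval).  Before the
    first switch the bath is isosmotic: ``Me = baseline_mosm, Se = 0``.
    """

    baseline_mosm: float = 300.0
    switches: tuple[tuple[float, float, float], ...] = ()
    duration: float = 480.0        # s
    frame_interval: float = 15.0   # s

    def __post_init__(self) -> None:
        _check(self.baseline_mosm > 0, "baseline_mosm", "must be > 0")
        _check(self.duration > 0, "duration", "must be > 0")
        _check(self.frame_interval > 0, "frame_interval", "must be > 0")
        times = [s[0] for s in self.switches]
        _check(all(t1 < t2 for t1, t2 in zip(times, times[1:])),
               "switches", "switch times must be strictly increasing")
        _check(all(t < self.duration for t in times),
               "switches", "switch times must precede the total duration")
        for t, me, se in self.switches:
            _check(me > 0, "switches", f"non-permeating osmolality at t={t} must be > 0")
            _check(se >= 0, "switches", f"permeating osmolality at t={t} must be >= 0")

    def bath_at(self, t: float) -> tuple[float, float]:
        """Bath (Me, Se) at time ``t`` (switches are left-closed)."""
        me, se = self.baseline_mosm, 0.0
        for ts, m, s in self.switches:
            if t >= ts:
                me, se = m, s
            else:
                break
        return me, se

    @property
    def frame_times(self):
        import numpy as np

        n = int(round(self.duration / self.frame_interval)) + 1
        return np.arange(n) * self.frame_interval

    @property
    def perturbation_time(self) -> float:
        """Time of the first switch (0 if the protocol has none)."""
        return self.switches[0][0] if self.switches else 0.0


# Calibrated so that, on the standard benchmark geometry, the aggregate
# cell-volume curve equilibrates (5%-of-plateau criterion on the smoothed
# mean) near 300 s under 80 mOsm/kg and near 150 s under 1,215 mOsm/kg,
# while keeping a regulatory return toward the initial volume present in
# the frame-sampled aggregate within the 480 s window.
# scripts/calibrate_transport.py reproduces the search.
_KW_DEFAULT = 0.12
_KR_DEFAULT = 0.0004
_DEFF_DEFAULT = 400.0


@dataclass(frozen=True)
class TransportParams:
    """Two-solute membrane transport with a linear volume-regulation leak.

    k_w   water transport rate (s^-1 per unit normalized osmotic difference)
    k_s   permeating-solute transport rate (s^-1)
    b     osmotically inactive volume fraction
    k_r   regulatory (RVD/RVI) leak rate (s^-1)
    D_eff effective interstitial diffusivity of bath solutes (µm²/s)
    """

    k_w: float = _KW_DEFAULT
    k_s: float = _KW_DEFAULT / 5.0
    b: float = 0.3
    k_r: float = _KR_DEFAULT
    D_eff: float = _DEFF_DEFAULT

    def __post_init__(self) -> None:
        for name in ("k_w", "k_s", "k_r", "D_eff"):
            _check(getattr(self, name) >= 0, name, "must be >= 0")
        _check(0.0 <= self.b < 1.0, "b", "must lie in [0, 1)")


def config_from_mapping(cls, mapping: dict, key_prefix: str = ""):
    """Build a config dataclass from a plain mapping, rejecting unknown keys."""
    known = {f.name for f in fields(cls)}
    unknown = set(mapping) - known
    if unknown:
        raise ConfigError(
            f"unknown {cls.__name__} keys: {sorted(unknown)}; known keys: {sorted(known)}")
    kwargs = dict(mapping)
    for k in ("shape", "voxel_size"):
        if k in kwargs and isinstance(kwargs[k], list):
            kwargs[k] = tuple(kwargs[k])
    if "switches" in kwargs and isinstance(kwargs["switches"], list):
        kwargs["switches"] = tuple(tuple(s) for s in kwargs["switches"])
    return cls(**kwargs)
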