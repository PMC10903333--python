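"""Coupled ground-truth simulation of a slice under osmotic exposure.

One driver integrates, on a shared time grid:

1. the extracellular solute field (backward Euler, :mod:`.field`);
2. the transport ODE of every cell, driven by the field interpolated at
   the cell's initial centre (:mod:`.transport`);
3. the same ODE at every field node, yielding the local-volume field
   ``v(x, t)`` that defines the tissue strain.

Nuclei and cell centres are then advected through the strain field
(:mod:`.displacement`).  The result carries everything the analysis
stages are later measured against: per-cell normalized volume
trajectories, nuclei trajectories with truth correspondences, field
snapshots and the t=0 tissue mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import SimConfig, SolutionProtocol, TransportParams
from .displacement import compute_nuclear_displacement
from .field import FieldStepper, OsmolalityField
from .geometry import CellPopulation, build_tissue_geometry
from .transport import IntegrationError, _rates


@dataclass
class GroundTruth:
    """Everything the synthetic benchmark knows to be true."""

    config: SimConfig
    protocol: SolutionProtocol
    params: TransportParams
    population: CellPopulation
    times: np.ndarray                  # frame times (T,)
    cell_v: np.ndarray                 # (T, n_cells) normalized volume
    cell_centers: np.ndarray           # (T, n_cells, 3) µm (z, y, x)
    nuclei_positions: np.ndarray       # (T, n_nuclei, 3) µm
    field: OsmolalityField             # bath components at frame times
    v_field: np.ndarray                # (T, nz_f, ny_f, nx_f) local volume
    tissue_mask0: np.ndarray           # (nz, ny, nx) bool, t = 0

    @property
    def nucleus_cell(self) -> np.ndarray:
        return self.population.nucleus_cell

    def cell_radii(self, frame: int) -> np.ndarray:
        return self.population.radii * np.cbrt(self.cell_v[frame])

    def cell_volumes_um3(self) -> np.ndarray:
        """(T, n_cells) absolute volumes."""
        return self.cell_v * self.population.volumes()[None, :]


def _trilinear_weights(grid, pts):
    """Flat corner indices and weights for trilinear sampling on a node grid."""
    idx = []
    wts = []
    shape = tuple(len(g) for g in grid)
    loc = []
    for ax, g in enumerate(grid):
        p = np.clip(pts[:, ax], g[0], g[-1])
        i = np.clip(np.searchsorted(g, p, side="right") - 1, 0, len(g) - 2)
        f = (p - g[i]) / (g[i + 1] - g[i])
        loc.append((i, f))
    strides = (shape[1] * shape[2], shape[2], 1)
    n = len(pts)
    idx = np.zeros((n, 8), dtype=np.int64)
    wts = np.ones((n, 8))
    for corner in range(8):
        bits = [(corner >> b) & 1 for b in (2, 1, 0)]
        flat = np.zeros(n, dtype=np.int64)
        w = np.ones(n)
        for ax, bit in enumerate(bits):
            i, f = loc[ax]
            flat += (i + bit) * strides[ax]
            w *= f if bit else (1.0 - f)
        idx[:, corner] = flat
        wts[:, corner] = w
    return idx, wts


def simulate_ground_truth(config: SimConfig, protocol: SolutionProtocol,
                          params: TransportParams, *,
                          lateral_bc: str = "neumann",
                          dt: float = 0.5,
                          population: CellPopulation | None = None,
                          with_tissue_mask: bool = True) -> GroundTruth:
    """Run the full coupled simulation for one protocol.

    ``lateral_bc`` defaults to "neumann": the standard benchmarks treat
    the simulated volume as a window interior to a much wider slice, so
    bath solutes enter through the exposed top face only.  Pass
    "dirichlet" for a free-standing slab whose lateral faces also touch
    the bath.
    """
    pop = population if population is not None \
        else build_tissue_geometry(config)
    times = protocol.frame_times
    m0 = protocol.baseline_mosm

    t_end = float(times.max())
    n_steps = max(int(np.ceil(t_end / dt - 1e-12)), 1) if t_end > 0 else 0
    h = t_end / n_steps if n_steps else dt

    stepper = FieldStepper(config, params.D_eff, h, lateral_bc=lateral_bc,
                           baseline_mosm=m0)
    grid = (stepper.z, stepper.y, stepper.x)
    n_nodes = len(stepper.z) * len(stepper.y) * len(stepper.x)

    # sample columns: all field nodes first, then the cells
    if pop.n_cells:
        cell_idx, cell_w = _trilinear_weights(
            grid, np.clip(pop.centers, 0.0, None))
    n_cols = n_nodes + pop.n_cells

    def bath_cols():
        fm, fs = stepper.grids()
        me = np.empty(n_cols)
        se = np.empty(n_cols)
        me[:n_nodes] = fm.ravel()
        se[:n_nodes] = fs.ravel()
        if pop.n_cells:
            me[n_nodes:] = (fm.ravel()[cell_idx] * cell_w).sum(axis=1)
            se[n_nodes:] = (fs.ravel()[cell_idx] * cell_w).sum(axis=1)
        return me, se

    # ODE state
    w = np.ones(n_cols)
    n_ = np.ones(n_cols)
    s = np.zeros(n_cols)

    snap_at: dict[int, list[int]] = {}
    for k, t_req in enumerate(times):
        snap_at.setdefault(int(round(t_req / h)) if n_steps else 0, []).append(k)

    shape_f = (len(times), len(stepper.z), len(stepper.y), len(stepper.x))
    snaps_m = np.empty(shape_f)
    snaps_s = np.empty(shape_f)
    v_field = np.empty(shape_f)
    cell_v = np.empty((len(times), pop.n_cells))

    def snapshot(i_step):
        for k in snap_at.get(i_step, ()):
            fm, fs = stepper.grids()
            snaps_m[k], snaps_s[k] = fm, fs
            v_all = params.b + (1.0 - params.b) * w
            v_field[k] = v_all[:n_nodes].reshape(shape_f[1:])
            cell_v[k] = v_all[n_nodes:]

    stepper.bath = protocol.bath_at(0.0)
    snapshot(0)
    me0, se0 = bath_cols()
    for i in range(n_steps):
        stepper.step(*protocol.bath_at((i + 1) * h))
        me1, se1 = bath_cols()
        meh, seh = 0.5 * (me0 + me1), 0.5 * (se0 + se1)
        k1 = _rates(params, m0, w, n_, s, me0, se0)
        k2 = _rates(params, m0, w + 0.5 * h * k1[0], n_ + 0.5 * h * k1[1],
                    s + 0.5 * h * k1[2], meh, seh)
        k3 = _rates(params, m0, w + 0.5 * h * k2[0], n_ + 0.5 * h * k2[1],
                    s + 0.5 * h * k2[2], meh, seh)
        k4 = _rates(params, m0, w + h * k3[0], n_ + h * k3[1],
                    s + h * k3[2], me1, se1)
        w = w + h / 6.0 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
        n_ = np.maximum(n_ + h / 6.0 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1]), 0.0)
        s = np.maximum(s + h / 6.0 * (k1[2] + 2 * k2[2] + 2 * k3[2] + k4[2]), 0.0)
        if np.any(w <= 0):
            raise IntegrationError(f"water volume non-positive at t={h * (i + 1):.2f} s")
        me0, se0 = me1, se1
        snapshot(i + 1)

    field = OsmolalityField(times=times, z=stepper.z, y=stepper.y, x=stepper.x,
                            nonpermeating=snaps_m, permeating=snaps_s)

    # strain-advected trajectories
    if pop.n_cells:
        nuclei = compute_nuclear_displacement(
            v_field, grid, pop.nucleus_positions,
            slab_thickness=config.slab_thickness)
        centers = compute_nuclear_displacement(
            v_field, grid, pop.centers, slab_thickness=config.slab_thickness)
    else:
        nuclei = np.empty((len(times), 0, 3))
        centers = np.empty((len(times), 0, 3))

    mask0 = rasterize_tissue_mask(pop, config) if with_tissue_mask \
        else np.zeros(config.shape, dtype=bool)

    return GroundTruth(config=config, protocol=protocol, params=params,
                       population=pop, times=times, cell_v=cell_v,
                       cell_centers=centers, nuclei_positions=nuclei,
                       field=field, v_field=v_field, tissue_mask0=mask0)


def rasterize_tissue_mask(pop: CellPopulation, config: SimConfig,
                          closing_um: float = 10.0) -> np.ndarray:
    """Union of cell spheres, morphologically closed (anisotropy-aware).

    This is the generator's definition of "tissue" at t = 0 and the
    reference the tissue-surface segmentation is compared against.
    """
    from scipy import ndimage as ndi

    from .render import _ball_union

    mask = _ball_union(pop.centers, pop.radii, config)
    if closing_um > 0 and mask.any():
        dz, dy, dx = config.voxel_size
        rad = tuple(max(int(round(closing_um / d)), 1) for d in (dz, dy, dx))
        zz, yy, xx = np.ogrid[-rad[0]:rad[0] + 1, -rad[1]:rad[1] + 1, -rad[2]:rad[2] + 1]
        ball = ((zz * dz / closing_um) ** 2 + (yy * dy / closing_um) ** 2
                + (xx * dx / closing_um) ** 2) <= 1.0
        pad = [(r, r) for r in rad]
        padded = np.pad(mask, pad)
        closed = ndi.binary_closing(padded, structure=ball)
        sl = tuple(slice(r, s + r) for r, s in zip(rad, mask.shape))
        mask = closed[sl]
    return mask
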