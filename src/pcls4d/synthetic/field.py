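"""Extracellular solute transport in the slab.

Bath solutes reach cells by diffusion through the interstitium, so a
slice responds in a depth- (and edge-) dependent, diffusion-limited way.
The solver integrates the diffusion equation for the two bath components
(non-permeating and permeating osmolality) on a regular grid covering the
slab with an implicit backward-Euler scheme, so no explicit stability
limit constrains the time step.

The implicit (backward Euler) step is an M-matrix solve, so the discrete
maximum principle holds exactly for any step size: field values can never
leave the interval spanned by the initial state and the bath history.

Boundary conditions
-------------------
* top face (z = slab thickness): Dirichlet, clamped to the bath value;
* bottom face (z = 0): zero flux (chamber glass);
* lateral faces: Dirichlet at the bath value for a free-standing slab
  (the default), or zero flux when the simulated volume is a window
  interior to a much wider slice (``lateral_bc="neumann"``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .config import SimConfig, SolutionProtocol


def _lap1d(n: int, h: float, left: str, right: str):
    """1D Laplacian over unknown nodes plus boundary-source indicator.

    ``left``/``right`` are "neumann" (mirror, node included) or
    "dirichlet" (boundary node excluded from the unknowns; its value
    contributes ``1/h**2`` to the adjacent unknown's source term).
    Returns (L, g) with L (n_u x n_u) and g (n_u,) in 1/h**2 units.
    """
    n_u = n - (left == "dirichlet") - (right == "dirichlet")
    main = np.full(n_u, -2.0)
    off = np.ones(n_u - 1)
    if left == "neumann":
        main[0] = -1.0
    if right == "neumann":
        main[-1] = -1.0
    L = sp.diags([off, main, off], [-1, 0, 1], format="csr") / h**2
    g = np.zeros(n_u)
    if left == "dirichlet":
        g[0] += 1.0 / h**2
    if right == "dirichlet":
        g[-1] += 1.0 / h**2
    return L, g


@dataclass
class OsmolalityField:
    """Fields sampled at frame times on the solver grid (nodes in µm)."""

    times: np.ndarray                 # (T,)
    z: np.ndarray                     # (nz,) node coordinates, 0 = bottom
    y: np.ndarray
    x: np.ndarray
    nonpermeating: np.ndarray         # (T, nz, ny, nx) mOsm/kg
    permeating: np.ndarray            # (T, nz, ny, nx) mOsm/kg

    def sample(self, points: np.ndarray, component: str = "nonpermeating") -> np.ndarray:
        """Trilinear interpolation at (z, y, x) µm points for all stored times.

        Returns an array of shape (T, n_points).
        """
        from scipy.interpolate import RegularGridInterpolator

        arr = getattr(self, component)
        pts = np.atleast_2d(points)
        out = np.empty((len(self.times), len(pts)))
        for k in range(len(self.times)):
            itp = RegularGridInterpolator((self.z, self.y, self.x), arr[k],
                                          bounds_error=False, fill_value=None)
            out[k] = itp(pts)
        return out


class FieldStepper:
    """Backward-Euler integrator for the two bath components.

    Holds the factorized implicit operator and the current state;
    :meth:`step` advances one time step with the given bath values and
    :meth:`grids` returns the full node fields including Dirichlet faces.
    """

    def __init__(self, config: SimConfig, d_eff: float, dt: float, *,
                 grid_spacing: tuple[float, float, float] | None = None,
                 lateral_bc: str = "dirichlet",
                 baseline_mosm: float = 300.0,
                 initial_permeating: float = 0.0):
        if lateral_bc not in ("dirichlet", "neumann"):
            raise ValueError("lateral_bc must be 'dirichlet' or 'neumann'")
        if dt <= 0:
            raise ValueError("dt must be > 0")
        dz0, dy0, dx0 = config.voxel_size
        if grid_spacing is None:
            grid_spacing = (dz0, 4 * dy0, 4 * dx0)
        lz = config.slab_thickness
        _, ly, lx = config.extent

        def axis_nodes(length, spacing):
            n = max(int(round(length / spacing)) + 1, 3)
            return np.linspace(0.0, length, n)

        self.z = axis_nodes(lz, grid_spacing[0])
        self.y = axis_nodes(ly, grid_spacing[1])
        self.x = axis_nodes(lx, grid_spacing[2])
        hz, hy, hx = (a[1] - a[0] for a in (self.z, self.y, self.x))

        lz_op, gz = _lap1d(len(self.z), hz, "neumann", "dirichlet")  # glass bottom, bath top
        self.lat = lateral_bc
        ly_op, gy = _lap1d(len(self.y), hy, lateral_bc, lateral_bc)
        lx_op, gx = _lap1d(len(self.x), hx, lateral_bc, lateral_bc)

        self._nu = (lz_op.shape[0], ly_op.shape[0], lx_op.shape[0])
        nzu, nyu, nxu = self._nu
        iz, iy, ix = sp.identity(nzu), sp.identity(nyu), sp.identity(nxu)
        lap = (sp.kron(sp.kron(lz_op, iy), ix)
               + sp.kron(sp.kron(iz, ly_op), ix)
               + sp.kron(sp.kron(iz, iy), lx_op)).tocsr()
        # boundary source: g3[i,j,k] = gz[i] + gy[j] + gx[k] over unknown nodes
        self._g3 = (gz[:, None, None] + gy[None, :, None] + gx[None, None, :]).ravel()

        n_u = nzu * nyu * nxu
        ident = sp.identity(n_u, format="csr")
        self._lu = splu((ident - dt * d_eff * lap).tocsc())
        self._dd = d_eff * dt
        self.dt = dt
        self.u_m = np.full(n_u, float(baseline_mosm))
        self.u_s = np.full(n_u, float(initial_permeating))
        self.bath = (float(baseline_mosm), float(initial_permeating))

    def step(self, bath_m: float, bath_s: float) -> None:
        self.u_m = self._lu.solve(self.u_m + self._dd * bath_m * self._g3)
        self.u_s = self._lu.solve(self.u_s + self._dd * bath_s * self._g3)
        self.bath = (bath_m, bath_s)

    def _embed(self, u_flat, bath_value):
        full = np.full((len(self.z), len(self.y), len(self.x)), bath_value,
                       dtype=np.float64)
        nzu, nyu, nxu = self._nu
        sl_y = slice(1, 1 + nyu) if self.lat == "dirichlet" else slice(0, nyu)
        sl_x = slice(1, 1 + nxu) if self.lat == "dirichlet" else slice(0, nxu)
        full[0:nzu, sl_y, sl_x] = u_flat.reshape(self._nu)
        return full

    def grids(self) -> tuple[np.ndarray, np.ndarray]:
        """Current (nonpermeating, permeating) fields on the full node grid."""
        return self._embed(self.u_m, self.bath[0]), self._embed(self.u_s, self.bath[1])


def simulate_osmolality_field(protocol: SolutionProtocol, config: SimConfig,
                              d_eff: float, *,
                              grid_spacing: tuple[float, float, float] | None = None,
                              lateral_bc: str = "dirichlet",
                              dt: float = 0.5,
                              times: np.ndarray | None = None) -> OsmolalityField:
    """Integrate both bath components and return snapshots at ``times``.

    ``times`` defaults to the protocol's frame times.  The solver grid is
    decoupled from the voxel grid: ``grid_spacing`` defaults to
    ``(dz, 4*dy, 4*dx)`` (the solute field is far smoother than the image).
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if times is None:
        times = protocol.frame_times
    times = np.asarray(times, dtype=float)

    t_end = float(times.max())
    n_steps = max(int(np.ceil(t_end / dt - 1e-12)), 1) if t_end > 0 else 0
    h = t_end / n_steps if n_steps else dt

    stepper = FieldStepper(config, d_eff, h, grid_spacing=grid_spacing,
                           lateral_bc=lateral_bc,
                           baseline_mosm=protocol.baseline_mosm)
    # map each requested time onto its nearest step (times need not divide dt)
    snap_at: dict[int, list[int]] = {}
    for k, t_req in enumerate(times):
        snap_at.setdefault(int(round(t_req / h)) if n_steps else 0, []).append(k)

    shape = (len(times), len(stepper.z), len(stepper.y), len(stepper.x))
    snaps_m = np.empty(shape)
    snaps_s = np.empty_like(snaps_m)

    def snapshot(i_step):
        for k in snap_at.get(i_step, ()):
            snaps_m[k], snaps_s[k] = stepper.grids()

    stepper.bath = protocol.bath_at(0.0)
    snapshot(0)
    for i in range(n_steps):
        stepper.step(*protocol.bath_at((i + 1) * h))
        snapshot(i + 1)

    return OsmolalityField(times=times, z=stepper.z, y=stepper.y, x=stepper.x,
                           nonpermeating=snaps_m, permeating=snaps_s)
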