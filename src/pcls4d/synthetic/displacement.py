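"""Strain-driven displacement of nuclei (and cell centres) in the slab.

Local isotropic swelling or shrinkage of the tissue is described by the
linear strain field ``lambda(x, t) = v_local(x, t)**(1/3)``, where
``v_local`` is the normalized volume response of the material at that
location.  The slab is anchored at the chamber glass, so a material
point initially at height ``z0`` rides on the accumulated axial strain
below it::

    z(t) = integral_0^z0 lambda(z', y0, x0, t) dz'

Laterally the tissue dilates about the slab's lateral centroid: the
distance from the centroid is scaled by the mean lateral strain along
the ray from the centroid to the point (evaluated at the point's initial
height).  Uniform ``v = 1`` therefore gives zero displacement, and
uniform swelling moves every point up, the more so the higher it sits.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import RegularGridInterpolator


def compute_nuclear_displacement(v_field: np.ndarray, grid: tuple[np.ndarray, np.ndarray, np.ndarray],
                                 points0: np.ndarray, *,
                                 slab_thickness: float | None = None,
                                 lateral_centroid: tuple[float, float] | None = None,
                                 n_quad: int = 64) -> np.ndarray:
    """Advect initial (z, y, x) positions through a local-volume field.

    Parameters
    ----------
    v_field
        Normalized local volume, shape ``(T, nz, ny, nx)`` on ``grid``.
    grid
        Node coordinates ``(z, y, x)`` in µm (z = 0 at the glass).
    points0
        Initial positions, shape ``(n, 3)`` as (z, y, x) µm; must lie
        inside the slab.
    n_quad
        Trapezoid points for the axial strain integral and the lateral
        ray average.

    Returns positions of shape ``(T, n, 3)``.
    """
    z, y, x = grid
    pts = np.atleast_2d(np.asarray(points0, dtype=float))
    lz = slab_thickness if slab_thickness is not None else z[-1]
    if np.any(pts[:, 0] < -1e-9) or np.any(pts[:, 0] > lz + 1e-9) \
            or np.any(pts[:, 1] < y[0] - 1e-9) or np.any(pts[:, 1] > y[-1] + 1e-9) \
            or np.any(pts[:, 2] < x[0] - 1e-9) or np.any(pts[:, 2] > x[-1] + 1e-9):
        raise ValueError("initial position outside the slab")
    cy, cx = lateral_centroid if lateral_centroid is not None \
        else ((y[0] + y[-1]) / 2.0, (x[0] + x[-1]) / 2.0)

    n_t = v_field.shape[0]
    n_p = len(pts)
    out = np.empty((n_t, n_p, 3))

    # Axial quadrature nodes per point: n_quad points from 0 to z0.
    frac = np.linspace(0.0, 1.0, n_quad)
    zq = pts[:, 0, None] * frac[None, :]                     # (n_p, n_quad)
    axial_nodes = np.stack([
        zq,
        np.broadcast_to(pts[:, 1, None], zq.shape),
        np.broadcast_to(pts[:, 2, None], zq.shape),
    ], axis=-1).reshape(-1, 3)

    # Lateral ray nodes at the initial height of each point.
    lat_frac = np.linspace(0.0, 1.0, n_quad)
    ly_q = cy + (pts[:, 1, None] - cy) * lat_frac[None, :]
    lx_q = cx + (pts[:, 2, None] - cx) * lat_frac[None, :]
    lateral_nodes = np.stack([
        np.broadcast_to(pts[:, 0, None], ly_q.shape),
        ly_q, lx_q,
    ], axis=-1).reshape(-1, 3)

    for k in range(n_t):
        lam = np.cbrt(v_field[k])
        itp = RegularGridInterpolator((z, y, x), lam,
                                      bounds_error=False, fill_value=None)
        lam_ax = itp(axial_nodes).reshape(n_p, n_quad)
        z_new = np.trapezoid(lam_ax, zq, axis=1)
        lam_lat = itp(lateral_nodes).reshape(n_p, n_quad).mean(axis=1)
        out[k, :, 0] = z_new
        out[k, :, 1] = cy + (pts[:, 1] - cy) * lam_lat
        out[k, :, 2] = cx + (pts[:, 2] - cx) * lam_lat
    return out
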