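"""Osmotic cell-volume dynamics.

State per cell (all normalized to the isosmotic initial state):

* ``w`` water volume fraction (w(0) = 1),
* ``n`` moles of non-permeating intracellular osmolytes (n(0) = 1),
* ``s`` moles of permeating solute, in units where the intracellular
  concentration contribution is ``M0 * s / w``.

Model equations (``M0`` = baseline osmolality, ``Me``/``Se`` = local
extracellular non-permeating / permeating osmolality)::

    Mi    = M0 * (n + s) / w          intracellular osmolality
    dw/dt = k_w * (Mi - Me - Se) / M0         water flux
    ds/dt = k_s * (Se - M0 * s / w) / M0      solute flux
    dn/dt = -k_r * (v - 1), n >= 0            RVD/RVI leak
    v     = b + (1 - b) * w                   normalized cell volume

Water leaves when the bath is hyperosmotic and enters when hyposmotic;
the permeating solute equilibrates at rate ``k_s`` and drags water back
in (shrink-swell); the regulation term leaks osmolytes out of swollen
cells (RVD) and accumulates them in shrunken ones (RVI), returning the
volume toward its isosmotic value.  With ``k_s = k_r = 0`` and a
constant bath the equilibrium obeys Boyle-van't Hoff:
``v_inf = b + (1 - b) * M0 / Me``.
"""

from __future__ import annotations

import numpy as np

from .config import TransportParams


class IntegrationError(RuntimeError):
    """Water volume became non-positive; reduce the time step."""


def _rates(params: TransportParams, m0, w, n, s, me, se):
    mi = m0 * (n + s) / w
    dw = params.k_w * (mi - me - se) / m0
    ds = params.k_s * (se - m0 * s / w) / m0
    v = params.b + (1.0 - params.b) * w
    dn = -params.k_r * (v - 1.0)
    return dw, dn, ds


def simulate_cell_volume(params: TransportParams, me, se, m0: float, dt: float,
                         *, pre_equilibrated: bool = True):
    """Integrate the transport model against sampled bath series.

    ``me`` and ``se`` are arrays of shape ``(T,)`` or ``(T, n_cells)``
    holding the local extracellular osmolalities at uniformly spaced
    times ``0, dt, 2*dt, ...``.  A classical RK4 step is taken per
    sample interval (bath values at half steps are interpolated
    linearly).  Returns ``(w, n, s, v)`` arrays matching the input shape.

    The initial state is ``w = n = 1`` and ``s = Se(0)/M0`` when
    ``pre_equilibrated`` (the cell already contains the permeating
    solute), else ``s = 0``.
    """
    was_1d = np.asarray(me).ndim == 1
    me = np.atleast_2d(np.asarray(me, dtype=float).T).T  # (T, k)
    se = np.atleast_2d(np.asarray(se, dtype=float).T).T
    if me.shape != se.shape:
        raise ValueError("me and se must have the same shape")
    n_t, k = me.shape
    w = np.ones(k)
    n = np.ones(k)
    s = se[0] / m0 if pre_equilibrated else np.zeros(k)

    ws = np.empty((n_t, k))
    ns = np.empty((n_t, k))
    ss = np.empty((n_t, k))
    ws[0], ns[0], ss[0] = w, n, s

    for i in range(n_t - 1):
        me0, se0 = me[i], se[i]
        me1, se1 = me[i + 1], se[i + 1]
        meh, seh = 0.5 * (me0 + me1), 0.5 * (se0 + se1)
        k1 = _rates(params, m0, w, n, s, me0, se0)
        k2 = _rates(params, m0, w + 0.5 * dt * k1[0], n + 0.5 * dt * k1[1],
                    s + 0.5 * dt * k1[2], meh, seh)
        k3 = _rates(params, m0, w + 0.5 * dt * k2[0], n + 0.5 * dt * k2[1],
                    s + 0.5 * dt * k2[2], meh, seh)
        k4 = _rates(params, m0, w + dt * k3[0], n + dt * k3[1],
                    s + dt * k3[2], me1, se1)
        w = w + dt / 6.0 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
        n = n + dt / 6.0 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
        s = s + dt / 6.0 * (k1[2] + 2 * k2[2] + 2 * k3[2] + k4[2])
        n = np.maximum(n, 0.0)
        s = np.maximum(s, 0.0)
        if np.any(w <= 0):
            raise IntegrationError(
                f"water volume became non-positive at t={dt * (i + 1):.3f} s; "
                "reduce dt")
        ws[i + 1], ns[i + 1], ss[i + 1] = w, n, s

    v = params.b + (1.0 - params.b) * ws
    if k == 1 and was_1d:
        return ws[:, 0], ns[:, 0], ss[:, 0], v[:, 0]
    return ws, ns, ss, v


def boyle_vant_hoff(params: TransportParams, m0: float, me: float) -> float:
    """Equilibrium normalized volume with only water moving (k_s = k_r = 0)."""
    return params.b + (1.0 - params.b) * m0 / me
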