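"""Numba inner loops for the explicit finite-volume solver.

Fields are (nx, ny) arrays of mass per cell.  Advection uses first-order
upwind fluxes built from face velocities; diffusion uses central differences;
both vanish on the four outer faces (no-flux boundaries), so the transport
part is exactly conservative.  The clearance sink and birth source are
pointwise.  All kernels mutate their field arguments in place and return
accumulated mass diagnostics.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _fluxes(m, vxf, vyf, Dv, Dh, dx, dy, fx, fy):
    """Fill face flux arrays for one field.

    fx has shape (nx+1, ny) with fx[0]=fx[nx]=0; fy has shape (nx, ny+1)
    with fy[:,0]=fy[:,ny]=0.  Positive flux means mass moving in +x / +y.
    """
    nx, ny = m.shape
    for i in range(1, nx):
        for j in range(ny):
            u = vxf[i, j]
            if u > 0.0:
                adv = u * m[i - 1, j] / dx
            else:
                adv = u * m[i, j] / dx
            fx[i, j] = adv - Dv * (m[i, j] - m[i - 1, j]) / (dx * dx)
    for i in range(nx):
        for j in range(1, ny):
            u = vyf[i, j]
            if u > 0.0:
                adv = u * m[i, j - 1] / dy
            else:
                adv = u * m[i, j] / dy
            fy[i, j] = adv - Dh * (m[i, j] - m[i, j - 1]) / (dy * dy)


@njit(cache=True)
def advance(m, vxf, vyf, Dv, Dh, kd, b, birth_rate, dx, dy, dt, n_steps):
    """Advance a single density field n_steps of size dt.

    kd is the clearance sink rate field (kappa * d, per day); b is the
    unit-mass birth distribution and birth_rate its per-day intensity.
    Returns (cleared, born, clipped) mass totals.
    """
    nx, ny = m.shape
    fx = np.zeros((nx + 1, ny))
    fy = np.zeros((nx, ny + 1))
    cleared = 0.0
    born = 0.0
    clipped = 0.0
    for _ in range(n_steps):
        _fluxes(m, vxf, vyf, Dv, Dh, dx, dy, fx, fy)
        for i in range(nx):
            for j in range(ny):
                div = fx[i + 1, j] - fx[i, j] + fy[i, j + 1] - fy[i, j]
                sink = kd[i, j] * m[i, j]
                src = birth_rate * b[i, j]
                m[i, j] += dt * (-div - sink + src)
                cleared += dt * sink
                born += dt * src
                if m[i, j] < 0.0:
                    clipped -= m[i, j]
                    m[i, j] = 0.0
    return cleared, born, clipped


@njit(cache=True)
def advance_tracked(m, q, r, vxf, vyf, Dv, Dh, kd, b, birth_rate,
                    retic_decay, dx, dy, dt, n_steps):
    """Advance the density m together with its age moment q and retic pool r.

    q is the first age moment (sum of age*mass per cell): it is transported
    and cleared like m, grows by +m per unit time (aging), and receives no
    birth source (newborns have age zero).  r is the detectable-reticulocyte
    mass: transported and cleared like m, fed by the birth source, and aged
    out at rate retic_decay (per day).
    """
    nx, ny = m.shape
    fx = np.zeros((nx + 1, ny))
    fy = np.zeros((nx, ny + 1))
    cleared = 0.0
    born = 0.0
    clipped = 0.0
    for _ in range(n_steps):
        _fluxes(m, vxf, vyf, Dv, Dh, dx, dy, fx, fy)
        # q and r see the same velocity field; their fluxes are computed from
        # their own values.  Reuse scratch arrays sequentially.
        qfx = np.zeros((nx + 1, ny))
        qfy = np.zeros((nx, ny + 1))
        _fluxes(q, vxf, vyf, Dv, Dh, dx, dy, qfx, qfy)
        rfx = np.zeros((nx + 1, ny))
        rfy = np.zeros((nx, ny + 1))
        _fluxes(r, vxf, vyf, Dv, Dh, dx, dy, rfx, rfy)
        for i in range(nx):
            for j in range(ny):
                mdiv = fx[i + 1, j] - fx[i, j] + fy[i, j + 1] - fy[i, j]
                qdiv = qfx[i + 1, j] - qfx[i, j] + qfy[i, j + 1] - qfy[i, j]
                rdiv = rfx[i + 1, j] - rfx[i, j] + rfy[i, j + 1] - rfy[i, j]
                sink = kd[i, j] * m[i, j]
                src = birth_rate * b[i, j]
                q[i, j] += dt * (-qdiv - kd[i, j] * q[i, j] + m[i, j])
                r[i, j] += dt * (-rdiv - kd[i, j] * r[i, j] + src - retic_decay * r[i, j])
                m[i, j] += dt * (-mdiv - sink + src)
                cleared += dt * sink
                born += dt * src
                if m[i, j] < 0.0:
                    clipped -= m[i, j]
                    m[i, j] = 0.0
                if q[i, j] < 0.0:
                    q[i, j] = 0.0
                if r[i, j] < 0.0:
                    r[i, j] = 0.0
                elif r[i, j] > m[i, j]:
                    r[i, j] = m[i, j]
    return cleared, born, clipped
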