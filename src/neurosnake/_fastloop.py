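"""Compiled inner loop for the closed-loop simulation.

This mirrors, arithmetic-for-arithmetic, one step of the modular path in
:mod:`neurosnake.experiments` (sensory readout -> RK4 oscillator step ->
motor map -> overdamped body step) so long batch runs stay cheap.  The
modular numpy path remains the reference; the test suite asserts the two
trajectories agree.

Status codes: 0 = ok, 1 = oscillator divergence (|x| > 1e3), 2 = non-finite
body state.
"""

from __future__ import annotations

import numpy as np
from numba import njit

DIVERGENCE_LIMIT = 1e3


@njit(cache=True)
def _bvp_rhs(x, y, sf, a, b, c, z, delta, eps_c, tau):
    dx = (c * (x - x ** 3 / 3.0 - y + z) + delta * (sf - x)) / tau
    dy = ((x - b * y + a) / c + eps_c * sf) / tau
    return dx, dy


@njit(cache=True)
def _coupling(x, Wn, iface, sensory, alpha):
    sf = np.dot(x, Wn)
    for k in range(iface.size):
        i = iface[k]
        sf[i] = alpha * sensory[k] + (1.0 - alpha) * sf[i]
    return sf


@njit(cache=True)
def _link_geometry(theta, head_xy, heading, n_links, half_pitch):
    phi = np.empty(n_links)
    centers = np.empty((n_links, 2))
    phi[0] = heading
    centers[0, 0] = head_xy[0]
    centers[0, 1] = head_xy[1]
    for i in range(1, n_links):
        phi[i] = phi[i - 1] + theta[i - 1]
        centers[i, 0] = centers[i - 1, 0] - half_pitch * (np.cos(phi[i - 1]) + np.cos(phi[i]))
        centers[i, 1] = centers[i - 1, 1] - half_pitch * (np.sin(phi[i - 1]) + np.sin(phi[i]))
    return centers, phi


@njit(cache=True)
def _muscle_lengths(theta, sides, mj, L0, kappa):
    n_m = sides.size
    L = np.empty(n_m)
    floor = 0.1 * L0
    for m in range(n_m):
        q = mj[m]
        val = L0 * (1.0 - sides[m] * kappa * 0.5 * (theta[q] + theta[q + 1]))
        L[m] = val if val > floor else floor
    return L


@njit(cache=True)
def run_loop(Wn, iface, n2m, sides, mj,
             a, b, c, z, delta, eps_c, alpha, tau, dt,
             L0, kappa, ks, kd, visc, g_motor, sigma, sens_clip, jlimit,
             half_pitch, ct, cn, n_links,
             x, y, theta, theta_dot, head,
             n_steps, stride,
             out_t, out_x, out_y, out_theta, out_L, out_head):
    """Advance the coupled system n_steps; record every ``stride`` steps.

    State arrays are updated in place; returns (status, n_recorded).
    """
    n_joints = theta.size
    n_m = sides.size
    rec = 0
    t = 0.0
    for step in range(n_steps + 1):
        L = _muscle_lengths(theta, sides, mj, L0, kappa)
        if step % stride == 0:
            out_t[rec] = t
            out_x[rec] = x
            out_y[rec] = y
            out_theta[rec] = theta
            out_L[rec] = L
            out_head[rec, 0] = head[0]
            out_head[rec, 1] = head[1]
            out_head[rec, 2] = head[2]
            rec += 1
        if step == n_steps:
            break

        # sensory readout (per interface neuron, via the muscle assignment)
        sensory = np.empty(n_m)
        for k in range(n_m):
            v = sigma * (L[n2m[k]] - L0) / L0
            if v > sens_clip:
                v = sens_clip
            elif v < -sens_clip:
                v = -sens_clip
            sensory[k] = v

        # RK4 oscillator step with frozen sensory input
        sf = _coupling(x, Wn, iface, sensory, alpha)
        k1x, k1y = _bvp_rhs(x, y, sf, a, b, c, z, delta, eps_c, tau)
        x2 = x + 0.5 * dt * k1x
        y2 = y + 0.5 * dt * k1y
        sf = _coupling(x2, Wn, iface, sensory, alpha)
        k2x, k2y = _bvp_rhs(x2, y2, sf, a, b, c, z, delta, eps_c, tau)
        x3 = x + 0.5 * dt * k2x
        y3 = y + 0.5 * dt * k2y
        sf = _coupling(x3, Wn, iface, sensory, alpha)
        k3x, k3y = _bvp_rhs(x3, y3, sf, a, b, c, z, delta, eps_c, tau)
        x4 = x + dt * k3x
        y4 = y + dt * k3y
        sf = _coupling(x4, Wn, iface, sensory, alpha)
        k4x, k4y = _bvp_rhs(x4, y4, sf, a, b, c, z, delta, eps_c, tau)
        x = x + dt / 6.0 * (k1x + 2 * k2x + 2 * k3x + k4x)
        y = y + dt / 6.0 * (k1y + 2 * k2y + 2 * k3y + k4y)
        if np.max(np.abs(x)) > DIVERGENCE_LIMIT:
            return 1, rec

        # motor command from the fresh interface activations
        rest = np.empty(n_m)
        for k in range(n_m):
            rest[n2m[k]] = L0 * (1.0 + g_motor * np.tanh(x[iface[k]]))

        # overdamped body step
        torque = np.zeros(n_joints)
        for m in range(n_m):
            q = mj[m]
            Ldot = -sides[m] * kappa * L0 * 0.5 * (theta_dot[q] + theta_dot[q + 1])
            F = ks * (rest[m] - L[m]) - kd * Ldot
            dLdth = -sides[m] * kappa * L0 * 0.5
            torque[q] += F * dLdth
            torque[q + 1] += F * dLdth
        theta_dot_new = torque / visc
        theta_new = theta + dt * theta_dot_new
        for j in range(n_joints):
            if theta_new[j] > jlimit:
                theta_new[j] = jlimit
                theta_dot_new[j] = 0.0
            elif theta_new[j] < -jlimit:
                theta_new[j] = -jlimit
                theta_dot_new[j] = 0.0
            if not np.isfinite(theta_new[j]):
                return 2, rec

        # locomotion: rigid velocity minimising anisotropic friction
        centers, phi = _link_geometry(theta, head[0:2], head[2], n_links, half_pitch)
        centers_new, _ = _link_geometry(theta_new, head[0:2], head[2], n_links,
                                        half_pitch)
        refx = centers[:, 0].mean()
        refy = centers[:, 1].mean()
        H = np.zeros((3, 3))
        gv = np.zeros(3)
        for i in range(n_links):
            tx = np.cos(phi[i])
            ty = np.sin(phi[i])
            nx = -ty
            ny = tx
            m11 = ct * tx * tx + cn * nx * nx
            m12 = ct * tx * ty + cn * nx * ny
            m22 = ct * ty * ty + cn * ny * ny
            rx = centers[i, 0] - refx
            ry = centers[i, 1] - refy
            c1 = -m11 * ry + m12 * rx
            c2 = -m12 * ry + m22 * rx
            H[0, 0] += m11
            H[0, 1] += m12
            H[0, 2] += c1
            H[1, 1] += m22
            H[1, 2] += c2
            H[2, 2] += -ry * c1 + rx * c2
            sx = (centers_new[i, 0] - centers[i, 0]) / dt
            sy = (centers_new[i, 1] - centers[i, 1]) / dt
            p1 = m11 * sx + m12 * sy
            p2 = m12 * sx + m22 * sy
            gv[0] += p1
            gv[1] += p2
            gv[2] += -ry * p1 + rx * p2
        H[1, 0] = H[0, 1]
        H[2, 0] = H[0, 2]
        H[2, 1] = H[1, 2]
        xi = np.linalg.solve(H, -gv)
        r0x = centers[0, 0] - refx
        r0y = centers[0, 1] - refy
        head[0] += dt * (xi[0] - xi[2] * r0y)
        head[1] += dt * (xi[1] + xi[2] * r0x)
        head[2] += dt * xi[2]

        theta = theta_new
        theta_dot = theta_dot_new
        t += dt
    return 0, rec
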