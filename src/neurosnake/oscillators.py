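"""Bonhoeffer–van der Pol (BVP / FitzHugh–Nagumo) oscillator network.

Each node i follows

    tau dx/dt = c (x - x^3/3 - y + z) + delta (S_f - x)
    tau dy/dt = (1/c)(x - b y + a) + eps_c S_f

where ``z`` is a tonic input setting the oscillatory regime and ``S_f`` is
the coupling input.  Hidden nodes receive the degree-normalised network term
``(1/K_i) sum_j w_ji x_j``; interface nodes blend that term with bodily
sensory feedback ``I`` through the sensor ratio ``alpha``:

    S_f = alpha I + (1 - alpha) * network term       (interface)
    S_f = network term                               (hidden)

Integration is fixed-step RK4 by default (Euler optional), with sensory
input held constant over a step (the body updates at the same rate, see
:mod:`neurosnake.experiments`).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .wirednet import WiredNetwork

DIVERGENCE_LIMIT = 1e3


class DivergenceError(FloatingPointError):
    """Integration left the physically plausible range."""


@dataclass(frozen=True)
class BVPParams:
    """BVP parameters; defaults are the standard operating point."""

    a: float = 0.7
    b: float = -0.2
    c: float = 2.0
    z: float = 0.4          # tonic input; grid {0.4, 0.45, 0.5, 0.55}
    delta: float = 0.01     # excitatory coupling gain
    eps_c: float = 0.015    # inhibitory coupling gain
    alpha: float = 0.0      # sensor ratio in [0, 1]
    tau: float = 1.0        # time constant [s]
    dt: float = 0.01        # integration step [s]
    scheme: str = "rk4"     # "rk4" or "euler"

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.dt <= 0:
            raise ValueError("dt must be positive")


@dataclass
class OscState:
    x: np.ndarray
    y: np.ndarray
    t: float = 0.0

    def copy(self) -> "OscState":
        return OscState(self.x.copy(), self.y.copy(), self.t)


def initial_state(n: int, rng: np.random.Generator,
                  amplitude: float = 0.1) -> OscState:
    """x, y i.i.d. uniform on [-amplitude, amplitude]."""
    return OscState(rng.uniform(-amplitude, amplitude, n),
                    rng.uniform(-amplitude, amplitude, n), 0.0)


def coupling_term(x: np.ndarray, net: WiredNetwork,
                  sensory: np.ndarray | None, alpha: float) -> np.ndarray:
    """Per-node coupling input S_f.

    ``sensory`` holds one feedback value per interface node (ordered by
    interface index); it may be None when alpha == 0 or there are no
    interface nodes.  Nodes with zero in-degree get a zero network term.
    """
    net_term = x @ net.coupling_matrix
    sf = net_term
    iface = net.interface_index
    if iface.size and alpha > 0.0:
        if sensory is None:
            raise ValueError("sensory input required for interface nodes with alpha > 0")
        sf = net_term.copy()
        sf[iface] = alpha * np.asarray(sensory) + (1.0 - alpha) * net_term[iface]
    return sf


def bvp_derivatives(x: np.ndarray, y: np.ndarray, sf: np.ndarray,
                    p: BVPParams) -> tuple[np.ndarray, np.ndarray]:
    """Right-hand side of the BVP system (dx/dt, dy/dt)."""
    # a single reduction is enough: any nan/inf poisons the sum
    if not np.isfinite(float(np.sum(x)) + float(np.sum(y))):
        raise DivergenceError("non-finite oscillator state")
    dx = (p.c * (x - x ** 3 / 3.0 - y + p.z) + p.delta * (sf - x)) / p.tau
    dy = ((x - p.b * y + p.a) / p.c + p.eps_c * sf) / p.tau
    return dx, dy


def integrate_step(state: OscState, net: WiredNetwork,
                   sensory: np.ndarray | None, p: BVPParams) -> OscState:
    """Advance the network state by one dt (sensory frozen over the step)."""
    x, y, dt = state.x, state.y, p.dt

    def f(xv, yv):
        return bvp_derivatives(xv, yv, coupling_term(xv, net, sensory, p.alpha), p)

    if p.scheme == "euler":
        dx, dy = f(x, y)
        xn, yn = x + dt * dx, y + dt * dy
    elif p.scheme == "rk4":
        k1x, k1y = f(x, y)
        k2x, k2y = f(x + 0.5 * dt * k1x, y + 0.5 * dt * k1y)
        k3x, k3y = f(x + 0.5 * dt * k2x, y + 0.5 * dt * k2y)
        k4x, k4y = f(x + dt * k3x, y + dt * k3y)
        xn = x + dt / 6.0 * (k1x + 2 * k2x + 2 * k3x + k4x)
        yn = y + dt / 6.0 * (k1y + 2 * k2y + 2 * k3y + k4y)
    else:
        raise ValueError(f"unknown scheme {p.scheme!r}")

    if np.max(np.abs(xn)) > DIVERGENCE_LIMIT:
        raise DivergenceError(
            f"|x| exceeded {DIVERGENCE_LIMIT:g} at t={state.t + dt:.2f}s")
    return OscState(xn, yn, state.t + dt)


def simulate_free(net: WiredNetwork, p: BVPParams, duration: float,
                  rng: np.random.Generator,
                  sample_every: float = 0.1) -> dict[str, np.ndarray]:
    """Open-loop (no body) simulation with alpha forced to 0.

    Returns ``{"time", "x", "y"}`` sampled at ``sample_every`` seconds.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    p = replace(p, alpha=0.0)
    state = initial_state(net.n_nodes, rng)
    stride = max(1, round(sample_every / p.dt))
    n_steps = round(duration / p.dt)
    times, xs, ys = [], [], []
    for step in range(n_steps + 1):
        if step % stride == 0:
            times.append(state.t)
            xs.append(state.x.copy())
            ys.append(state.y.copy())
        if step < n_steps:
            state = integrate_step(state, net, None, p)
    return {"time": np.array(times), "x": np.array(xs), "y": np.array(ys)}


def nullcline_intersection(p: BVPParams, x0: float = 0.0) -> tuple[float, float]:
    """Uncoupled equilibrium: intersection of the cubic and linear nullclines.

    Solves x - x^3/3 - y + z = 0 and x - b y + a = 0.
    """
    from scipy.optimize import brentq

    def g(x):
        y = (x + p.a) / p.b
        return x - x ** 3 / 3.0 - y + p.z

    # bracket a root around x0
    for half_width in (1.0, 2.0, 4.0, 8.0):
        lo, hi = x0 - half_width, x0 + half_width
        if g(lo) * g(hi) < 0:
            x_star = brentq(g, lo, hi, xtol=1e-15)
            return x_star, (x_star + p.a) / p.b
    raise ValueError("no nullcline intersection found near x0")
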