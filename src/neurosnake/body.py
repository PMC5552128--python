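"""Planar snake-like musculoskeletal body.

A chain of rigid links (default 15, each 0.1 m long with a 0.02 m gap,
0.6 kg) connected by planar hinge joints (14) and actuated by antagonistic
two-joint muscles: one left/right pair flanking every pair of adjacent
joints (q, q+1), giving 2 * (n_joints - 1) = 26 muscles for the default
body.

Mechanics are deliberately simple and overdamped:

* each muscle is a linear spring-damper whose rest length is modulated by
  its interface neuron's command (``motor_map``);
* joint angular velocity is proportional to the net muscle torque
  (first-order dynamics — inertia is neglected), with hard joint limits;
* locomotion uses the classic anisotropic ground-friction resolution for
  undulatory crawlers: at each step the rigid-body velocity (v, omega) of
  the whole chain is the minimiser of the frictional dissipation
  ``sum_i c_t (v_i . t_i)^2 + c_n (v_i . n_i)^2`` given the internal shape
  change, so traveling body waves yield net translation when lateral
  friction exceeds longitudinal friction.

Muscle length is a declared geometric function of the two spanned joint
angles, ``L = L0 (1 - s * kappa * (theta_q + theta_{q+1}) / 2)`` with side
sign ``s`` (+1 left, -1 right); sensory feedback is the relative length
deviation scaled by a gain and clipped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BodyParams:
    """Geometry, muscle and friction parameters (SI units)."""

    link_length: float = 0.1    # [m]
    link_width: float = 0.1     # [m]
    link_height: float = 0.1    # [m]
    gap: float = 0.02           # [m] between adjacent links
    link_mass: float = 0.6      # [kg] (bookkeeping only; dynamics overdamped)
    stiffness: float = 100.0    # muscle spring constant k_s [N/m]
    damping: float = 1.0        # muscle damper k_d [N s/m]
    joint_visc: float = 0.2     # joint viscous coefficient [N m s/rad]
    kappa: float = 0.3          # muscle geometry factor [1/rad]
    motor_gain: float = 0.2     # rest-length modulation gain g
    sensory_gain: float = 2.0   # sigma in I = sigma (L - L0)/L0
    sensory_clip: float = 2.0
    joint_limit: float = np.pi / 3
    friction_long: float = 0.1  # longitudinal friction coefficient c_t
    friction_lat: float = 1.0   # lateral friction coefficient c_n

    @property
    def rest_length(self) -> float:
        """Slack length L0: a two-joint muscle spans two link pitches."""
        return 2.0 * (self.link_length + self.gap)


@dataclass
class BodyModel:
    n_links: int
    params: BodyParams
    # (side, q) per muscle: side +1 = left, -1 = right; spans joints q, q+1
    muscle_sides: np.ndarray = field(init=False)
    muscle_joints: np.ndarray = field(init=False)
    # interface neuron -> muscle assignment (identity by default)
    neuron_to_muscle: np.ndarray = field(init=False)

    def __post_init__(self):
        if self.n_links < 3:
            raise ValueError("need at least 3 links")
        spans = np.arange(self.n_joints - 1)
        # left muscles first (body order), then right muscles
        self.muscle_sides = np.concatenate([np.ones_like(spans), -np.ones_like(spans)])
        self.muscle_joints = np.concatenate([spans, spans])
        self.neuron_to_muscle = np.arange(self.n_muscles)

    @property
    def n_joints(self) -> int:
        return self.n_links - 1

    @property
    def n_muscles(self) -> int:
        return 2 * (self.n_joints - 1)

    @property
    def body_length(self) -> float:
        p = self.params
        return self.n_links * p.link_length + (self.n_links - 1) * p.gap


@dataclass
class BodyState:
    theta: np.ndarray        # joint angles [rad]
    theta_dot: np.ndarray    # joint angular velocities [rad/s]
    head_xy: np.ndarray      # head link centre [m]
    heading: float           # head link orientation [rad]
    t: float = 0.0

    def copy(self) -> "BodyState":
        return BodyState(self.theta.copy(), self.theta_dot.copy(),
                         self.head_xy.copy(), self.heading, self.t)


def build_snake(n_links: int = 15, params: BodyParams | None = None) -> BodyModel:
    """Default body: 15 links -> 14 joints, 26 two-joint muscles."""
    return BodyModel(n_links, params or BodyParams())


def initial_body_state(model: BodyModel) -> BodyState:
    return BodyState(np.zeros(model.n_joints), np.zeros(model.n_joints),
                     np.zeros(2), 0.0, 0.0)


# ---------------------------------------------------------------------------
# Muscle geometry, motor and sensory maps
# ---------------------------------------------------------------------------


def muscle_length(state: BodyState, model: BodyModel) -> np.ndarray:
    """Geometric muscle lengths; mirror-symmetric in the side sign.

    Lengths are clamped at 0.1 * L0 (and logged) if the linearised geometry
    would make them non-positive.
    """
    p = model.params
    q = model.muscle_joints
    mean_bend = 0.5 * (state.theta[q] + state.theta[q + 1])
    L = p.rest_length * (1.0 - model.muscle_sides * p.kappa * mean_bend)
    floor = 0.1 * p.rest_length
    if np.any(L < floor):
        logger.warning("muscle length clamped at %.3g m", floor)
        L = np.maximum(L, floor)
    return L


def muscle_velocity(state: BodyState, model: BodyModel) -> np.ndarray:
    p = model.params
    q = model.muscle_joints
    return -model.muscle_sides * p.kappa * p.rest_length * 0.5 * (
        state.theta_dot[q] + state.theta_dot[q + 1])


def motor_map(x_interface: np.ndarray, model: BodyModel) -> np.ndarray:
    """Interface activations -> target muscle rest lengths.

    u_m = tanh(x) squashes the command to [-1, 1]; the rest length is
    ``L0 (1 + g u_m)``.  Neuron order follows ``model.neuron_to_muscle``.
    """
    x = np.asarray(x_interface, dtype=float)
    if x.shape[0] != model.n_muscles:
        raise ValueError(
            f"expected {model.n_muscles} interface activations, got {x.shape[0]}")
    u = np.tanh(x)
    rest = np.empty(model.n_muscles)
    rest[model.neuron_to_muscle] = model.params.rest_length * (
        1.0 + model.params.motor_gain * u)
    return rest


def sensory_readout(state: BodyState, model: BodyModel) -> np.ndarray:
    """Relative muscle-length deviation, one value per interface neuron."""
    p = model.params
    L = muscle_length(state, model)
    I = p.sensory_gain * (L - p.rest_length) / p.rest_length
    I = np.clip(I, -p.sensory_clip, p.sensory_clip)
    return I[model.neuron_to_muscle]


# ---------------------------------------------------------------------------
# Kinematics and locomotion
# ---------------------------------------------------------------------------


def link_frames(state: BodyState, model: BodyModel) -> tuple[np.ndarray, np.ndarray]:
    """Link centre positions and orientations from head pose + joint angles."""
    p = model.params
    half_pitch = 0.5 * (p.link_length + p.gap)
    phi = state.heading + np.concatenate([[0.0], np.cumsum(state.theta)])
    u = np.stack([np.cos(phi), np.sin(phi)], axis=1)
    steps = -half_pitch * (u[:-1] + u[1:])
    centers = np.empty((model.n_links, 2))
    centers[0] = state.head_xy
    centers[1:] = state.head_xy + np.cumsum(steps, axis=0)
    return centers, phi


def _rigid_velocity(model: BodyModel, centers: np.ndarray, phi: np.ndarray,
                    shape_vel: np.ndarray) -> tuple[np.ndarray, float]:
    """Rigid (v, omega) minimising anisotropic frictional dissipation.

    ``shape_vel`` is the per-link velocity due to internal shape change with
    the head frame held fixed.  Solves the 3x3 weighted least-squares normal
    equations.
    """
    p = model.params
    ref = centers.mean(axis=0)
    r = centers - ref
    t_hat = np.stack([np.cos(phi), np.sin(phi)], axis=1)
    n_hat = np.stack([-np.sin(phi), np.cos(phi)], axis=1)
    # M_i = c_t t t^T + c_n n n^T  (2x2 per link)
    M = (p.friction_long * np.einsum("ij,ik->ijk", t_hat, t_hat)
         + p.friction_lat * np.einsum("ij,ik->ijk", n_hat, n_hat))
    # v_i = s_i + v + omega * perp(r_i); unknowns xi = (vx, vy, omega)
    B = np.zeros((model.n_links, 2, 3))
    B[:, 0, 0] = 1.0
    B[:, 1, 1] = 1.0
    B[:, 0, 2] = -r[:, 1]
    B[:, 1, 2] = r[:, 0]
    H = np.einsum("iaj,iab,ibk->jk", B, M, B)
    g = np.einsum("iaj,iab,ib->j", B, M, shape_vel)
    xi = np.linalg.solve(H, -g)
    v = xi[:2]
    omega = xi[2]
    # translate the solution back to the head point
    r_head = centers[0] - ref
    v_head = v + omega * np.array([-r_head[1], r_head[0]])
    return v_head, omega


def body_step(model: BodyModel, state: BodyState, rest_lengths: np.ndarray,
              dt: float) -> BodyState:
    """Advance the body by dt under the given muscle rest-length commands.

    Overdamped joint update from muscle torques, then head-pose update from
    the friction-resolved rigid velocity.  Deterministic.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    p = model.params
    L = muscle_length(state, model)
    Ldot = muscle_velocity(state, model)
    F = p.stiffness * (rest_lengths - L) - p.damping * Ldot
    # dL/dtheta_q = -s * kappa * L0 / 2 for both spanned joints
    dL_dtheta = -model.muscle_sides * p.kappa * p.rest_length * 0.5
    torque = np.zeros(model.n_joints)
    np.add.at(torque, model.muscle_joints, F * dL_dtheta)
    np.add.at(torque, model.muscle_joints + 1, F * dL_dtheta)

    theta_dot = torque / p.joint_visc
    theta = state.theta + dt * theta_dot
    # hard joint limits: clamp and zero the velocity past the stop
    over = np.abs(theta) > p.joint_limit
    theta = np.clip(theta, -p.joint_limit, p.joint_limit)
    theta_dot = np.where(over, 0.0, theta_dot)

    if not (np.all(np.isfinite(theta)) and np.all(np.isfinite(theta_dot))):
        raise FloatingPointError(f"body state diverged at t={state.t + dt:.2f}s")

    # locomotion: shape velocity with the head frame frozen
    centers, phi = link_frames(state, model)
    tmp = BodyState(theta, theta_dot, state.head_xy, state.heading, state.t)
    centers_new, _ = link_frames(tmp, model)
    shape_vel = (centers_new - centers) / dt
    v_head, omega = _rigid_velocity(model, centers, phi, shape_vel)

    return BodyState(theta, theta_dot,
                     state.head_xy + dt * v_head,
                     state.heading + dt * omega,
                     state.t + dt)
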