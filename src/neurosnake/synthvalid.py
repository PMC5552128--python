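"""Synthetic fixtures with known ground truth for every analysis stage.

Three families:

* :func:`gaussian_var_pair` — a bivariate Gaussian autoregressive pair with
  analytically known transfer entropy (closed-form from the stationary
  covariance), the oracle for the KSG estimators;
* :func:`planted_blockmodel` — stochastic-blockmodel adjacency with a
  planted partition, the oracle for the IRM;
* :func:`switching_traj` — multivariate joint-angle-like series that switch
  between distinct phase-offset sinusoid configurations at known times, the
  oracle for the behavior pipeline;
* :func:`driven_panel` — a small panel where one series drives a known set
  of others with lag 1, for directionality checks.

Ground truth is fully determined by the parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any

import numpy as np


@dataclass
class Fixture:
    kind: str
    data: dict[str, Any]
    ground_truth: dict[str, Any]
    seed: int | None = None


# ---------------------------------------------------------------------------
# Gaussian VAR pair with closed-form transfer entropy
# ---------------------------------------------------------------------------


def analytic_var_te(a_x: float, c_y: float, noise_sd: float = 1.0,
                    y_sd: float = 1.0) -> float:
    """Closed-form TE(Y -> X) in nats for X_{t+1} = a_x X_t + c_y Y_t + eps.

    With Y i.i.d. N(0, y_sd^2) and eps ~ N(0, noise_sd^2):
    var(X_{t+1} | X_t)       = c_y^2 y_sd^2 + noise_sd^2
    var(X_{t+1} | X_t, Y_t)  = noise_sd^2
    TE = 1/2 ln(ratio).
    """
    if abs(a_x) >= 1:
        raise ValueError("non-stationary: need |a_x| < 1")
    return 0.5 * np.log(1.0 + (c_y * y_sd) ** 2 / noise_sd ** 2)


def analytic_gaussian_mi(rho: float) -> float:
    """MI of a bivariate Gaussian with correlation rho, nats."""
    return -0.5 * np.log(1.0 - rho ** 2)


def gaussian_var_pair(a_x: float, c_y: float, n: int,
                      rng: np.random.Generator, noise_sd: float = 1.0) -> Fixture:
    """Simulate the driven AR pair; ground truth holds both analytic TEs."""
    if abs(a_x) >= 1:
        raise ValueError("non-stationary: need |a_x| < 1")
    y = rng.normal(0.0, 1.0, n)
    x = np.empty(n)
    # start from the stationary distribution of x
    var_x = (c_y ** 2 + noise_sd ** 2) / (1.0 - a_x ** 2)
    x[0] = rng.normal(0.0, np.sqrt(var_x))
    eps = rng.normal(0.0, noise_sd, n)
    for t in range(n - 1):
        x[t + 1] = a_x * x[t] + c_y * y[t] + eps[t + 1]
    return Fixture(
        "gaussian_var_pair",
        {"x": x, "y": y},
        {"te_y_to_x": analytic_var_te(a_x, c_y, noise_sd),
         "te_x_to_y": 0.0},  # no feedback
    )


# ---------------------------------------------------------------------------
# Planted stochastic blockmodel
# ---------------------------------------------------------------------------


def planted_blockmodel(n: int, blocks: int, p_in: float, p_out: float,
                       rng: np.random.Generator) -> Fixture:
    """Directed binary adjacency with a planted equal-size partition."""
    if not p_in > p_out:
        raise ValueError("need p_in > p_out")
    partition = np.sort(np.arange(n) % blocks)
    same = partition[:, None] == partition[None, :]
    P = np.where(same, p_in, p_out)
    A = (rng.random((n, n)) < P).astype(np.int64)
    np.fill_diagonal(A, 0)
    return Fixture("blockmodel", {"adjacency": A}, {"partition": partition})


# ---------------------------------------------------------------------------
# Switching sinusoid trajectories
# ---------------------------------------------------------------------------


def switching_traj(n_patterns: int, dwell_times: list[float], n_joints: int,
                   rng: np.random.Generator, *, sample_dt: float = 0.1,
                   freq: float = 0.8, noise_sd: float = 0.02,
                   phase_drift_sd: float = 0.12, phase_drift_tau: float = 30.0,
                   min_separation: float = 3.0) -> Fixture:
    """Joint-angle series switching between planted sinusoid patterns.

    Each pattern is a distinct configuration of per-joint phase offsets and
    amplitudes (drawn once per pattern), so windowed joint-pair correlations
    concentrate around a pattern-specific value and differ across patterns.
    The pattern sequence cycles 0, 1, ..., n_patterns-1, 0, ... through
    ``dwell_times``.

    Within a pattern the joint phases wander slowly around the planted
    configuration (independent Ornstein–Uhlenbeck drift per joint, sd
    ``phase_drift_sd`` rad, correlation time ``phase_drift_tau`` s) plus
    small white measurement noise — emulating a gait that is held but never
    executed identically, which is the signal class the windowed-correlation
    pipeline is built for.  Phase configurations are redrawn until every
    pattern pair is at least ``min_separation`` apart in the space of
    theoretical joint-pair correlations (cos of the phase differences), so
    "distinct patterns" is guaranteed, not merely likely.
    """
    iu = np.triu_indices(n_joints, 1)
    for _ in range(100):
        phases = rng.uniform(0.0, 2 * np.pi, (n_patterns, n_joints))
        corr = np.cos(phases[:, iu[0]] - phases[:, iu[1]])  # theoretical r per pair
        d = np.linalg.norm(corr[:, None, :] - corr[None, :, :], axis=2)
        if n_patterns == 1 or d[np.triu_indices(n_patterns, 1)].min() >= min_separation:
            break
    else:
        raise ValueError("could not draw sufficiently distinct patterns")
    amps = rng.uniform(0.5, 1.0, (n_patterns, n_joints))
    seq = [i % n_patterns for i in range(len(dwell_times))]
    times, theta, labels, switches = [], [], [], []
    t = 0.0
    # OU phase drift is continuous across the whole fixture
    decay = np.exp(-sample_dt / phase_drift_tau)
    kick = phase_drift_sd * np.sqrt(1.0 - decay ** 2)
    eta = rng.normal(0.0, phase_drift_sd, n_joints)
    for pat, dwell in zip(seq, dwell_times):
        n_samp = round(dwell / sample_dt)
        tt = t + np.arange(n_samp) * sample_dt
        th = np.empty((n_samp, n_joints))
        for s in range(n_samp):
            eta = eta * decay + kick * rng.normal(0.0, 1.0, n_joints)
            th[s] = amps[pat] * np.sin(2 * np.pi * freq * tt[s] + phases[pat] + eta)
        th += rng.normal(0.0, noise_sd, th.shape)
        times.append(tt)
        theta.append(th)
        labels.append(np.full(n_samp, pat))
        t += n_samp * sample_dt
        switches.append(t)
    return Fixture(
        "switching_traj",
        {"times": np.concatenate(times), "theta": np.vstack(theta)},
        {"labels": np.concatenate(labels), "switch_times": switches[:-1],
         "n_patterns": n_patterns, "dwell_times": list(dwell_times)},
    )


# ---------------------------------------------------------------------------
# Driven panel for directionality checks
# ---------------------------------------------------------------------------


def driven_panel(n_series: int, driver: int, driven: list[int], n: int,
                 rng: np.random.Generator, coupling: float = 0.8,
                 a: float = 0.5) -> Fixture:
    """AR(1) panel where ``driver`` feeds ``driven`` series with lag 1."""
    X = np.zeros((n, n_series))
    eps = rng.normal(0.0, 1.0, (n, n_series))
    X[0] = eps[0]
    for t in range(n - 1):
        X[t + 1] = a * X[t] + eps[t + 1]
        for d in driven:
            X[t + 1, d] += coupling * X[t, driver]
    return Fixture("driven_panel", {"x": X},
                   {"driver": driver, "driven": list(driven)})
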