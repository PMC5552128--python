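"""Closed-loop simulation orchestration, parameter grids and aggregation.

The closed loop advances oscillators and body at the same fixed step:
muscle-length sensory readout -> coupling blend (sensor ratio alpha) ->
RK4 oscillator step -> motor command (rest-length modulation) -> overdamped
body step.  Runs are deterministic given (config, seed).

A batch run sweeps the sensor ratio / tonic input / topology grid, pushes
every run through the behavior pipeline (pooled Otsu duration threshold),
optionally estimates per-pattern information networks, and reports
per-condition summaries plus duration-vs-structure correlations.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import behavior, body, infoflow, oscillators, wirednet

logger = logging.getLogger(__name__)

ALPHA_GRID = (0.0, 0.1, 0.3, 0.5, 0.7, 0.9, 1.0)
Z_GRID = (0.4, 0.45, 0.5, 0.55)


@dataclass
class ExperimentConfig:
    """Full configuration of one condition (and grid defaults)."""

    topology: str = "ws"          # regular | ws | ba | random
    n_nodes: int = 200
    n_interface: int = 26
    m: int = 2                    # lattice half-neighbourhood (regular/ws)
    m0: int = 2                   # BA seed nodes
    m_ba: int = 1                 # BA attachments per node (< m0)
    p: float = 0.05               # WS rewiring probability
    weight_scheme: str = "random"
    role_strategy: str = "random"

    bvp: oscillators.BVPParams = field(default_factory=oscillators.BVPParams)
    n_links: int = 15
    body_params: body.BodyParams = field(default_factory=body.BodyParams)

    duration: float = 2000.0      # [s]
    burn_in: float = 50.0         # [s] excluded from analysis
    sample_every: float = 0.1     # [s] analysis sampling rate

    window_size: float = 10.0     # behavior Delta t [s]
    shift: float = 0.5            # behavior t_s [s]
    k_nn: int = behavior.KNN_DEFAULT
    eps_db: float = behavior.DBSCAN_EPS
    min_pts: int = behavior.DBSCAN_MIN_PTS

    te_min_samples: int = 500
    te_max_samples: int = 1000
    te_stride: int = 1
    irm_gamma: float = 1.0
    irm_beta: float = 7.0

    n_repeats: int = 5
    base_seed: int = 0

    def manifest(self) -> dict:
        d = dataclasses.asdict(self)
        d["bvp"] = dataclasses.asdict(self.bvp)
        d["body_params"] = dataclasses.asdict(self.body_params)
        return d


@dataclass
class CoupledTrajectory:
    """Sampled closed-loop run: neuron states + joint angles + muscle lengths."""

    time: np.ndarray
    x: np.ndarray          # (n_samples, n_nodes)
    y: np.ndarray
    theta: np.ndarray      # (n_samples, n_joints)
    muscle_len: np.ndarray  # (n_samples, n_muscles)
    head_pose: np.ndarray  # (n_samples, 3): x, y, heading
    roles: np.ndarray
    burn_in: float
    seed: int | None = None

    def analysis_slice(self) -> np.ndarray:
        """Boolean mask excluding the burn-in."""
        return self.time >= self.burn_in

    def save(self, path: str) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            for name in ("time", "x", "y", "theta", "muscle_len", "head_pose"):
                f.create_dataset(name, data=getattr(self, name))
            f.create_dataset("roles", data=np.array(
                [str(r) for r in self.roles], dtype="S16"))
            f.attrs["burn_in"] = self.burn_in
            f.attrs["seed"] = -1 if self.seed is None else self.seed

    @classmethod
    def load(cls, path: str) -> "CoupledTrajectory":
        import h5py

        with h5py.File(path, "r") as f:
            roles = np.array([r.decode() for r in f["roles"][()]], dtype=object)
            seed = int(f.attrs["seed"])
            return cls(*[f[name][()] for name in
                         ("time", "x", "y", "theta", "muscle_len", "head_pose")],
                       roles=roles, burn_in=float(f.attrs["burn_in"]),
                       seed=None if seed == -1 else seed)

    def export_csv(self, path: str) -> None:
        cols = {"time": self.time}
        cols.update({f"x{i}": self.x[:, i] for i in range(self.x.shape[1])})
        cols.update({f"theta{i}": self.theta[:, i]
                     for i in range(self.theta.shape[1])})
        pd.DataFrame(cols).to_csv(path, index=False)


def derive_rng(base_seed: int, *key: int) -> np.random.Generator:
    """Independent, reproducible stream per (condition, repeat) key."""
    return np.random.default_rng(np.random.SeedSequence(base_seed, spawn_key=key))


def build_network(config: ExperimentConfig,
                  rng: np.random.Generator) -> wirednet.WiredNetwork:
    """Topology + weight scheme dispatch."""
    kw = dict(n_interface=config.n_interface, role_strategy=config.role_strategy)
    if config.topology == "regular":
        net = wirednet.build_regular(config.n_nodes, config.m, rng=rng, **kw)
    elif config.topology == "ws":
        net = wirednet.build_ws(config.n_nodes, config.m, config.p, rng, **kw)
    elif config.topology == "random":
        net = wirednet.build_ws(config.n_nodes, config.m, 1.0, rng, **kw)
    elif config.topology == "ba":
        net = wirednet.build_ba(config.n_nodes, config.m0, config.m_ba, rng, **kw)
    else:
        raise ValueError(f"unknown topology {config.topology!r}")
    return wirednet.assign_weights(net, config.weight_scheme, rng)


def run_coupled_simulation(config: ExperimentConfig, seed: int,
                           net: wirednet.WiredNetwork | None = None,
                           fast: bool = True) -> CoupledTrajectory:
    """One closed-loop run; deterministic given (config, seed, net).

    ``fast=True`` uses the compiled fused loop (:mod:`neurosnake._fastloop`);
    ``fast=False`` steps through the modular functions.  The two paths
    follow the same arithmetic and agree to floating-point noise.
    """
    rng = derive_rng(seed)
    if net is None:
        net = build_network(config, rng)
    if net.interface_index.size != 2 * (config.n_links - 2):
        raise ValueError(
            f"{net.interface_index.size} interface nodes cannot drive "
            f"{2 * (config.n_links - 2)} muscles")
    model = body.build_snake(config.n_links, config.body_params)
    p = config.bvp
    osc = oscillators.initial_state(net.n_nodes, rng)
    bstate = body.initial_body_state(model)
    iface = net.interface_index

    stride = max(1, round(config.sample_every / p.dt))
    n_steps = round(config.duration / p.dt)
    t0 = time.perf_counter()

    if fast:
        if p.scheme != "rk4":
            raise ValueError("fast path implements the RK4 scheme only")
        from . import _fastloop

        bp = model.params
        n_rec = n_steps // stride + 1
        out_t = np.empty(n_rec)
        out_x = np.empty((n_rec, net.n_nodes))
        out_y = np.empty((n_rec, net.n_nodes))
        out_theta = np.empty((n_rec, model.n_joints))
        out_L = np.empty((n_rec, model.n_muscles))
        out_head = np.empty((n_rec, 3))
        status, rec_n = _fastloop.run_loop(
            np.ascontiguousarray(net.coupling_matrix), iface.astype(np.int64),
            model.neuron_to_muscle.astype(np.int64),
            model.muscle_sides.astype(np.float64),
            model.muscle_joints.astype(np.int64),
            p.a, p.b, p.c, p.z, p.delta, p.eps_c, p.alpha, p.tau, p.dt,
            bp.rest_length, bp.kappa, bp.stiffness, bp.damping, bp.joint_visc,
            bp.motor_gain, bp.sensory_gain, bp.sensory_clip, bp.joint_limit,
            0.5 * (bp.link_length + bp.gap), bp.friction_long, bp.friction_lat,
            model.n_links,
            osc.x.copy(), osc.y.copy(), bstate.theta.copy(),
            bstate.theta_dot.copy(), np.array([*bstate.head_xy, bstate.heading]),
            n_steps, stride,
            out_t, out_x, out_y, out_theta, out_L, out_head)
        traj = CoupledTrajectory(
            out_t[:rec_n], out_x[:rec_n], out_y[:rec_n], out_theta[:rec_n],
            out_L[:rec_n], out_head[:rec_n], net.roles, config.burn_in, seed)
        if status == 1:
            raise oscillators.DivergenceError(
                f"|x| exceeded {oscillators.DIVERGENCE_LIMIT:g} "
                f"(partial trajectory: {rec_n} samples)")
        if status == 2:
            raise FloatingPointError("body state diverged")
        logger.info("run seed=%s alpha=%.2f z=%.2f: %.1f s wall",
                    seed, p.alpha, p.z, time.perf_counter() - t0)
        return traj

    rec = {k: [] for k in ("time", "x", "y", "theta", "L", "head")}
    for step in range(n_steps + 1):
        if step % stride == 0:
            rec["time"].append(osc.t)
            rec["x"].append(osc.x.copy())
            rec["y"].append(osc.y.copy())
            rec["theta"].append(bstate.theta.copy())
            rec["L"].append(body.muscle_length(bstate, model))
            rec["head"].append(np.array([*bstate.head_xy, bstate.heading]))
        if step == n_steps:
            break
        sensory = body.sensory_readout(bstate, model)
        osc = oscillators.integrate_step(osc, net, sensory, p)
        rest = body.motor_map(osc.x[iface], model)
        bstate = body.body_step(model, bstate, rest, p.dt)
    logger.info("run seed=%s alpha=%.2f z=%.2f: %.1f s wall",
                seed, p.alpha, p.z, time.perf_counter() - t0)
    return CoupledTrajectory(
        np.array(rec["time"]), np.array(rec["x"]), np.array(rec["y"]),
        np.array(rec["theta"]), np.array(rec["L"]), np.array(rec["head"]),
        net.roles, config.burn_in, seed)


# ---------------------------------------------------------------------------
# Batch analysis
# ---------------------------------------------------------------------------


@dataclass
class RunAnalysis:
    labeling: behavior.WindowLabeling
    traj: CoupledTrajectory
    condition: dict


def analyze_run(traj: CoupledTrajectory, config: ExperimentConfig,
                threshold: float | None = None) -> behavior.WindowLabeling:
    """Behavior pipeline on one trajectory (burn-in excluded)."""
    keep = traj.analysis_slice()
    return behavior.analyze_joint_angles(
        traj.theta[keep], traj.time[keep],
        window_size=config.window_size, shift=config.shift,
        k_nn=config.k_nn, eps=config.eps_db, min_pts=config.min_pts,
        threshold=threshold)


def pattern_sample_mask(traj: CoupledTrajectory,
                        labeling: behavior.WindowLabeling,
                        label: int) -> np.ndarray:
    """Analysis-rate sample mask for the union of one pattern's episodes."""
    mask = np.zeros(traj.time.size, dtype=bool)
    for e in labeling.episodes:
        if e.label == label:
            mask |= (traj.time >= e.start) & (traj.time < e.end)
    return mask


def pattern_info_records(traj: CoupledTrajectory, config: ExperimentConfig,
                         labeling: behavior.WindowLabeling,
                         rng: np.random.Generator,
                         with_irm: bool = False) -> list[dict]:
    """Per-pattern information-network records (duration + measures + TE).

    ``with_irm`` additionally estimates the MI matrix, binarizes it and fits
    the IRM block partition (slower; the duration-vs-structure correlations
    only need the TE-based measures).
    """
    records = []
    for label in labeling.pattern_labels:
        mask = pattern_sample_mask(traj, labeling, int(label))
        net = infoflow.estimate_info_network(
            traj.x, mask, traj.roles, int(label),
            sample_dt=config.sample_every, stride=config.te_stride,
            min_samples=config.te_min_samples,
            max_samples=config.te_max_samples, with_mi=with_irm)
        if net is None:
            continue
        if with_irm:
            try:
                infoflow.analyze_info_network(net, config.irm_gamma,
                                              config.irm_beta, rng=rng)
            except infoflow.DegenerateInputError:
                logger.info("pattern %d: constant MI matrix, skipped", label)
                continue
        else:
            net.measures = infoflow.info_network_measures(net)
        infl = infoflow.body_influence(net)
        rec = {
            "pattern": int(label),
            "duration": net.segment_duration,
            "avg_clustering": net.measures.avg_clustering,
            "avg_shortest_path": net.measures.avg_shortest_path,
            "te_hidden_to_interface": infl.te_hidden_to_interface,
            "te_interface_to_hidden": infl.te_interface_to_hidden,
        }
        if with_irm:
            rec["n_blocks"] = int(np.unique(net.irm_partition).size)
        records.append(rec)
    return records


def run_grid(base: ExperimentConfig, alphas=ALPHA_GRID, zs=(0.45,), *,
             with_info_networks: bool = False
             ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sweep alpha x z with n_repeats seeded runs per condition.

    Returns (per-condition summary, per-pattern-instance records).  The Otsu
    stability threshold is pooled over the whole batch.  Failed (diverged)
    runs are logged and excluded with a count.
    """
    runs: list[tuple[dict, CoupledTrajectory, behavior.WindowLabeling]] = []
    n_failed = 0
    conditions = [(ai, zi, a, z) for ai, a in enumerate(alphas)
                  for zi, z in enumerate(zs)]
    logger.info("grid: %d conditions x %d repeats", len(conditions),
                base.n_repeats)
    for ai, zi, a, z in conditions:
        cfg = replace(base, bvp=replace(base.bvp, alpha=a, z=z))
        for rep in range(base.n_repeats):
            seed = int(derive_rng(base.base_seed, ai, zi, rep)
                       .integers(2 ** 31))
            try:
                traj = run_coupled_simulation(cfg, seed)
                lab = analyze_run(traj, cfg)
            except (oscillators.DivergenceError, FloatingPointError) as exc:
                n_failed += 1
                logger.warning("run failed (alpha=%s z=%s rep=%d): %s",
                               a, z, rep, exc)
                continue
            runs.append(({"alpha": a, "z": z, "repeat": rep, "seed": seed,
                          "config": cfg}, traj, lab))
    if n_failed:
        logger.warning("%d run(s) failed and were excluded", n_failed)

    # pooled Otsu duration threshold across the batch
    all_durations = np.array([e.duration for _, _, lab in runs
                              for e in lab.episodes])
    try:
        pooled_thr = behavior.otsu_threshold(all_durations)
    except ValueError:
        pooled_thr = float("inf")
    summaries, pattern_rows = [], []
    for cond, traj, lab in runs:
        lab.stability_threshold = pooled_thr
        lab.stable_patterns = behavior.classify_patterns(lab.episodes, pooled_thr)
        s = lab.summary()
        summaries.append({**{k: cond[k] for k in ("alpha", "z", "repeat", "seed")},
                          **s, "threshold": pooled_thr})
        if with_info_networks:
            rng = derive_rng(cond["seed"], 999)
            for rec in pattern_info_records(traj, cond["config"], lab, rng):
                pattern_rows.append({**{k: cond[k] for k in
                                        ("alpha", "z", "repeat", "seed")}, **rec})

    per_run = pd.DataFrame(summaries)
    agg = (per_run.groupby(["alpha", "z"])
           .agg(n_patterns_mean=("n_patterns", "mean"),
                n_patterns_sd=("n_patterns", "std"),
                n_stable_mean=("n_stable", "mean"),
                n_stable_sd=("n_stable", "std"),
                max_duration_mean=("max_duration", "mean"),
                max_duration_sd=("max_duration", "std"),
                n_runs=("n_patterns", "size"))
           .reset_index())
    agg.attrs["per_run"] = per_run
    agg.attrs["n_failed"] = n_failed
    agg.attrs["threshold"] = pooled_thr
    return agg, pd.DataFrame(pattern_rows)


def correlate_structure_duration(records: pd.DataFrame) -> pd.DataFrame:
    """Pearson r of pattern duration vs each information-network measure."""
    if len(records) < 3:
        raise ValueError("need at least 3 pattern instances")
    out = []
    for col in ("avg_clustering", "avg_shortest_path",
                "te_hidden_to_interface", "te_interface_to_hidden"):
        sub = records[["duration", col]].dropna()
        if sub[col].std() == 0 or sub["duration"].std() == 0 or len(sub) < 3:
            r = float("nan")
        else:
            r = float(np.corrcoef(sub["duration"], sub[col])[0, 1])
        out.append({"measure": col, "pearson_r": r, "n": len(sub)})
    return pd.DataFrame(out)


def save_manifest(config: ExperimentConfig, path: str, **extra) -> None:
    with open(path, "w") as fh:
        json.dump({"config": config.manifest(), **extra}, fh, indent=2)
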