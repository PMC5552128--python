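# Methods

## The model

`neurosnake` couples two dynamical systems:

**Oscillator network.** Each of N = 200 nodes is a Bonhoeffer–van der Pol
(FitzHugh–Nagumo) oscillator

    tau dx/dt = c (x - x^3/3 - y + z) + delta (S_f - x)
    tau dy/dt = (1/c)(x - b y + a) + eps_c S_f

with a = 0.7, b = -0.2, c = 2.0, tonic input z in {0.4, 0.45, 0.5, 0.55},
excitatory gain delta = 0.01 and inhibitory gain eps_c = 0.015.  The
coupling input S_f is the in-degree-normalised weighted sum of presynaptic
activations; for the 26 *interface* nodes it is blended with bodily sensory
feedback I through the sensor ratio alpha:

    S_f = alpha I + (1 - alpha) (1/K) sum_j w_ji x_j .

Connectivity ("wired network") comes from one of four generators — ring
lattice (m = 2), Watts–Strogatz rewiring (p = 0.01/0.05), the p = 1 random
graph, or Barabási–Albert preferential attachment with +1 degree smoothing
(m0 = 2, m = 1) — symmetrised into a directed weight matrix.  Weights are
either uniform (1) or i.i.d. uniform on [-1, 1] with incoming absolute
weights normalised to 1 per node.  The 26 interface nodes are placed
uniformly at random (placement strategy is configurable).

**Body.** A planar chain of 15 rigid links (0.1 m cube links, 0.02 m gaps,
0.6 kg) joined by 14 hinge joints and actuated by 26 antagonistic two-joint
muscles, one left/right pair per adjacent-joint pair.  The physics is
deliberately reduced to an overdamped articulated chain:

* muscle length is the linearised geometric function
  `L = L0 (1 - s * kappa * (theta_q + theta_{q+1})/2)` with side sign s and
  geometry factor kappa = 0.3 rad^-1, L0 = 0.24 m (two link pitches);
* each muscle is a linear spring–damper (k_s = 100 N/m, k_d = 1 N s/m)
  whose rest length the interface neuron modulates,
  `L_rest = L0 (1 + g tanh x)`, motor gain g = 0.2;
* joint angular velocity is net muscle torque over a viscous coefficient
  (0.2 N m s/rad), with hard stops at ±pi/3 — inertia is neglected, so a
  bent body relaxes monotonically and the loop has mechanical low-pass
  character;
* locomotion is the classical resistive-force treatment of undulatory
  crawling: at each step the rigid-body velocity (v, omega) minimises the
  anisotropic friction dissipation (lateral/longitudinal ratio 10:1) given
  the internal shape change, so traveling body waves produce net
  translation.

The torque balance gives a steady bend of `g (u_R - u_L) / (2 kappa)` per
fully-commanded antagonist pair, ~0.67 rad at saturation — inside the joint
limits, so posture states are set by commands, not stops.

Sensory feedback is relative length deviation, `I = sigma (L - L0)/L0`
(sigma = 2, clipped to ±2), one value per interface neuron.

These body constants are not taken from any reference; they were chosen
once so that the loop has the features the analysis requires: joint
response fast relative to the ~10 s oscillation period, muscle commands
that can drive visible but non-saturating bends, and locomotion gain
sufficient for serpentine displacement.  Fidelity to 3-D contact dynamics
is an explicit non-goal.

**Integration.** Fixed-step RK4 at dt = 0.01 s (tau = 1 s), sensory input
held constant within a step, body stepped at the same dt.  States are
sampled every 0.1 s for analysis.  Runs last 2000 s with the first 50 s
discarded.  A numba-compiled fused loop reproduces the modular step
arithmetic (the suite asserts agreement to 1e-9) and makes a 2000 s,
200-node run a ~10 s computation.

## Behavior analysis

Windowed Pearson correlations of all 91 joint-angle pairs (window 10 s,
shift 0.5 s) feed a Laplacian-eigenmaps embedding (binary symmetrised
kNN graph, 350 neighbours, 3 output dimensions, deterministic sign
convention), DBSCAN (eps = 0.16, min_pts = 10), episode extraction, and an
Otsu threshold on episode durations that splits patterns into stable and
unstable.  DBSCAN's noise label is reported as the unstable movement
fraction.  Within a batch the Otsu threshold is pooled across runs.

Two free conventions deserve explanation, because the embedding scale is
mathematically arbitrary (eigenvectors are normalised) while the DBSCAN
radius is fixed:

* **Degenerate-mode gating.**  When the data form fewer than four
  well-separated clusters, the three requested eigenvectors include modes
  that vary *within* one cluster; their eigenvalues sit two orders of
  magnitude above the cluster-separating ones (observed ratios ≈ 90–130
  versus ≤ 11 for meaningful dimensions).  Columns with
  lambda_c/lambda_2 > 30 are down-weighted by lambda_2/lambda_c, which
  leaves continuous trajectories untouched and stops isolated clusters
  from being shredded along an internal coordinate.
* **Step-referenced scale.**  The embedding is rescaled so the median step
  between temporally adjacent windows is 0.08, capped at 6× the unit-RMS
  scale.  The DBSCAN radius then distinguishes slow, recurrently visited
  stretches (movement patterns) from fast transits (switches).  The cap
  matters for strongly clustered data, where the median step reflects only
  within-cluster jitter: a scale sweep shows clustered fixtures segment
  correctly anywhere between 1× and ~8× unit-RMS while simulated
  trajectories need ~5–6×, so the capped adaptive rule serves both.

## Information networks

For each movement pattern (union of its episodes, ≥ 500 analysis samples;
long segments thinned to ≤ 1000), pairwise transfer entropy with history
lengths l = k = 1 is estimated between all ordered neuron pairs by the
Kraskov–Stögbauer–Grassberger conditional estimator:
TE(Y→X) = I(X_{t+1}; Y_t | X_t), k = 4 neighbours, max-norm, series
z-scored with a deterministic 1e-10 jitter to break ties.  Estimates are
in nats; small negative estimates are kept in the matrix but clamped at 0
for network measures.  Mutual information (same estimator family) is
binarized by Otsu and partitioned by an infinite relational model:
collapsed Gibbs sampling with CRP concentration gamma = 1 and Beta(1, 7)
block-link priors (the single noise hyper-parameter mapped to the failure
pseudo-count, biasing block links toward sparsity), singleton
initialisation, 30–50 sweeps with a final greedy sweep, highest-posterior
partition returned.

Network measures reuse the wired-network code: the Fagiolo weighted
directed clustering coefficient on |W|/max|W| (nodes with undefined
denominator contribute 0), and inverse-|w| shortest paths averaged over
reachable ordered pairs (unreachable pairs excluded and counted).  Body
influence is summarised as mean TE over hidden→interface and
interface→hidden ordered pairs.

## Synthetic validation

Fixtures with analytically known ground truth exercise each stage:

* `gaussian_var_pair` — X_{t+1} = a_x X_t + c_y Y_t + eps with closed-form
  TE(Y→X) = ½ ln(1 + c_y² var(Y)/var(eps)); the suite also re-derives the
  value by regression residual variances on long series.
* `planted_blockmodel` — directed stochastic blockmodel for the IRM.
* `switching_traj` — joint-angle sinusoids switching between planted
  phase/amplitude configurations.  Within a pattern the phases wander as
  an Ornstein–Uhlenbeck process (sd 0.12 rad, tau 30 s) plus white noise,
  emulating a gait that is held but never repeated exactly; the carrier
  frequency (0.8 Hz) is detuned from the analysis window grid because a
  period that divides the window shift makes finite-window correlation
  estimates cycle through a few discrete values — an artifact, not a
  behavior.  Planted configurations are redrawn until pairwise separation
  in correlation space is ≥ 3, making "distinct patterns" a guarantee.
* `driven_panel` — lag-1 driven AR panel for directionality checks.

What passing these fixtures does *not* show: the generator produces
idealised switches (instantaneous, between stationary gaits); real
coupled-system transitions are gradual, and transient fragments around
them may appear as extra short-lived clusters.  Accordingly the recovery
claim is exact for the *stable* pattern count, and within one for the raw
cluster count.

## Scaled study conditions

The full grid of the reference study (4 network types × 2 weight schemes ×
7 sensor ratios × 4 tonic inputs × 100 repeats of 2000 s) is desk-hostile;
the package's own batches default to the WS(p = 0.05)/random-weight
network and scale down as follows, recorded per batch in the manifest:

* sensor-ratio trends (pattern counts, durations): full 200-node, 2000 s
  runs, 5 repeats per alpha at z = 0.4; the duration trend is summarised
  by the per-condition *maximum* episode duration, whose upward trend is
  far more stable across small batches than per-run means;
* information-network batches: 60-node networks (26 interface, 34 hidden)
  and 1200 s runs, because pairwise KSG over 200 neurons is quadratic in N
  and dominates; TE segments are thinned to ≤ 600 samples there;
* the reference single condition (z = 0.4, alpha = 0.3) runs at full size.

## Known limitations

* The overdamped body executes incoherent motor commands as faithfully as
  coherent ones; a physical body with inertia and ground contact resists
  uncoordinated actuation.  Low-alpha runs therefore still show patterned
  (if short-lived) coordination rather than collapsing into noise, which
  weakens the contrast at the alpha = 0 end of grid trends: across
  5-repeat batches the pattern count at alpha = 0 is statistically tied
  with the interior peak (the interior maximum shows in roughly two of
  three batches), whereas the drop at alpha = 1 is large and consistent.
* With out_dim fixed at 3, runs whose dynamics populate fewer than four
  quasi-attractors rely on the spectral gating above; the gate threshold
  (30) sits in a wide empirical margin but is a heuristic.
* TE magnitudes depend on the sampling rate and thinning; only their
  ordering and correlations with duration are interpreted.
* IRM block counts depend on the Beta(1, 7) interpretation of the single
  printed noise hyper-parameter; the cited model family has two Beta
  pseudo-counts and the mapping is pinned in config.
* The muscle geometry is linearised in the joint angles; lengths are
  floored at 0.1 L0, and commands only modulate rest length (no
  force-velocity curve).
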