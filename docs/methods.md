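# Methods

## The scientific question

Cluster-based indicators of criticality — above all an interior maximum of
the time-averaged second-largest cluster size S2 as a function of the
control parameter — are widely used to decide whether a dynamical system on
a network sits at a phase transition. `criticonn` implements the models and
measures needed to show that this indicator can fail for a purely
structural reason: when the network loses integrity and splits into weakly
coupled or fully disconnected subsystems, the whole-system S2 stops peaking
even though every subsystem remains critical. The mechanism is a
*cluster-ordering* effect, not a loss of criticality.

## Models

### Excitable (Greenberg–Hastings) dynamics

Each node is inactive (I), active (A) or refractory (R). Synchronously at
every discrete step:

* A → R always;
* R → I with probability `r2`;
* I → A if the summed weight of active in-neighbours strictly exceeds the
  threshold `T` (`sum_{j active} w_ij > T`), else spontaneously with
  probability `r1`.

`T` is the control parameter: small `T` gives a supercritical high-activity
phase, large `T` a quiescent phase. The canonical rates are `r1 = 2/N` and
`r2 = r1^0.2` (N = 998 gives r2 ≈ 0.29); the Watts–Strogatz comparison runs
use `r1 = 0.001`, `r2 = 0.3` explicitly. Runs start with `ceil(0.01 N)`
active nodes, last `t_max = 10000` steps by default, discard the first
`t_init = 200`, and the three-state raster is conflated (R → 0) before any
statistic is computed. All three transitions read the start-of-step state;
a node activated within a step cannot excite its neighbours until the next
step.

A mean-field estimate of the critical threshold is
`T_c = <w_in> · r2 / (1 + 2 r2)`. On in-strength-normalized networks
(`w~_ij = w_ij / w_in_i`, the homeostatic-plasticity convention that
equalizes excitability; the normalized matrix is directed even for
symmetric input) `<w_in> = 1` and `T_c` depends on `r2` only.

### Ising Metropolis dynamics

Spins ±1 on the binary support of the network with energy
`E = -J Σ_{bonds} s_i s_j`, each unordered bond counted once — the
convention under which the infinite square lattice orders at
`T_c = 2/ln(1+√2) ≈ 2.269`. A sweep proposes N single-site flips (sites
picked uniformly at random by default; raster order available behind
`proposal_order="sequential"` for sensitivity checks), each accepted with
probability `min(exp(-ΔE/T), 1)`, with `ΔE` computed locally as
`2 J s_i Σ_neigh s_j`. Default protocol: J = 1, 100×100 nonperiodic
lattice, initial spins −1 with probability 0.75, 30 equally spaced
temperatures in [0.01, 4.5], 5000 sweeps with the first 200 discarded.

### Clusters and ordering

Clusters are maximal sets of nodes sharing the same activity value,
connected through the undirected structural support `w_ij + w_ji > 0`
(directed matrices are symmetrized for connectivity only). The excitable
model counts clusters of *active* nodes only; the Ising model counts
same-spin domains of both signs. S1(t) ≥ S2(t) are the two largest
momentary sizes; a single-cluster or empty configuration has S2 = 0, and
ties in size are broken arbitrarily (all downstream statistics depend on
sizes only). Time averages follow `S_i = (1/t_sim) Σ_t S_i(t)`.

For a network split into two fully disconnected subsystems A and B, at
every step

```
S1(t) = max(S1_A, S1_B),    S2(t) = 2nd largest of {S1_A, S2_A, S1_B, S2_B}
```

exactly. This identity — property-tested exactly on divided lattices and
lesioned connectomes — is the entire mechanism of the lost peak: near T_c
the subsystem runner-up S2_A competes with the other subsystem's champion
S1_B, and below T_c the whole-system S2 merely tracks S1 of the smaller
subsystem, which grows monotonically as the system orders.

### Artificial strokes

Two lesion variants on an RSN-labelled connectome, both zeroing weights
(never deleting nodes, so matrix dimensions and the parcellation stay
valid) and both leaving the target RSN's internal weights bit-identical:

* `node_severity`: `round(severity · |RSN|)` uniformly chosen RSN nodes
  lose all connections to nodes outside the RSN (round-half-up);
* `edge_fraction`: `round(severity · |cut|)` undirected inter-RSN
  connections chosen uniformly are removed; a tract is one connection, so
  both directions are zeroed together.

Reported lesion results are means over independently seeded realizations
(20 by default in the pipeline).

## Indicators and structural measures

* total activity `A(t)`, its mean and *population* standard deviation
  (divisor `t_sim`), and the lag-1 autocorrelation of the raw `A(t)` with
  overall mean and population variance (0 by convention for a constant
  series);
* population variance of S1(t);
* `I2`, the trapezoidal area under S2 over the sampled grid (comparisons
  across conditions must share one grid);
* peak location = grid argmax, ties to the smaller grid value; a boundary
  argmax operationalizes the "lost peak" regime;
* normalizations: curve/max, and the relative change `(A - A0)/A0` against
  the unmodified system;
* conductance `h_G(S) = cut(S)/min(vol(S), vol(S̄))` with
  `cut = Σ_{i∈S, j∉S} (w_ij + w_ji)` and `vol(S) = Σ_{i∈S} w_out_i`;
* weighted directed modularity `Q` and its ceiling `Q_max` for a perfectly
  mixed network with the same strengths; all reported modularity is
  `Q/Q_max`. Community detection delegates to networkx's Louvain
  (resolution 1, 10 seeded restarts, best partition selected by this
  package's own Q), but every Q evaluation uses this package's code.

## Synthetic data

The empirical connectomes behind the original analyses (individual
stroke/control matrices and the Hagmann et al. healthy connectome) are not
redistributable, so the `networks` module generates stand-ins:

* **Watts–Strogatz networks**, N = 2000, degree k (k/2 neighbours per
  side; edge count exactly Nk/2 for any rewiring probability), rewiring
  π = 0.5, i.i.d. exponential weights `p(w) = λ e^{-λw}` with λ = 12.5
  mimicking empirical connectome weights; k = 10 gives the critical
  reference, k = 2 the non-critical one.
* **Modular connectomes**: 998 nodes in 8 RSN-labelled modules (sizes
  150, 140, 130, 125, 120, 110, 104 and an "auditory" module of 119 —
  the module used as the small disconnected subsystem), weighted
  stochastic-block topology with expected within-module degree 24 and
  between-module degree 10 (total ≈ 34, matching the ≈ 36 mean degree of
  the Hagmann connectome), exponential(12.5) weights, every module forced
  internally connected. Degrees are narrowly distributed; real connectomes
  additionally have heavy-tailed strengths and spatial embedding, which
  the generator does not emulate — see Limitations.
* **Square lattices**, nonperiodic, unit weights, optionally divided into
  two 100×50 halves (cut parallel to the long side; orientation is
  irrelevant to the statistics) or into a central `s×s` patch (subsystem
  B) and its complement, with every crossing bond removed.

What passing tests on these stand-ins do show: the cluster-ordering
identity, the loss and recovery of the S2 peak under division/lesioning,
and the coupling between integrity measures and the S2 anomaly — all of
which are structural/combinatorial mechanisms insensitive to the fine
topology. What they do not show: quantitative agreement with numbers tied
to the empirical Hagmann matrix (critical thresholds 0.073/0.15, S1 ≈
0.17N, S2 ≈ 0.006N at peak, correlation ρ = 0.88), which require the real
connectome files.

## Numerical choices

* Strict `>` in the excitable threshold test, as defined.
* Initial active count rounds up (`ceil(0.01 N)`).
* One independent run per grid point in every sweep; per-point sub-seeds
  are spawned deterministically from the master seed (`SeedSequence`), so
  results are reproducible and independent of execution order. All
  randomness flows through explicitly passed seeds; no global RNG state.
* Inner loops (excitable stepping, Metropolis sweeps, per-step
  connected-component labelling via union-find) are numba-compiled; the
  pure-numpy `gh_step`, `metropolis_sweep` and scipy-based `find_clusters`
  define the reference semantics and the kernels are tested against them
  (exactly, on deterministic parameter corners, and against brute-force
  BFS oracles).
* GH threshold grids default to 30 linear points spanning
  `[0.2, 3] · T_c^MF` so any network's sweep covers its predicted critical
  value.
* The test suite runs the divided-lattice analyses at reduced sizes
  (48×48 lattices, 15 temperatures, 1500 sweeps; 240-node connectomes with
  12-point grids) — sizes at which every qualitative effect is already
  unambiguous — and the undivided 100×100 critical-temperature check at
  the full protocol.

## Known limitations

* The mean-field threshold `T_c = <w_in> r2/(1+2r2)` is an upper bound in
  practice: on the synthetic generators the steady-state active fraction
  matches the mean-field value (measured 0.182 vs predicted 0.183 at
  N = 998) but the active phase collapses at ≈ 0.68·T_c^MF, because with
  mean degree ≈ 34 the per-node drive fluctuates with ≈ 40% relative sd
  around its mean. The prediction locates the transition only to within a
  factor ~1.5 on these topologies; empirical connectomes with heavy-tailed
  hub strengths sit closer to the mean-field value.
* On a finite 100×100 lattice the S2 peak of same-spin domains lies
  slightly above T_c and the time-averaged S2 just above T_c has a large
  run-to-run sd under the 5000-sweep protocol (critical slowing), so the
  grid argmax can fluctuate by one grid step between seeds.
* Avalanche statistics, cluster-size distributions, functional-correlation
  reproduction and correlation-matrix-eigenvalue indicators are out of
  scope.
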