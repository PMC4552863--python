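# Methods

## Model and assumptions

`bdnevo` treats a connectome as a brain dynamical network: an undirected
graph whose nodes carry identical Hindmarsh–Rose (HR) neurons and whose
links split into two layers. Electrical synapses (gap junctions) act as
linear diffusive coupling through the graph Laplacian `G = K − A` of the
electrical adjacency and operate, in the model-generated topologies,
strictly inside clusters — mirroring the local, physical character of
gap junctions. Chemical synapses act through the nonlinear excitatory
term `−g_n (pᵢ − V_syn) Σⱼ Bᵢⱼ S(pⱼ)` and operate strictly between
clusters — mirroring the longer range of axonal projections. The
combined graph `C` (the binary union of the two layers) must be
connected before any Lyapunov-exponent estimate is meaningful; this is
checked by `Connectome.is_connected()` and asserted in the tests.

All neurons are identical and noise-free; heterogeneity enters only
through the initial condition, a common attractor-adjacent base point
`(p, q, n) = (−1.30784489, −7.32183132, 3.35299859)` offset per neuron by
one uniform jitter `η ∈ [0, 0.5]`. The same draw offsets all three
coordinates of a neuron (an option allows independent draws); starting
near the attractor keeps the required transient short. Phases start at 0
and are integrated as a fourth state equation; they never feed back into
`(p, q, n)`, and only phase *differences* enter any measure, so the
zero-phase convention is benign. Where `pᵢ² + qᵢ²` vanishes the phase
velocity is undefined; it is set to 0 for that sample and logged — on
the bursting attractor the fast pair never rests at the origin, so the
fallback is a guard for degenerate hand-built states, not a modelling
statement.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `a, b, c, d, s` | 1, 3, 1, 5, 4 | HR polynomial constants (dimensionless) |
| `p0` | −1.6 | resting-potential offset |
| `I_ext` | 3.25 | external drive; with the above, spike bursting |
| `r` | 0.005 | slow-current timescale; chosen so each neuron is chaotic |
| `theta_syn, lambda_sig` | −0.25, 10 | sigmoid threshold and slope of `S(p)` |
| `V_syn` | 2 | reversal potential; on the attractor `|p| < 2`, so `(p − V_syn) < 0` and the chemical layer is excitatory |
| `g_n, g_l` | run-specific | chemical / electrical coupling strengths, the two axes of every parameter space |
| `dt` | 0.01 | Euler step (model time units) |
| `t_t` | 300 | transient excluded from every statistic |
| `t_f` | 2500 (evolution), 5000 (empirical runs) | integration horizon |

Time is in the HR system's dimensionless units; Lyapunov exponents and
`I_c` are inverse-time quantities in those units (nats per unit time for
the information reading).

## Lyapunov exponents and the capacity bound

The two largest exponents come from the classical Benettin method: two
tangent vectors evolve under the analytic Jacobian of the coupled system
alongside the trajectory and are Gram–Schmidt re-orthonormalized every
`renorm_interval = 10` Euler steps; exponents are the time-averaged log
stretch factors accumulated after `t_t`. Choices that the method leaves
open were fixed as follows:

- The tangent space covers only the `3N` coordinates `(p, q, n)`. The
  phases do not influence the rest of the state, so including them would
  merely add a neutral direction that could shadow `λ₂`.
- Initial tangent vectors are the first two identity columns —
  seed-independent, so two runs from the same state are identical.
- The Jacobian is analytic (including the sigmoid derivative and the
  `(pᵢ − V_syn)` product rule); a finite-difference cross-check lives in
  the test suite, and exponent estimates are stable to within 5% under
  `renorm_interval ∈ {5, 10, 20}`.
- A vanishing tangent vector after renormalization is reinitialized to a
  basis vector with a logged warning; non-finite growth aborts the run.

`info_capacity(λ₁, λ₂) = λ₁ − λ₂` is the network's upper bound for the
mutual information rate between any two nodes. It is near zero both when
the network synchronizes (degenerate leading exponents) and when strong
coupling quenches the dynamics; it is large near criticality, where
`λ₁ > 0` and `λ₂ ≈ 0⁺`. A generic Benettin routine
(`benettin_exponents`) accepts arbitrary `f` and Jacobian callables and
serves as the oracle path: on constant-coefficient linear systems it
recovers the leading eigenvalue real parts to well under 1%.

## Network evolution

Growth starts from a ring of `N_c` clusters: each cluster graph is
generated independently (Watts–Strogatz by default; Erdős–Rényi,
Barabási–Albert, or a star with 20% of its spokes rewired as
alternatives), placed on the block diagonal of `A`, and one hub per
cluster — its maximum-degree node, ties broken by smallest index — is
chemically linked to the hubs of both neighbouring clusters. Candidate
links are all absent inter-cluster pairs, visited exactly once in a
uniformly random order; a candidate is retained iff it strictly
increases `I_c` (ties reject, preventing drift through neutral links).
Couplings and the electrical layer are frozen for the whole run and
links are never deleted. One seed-derived initial state is reused for
every candidate evaluation so that `I_c` comparisons are not confounded
by initial-condition noise; a config knob allows shorter per-candidate
horizons than the final reporting run, since only the comparison sign
matters.

After each acceptance the global order parameter and the per-cluster
mean pairwise locking (over *connected* intra-cluster pairs only; a
cluster without internal links reports NaN, not 0) are recorded.
Regressing these series on the acceptance index gives the slopes `θ`
used to label each cluster Hebbian-like (`θ > 0`: added synapses raise
synchrony) or no-Hebbian-like.

## Structure and spectra

Small-worldness uses `σ_sw = γ/μ` with `γ = C/⟨C_r⟩₁₀₀` and
`μ = L/⟨L_r⟩₁₀₀` against 100 degree-sequence-preserving surrogates
(repeated double edge swaps; a surrogate that stays disconnected after
bounded retries contributes the mean shortest path of its largest
component, logged). `C` is the mean of local clustering coefficients.
Communities come from igraph's walktrap with walk length 6, the
dendrogram cut at maximum Newman modularity; singleton communities are
reported but excluded from cluster-level statistics. Coupling ranges
transfer between networks by scaling the chemical maximum with the
average-chemical-degree ratio and the electrical maximum with the ratio
of the smallest positive electrical-Laplacian eigenvalues.

The normalized Laplacian is the row-normalized form (`L_ii = 1`,
`L_ij = −1/kᵢ`); eigenvalues are computed from the similar symmetric
form and lie in [0, 2]. Densities convolve the eigenvalue frequencies
with a Gaussian kernel of width σ = 0.015 on a fixed grid of step 0.001
over [0, 2] and are renormalized so the discrete frequencies sum to one.
The spectral distance is implemented exactly as its defining
double-minimization over raw grid indices, with `k = 2000` intervals;
it is deliberately scale-dependent, so the grid and `k` are frozen for
comparability. No square root is applied to the per-index terms.

## Synthetic data and what the tests show

The topology generators *are* the study conditions: rings of 6×10 (the
reference model), its 120-neuron double, and scaled-down 3×6 rings used
throughout the test suite. They emulate the modular, small-world,
two-layer architecture of real connectomes but none of their weighted,
directed, spatially embedded, or plastic character — and every node
carries the same point neuron. Passing tests therefore validate the
*method* (integration, exponents, growth rule, measures) under the
model's assumptions; they do not certify conclusions about any real
nervous system. Loaders for empirical connectomes (edge list, dense CSV,
GraphML; symmetrized, binarized, isolated nodes removed) default to
using the single loaded adjacency for both layers, since empirical
networks arrive without an electrical/chemical split; pass two files to
override.

Problem sizes in the default test run were chosen to keep the whole
suite in the minutes range: boundedness on the 60-neuron ring at
`t_f = 1000`; the synchronization/capacity anti-correlation on an
18-neuron, 3-cluster ring over a 5×5 coupling grid at `t_f = 500`;
paired evolution runs on the same 18-neuron geometry over 5 seeds; the
single-neuron chaos check at `t_f = 2000`.

## Known limitations

- First-order Euler at `dt = 0.01` is the reference protocol
  (step-halving confirms the expected first-order error decay), so
  trajectories are accurate statistically, not pathwise; higher-order
  integration is available only as a cross-check path.
- Finite-horizon Lyapunov estimates carry fluctuation of order
  10⁻²–10⁻³ at the horizons above. On small (≈18-neuron) networks the
  per-link change in `I_c` is comparable to that fluctuation, so the
  *number* of links retained by evolution becomes a record process that
  no longer discriminates coupling regimes, even though the functional
  contrast (high-sync/low-capacity vs low-sync/high-capacity final
  states, and mMIR ordering) reproduces robustly. Recovering
  regime-dependent link counts requires the full 60-neuron geometry and
  long horizons, outside the default suite's size budget.
- The infinite-time average in the pairwise locking measure is replaced
  by the finite recording window, reported with every result.
- The spectral distance is not a metric and depends on axis scaling;
  it only ranks structural similarity under the frozen grid.
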