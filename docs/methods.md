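# Methods

## The model

`pertnet` models a signaling system as N interacting nodes — proteins and
phospho-proteins, phenotype readouts such as cell viability, and unmeasured
"activity" nodes standing in for drug-target activity.  Every variable is a
log2-ratio response relative to an unperturbed control, so 0 is the resting
state and negative values are knockdowns.  The dynamics are

    dx_i/dt = eps_i * tanh( sum_{j != i} w_ij x_j + u_i ) - alpha_i x_i

* `w_ij` — influence of node j on the rate of change of node i (inverse
  pseudo-time units).  Nonzero entries are the network's directed edges.
  Self-interactions are structurally forbidden (`w_ii = 0`), and activity
  nodes accept no incoming edges: they are perturbed but never measured, so
  there is no data to constrain their regulators.
* `u_i` — a constant external force encoding a targeted perturbation.  Drug
  combinations are element-wise sums of single-drug force vectors.  A drug
  whose downstream effector retains a fraction r of its untreated level is
  encoded as u = log2(r); the isolated-node steady state is then
  (eps/alpha)·tanh(u).
* `alpha_i` (restoration rate) and `eps_i` (saturation scale of the
  sigmoid) default to 1 during inference and are fitted only in the final
  gradient-descent refinement.

The force enters inside the sigmoid.  This placement is fixed by the
activity-node arithmetic above (r = 0.55 gives u = −0.863 and steady state
−0.697 with unit kinetics), which the test suite pins down.

A genetic-style perturbation clamps a node: its derivative is zeroed and its
value held fixed throughout integration.

## Steady-state decoupling and the cost of a model

Fitting W by simulating every candidate model is too costly, so training
responses are assumed to be steady states and observed neighbor values
replace the self-consistent solution:

    x_hat_i^mu = tanh( sum_j w_ij x*_j^mu + u_i^mu )

This decouples the rows of W: row i is constrained only by node i's own
residuals.  A configuration's cost is

    C(W) = beta * sum_{i,mu} (x_hat_i^mu − x*_i^mu)^2 + lambda * #{w_ij != 0}

an error term weighted by an inverse temperature `beta` plus an L0 penalty
that encodes the sparsity of real signaling networks (L1 was deliberately
not used: it constrains the magnitudes, not the count).  exp(−C) defines a
Boltzmann distribution over configurations; its per-edge marginals are what
Belief Propagation approximates.

## Belief propagation

Edge values live on a discrete symmetric grid Ω containing zero (11 values
on [−1, 1] for the biological operating regime; 41 values on [−2, 2] for toy
benchmarks whose generator weights reach 2).  For each (target row i, source
j, condition mu) a factor rho^mu(w_ij) stores the per-condition evidence.
One cavity update:

1. cavity marginals for every other parameter of the row:
   P(w) ∝ exp(lambda·[w=0]) · prod_{nu != mu} rho^nu(w), computed in log
   space;
2. the non-cavity parameters' aggregate field h = sum w_ij·x*_j is
   summarized by its mean and variance under those marginals and treated as
   Gaussian (central-limit approximation over independent factors);
3. the new factor integrates the squared-error likelihood against that
   Gaussian, per candidate value omega:
   rho^mu(omega) ∝ ∫ N(h; m, v) exp(−beta (x*_i − tanh(h + omega x*_j +
   u_i))^2) dh.

The integral is evaluated by Gauss–Hermite quadrature (order 20 by default;
a zero variance collapses to a point evaluation automatically because all
quadrature nodes coincide).  Final marginals are the product of a row's
factors with the sparsity prior, normalized per edge — the partition
function is never materialized.

A sweep visits every (row, condition) block in a fresh seeded random
permutation; within a block all cavity parameters of the row are updated
jointly, which is exactly equivalent to sequential single-cavity updates
because cavity marginals exclude the block's own condition.  Convergence is
declared when no final marginal moves by more than `tol` (default 1e-6)
between sweeps; `max_sweeps` defaults to 200 and damping (default 0) is
available as a rescue for non-convergent runs.  Rows are independent, so any
row subset can be processed in isolation with identical results — decimation
exploits this.

The sweep kernel is compiled with numba when available; a pure-numpy
implementation of the identical update remains as the fallback and as the
reference the unit tests exercise edge by edge.

Hyperparameters: `beta = 2, lambda = 5` is the shipped default operating
point for biological data.  `select_hyperparameters` implements the
connectivity-targeting selection recipe: scan a (beta, lambda) lattice, build each
configuration's representative network (per-edge most probable value,
zeroing |w| < 0.2, ties broken toward the smallest |omega|), and pick the
lowest-expected-error configuration whose connectivity lands near a target
(default 1.5 edges per node).

## Decimation, refinement, ensembles

BP marginals describe a set of good models; explicit executable models are
drawn from them by decimation: sample an (edge, value) pair with probability
proportional to its joint marginal mass, pin that factor to a delta,
re-run BP to full tolerance (warm-started from the current factors), and
repeat until every parameter of the row is pinned.  Sampling the (edge,
value) pair jointly subsumes both "pick an edge then a value" readings;
rows are decimated independently, which is an exact factorization of the
sampling process under the row-decoupled posterior.

Each discrete model is then refined by backtracking gradient descent on the
*fully coupled* simulated steady-state error — the decoupling approximation
is dropped here — with central-difference gradients over the nonzero
weights plus log-parameterized alpha and eps (bounded to [0.05, 20] to keep
the dynamics non-degenerate).  Steps that raise the error, or that push any
training condition into oscillation, are rejected and the step halved (up
to 20 times); convergence is declared after 5 consecutive relative
improvements below 1e-6.  The zero pattern never changes: sparsity was
decided by the L0 prior upstream.

Ensembles instantiate `n_generate` models with consecutive seeds (the
result is independent of execution order), rank them by simulated training
error and keep the best `n_keep`.  The reference protocol (1000 generated,
top 100 kept) is the `RunConfig` default; tests and examples use smaller
ensembles.

## Simulation

Steady states are computed with an adaptive integrator (LSODA) in growing
time windows until max|dx/dt| < 1e-8 or t = 1e4 pseudo-time units.  A run
that reaches t_max unconverged is flagged oscillatory when the state
amplitude over the last 10% of the trajectory exceeds 10× the tolerance;
oscillating conditions are excluded from synthetic training sets (and
listed in the dataset manifest) and excluded-and-counted during screening.
The "within machine precision" convergence idea is operationalized by the
explicit tolerance above; any adaptive integrator meeting it is acceptable.

## Synthetic data

The toy generator emulates the benchmark conditions the method was
validated under, not any particular real dataset:

* **Topologies** are cascade-like: nodes are arranged in ~sqrt(N) layers
  with a forward backbone, then motif moves (serial extensions, parallel
  routes, feed-forward shortcuts, feedback reversals, extra inputs) add
  edges until the requested count.  Edge magnitudes are uniform on (0, 2]
  with random sign (p(positive) = 0.5); alpha = eps = 1.  Scale-free
  gene-regulatory topologies are deliberately out of scope — they are not
  typical of signal transduction.
* **Drug panels**: each in silico drug strongly inhibits one distinct main
  target (u = −1 at unit dose, a ~50% knockdown) and carries up to 4
  off-target effects of random sign with magnitudes 10–50% of the main
  strength ("smaller", quantified here as a uniform fraction).  Singles are
  applied at each dose level; pairs (all C(n,2)) at the lowest dose, as
  element-wise sums.  When off-targets are "unknown", the modeler's U
  contains only main-target forces while the data were generated with the
  full forces.
* **Noise** is multiplicative Gaussian, x → x·(1 + g) with g ~ N(0, cv) —
  multiplicative because the parameter is a coefficient of variation (15%
  realistic, 30% worst case).  An additive mode exists behind a flag.
  Simulation itself is deterministic; noise is applied post-simulation.

What the generator does *not* emulate: biological replicate structure,
antibody cross-reactivity, detection floors in log-space, or unmodeled
latent nodes.  Passing the synthetic benchmarks therefore demonstrates the
inference machinery under the model's own assumptions, not performance on
any particular real assay.

## Benchmarks and the problem sizes used

Three standard protocols live in `pertnet.benchmarks`:

* **Ideal recovery**: 10-node, 15-edge generators (1.5 edges/node), 120
  fully randomized dense perturbation patterns of strength 2, noise-free,
  41-value grid.  Operating point beta = 2, lambda = 3, selected by the
  connectivity-targeting recipe on a reference toy dataset of this shape.
  The benchmark generator is drawn to carry at most 2 edges below |w| =
  0.25 (a retry loop on the topology seed), emulating benchmark networks
  whose interactions are meant to be detectable at the 0.2 call threshold —
  an edge weaker than the threshold is unrecoverable by construction, not
  by failure of the inference.  Expected behavior: at most 2 missed edges
  and zero false positives per seed.
* **Drug panel** (realistic conditions): a motif-rich 20-node, 60-edge
  cascade generator probed by 14 drugs singly and in all pairs (105
  conditions before oscillation exclusion), noise-free with off-targets
  known, 11-value grid on [−2, 2]; main targets are strongly inhibited
  (u = −2) with off-target effects 10–50% as large.  In this data-limited
  regime the posterior is multimodal and a single BP run commits to one
  mode, so the marginals of 5 seeded restarts are averaged (a uniform mode
  mixture) before scoring recall and precision of the thresholded (0.2)
  mean network, averaged over three generator seeds.  The regime is
  intrinsically compensation-prone: false positives concentrate in
  upstream / symmetric / co-regulation motifs around missed true edges,
  which `classify_compensatory_motifs` labels — recall lands near 60% and
  precision near 30–40% here, and both depend strongly on the particular
  generator draw and drug-target assignment.
* **Parameter correlation** (data-limited regime): generators of sizes
  10–40 at 1.5 edges/node, each trained with exactly M = N single-node
  knockdown patterns (u = −1 per node) on the 41-value grid at the default
  operating point (beta 2, lambda 5); pooled Pearson correlation between
  BP mean parameters and the true nonzero weights.  Sizes stop at 40 to keep the desk-scale run in minutes;
  the protocol extends unchanged to larger systems.

The BP-vs-MC harness reports wall-clock convergence of both methods on the
same dataset; the numbers are hardware-dependent and are never asserted.

## Numerical choices and degenerate inputs

* Log-space products everywhere factors multiply; probabilities floored at
  1e-300 before logs.
* Representative-network ties broken toward the smallest |omega| (biases
  toward weak/sparse calls).
* An empty condition set returns prior-only marginals; beta = 0 likewise.
* Empty inferred networks report precision 1.0 with a `no_calls` flag (no
  calls were wrong); recall 0.
* A sign-mismatched edge call counts as both a false negative and a false
  positive.
* In silico screening clamps the target at x = −1 (log2 of 50% viability
  knockdown) by default: with eps/alpha = 1 a finite force cannot reach
  −1 through tanh, so force mode — which calibrates u against the
  isolated-node response — is only valid when strength < eps/alpha.
* Leave-k-out withholds every pair involving the drug *and* its high-dose
  single, keeping only the low-dose solo condition; a flag restores the
  high-dose single (the protocol wording is ambiguous on this point).
  The cross-validation error is reported as RMS prediction error per data
  point (the commonly quoted "CV" value has no printed formula), with mean
  absolute error alongside.
* Predictions for withheld conditions average the simulated steady states
  over the kept models (per-model pooling is the alternative reading).

## Known limitations

* BP on this dense, loopy factor graph can break the mode symmetry of a
  genuinely multimodal posterior: when a compensatory configuration has
  nearly the cost of the true one (saturated targets, collinear parents),
  a single BP run may commit to the wrong mode.  Restarting with a
  different seed and keeping the lower-expected-error fixed point helps;
  the benchmarks run single seeds and report what they get.
* The decoupling approximation divorces the likelihood from the dynamics;
  it is the main known source of false positives between correlated nodes.
* Numeric gradients make refinement O(parameters) simulations per
  iteration; fine for tens of nodes, the wrong tool for hundreds.
* Time-series likelihoods, enzyme-kinetic rate laws and prior-knowledge
  constraints are out of scope.
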