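# Methods

## Model and assumptions

The population is modeled as a discrete-time Markov chain on the *K = 2^m*
marker-combination states with a fixed time step of one day. The core
assumptions, inherited from the experimental design the package serves:

1. **State transitions are memoryless** — a cell's next state depends only on
   its current state (and the fixed environment), not on its history.
2. **Proliferation is neglected in estimation** — the estimator is unbiased
   only when all states divide at (approximately) the same rate. The simulator
   deliberately supports *unequal* doubling times so this assumption can be
   violated on purpose; the recovery benchmark then shows the bias growing
   with the spread of rates.
3. **No spatial structure or cell–cell interaction terms** — transitions are
   independent across cells.

Under pure starts, *W(0)* is the identity and *W(0)Pⁿ = W(n)*, so each
snapshot determines *P* up to a matrix *n*-th root.

## Estimation

`estimate_root` forms *A = W(0)⁻¹W(n)* and takes its principal *n*-th root by
eigendecomposition: each eigenvalue is raised to the principal complex power
1/*n*, the matrix is reassembled, and imaginary parts are discarded (their
largest magnitude is reported as a diagnostic; it is ~10⁻¹⁶ for well-posed
inputs and grows when the data leave the identifiable regime, see below).
If the eigenvector basis is rank-deficient or its condition number exceeds
10¹² — a defective or near-defective *A* — the estimator falls back to a
projected optimization: rows parametrized by softmax, ‖*Pⁿ − A*‖²_F minimized
by L-BFGS-B with an analytic gradient from a seeded start, deterministic for a
fixed seed, with the final residual reported.

`regularize` projects the raw root onto the stochastic matrices: clip to
[0, 1], renormalize each row; a row whose clipped sum is zero carries no
evidence and becomes the unit self-transition row. Clipping above 1 before
renormalization changes nothing when row sums exceed 1, so the combined map is
idempotent (rows already summing to 1 within 10⁻¹⁵ are left untouched to keep
idempotence exact in floating point). `average_estimates` is the unweighted
entrywise mean across measurement days. The per-day labeling convention: an
estimate obtained from the day-*n* snapshot is written *P̂₍ₙ₎* with *n* the
actual day (20/30/70 in the motivating design); sources that index the same
three estimates by snapshot ordinal rather than day describe the identical
computation.

### Identifiability of matrix roots

The principal root of *Pⁿ* equals *P* exactly only when every eigenvalue λ of
*P* satisfies |arg λ| < π/*n*. Two practical consequences shape both the
generator defaults and the test ensembles:

- **Branch condition.** Chains with complex or negative eigenvalues of large
  argument cannot be recovered from a single late snapshot by *any* root-based
  estimator. The generator's `irreducible` structure is therefore built
  *reversible* (a symmetric weight matrix row-normalized, giving detailed
  balance and hence a real spectrum) and *lazy* (diagonal mass shifted in,
  making the spectrum positive) — biologically, a marker-switching process
  relaxing toward equilibrium rather than oscillating.
- **Floating-point floor.** A mode with λⁿ below ~10⁻¹² relative to the O(1)
  entries of *Pⁿ* is numerically annihilated by the powering itself; the root
  then sees only rounding noise in that mode. Worse, when a snapshot is taken
  after the chain has fully mixed, *measurement* noise ε in *W(n)* produces
  spurious eigenvalues of magnitude ε^(1/n) — for ε = 10⁻³ at *n* = 70 that is
  ≈ 0.9, i.e. large spurious structure with random eigenvectors, essentially
  independent of how small ε is. A fully mixed snapshot estimates the
  stationary composition, not the daily rates.

## Synthetic-data generator

The generator emulates the pure-start multipotency assay: per-state cultures,
daily transitions, optional per-state doubling times
(*g*ᵢ = 2^(1/dᵢ) per day), phenotyping by drawing `n_cells` without
replacement from the census (multivariate hypergeometric; all cells when
fewer). `expected` mode propagates means exactly (division applied before
transition within each day — the model has no intrinsic intra-day order, so
one was fixed and documented); `per-cell` mode draws binomial divisions and
multinomial transitions per state, which is distributionally identical to
advancing each cell individually. A `passage_cap` (default 10⁷) subsamples the
census when growth exceeds it, as routine culture passaging does, keeping
counts in integer range. All randomness flows from one seed through
`numpy.random.SeedSequence.spawn`, one child per culture, so any sub-run is
reproducible in isolation.

Default parameters and why:

| parameter | default | rationale |
|---|---|---|
| `self_mass` (daily self-retention floor) | 0.93 | puts per-state relaxation at ~60–70 days for K = 16, so snapshots at days 20/30/70 are all measurably off equilibrium — the regime the three-snapshot design interrogates; a default that mixed in a week would make the late snapshots pure noise |
| measurement days | 20, 30, 70 | the standard pure-start re-phenotyping schedule |
| `n_cells` per measurement | 10⁵ | a realistic FACS acquisition for a harvested aliquot |
| `doubling_times` | none | estimation assumes equal proliferation; unequal times are an explicit stressor, not a default |
| Kronecker factor flip rates | U(0.05, 0.45) per direction | keeps each 2-state factor's second eigenvalue positive (a + b < 1), preserving root identifiability |

What the simulator does **not** emulate: FACS gating error and spillover,
replicate-level batch effects, cell death, spatial/sphere structure, and
cell–cell interactions. Passing recovery tests therefore demonstrate
correctness of the estimator under multinomial sampling and demographic
(per-cell) stochasticity — not robustness to instrument systematics.

## Numerical and design choices

- **Replicates** are normalized per replicate and averaged unweighted; rows
  aggregate experiments, not cells, so each replicate and each pure start
  carries equal weight (the same convention is used when coarse-graining rows
  for the marker-independence test).
- **Stationary distributions** come from the null space of *Pᵀ − I* restricted
  to each closed communicating class (classes from the strongly connected
  components of the support graph, entries > 10⁻¹²). With several closed
  classes the result is flagged non-unique and one extremal solution per class
  is returned.
- **Relaxation times** are integers (chain steps); the default metric is total
  variation with ε = 0.01, both configurable and recorded in outputs. Periodic
  chains are refused rather than assigned a Cesàro limit. The not-reached
  sentinel always carries the last distance and the cutoff used.
- **Absorbing detection** uses exit probability ≤ 10⁻⁹ rather than exact
  equality, since regularized matrices are floating point.
- **Transition-graph threshold** τ defaults to 0 with a 10⁻¹² floor: after
  regularization, "occurring" is most naturally a nonzero entry; τ is exposed
  because the appropriate cutoff depends on the data's noise level.
- **Krackhardt hierarchy** defaults to reachability mode (dyads on the
  transitive closure), matching the classical graph-level measure and giving
  score 1 for a perfect tree and 0 for any strongly connected graph; a
  `direct` mode on raw edges is also reported since the verbal definition
  admits both readings. Self-loops are excluded — hierarchy concerns
  between-state order. The score is undefined (explicit `None`) on a graph
  with no ties.
- **Marker-independence verdicts** print the absolute steady-state difference;
  the 0.05 verdict threshold is labeled a convention and is configurable. The
  dependence counterexample (`gated_marker_chain`) must be observed in its
  transient window (e.g. days 5/10/20): late snapshots of *any* chain pull the
  coarse-grained steady-state estimate toward the true marginal, hiding the
  non-Markov character of the collapsed dynamics.
- **Admixture design** is a seeded search (stationary point, pure states,
  Dirichlet draws) for a starting mix whose relaxation time is closest to the
  target; best-effort, achieved time always reported.

## Problem sizes

The test suite and the acceptance script run the full K = 16 pipeline with
10⁵-cell per-cell simulations over 70 simulated days and 5 seeds; this
completes in seconds. Root-oracle ensembles use K ≤ 6 with horizons up to 30
days and spectra bounded below 0.6 so every mode stays above the
floating-point floor described above.

## Known limitations

- Root-based estimation degrades sharply once snapshots are fully mixed
  (see identifiability); the package reports the discarded imaginary mass and
  the optimizer residual as diagnostics but cannot manufacture information the
  design did not collect.
- No confidence intervals on transition probabilities; the chain is estimated
  pointwise, as the averaging formula defines it.
- Continuous-time generator (rate-matrix) estimation is out of scope; the
  1-day step is fixed, and hierarchy/equilibrium conclusions are insensitive
  to the step choice.
- The marker-independence test compares steady states only; it does not test
  full factorization of the transition law.
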