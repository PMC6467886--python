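"""Ground-truth models and simulated pure-start plasticity experiments.

The simulator emulates the experimental design the estimation pipeline is
built for: populations of cells that switch among K phenotypic states
once per day according to a ground-truth row-stochastic matrix,
optionally proliferate with state-specific doubling times, and are
phenotyped at chosen days by drawing a finite sample of cells without
replacement (mimicking FACS counting of a harvested aliquot).

Two fidelity levels are provided.  ``expected`` mode propagates the mean
composition deterministically (``x_{t+1} ∝ (x_t ∘ g) P`` with growth
factors ``g_i = 2**(1/d_i)``) and is exact for oracle tests; ``per-cell``
mode simulates every division and transition stochastically at the level
of per-state counts (binomial divisions, multinomial transitions), which
is distributionally identical to advancing each cell individually.

Ground-truth structures
-----------------------
``irreducible``
    A lazy reversible chain: detailed balance makes the spectrum real,
    and the diagonal mass keeps it positive, so the daily chain is
    exactly identifiable from any single snapshot via the principal
    matrix root.  Biologically this is the fully plastic, non-hierarchical
    regime where most cells retain their phenotype from one day to the
    next.
``tree-hierarchy``
    A perfect hierarchy: transitions run only from parent to child along
    a random tree, leaves are absorbing.  Krackhardt score 1.
``with-transient``
    One designated state receives no incoming transitions but can exit —
    a reducible chain with a transient state and no absorbing state, the
    qualitative structure seen under severe hypoxia.
``kronecker-independent``
    The Kronecker product of independent per-marker 2-state chains, the
    regime in which each marker switches independently of the others.

All randomness flows from a single seed through ``numpy`` seed-sequence
spawning, so any sub-run is independently reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .equilibrium import Composition, stationary_distribution
from .inference import TransitionMatrix, estimate_transition_matrix
from .io import ObservationTable, build_proportion_matrix
from .states import StateSpace, build_state_space

__all__ = [
    "GroundTruthModel",
    "SimulatedExperiment",
    "generate_ground_truth",
    "simulate_experiment",
    "recovery_benchmark",
    "random_reversible_chain",
    "gated_marker_chain",
]

STRUCTURES = ("irreducible", "tree-hierarchy", "with-transient", "kronecker-independent")


@dataclass
class GroundTruthModel:
    """True chain plus proliferation and bookkeeping for recovery tests."""

    p_true: TransitionMatrix
    structure: str
    seed: int
    space: StateSpace
    doubling_times: np.ndarray | None = None  # per-state days; None = no growth
    factors: list[np.ndarray] | None = None  # kronecker-independent: 2x2 chains
    transient_state: str | None = None  # with-transient: the designated state
    tree_parents: list[int] | None = None  # tree-hierarchy: parent index per state

    def to_json(self, path: str | Path) -> None:
        blob = {
            "structure": self.structure,
            "seed": self.seed,
            "markers": list(self.space.markers),
            "labels": list(self.space.labels),
            "p_true": self.p_true.values.tolist(),
            "doubling_times": None
            if self.doubling_times is None
            else self.doubling_times.tolist(),
            "factors": None if self.factors is None else [f.tolist() for f in self.factors],
            "transient_state": self.transient_state,
            "tree_parents": self.tree_parents,
        }
        Path(path).write_text(json.dumps(blob, indent=2))


@dataclass
class SimulatedExperiment:
    table: ObservationTable
    design: str
    days: list[int]
    n_cells: int
    mode: str
    seed: int
    model: GroundTruthModel
    # per (initial label, day): exact expected composition (expected mode)
    # or sampled counts (per-cell mode)
    compositions: dict = field(default_factory=dict)


def random_reversible_chain(
    k: int, self_mass: float, rng: np.random.Generator
) -> np.ndarray:
    """Lazy reversible chain with real positive spectrum.

    Built from a symmetric positive weight matrix ``S`` as
    ``Q = diag(S 1)^-1 S`` (reversible w.r.t. its row sums, hence real
    spectrum in [-1, 1]) then shifted, ``P = a I + (1 - a) Q`` with
    ``a = max(self_mass, 0.5)``, which maps the spectrum into (0, 1].
    """
    s = rng.uniform(0.1, 1.0, size=(k, k))
    s = (s + s.T) / 2.0
    q = s / s.sum(axis=1, keepdims=True)
    a = max(self_mass, 0.5)
    return a * np.eye(k) + (1.0 - a) * q


def gated_marker_chain(
    a_loss_gated: float = 0.4,
    a_recover: float = 0.05,
    b_flip: float = 0.03,
    markers: tuple[str, str] = ("A", "B"),
) -> TransitionMatrix:
    """Two-marker chain whose first marker is gated by the second.

    Marker A switches from positive to negative with probability
    ``a_loss_gated`` per day — but only while marker B is positive — and
    recovers the positive state with probability ``a_recover`` regardless
    of B; B flips symmetrically with probability ``b_flip``.  The two
    markers are therefore strongly dependent: the coarse-grained 2-state
    dynamics of A are not Markov, and its apparent steady state (fit from
    transient-window snapshots) deviates from the marginal of the full
    chain's stationary distribution.  The counterexample companion to the
    ``kronecker-independent`` structure.
    """
    space = build_state_space(list(markers))
    idx = {s: i for i, s in enumerate(space.signs)}
    p = np.zeros((4, 4))
    for (sa, sb), i in idx.items():
        pa = (a_loss_gated if sb == 1 else 0.0) if sa == 1 else a_recover
        pb = b_flip
        for fa in (0, 1):
            for fb in (0, 1):
                j = idx[(-sa if fa else sa, -sb if fb else sb)]
                p[i, j] += (pa if fa else 1 - pa) * (pb if fb else 1 - pb)
    return TransitionMatrix(p, space=space, provenance=[("ground-truth", "gated")])


def _tree_chain(k: int, self_mass: float, rng: np.random.Generator):
    parents = [-1] + [int(rng.integers(0, i)) for i in range(1, k)]
    children = {i: [j for j in range(k) if parents[j] == i] for i in range(k)}
    p = np.zeros((k, k))
    # distinct internal diagonals keep the chain diagonalizable
    diags = np.sort(rng.uniform(self_mass, min(self_mass + 0.3, 0.95), size=k))
    for i in range(k):
        if children[i]:
            p[i, i] = diags[i]
            w = rng.dirichlet(np.ones(len(children[i])))
            for c, wc in zip(children[i], w):
                p[i, c] = (1.0 - diags[i]) * wc
        else:
            p[i, i] = 1.0  # leaf: absorbing
    return p, parents


def generate_ground_truth(
    k: int | None = None,
    structure: str = "irreducible",
    self_mass: float = 0.93,
    seed: int = 0,
    markers: list[str] | None = None,
    doubling_times: np.ndarray | list | None = None,
) -> GroundTruthModel:
    """Seeded, reproducible ground-truth chain of a chosen structure.

    Parameters
    ----------
    k:
        Number of states (a power of two; inferred from ``markers`` when
        those are given).
    self_mass:
        Lower bound on the daily self-retention probability.  The default
        0.93 puts phenotype switching on the weeks time scale (per-state
        relaxation times of roughly 60-70 days at K=16), so snapshots at
        days 20/30/70 are all measurably off equilibrium — the regime the
        pure-start design is built to interrogate.  A snapshot taken
        after the chain has fully mixed estimates only the stationary
        composition, not the daily rates.
    doubling_times:
        Optional per-state doubling times in days; ``None`` disables
        proliferation (the estimation model neglects it anyway when rates
        are equal).
    """
    if structure not in STRUCTURES:
        raise ValueError(f"unknown structure {structure!r}; choose from {STRUCTURES}")
    if not 0.0 <= self_mass < 1.0:
        raise ValueError("self_mass must lie in [0, 1)")
    if markers is not None:
        space = build_state_space(markers)
        if k is not None and k != space.n_states:
            raise ValueError("k inconsistent with markers")
        k = space.n_states
    else:
        if k is None or k < 2:
            raise ValueError("need k >= 2 states")
        m = int(round(np.log2(k)))
        if 2**m != k:
            raise ValueError("k must be a power of two (marker-combination states)")
        space = build_state_space([f"M{i + 1}" for i in range(m)])
    rng = np.random.default_rng(seed)

    factors = None
    transient_state = None
    tree_parents = None
    if structure == "irreducible":
        p = random_reversible_chain(k, self_mass, rng)
    elif structure == "tree-hierarchy":
        p, tree_parents = _tree_chain(k, self_mass, rng)
    elif structure == "with-transient":
        idx = int(rng.integers(0, k))
        base = random_reversible_chain(k - 1, self_mass, rng)
        others = [j for j in range(k) if j != idx]
        p = np.zeros((k, k))
        p[np.ix_(others, others)] = base  # nobody enters the transient state
        q = rng.uniform(self_mass, 0.95)
        out = rng.dirichlet(np.ones(k - 1))
        p[idx, idx] = q
        p[idx, others] = (1.0 - q) * out
        transient_state = space.labels[idx]
    else:  # kronecker-independent
        m = space.n_markers
        factors = []
        for _ in range(m):
            a, b = rng.uniform(0.05, 0.45, size=2)  # a + b < 1: positive spectrum
            factors.append(np.array([[1 - a, a], [b, 1 - b]]))
        p = factors[0]
        for f in factors[1:]:
            p = np.kron(p, f)

    dts = None
    if doubling_times is not None:
        dts = np.asarray(doubling_times, dtype=float)
        if dts.shape != (k,):
            raise ValueError(f"doubling_times must have length {k}")
        if (dts == 0).any():
            raise ValueError("doubling times must be nonzero")

    _verify_structure(p, structure, space, transient_state)
    return GroundTruthModel(
        p_true=TransitionMatrix(p, space=space, provenance=[("ground-truth", structure)]),
        structure=structure,
        seed=seed,
        space=space,
        doubling_times=dts,
        factors=factors,
        transient_state=transient_state,
        tree_parents=tree_parents,
    )


def _verify_structure(
    p: np.ndarray, structure: str, space: StateSpace, transient_state: str | None
) -> None:
    assert np.allclose(p.sum(axis=1), 1.0, atol=1e-12)
    if structure == "with-transient":
        i = space.index(transient_state)
        col = p[:, i].copy()
        col[i] = 0.0
        assert np.all(col == 0.0), "transient state must have zero incoming mass"
        assert p[i, i] < 1.0, "transient state must be exitable"


def _growth_factors(model: GroundTruthModel) -> np.ndarray | None:
    if model.doubling_times is None:
        return None
    return 2.0 ** (1.0 / model.doubling_times)


def _expected_trajectory(
    model: GroundTruthModel, x0: np.ndarray, t_end: int
) -> dict[int, np.ndarray]:
    g = _growth_factors(model)
    p = model.p_true.values
    traj = {0: x0.copy()}
    x = x0.copy()
    for t in range(1, t_end + 1):
        if g is not None:
            x = x * g
            x = x / x.sum()
        x = x @ p
        traj[t] = x.copy()
    return traj


def _per_cell_trajectory(
    model: GroundTruthModel,
    counts0: np.ndarray,
    days: list[int],
    n_cells: int,
    rng: np.random.Generator,
    passage_cap: int | None,
) -> dict[int, np.ndarray]:
    """Stochastic per-state counts; returns sampled phenotyping counts per day.

    Each day: divisions (binomial per state with probability
    ``2**(1/d) - 1``), then transitions (multinomial per state).  At a
    measurement day, ``n_cells`` cells are drawn without replacement from
    the census (all cells when fewer).  If the census exceeds
    ``passage_cap`` the culture is passaged: subsampled without
    replacement down to the cap, as routine cell culture does.
    """
    p = model.p_true.values
    k = p.shape[0]
    g = None
    if model.doubling_times is not None:
        g = 2.0 ** (1.0 / model.doubling_times) - 1.0
    counts = counts0.astype(np.int64).copy()
    samples: dict[int, np.ndarray] = {}
    t_end = max(days)
    if 0 in days:
        samples[0] = _phenotype_sample(counts, n_cells, rng)
    for t in range(1, t_end + 1):
        if g is not None:
            births = rng.binomial(counts, np.clip(g, 0.0, 1.0))
            counts = counts + births
        new = np.zeros(k, dtype=np.int64)
        for i in range(k):
            if counts[i] > 0:
                new += rng.multinomial(counts[i], p[i])
        counts = new
        if passage_cap is not None and counts.sum() > passage_cap:
            counts = rng.multivariate_hypergeometric(counts, passage_cap)
        if t in days:
            samples[t] = _phenotype_sample(counts, n_cells, rng)
    return samples


def _phenotype_sample(
    counts: np.ndarray, n_cells: int, rng: np.random.Generator
) -> np.ndarray:
    total = int(counts.sum())
    if total <= n_cells:
        return counts.copy()
    return rng.multivariate_hypergeometric(counts, n_cells)


def simulate_experiment(
    model: GroundTruthModel,
    days: list[int],
    n_cells: int = 100_000,
    mode: str = "expected",
    seed: int = 0,
    design: str = "pure-start",
    admixtures: dict[str, np.ndarray] | None = None,
    n0: int | None = None,
    passage_cap: int | None = 10_000_000,
    condition: str = "sim",
) -> SimulatedExperiment:
    """Simulate a phenotyping time course and emit an observation table.

    ``design="pure-start"`` runs one culture per state, initiated pure
    (the multipotency assay); ``design="admixture"`` runs the supplied
    named starting mixes.  ``expected`` mode emits exact fractions,
    ``per-cell`` mode emits sampled counts.  ``n0`` is the number of
    founding cells per culture in per-cell mode (default ``n_cells``).
    """
    if mode not in ("expected", "per-cell"):
        raise ValueError("mode must be 'expected' or 'per-cell'")
    if design not in ("pure-start", "admixture"):
        raise ValueError("design must be 'pure-start' or 'admixture'")
    days = sorted(set(int(d) for d in days))
    if any(d < 0 for d in days):
        raise ValueError("days must be non-negative integers")
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    space = model.space
    k = space.n_states
    if design == "pure-start":
        starts = {lab: np.eye(k)[i] for i, lab in enumerate(space.labels)}
    else:
        if not admixtures:
            raise ValueError("admixture design needs admixtures={label: composition}")
        starts = {lab: np.asarray(x, float) for lab, x in admixtures.items()}
        for lab, x in starts.items():
            Composition(x, space, label=lab)  # validates simplex membership

    records = []
    compositions: dict = {}
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(starts))
    for (start_label, x0), child in zip(starts.items(), children):
        if mode == "expected":
            traj = _expected_trajectory(model, x0, max(days) if days else 0)
            for d in days:
                x = traj[d]
                compositions[(start_label, d)] = x
                for j, obs in enumerate(space.labels):
                    records.append(
                        dict(
                            condition=condition,
                            initial_state=start_label,
                            time_days=d,
                            observed_state=obs,
                            value=float(x[j]),
                        )
                    )
        else:
            rng = np.random.default_rng(child)
            base = n0 if n0 is not None else n_cells
            if design == "pure-start":
                counts0 = (base * x0).astype(np.int64)  # exactly pure at day 0
            else:
                counts0 = rng.multinomial(base, x0)
            samples = _per_cell_trajectory(
                model, counts0, days, n_cells, rng, passage_cap
            )
            for d in days:
                c = samples[d]
                compositions[(start_label, d)] = c
                for j, obs in enumerate(space.labels):
                    records.append(
                        dict(
                            condition=condition,
                            initial_state=start_label,
                            time_days=d,
                            observed_state=obs,
                            value=float(c[j]),
                        )
                    )
    table = ObservationTable(
        pd.DataFrame.from_records(records),
        value_kind="fractions" if mode == "expected" else "counts",
    )
    return SimulatedExperiment(
        table=table,
        design=design,
        days=days,
        n_cells=n_cells,
        mode=mode,
        seed=seed,
        model=model,
        compositions=compositions,
    )


def recovery_benchmark(
    model: GroundTruthModel,
    days: list[int],
    n_cells: int = 100_000,
    seeds: list[int] = (0,),
    mode: str = "per-cell",
    n0: int | None = None,
    passage_cap: int | None = 10_000_000,
) -> dict:
    """End-to-end parameter recovery: simulate, estimate, compare.

    Runs the full pipeline (observation table → proportion matrices →
    root estimation → regularization → averaging) for each seed and
    reports the max and mean absolute error of the estimated transition
    matrix against the ground truth and the total-variation error of the
    estimated versus true stationary distribution.
    """
    space = model.space
    per_seed = []
    pi_true = stationary_distribution(model.p_true)
    for seed in seeds:
        exp = simulate_experiment(
            model, days=days, n_cells=n_cells, mode=mode, seed=seed,
            n0=n0, passage_cap=passage_cap,
        )
        snaps = [
            build_proportion_matrix(exp.table, space, t=d, condition="sim")
            for d in days
        ]
        p_hat, raws = estimate_transition_matrix(snaps, seed=seed)
        err = np.abs(p_hat.values - model.p_true.values)
        entry = {
            "seed": seed,
            "max_abs_error": float(err.max()),
            "mean_abs_error": float(err.mean()),
            "fallback_used": any(r.fallback_used for r in raws),
        }
        if pi_true.unique:
            pi_hat = stationary_distribution(p_hat)
            if pi_hat.unique:
                entry["tv_stationary"] = 0.5 * float(
                    np.abs(pi_hat.pi.x - pi_true.pi.x).sum()
                )
        per_seed.append(entry)
    summary = {
        "per_seed": per_seed,
        "mean_abs_error": float(np.mean([e["mean_abs_error"] for e in per_seed])),
        "max_abs_error": float(np.max([e["max_abs_error"] for e in per_seed])),
    }
    tvs = [e["tv_stationary"] for e in per_seed if "tv_stationary" in e]
    if tvs:
        summary["mean_tv_stationary"] = float(np.mean(tvs))
        summary["max_tv_stationary"] = float(np.max(tvs))
    return summary
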