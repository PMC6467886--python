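"""Stationary compositions, relaxation times, and state classification.

The stationary distribution ``pi`` (``pi P = pi``) is the predicted
long-run phenotypic composition; the relaxation time of an initial
composition ``x0`` is the smallest integer number of daily steps after
which ``x0 P**t`` is within a tolerance of ``pi`` (default: total
variation distance below 0.01).  Reducibility analysis classifies states
as transient or recurrent from the strongly connected components of the
thresholded transition graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import scipy.linalg

from .inference import TransitionMatrix
from .states import StateSpace

__all__ = [
    "Composition",
    "EquilibriumResult",
    "RelaxationResult",
    "StateClassification",
    "AdmixtureDesign",
    "stationary_distribution",
    "predict_composition",
    "time_to_equilibrium",
    "classify_states",
    "design_admixture",
]

_SUM_TOL = 1e-9
#: entries below this are treated as structural zeros when building graphs
_ZERO = 1e-12
#: tolerance on exit probability for calling a state absorbing
TAU_ABSORBING = 1e-9


@dataclass
class Composition:
    """A point on the K-simplex: fractions over states."""

    x: np.ndarray
    space: StateSpace
    label: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.x, dtype=float)
        if v.shape != (self.space.n_states,):
            raise ValueError(f"expected length-{self.space.n_states} vector")
        if (v < -_SUM_TOL).any() or (v > 1 + _SUM_TOL).any():
            raise ValueError("fractions must lie in [0, 1]")
        if abs(v.sum() - 1.0) > _SUM_TOL:
            raise ValueError(f"fractions must sum to 1 (got {v.sum()})")
        self.x = v

    @classmethod
    def pure(cls, space: StateSpace, label: str) -> "Composition":
        x = np.zeros(space.n_states)
        x[space.index(label)] = 1.0
        return cls(x, space, label=f"pure:{label}")


@dataclass
class EquilibriumResult:
    """Stationary composition(s) of the chain."""

    pi: Composition | None  # the stationary state when unique
    unique: bool
    # one extremal stationary distribution per closed recurrent class
    solutions: list[Composition] = field(default_factory=list)
    residual: float = 0.0  # ||pi P - pi||_inf for the reported pi


@dataclass
class RelaxationResult:
    """Time to approximate equilibrium from one initial composition."""

    days: int | None  # None when not reached within t_max
    reached: bool
    last_distance: float
    eps: float
    metric: str
    t_max: int


@dataclass
class StateClassification:
    transient: list[str]
    recurrent: list[str]
    absorbing: list[str]
    irreducible: bool
    recurrent_classes: list[list[str]]
    per_state: dict[str, str] = field(default_factory=dict)


@dataclass
class AdmixtureDesign:
    composition: Composition
    achieved_days: int | None
    target_days: int
    candidates_tried: int


_METRICS = {
    "tv": lambda a, b: 0.5 * float(np.abs(a - b).sum()),
    "l1": lambda a, b: float(np.abs(a - b).sum()),
    "l2": lambda a, b: float(np.linalg.norm(a - b)),
    "linf": lambda a, b: float(np.abs(a - b).max()),
}


def _support_graph(values: np.ndarray, labels, tau: float = 0.0) -> nx.DiGraph:
    thr = max(tau, _ZERO)
    g = nx.DiGraph()
    g.add_nodes_from(labels)
    k = len(labels)
    for i in range(k):
        for j in range(k):
            if values[i, j] > thr:
                g.add_edge(labels[i], labels[j])
    return g


def _closed_classes(p: TransitionMatrix, tau: float = 0.0) -> tuple[list[set], list[set]]:
    """(closed recurrent classes, open transient classes) as label sets."""
    g = _support_graph(p.values, p.labels, tau)
    cond = nx.condensation(g)
    closed, open_ = [], []
    for node, data in cond.nodes(data=True):
        members = set(data["members"])
        if cond.out_degree(node) == 0:
            closed.append(members)
        else:
            open_.append(members)
    return closed, open_


def _class_stationary(p: TransitionMatrix, members: set) -> np.ndarray:
    """Stationary distribution supported on one closed class."""
    idx = [i for i, lab in enumerate(p.labels) if lab in members]
    sub = p.values[np.ix_(idx, idx)]
    sub = sub / sub.sum(axis=1, keepdims=True)  # closed => sums already 1
    ns = scipy.linalg.null_space(sub.T - np.eye(len(idx)), rcond=1e-10)
    if ns.shape[1] == 0:  # fall back to the eigenvector closest to 1
        w, v = np.linalg.eig(sub.T)
        vec = v[:, np.argmin(np.abs(w - 1.0))].real
    else:
        vec = ns[:, 0]
    vec = np.abs(vec)
    vec = vec / vec.sum()
    full = np.zeros(p.space.n_states)
    full[idx] = vec
    return full


def stationary_distribution(p: TransitionMatrix) -> EquilibriumResult:
    """Left eigenvector of ``P`` for eigenvalue 1, normalized to sum 1.

    When the chain has several closed recurrent classes the stationary
    distribution is not unique: ``unique`` is false and one extremal
    solution per class is reported (every stationary distribution is a
    convex combination of these).
    """
    closed, _ = _closed_classes(p)
    sols = [
        Composition(_class_stationary(p, members), p.space, label=f"class{i}")
        for i, members in enumerate(closed)
    ]
    if len(closed) == 1:
        pi = Composition(sols[0].x, p.space, label="stationary")
        residual = float(np.abs(pi.x @ p.values - pi.x).max())
        return EquilibriumResult(pi=pi, unique=True, solutions=sols, residual=residual)
    return EquilibriumResult(pi=None, unique=False, solutions=sols)


def predict_composition(
    p: TransitionMatrix, x0: Composition, t: int
) -> Composition:
    """Forward prediction ``x0 P**t`` by repeated multiplication."""
    if t < 0:
        raise ValueError("t must be non-negative")
    x = x0.x.copy()
    for _ in range(int(t)):
        x = x @ p.values
    x = np.clip(x, 0.0, None)
    x = x / x.sum()
    return Composition(x, p.space, label=f"{x0.label}@day{t}")


def _is_aperiodic(p: TransitionMatrix) -> bool:
    closed, _ = _closed_classes(p)
    g = _support_graph(p.values, p.labels)
    return all(nx.is_aperiodic(g.subgraph(members)) for members in closed)


def time_to_equilibrium(
    p: TransitionMatrix,
    x0: Composition,
    eps: float = 0.01,
    metric: str = "tv",
    t_max: int = 1000,
) -> RelaxationResult:
    """Smallest integer day ``t`` with ``distance(x0 P**t, pi) < eps``.

    Requires a unique stationary state and an aperiodic chain (periodic
    chains never settle pointwise and are refused rather than reported via
    a Cesaro limit).  If ``t_max`` is exceeded, the sentinel result has
    ``reached=False`` and carries the last distance.
    """
    if eps <= 0:
        raise ValueError("eps must be positive")
    if metric not in _METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {sorted(_METRICS)}")
    eq = stationary_distribution(p)
    if not eq.unique:
        raise ValueError("stationary state is not unique; relaxation time undefined")
    if not _is_aperiodic(p):
        raise ValueError("chain is periodic; no pointwise equilibrium is approached")
    dist = _METRICS[metric]
    pi = eq.pi.x
    x = x0.x.copy()
    d = dist(x, pi)
    t = 0
    while d >= eps and t < t_max:
        x = x @ p.values
        t += 1
        d = dist(x, pi)
    if d < eps:
        return RelaxationResult(t, True, d, eps, metric, t_max)
    return RelaxationResult(None, False, d, eps, metric, t_max)


def classify_states(p: TransitionMatrix, tau: float = 0.0) -> StateClassification:
    """Transient/recurrent/absorbing classification of all states.

    Built on the strongly connected components of the tau-thresholded
    support graph: states in non-closed components are transient, the
    rest recurrent.  A state is absorbing when its exit probability
    ``1 - P[i, i]`` is below ``TAU_ABSORBING`` (regularized matrices are
    floating point, so an exact-zero test would be brittle).
    """
    if tau < 0:
        raise ValueError("tau must be non-negative")
    closed, open_ = _closed_classes(p, tau)
    recurrent_classes = [sorted(m, key=p.labels.index) for m in closed]
    recurrent = sorted(
        (lab for m in closed for lab in m), key=p.labels.index
    )
    transient = sorted((lab for m in open_ for lab in m), key=p.labels.index)
    absorbing = [
        lab
        for i, lab in enumerate(p.labels)
        if 1.0 - p.values[i, i] <= TAU_ABSORBING
    ]
    per_state = {lab: "recurrent" for lab in recurrent}
    per_state.update({lab: "transient" for lab in transient})
    return StateClassification(
        transient=transient,
        recurrent=recurrent,
        absorbing=absorbing,
        irreducible=len(closed) == 1 and not open_,
        recurrent_classes=recurrent_classes,
        per_state=per_state,
    )


def design_admixture(
    p: TransitionMatrix,
    target_days: int,
    eps: float = 0.01,
    metric: str = "tv",
    seed: int = 0,
    n_candidates: int = 200,
    t_max: int = 1000,
) -> AdmixtureDesign:
    """Search the simplex for a starting mix with a chosen relaxation time.

    Candidates are the stationary state itself, every pure state, and
    seeded Dirichlet(1) draws; the candidate whose relaxation time is
    closest to ``target_days`` wins (ties go to the earliest candidate).
    Best-effort: the achieved time is always reported.
    """
    eq = stationary_distribution(p)
    if not eq.unique:
        raise ValueError("stationary state is not unique; cannot target a relaxation time")
    rng = np.random.default_rng(seed)
    k = p.space.n_states
    candidates = [eq.pi.x]
    candidates += [np.eye(k)[i] for i in range(k)]
    candidates += list(rng.dirichlet(np.ones(k), size=max(0, n_candidates)))
    best, best_days, best_gap = None, None, np.inf
    for x in candidates:
        comp = Composition(x, p.space)
        res = time_to_equilibrium(p, comp, eps=eps, metric=metric, t_max=t_max)
        days = res.days if res.reached else t_max + 1
        gap = abs(days - target_days)
        if gap < best_gap:
            best, best_days, best_gap = comp, res.days, gap
        if gap == 0:
            break
    best.label = f"admixture(target={target_days}d)"
    return AdmixtureDesign(
        composition=best,
        achieved_days=best_days,
        target_days=target_days,
        candidates_tried=len(candidates),
    )
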