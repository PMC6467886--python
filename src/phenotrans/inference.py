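"""Daily transition-matrix estimation from proportion snapshots.

The model is a discrete-time Markov chain with a 1-day step: a cell in
state ``i`` is in state ``j`` one day later with probability ``P[i, j]``,
independent of its history.  With pure starts, the proportion matrices
satisfy ``W(0) P**n = W(n)``, so each snapshot yields a raw estimate

    P_hat(n) = (W(0)^-1 W(n)) ** (1/n)

computed as the principal matrix n-th root.  Raw roots are generally not
stochastic (small negative or complex-origin entries), so they are
regularized — clipped to [0, 1] and row-renormalized — and the per-day
estimates are averaged with equal weight into the final matrix.

Identifiability caveat: the principal root of ``P**n`` equals ``P`` only
when every eigenvalue of ``P`` satisfies ``|arg(lambda)| < pi/n``.  Chains
with strong daily self-retention (lazy chains) and real positive spectra
satisfy this for all practical ``n``; strongly oscillatory chains do not,
and no root-based estimator can recover them from a single late snapshot.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .io import ProportionMatrix
from .states import StateSpace

__all__ = [
    "RawRootMatrix",
    "TransitionMatrix",
    "TransitionGraph",
    "principal_root",
    "clip_and_renormalize",
    "estimate_root",
    "regularize",
    "average_estimates",
    "fit_root_by_optimization",
    "extract_graph",
    "estimate_transition_matrix",
]

_ROW_SUM_TOL = 1e-9
#: numerical floor under which an off-diagonal entry never counts as an edge
EDGE_FLOOR = 1e-12
#: condition-number guard for the eigenvector matrix; above this the
#: eigendecomposition route is considered unreliable and the optimizer is used
_EIG_COND_MAX = 1e12


@dataclass
class RawRootMatrix:
    """Principal n-th root of ``W(0)^-1 W(n)`` before regularization."""

    values: np.ndarray  # real; imaginary parts already discarded
    t: int
    space: StateSpace
    max_imag: float = 0.0  # largest |imaginary part| discarded
    fallback_used: bool = False
    residual: float | None = None  # ||P**n - Wn||_F when the optimizer ran


@dataclass
class TransitionMatrix:
    """Row-stochastic daily transition probabilities."""

    values: np.ndarray
    space: StateSpace
    step_days: int = 1
    provenance: list = field(default_factory=list)  # (t, note) pairs

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        k = self.space.n_states
        if v.shape != (k, k):
            raise ValueError(f"expected {k}x{k} matrix, got {v.shape}")
        if (v < -_ROW_SUM_TOL).any() or (v > 1 + _ROW_SUM_TOL).any():
            raise ValueError("transition probabilities must lie in [0, 1]")
        if not np.allclose(v.sum(axis=1), 1.0, atol=_ROW_SUM_TOL):
            raise ValueError("rows must sum to 1")
        self.values = v

    @property
    def labels(self) -> tuple[str, ...]:
        return self.space.labels


@dataclass
class TransitionGraph:
    """Directed graph of direct transitions above a probability threshold."""

    graph: "object"  # networkx.DiGraph with 'weight' on edges
    tau: float
    n_states: int

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def n_possible(self) -> int:
        return self.n_states * (self.n_states - 1)

    def edges(self) -> list[tuple[str, str, float]]:
        return [(u, v, d["weight"]) for u, v, d in self.graph.edges(data=True)]


def principal_root(a: np.ndarray, n: int) -> tuple[np.ndarray, float, bool]:
    """Principal n-th root of a square matrix by eigendecomposition.

    Returns ``(values, max_imag, ok)``: the real part of the root, the
    largest discarded imaginary magnitude, and whether the
    eigendecomposition was trustworthy (well-conditioned eigenvector
    basis with a faithful reconstruction).  ``ok=False`` signals a
    defective or near-defective matrix; callers should fall back to an
    optimization route.
    """
    a = np.asarray(a, dtype=float)
    k = a.shape[0]
    eigvals, eigvecs = np.linalg.eig(a.astype(complex))
    if np.linalg.matrix_rank(eigvecs) < k:
        return np.full_like(a, np.nan), np.inf, False
    cond = np.linalg.cond(eigvecs)
    recon = eigvecs @ np.diag(eigvals) @ np.linalg.inv(eigvecs)
    recon_err = np.abs(recon - a).max()
    if cond > _EIG_COND_MAX or recon_err > 1e-8 * max(1.0, np.abs(a).max()):
        return np.full_like(a, np.nan), np.inf, False
    roots = eigvals ** (1.0 / n)  # principal branch
    p_raw = eigvecs @ np.diag(roots) @ np.linalg.inv(eigvecs)
    return p_raw.real, float(np.abs(p_raw.imag).max()), True


def clip_and_renormalize(values: np.ndarray) -> np.ndarray:
    """Clip to [0, 1] and renormalize rows; a dead row becomes self-transition."""
    v = np.asarray(values, dtype=float)
    if not np.isfinite(v).all():
        raise ValueError("non-finite entries in raw root matrix")
    v = np.clip(v, 0.0, 1.0)
    sums = v.sum(axis=1)
    out = np.empty_like(v)
    for i, s in enumerate(sums):
        if s <= 0.0:
            out[i] = 0.0
            out[i, i] = 1.0
        elif abs(s - 1.0) < 1e-15:
            out[i] = v[i]  # already normalized; keep the map idempotent
        else:
            out[i] = v[i] / s
    return out


def estimate_root(
    w0: ProportionMatrix,
    wn: ProportionMatrix,
    n: int | None = None,
    seed: int = 0,
) -> RawRootMatrix:
    """Principal n-th root of ``A = W(0)^-1 W(n)`` by eigendecomposition.

    Each eigenvalue is taken to its principal complex 1/n power; the
    reconstructed matrix's imaginary parts are discarded and their largest
    magnitude recorded.  If ``A`` is defective (ill-conditioned
    eigenvector basis or poor reconstruction), the estimate falls back to
    the projected optimization route :func:`fit_root_by_optimization`.

    ``n`` defaults to ``wn.t - w0.t``.

    Raises
    ------
    ValueError
        If ``W(0)`` is singular or ``n < 1``.
    """
    if w0.space is not wn.space and w0.space.labels != wn.space.labels:
        raise ValueError("proportion matrices use different state spaces")
    if n is None:
        n = wn.t - w0.t
    if n < 1:
        raise ValueError("need n >= 1 day between snapshots")
    k = w0.space.n_states
    if np.linalg.matrix_rank(w0.values) < k:
        raise ValueError("W(0) is singular; cannot solve for the transition matrix")
    a = np.linalg.solve(w0.values, wn.values)

    values, max_imag, ok = principal_root(a, n)
    if not ok:
        # defective or near-defective A: optimization route
        fitted = fit_root_by_optimization(wn, n=n, seed=seed, w0=w0)
        return RawRootMatrix(
            values=fitted.values,
            t=wn.t,
            space=wn.space,
            max_imag=0.0,
            fallback_used=True,
            residual=fitted.provenance[-1][1].get("residual")
            if fitted.provenance
            else None,
        )
    return RawRootMatrix(values=values, t=wn.t, space=wn.space, max_imag=max_imag)


def regularize(raw: RawRootMatrix) -> TransitionMatrix:
    """Project a raw root onto the row-stochastic matrices.

    Entries are clipped to [0, 1] and each row divided by its sum; a row
    whose clipped sum is 0 carries no evidence and becomes the unit
    self-transition row.  Already-stochastic input is a fixed point.
    """
    out = clip_and_renormalize(raw.values)
    return TransitionMatrix(
        out, space=raw.space, provenance=[(raw.t, {"fallback": raw.fallback_used})]
    )


def average_estimates(estimates: list[TransitionMatrix]) -> TransitionMatrix:
    """Entrywise unweighted mean of per-time-point estimates."""
    if not estimates:
        raise ValueError("need at least one estimate")
    space = estimates[0].space
    for e in estimates[1:]:
        if e.space.labels != space.labels:
            raise ValueError("estimates use different state spaces")
    mean = np.mean([e.values for e in estimates], axis=0)
    assert np.allclose(mean.sum(axis=1), 1.0, atol=1e-12)
    prov = [p for e in estimates for p in e.provenance]
    return TransitionMatrix(mean, space=space, provenance=prov)


def _softmax_rows(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def fit_root_by_optimization(
    wn: ProportionMatrix,
    n: int,
    seed: int = 0,
    w0: ProportionMatrix | None = None,
    max_iter: int = 5000,
) -> TransitionMatrix:
    """Fit a stochastic n-th root by minimizing ``||P**n - A||_F``.

    ``P`` is parametrized row-wise through a softmax, so iterates stay on
    the simplex, and optimized with L-BFGS-B from a seeded start; the run
    is deterministic for a fixed seed.  The final residual is recorded in
    the provenance; non-convergence returns the best iterate with a
    ``converged: False`` flag rather than raising.
    """
    if n < 1:
        raise ValueError("need n >= 1")
    target = wn.values
    if w0 is not None:
        target = np.linalg.solve(w0.values, wn.values)
    k = wn.space.n_states
    rng = np.random.default_rng(seed)

    def unpack(x: np.ndarray) -> np.ndarray:
        return _softmax_rows(x.reshape(k, k))

    def objective(x: np.ndarray) -> tuple[float, np.ndarray]:
        p = unpack(x)
        powers = [np.eye(k)]
        for _ in range(n - 1):
            powers.append(powers[-1] @ p)
        pn = powers[-1] @ p
        r = pn - target
        f = float((r * r).sum())
        # d f / d P = 2 * sum_k P^k^T R P^(n-1-k)^T
        g_p = np.zeros((k, k))
        for m in range(n):
            g_p += powers[m].T @ (2.0 * r) @ powers[n - 1 - m].T
        # softmax chain rule per row
        g_x = np.empty((k, k))
        for i in range(k):
            pi = p[i]
            g_x[i] = pi * (g_p[i] - pi @ g_p[i])
        return f, g_x.ravel()

    x0 = 0.1 * rng.standard_normal(k * k)
    # warm start from the regularized eigen-root when it exists
    try:
        eigvals, eigvecs = np.linalg.eig(target.astype(complex))
        guess = (eigvecs @ np.diag(eigvals ** (1.0 / n)) @ np.linalg.inv(eigvecs)).real
        guess = np.clip(guess, 1e-6, None)
        guess /= guess.sum(axis=1, keepdims=True)
        x0 = x0 + np.log(guess).ravel()
    except np.linalg.LinAlgError:
        pass

    res = minimize(
        objective,
        x0,
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "ftol": 1e-18, "gtol": 1e-14},
    )
    p = unpack(res.x)
    residual = float(np.linalg.norm(np.linalg.matrix_power(p, n) - target, "fro"))
    info = {
        "residual": residual,
        "converged": bool(res.success or residual < 1e-6),
        "iterations": int(res.nit),
        "seed": seed,
    }
    return TransitionMatrix(p, space=wn.space, provenance=[(wn.t, info)])


def extract_graph(p: TransitionMatrix, tau: float = 0.0) -> TransitionGraph:
    """Directed graph of the occurring direct transitions.

    An edge ``i -> j`` (``i != j``) is present when ``P[i, j]`` exceeds
    ``max(tau, EDGE_FLOOR)``; the floor removes pure floating-point dust.
    With K states there are ``K*(K-1)`` possible direct transitions.
    """
    import networkx as nx

    if tau < 0:
        raise ValueError("tau must be non-negative")
    thr = max(tau, EDGE_FLOOR)
    g = nx.DiGraph()
    g.add_nodes_from(p.labels)
    v = p.values
    for i, src in enumerate(p.labels):
        for j, dst in enumerate(p.labels):
            if i != j and v[i, j] > thr:
                g.add_edge(src, dst, weight=float(v[i, j]))
    return TransitionGraph(graph=g, tau=tau, n_states=p.space.n_states)


def estimate_transition_matrix(
    snapshots: list[ProportionMatrix],
    w0: ProportionMatrix | None = None,
    seed: int = 0,
) -> tuple[TransitionMatrix, list[RawRootMatrix]]:
    """Full estimation pipeline: root per snapshot, regularize, average.

    ``w0`` defaults to the identity at day 0 (pure starts).  Returns the
    averaged estimate together with the raw roots for diagnostics.
    """
    if not snapshots:
        raise ValueError("need at least one snapshot")
    space = snapshots[0].space
    if w0 is None:
        w0 = ProportionMatrix(np.eye(space.n_states), t=0, space=space)
    raws = [estimate_root(w0, wn, seed=seed) for wn in snapshots]
    per_day = [regularize(r) for r in raws]
    return average_estimates(per_day), raws
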