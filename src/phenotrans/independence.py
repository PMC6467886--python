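"""Per-marker coarse-graining and independence of marker transitions.

If switching between the positive and low/negative level of one marker
does not depend on the other markers, the full K-state chain factorizes
over markers and the 2-state chain obtained by coarse-graining the
proportion data for that marker has the same steady state as the
marginal of the full model's stationary distribution.  Large differences
between the two indicate that the marker's transitions are gated by the
other markers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .equilibrium import stationary_distribution
from .inference import TransitionMatrix, estimate_transition_matrix
from .io import ProportionMatrix
from .states import PLUS, MINUS, StateSpace, build_state_space

__all__ = [
    "MarkerResult",
    "MarkerIndependenceReport",
    "coarse_grain_proportions",
    "marginal_steady_state",
    "marker_independence_test",
]

#: conventional verdict threshold on the absolute steady-state difference;
#: printed with the report, configurable, and explicitly a convention
DEFAULT_VERDICT_THRESHOLD = 0.05


@dataclass
class MarkerResult:
    marker: str
    transition_2x2: np.ndarray  # estimated coarse-grained daily chain, (+, -) order
    steady_2state: np.ndarray  # stationary of the 2x2 chain
    steady_marginal: np.ndarray  # full-model stationary summed by marker sign
    abs_difference: float  # |difference| (symmetric across the two signs)
    degenerate: bool = False  # non-unique stationary in either route


@dataclass
class MarkerIndependenceReport:
    results: list[MarkerResult]
    threshold: float
    verdicts: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.verdicts:
            self.verdicts = {
                r.marker: (
                    "degenerate"
                    if r.degenerate
                    else ("independent" if r.abs_difference < self.threshold else "dependent")
                )
                for r in self.results
            }


def coarse_grain_proportions(
    w: ProportionMatrix, space: StateSpace, marker: str
) -> ProportionMatrix:
    """Collapse a K x K proportion matrix to the 2-state (+, -) chain of one marker.

    Columns (observed phenotypes) are summed within each sign group; rows
    (initial pure-start experiments) are averaged unweighted within each
    sign group — rows aggregate experiments, not cells, so each pure start
    carries equal weight.
    """
    pos = space.states_with(marker, PLUS)
    neg = space.states_with(marker, MINUS)
    v = w.values
    out = np.empty((2, 2))
    for r, rows in enumerate((pos, neg)):
        col_pos = v[np.ix_(rows, pos)].sum(axis=1)
        col_neg = v[np.ix_(rows, neg)].sum(axis=1)
        out[r, 0] = col_pos.mean()
        out[r, 1] = col_neg.mean()
    sub_space = build_state_space([marker])
    return ProportionMatrix(out, t=w.t, space=sub_space, condition=w.condition)


def marginal_steady_state(
    p_full: TransitionMatrix, space: StateSpace, marker: str
) -> tuple[np.ndarray, bool]:
    """(+, -) marginal of the full model's stationary distribution.

    Returns the 2-vector and a flag that is true when the stationary
    distribution is not unique (marginal then undefined).
    """
    eq = stationary_distribution(p_full)
    if not eq.unique:
        return np.full(2, np.nan), True
    pi = eq.pi.x
    pos = space.states_with(marker, PLUS)
    neg = space.states_with(marker, MINUS)
    return np.array([pi[pos].sum(), pi[neg].sum()]), False


def marker_independence_test(
    snapshots: list[ProportionMatrix],
    p_full: TransitionMatrix,
    space: StateSpace,
    threshold: float = DEFAULT_VERDICT_THRESHOLD,
    seed: int = 0,
) -> MarkerIndependenceReport:
    """Compare per-marker 2-state steady states with full-model marginals.

    For each marker the proportion snapshots are coarse-grained to 2 x 2
    matrices and pushed through the same root / regularize / average
    pipeline as the full model; the resulting 2-state stationary
    distribution is compared with the marginalized stationary distribution
    of ``p_full``.  Nearly equal proportions indicate that the marker's
    transitions are independent of the other markers.
    """
    if not snapshots:
        raise ValueError("need at least one proportion snapshot")
    results = []
    for marker in space.markers:
        coarse = [coarse_grain_proportions(w, space, marker) for w in snapshots]
        p2, _ = estimate_transition_matrix(coarse, seed=seed)
        eq2 = stationary_distribution(p2)
        marg, marg_degenerate = marginal_steady_state(p_full, space, marker)
        degenerate = marg_degenerate or not eq2.unique
        if degenerate:
            steady2 = np.full(2, np.nan) if not eq2.unique else eq2.pi.x
            diff = float("nan")
        else:
            steady2 = eq2.pi.x
            diff = float(abs(steady2[0] - marg[0]))
        results.append(
            MarkerResult(
                marker=marker,
                transition_2x2=p2.values,
                steady_2state=steady2,
                steady_marginal=marg,
                abs_difference=diff,
                degenerate=degenerate,
            )
        )
    return MarkerIndependenceReport(results=results, threshold=threshold)
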