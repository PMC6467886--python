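"""Marker-combination state spaces.

A phenotypic state is a combination of positive / low-negative status over
``m`` binary cell-membrane markers (e.g. CD133, CD44, CD15, A2B5), giving
``K = 2**m`` states.  The canonical order is lexicographic over sign
vectors with ``+`` sorting before ``-``, so the all-positive state comes
first; labels are ``P1 .. PK`` in that order.  Every matrix in the package
shares this ordering.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

__all__ = ["StateSpace", "build_state_space"]

PLUS = 1
MINUS = -1


@dataclass(frozen=True)
class StateSpace:
    """Ordered set of marker-combination phenotypes.

    Attributes
    ----------
    markers:
        Marker names, in the order used for sign vectors.
    signs:
        ``K`` sign vectors, each a tuple of ``+1`` / ``-1`` per marker,
        in canonical order (all-positive first).
    labels:
        State labels ``P1 .. PK`` aligned with ``signs``.
    """

    markers: tuple[str, ...]
    signs: tuple[tuple[int, ...], ...]
    labels: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        m = len(self.markers)
        if len(set(self.markers)) != m:
            raise ValueError("marker names must be unique")
        if len(self.signs) != 2**m:
            raise ValueError(f"expected {2**m} sign vectors, got {len(self.signs)}")
        if len(set(self.signs)) != len(self.signs):
            raise ValueError("sign vectors must be unique")
        if not self.labels:
            object.__setattr__(
                self, "labels", tuple(f"P{i + 1}" for i in range(len(self.signs)))
            )
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("state labels must be unique")

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def n_states(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown state label {label!r}") from None

    def marker_index(self, marker: str) -> int:
        try:
            return self.markers.index(marker)
        except ValueError:
            raise KeyError(f"unknown marker {marker!r}") from None

    def states_with(self, marker: str, sign: int) -> list[int]:
        """Indices of states with the given sign (+1 or -1) for `marker`."""
        j = self.marker_index(marker)
        return [i for i, s in enumerate(self.signs) if s[j] == sign]

    def describe(self, label: str) -> str:
        """Human-readable marker signature, e.g. ``CD133+CD44-``."""
        s = self.signs[self.index(label)]
        return "".join(f"{m}{'+' if v == PLUS else '-'}" for m, v in zip(self.markers, s))


def build_state_space(marker_names: list[str] | tuple[str, ...]) -> StateSpace:
    """Enumerate the ``2**m`` phenotypes of ``m`` binary markers.

    States are ordered lexicographically over sign vectors with ``+``
    before ``-``; the all-positive phenotype is ``P1`` and the
    all-negative one is the last state.

    Raises
    ------
    ValueError
        If no markers, more than 8 markers, or duplicate names are given.
    """
    markers = tuple(marker_names)
    if not 1 <= len(markers) <= 8:
        raise ValueError("need between 1 and 8 markers")
    if len(set(markers)) != len(markers):
        raise ValueError("marker names must be unique")
    signs = tuple(itertools.product((PLUS, MINUS), repeat=len(markers)))
    return StateSpace(markers=markers, signs=signs)
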