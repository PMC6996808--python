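"""Discretisation of body length into classes shared by all species.

Every species lives on one common grid of ``n_l`` half-open length
classes ``[lower_j, upper_j)`` in centimetres.  A fish "in class j" is
treated as having the class midpoint length, and the midpoint weight
``W_a * mid**W_b``, for all weight-based quantities (spawning-stock
biomass, predation suitability, catch weight).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["LengthGrid", "build_length_grid"]


@dataclass(frozen=True)
class LengthGrid:
    """Shared length discretisation.

    Parameters
    ----------
    lower, upper
        Class boundaries in cm; ``upper[j] == lower[j + 1]`` and both
        strictly increasing.  Classes are half-open ``[lower, upper)``.
    """

    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        lower = np.asarray(self.lower, dtype=float)
        upper = np.asarray(self.upper, dtype=float)
        object.__setattr__(self, "lower", lower)
        object.__setattr__(self, "upper", upper)
        if lower.ndim != 1 or lower.shape != upper.shape:
            raise ValueError("lower and upper bounds must be 1-d and equal length")
        if lower.size < 2:
            raise ValueError("a length grid needs at least 2 classes")
        if not np.all(upper > lower):
            raise ValueError("each upper bound must exceed its lower bound")
        if not (np.all(np.diff(lower) > 0) and np.all(np.diff(upper) > 0)):
            raise ValueError("class bounds must be strictly increasing")
        if not np.allclose(upper[:-1], lower[1:]):
            raise ValueError("classes must be contiguous: upper[j] == lower[j+1]")
        if lower[0] < 0:
            raise ValueError("lengths cannot be negative")

    @property
    def n_l(self) -> int:
        return self.lower.size

    @property
    def mid(self) -> np.ndarray:
        """Class midpoint lengths (cm)."""
        return 0.5 * (self.lower + self.upper)

    @property
    def width(self) -> np.ndarray:
        return self.upper - self.lower


def build_length_grid(
    n_l: int = 32,
    max_linf: float | None = None,
    bounds: np.ndarray | None = None,
) -> LengthGrid:
    """Build a length grid of ``n_l`` classes.

    With ``bounds`` omitted, returns ``n_l`` equal-width classes spanning
    ``(0, max_linf]`` — the conventional default grid, sized so the
    largest species' asymptotic length sits at the top of the grid.
    Explicit ``bounds`` (a vector of ``n_l + 1`` increasing edges)
    override both ``n_l`` and ``max_linf``.
    """
    if bounds is not None:
        edges = np.asarray(bounds, dtype=float)
        if edges.ndim != 1 or edges.size < 3:
            raise ValueError("bounds must be a 1-d vector of at least 3 edges")
        return LengthGrid(lower=edges[:-1], upper=edges[1:])
    if n_l < 2:
        raise ValueError("n_l must be at least 2")
    if max_linf is None or max_linf <= 0:
        raise ValueError("max_linf must be positive when bounds are omitted")
    edges = np.linspace(0.0, float(max_linf), n_l + 1)
    return LengthGrid(lower=edges[:-1], upper=edges[1:])
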