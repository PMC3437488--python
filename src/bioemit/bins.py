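"""Aerodynamic-diameter size bins: the coordinate system of every profile.

Cascade impactors classify particles by aerodynamic diameter (the diameter
of a unit-density sphere with the same settling velocity).  A stage collects
everything between its own cut-point and the next stage's, so a size
distribution is a set of ordered, non-overlapping diameter intervals.  All
concentration, loss-rate and emission profiles in this package are indexed
by such a grid, and operations refuse to combine profiles whose grids do
not match exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SizeBin", "SizeBinGrid", "IMPACTOR_BINS"]


@dataclass(frozen=True)
class SizeBin:
    """One aerodynamic-diameter interval [d_lo, d_hi) in micrometres."""

    d_lo: float
    d_hi: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.d_lo) and np.isfinite(self.d_hi)):
            raise ValueError(f"bin edges must be finite, got ({self.d_lo}, {self.d_hi})")
        if not 0 < self.d_lo < self.d_hi:
            raise ValueError(
                f"require 0 < d_lo < d_hi, got ({self.d_lo}, {self.d_hi})"
            )

    @property
    def dlog10(self) -> float:
        """Decadal-log width, log10(d_hi) - log10(d_lo)."""
        return float(np.log10(self.d_hi) - np.log10(self.d_lo))

    @property
    def midpoint_log(self) -> float:
        """Geometric-mean diameter (μm), the log-scale bin centre."""
        return float(np.sqrt(self.d_lo * self.d_hi))

    def __str__(self) -> str:
        return f"{self.d_lo:g}-{self.d_hi:g} um"


@dataclass(frozen=True)
class SizeBinGrid:
    """Ordered, non-overlapping sequence of :class:`SizeBin`."""

    bins: tuple[SizeBin, ...]

    def __post_init__(self) -> None:
        if len(self.bins) == 0:
            raise ValueError("a size-bin grid needs at least one bin")
        for a, b in zip(self.bins, self.bins[1:]):
            if b.d_lo < a.d_hi:
                raise ValueError(f"bins overlap or are unordered: {a} then {b}")

    @classmethod
    def from_edges(cls, edges) -> "SizeBinGrid":
        """Build a contiguous grid from a monotone sequence of edges (μm)."""
        edges = [float(e) for e in edges]
        return cls(tuple(SizeBin(lo, hi) for lo, hi in zip(edges, edges[1:])))

    def __len__(self) -> int:
        return len(self.bins)

    def __iter__(self):
        return iter(self.bins)

    def __getitem__(self, i: int) -> SizeBin:
        return self.bins[i]

    @property
    def d_lo(self) -> np.ndarray:
        return np.array([b.d_lo for b in self.bins])

    @property
    def d_hi(self) -> np.ndarray:
        return np.array([b.d_hi for b in self.bins])

    @property
    def dlog10(self) -> np.ndarray:
        return np.array([b.dlog10 for b in self.bins])

    def labels(self) -> list[str]:
        return [str(b) for b in self.bins]


#: The six-stage impactor grid used throughout: cut-points at 0.4, 1.1, 2.1,
#: 3.3, 4.7 and 9.0 μm, with the top (>9 μm) stage capped at 20 μm because
#: gravitational settling removes larger particles from room air too quickly
#: for them to be sampled.
IMPACTOR_BINS = SizeBinGrid.from_edges([0.4, 1.1, 2.1, 3.3, 4.7, 9.0, 20.0])
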