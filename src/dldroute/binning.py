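"""Shared-edge size histograms with a Freedman–Diaconis bin width.

All reservoirs in one analysis are binned on a single common grid so that the
per-bin conditional distributions are directly comparable.  The bin width is
chosen from the inlet (unsorted) sample by the Freedman–Diaconis rule
``2 · IQR · n^(-1/3)``; the grid is anchored at the pooled minimum so that
outlet sizes falling outside the inlet range remain representable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["BinGrid", "SizeHistogram", "freedman_diaconis_width", "build_grid", "histogram"]


@dataclass(frozen=True)
class BinGrid:
    """Equally spaced bin edges (μm) shared by all histograms of an analysis.

    Bins are half-open ``[lo, hi)``; the last bin additionally includes its
    upper edge so the grid covers its full closed range.
    """

    edges: np.ndarray
    width: float

    def __post_init__(self):
        edges = np.asarray(self.edges, dtype=float)
        object.__setattr__(self, "edges", edges)
        if edges.ndim != 1 or edges.size < 2:
            raise ValueError("grid needs at least two edges")
        steps = np.diff(edges)
        if np.any(np.abs(steps - self.width) > 1e-9):
            raise ValueError("edges must be equally spaced by the stated width")
        if self.width <= 0:
            raise ValueError("bin width must be > 0")

    @property
    def n_bins(self) -> int:
        return self.edges.size - 1

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    def find_bin(self, sizes) -> np.ndarray:
        """Bin index for each size under the half-open convention.

        Raises ``ValueError`` naming the first out-of-range value.
        """
        x = np.asarray(sizes, dtype=float)
        below = x < self.edges[0]
        above = x > self.edges[-1]
        if np.any(below | above):
            bad = x[below | above][0]
            raise ValueError(f"size {bad} outside grid range [{self.edges[0]}, {self.edges[-1]}]")
        idx = np.searchsorted(self.edges, x, side="right") - 1
        # values equal to the last edge belong to the last (closed) bin
        return np.minimum(idx, self.n_bins - 1)

    def same_grid(self, other: "BinGrid", tol: float = 1e-12) -> bool:
        return (
            self.edges.size == other.edges.size
            and bool(np.all(np.abs(self.edges - other.edges) <= tol))
        )


@dataclass(frozen=True)
class SizeHistogram:
    """Discrete size distribution ``P(d_i | reservoir)`` on a shared grid.

    ``counts`` holds raw per-bin counts (float so that mixture
    reconstructions, which carry fractional mass, reuse the same container);
    ``pmf`` is the exact normalisation ``counts / n``.  ``size_sums``, when
    available, holds the per-bin sum of member sizes, from which the
    within-bin mean size follows; it lets downstream estimators place each
    bin's probability at the density-weighted position rather than the
    geometric center.
    """

    grid: BinGrid
    counts: np.ndarray
    reservoir: str
    size_sums: np.ndarray | None = None

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "counts", counts)
        if counts.shape != (self.grid.n_bins,):
            raise ValueError("counts length must equal the number of bins")
        if np.any(counts < 0):
            raise ValueError("counts must be nonnegative")
        if self.size_sums is not None:
            sums = np.asarray(self.size_sums, dtype=float)
            object.__setattr__(self, "size_sums", sums)
            if sums.shape != counts.shape:
                raise ValueError("size_sums must have one entry per bin")

    @property
    def n(self) -> float:
        return float(self.counts.sum())

    @property
    def pmf(self) -> np.ndarray:
        total = self.counts.sum()
        if total == 0:
            return np.zeros_like(self.counts)
        return self.counts / total


def freedman_diaconis_width(sizes) -> float:
    """Freedman–Diaconis bin width ``2 · IQR · n^(-1/3)`` in μm.

    The IQR uses linear-interpolation quantiles.  Degenerate data fall back
    to ``(max - min) / ceil(sqrt(n))`` when the IQR is zero, and to 1.0 μm
    when all values coincide.
    """
    x = np.asarray(sizes, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 2:
        raise ValueError("need at least 2 finite sizes to choose a bin width")
    q25, q75 = np.percentile(x, [25.0, 75.0])  # linear interpolation (default)
    iqr = q75 - q25
    if iqr > 0:
        return float(2.0 * iqr * x.size ** (-1.0 / 3.0))
    lo, hi = float(x.min()), float(x.max())
    if hi > lo:
        return (hi - lo) / math.ceil(math.sqrt(x.size))
    return 1.0


def build_grid(inlet_sizes, all_sizes) -> BinGrid:
    """Common grid: width from the inlet, extent from the pooled data.

    Edges start at ``min(all_sizes)`` and extend in ``ceil(range / width)``
    equal steps to cover ``max(all_sizes)``.
    """
    inlet = np.asarray(inlet_sizes, dtype=float)
    pooled = np.asarray(all_sizes, dtype=float)
    if inlet.size == 0 or pooled.size == 0:
        raise ValueError("inlet and pooled size collections must be nonempty")
    width = freedman_diaconis_width(inlet)
    lo = float(pooled.min())
    hi = float(pooled.max())
    n_bins = max(1, math.ceil((hi - lo) / width)) if hi > lo else 1
    edges = lo + width * np.arange(n_bins + 1)
    # guard against a float-rounding shortfall at the top edge
    while edges[-1] < hi:
        edges = np.append(edges, edges[-1] + width)
    return BinGrid(edges=edges, width=width)


def histogram(sizes, grid: BinGrid, reservoir: str) -> SizeHistogram:
    """Bin sizes on the shared grid; counts are conserved by construction."""
    x = np.asarray(sizes, dtype=float)
    idx = grid.find_bin(x)
    counts = np.bincount(idx, minlength=grid.n_bins).astype(float)
    sums = np.bincount(idx, weights=x, minlength=grid.n_bins)
    return SizeHistogram(grid=grid, counts=counts, reservoir=reservoir, size_sums=sums)
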