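"""Routing probabilities ``P(outlet | size)`` by the conditional-probability identity.

Two equivalent estimators are provided.  When per-bin, per-outlet counts
``n_{d_i,k}`` are available directly, the routing probability is the count
ratio

    P(k | d_i) = n_{d_i,k} / sum_j n_{d_i,j}.

When only the outlet size distributions ``P(d_i | k)`` and the outlet
fractions ``P(k)`` are measured -- the experimentally accessible quantities --
the identity

    P(k | d_i) = P(k) P(d_i | k) / sum_j P(j) P(d_i | j)

gives the same table exactly (the unknown total particle count cancels under
the no-loss assumption).  Bins where no outlet has mass are *undefined*, not
zero: an explicit mask records them and downstream consumers must consult it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from dldroute.binning import BinGrid, SizeHistogram
from dldroute.io import OUTLETS

__all__ = ["RoutingTable", "routing_from_distributions", "routing_from_counts", "reconstruct_inlet"]


@dataclass(frozen=True)
class RoutingTable:
    """Per-bin routing probabilities with an undefined-bin mask.

    ``probs[i, j]`` is ``P(outlet_j | d_i)`` with outlets ordered as
    :data:`dldroute.io.OUTLETS` (small, medium, large).  ``support[i]`` is
    the per-bin particle mass behind the estimate (raw counts or the
    reconstructed inlet mixture), used for tie-breaking and yield weighting.

    ``abscissa[i]`` is the size at which bin i's probabilities are taken to
    apply when interpolating between bins: the density-weighted within-bin
    mean size where the source histograms provide it, otherwise the
    geometric bin center.  Using the weighted position removes the small
    systematic shift that a sloping size density across a bin would
    otherwise impose on the crossover estimate.
    """

    grid: BinGrid
    probs: np.ndarray
    defined: np.ndarray
    support: np.ndarray
    abscissa: np.ndarray | None = None

    def __post_init__(self):
        probs = np.asarray(self.probs, dtype=float)
        defined = np.asarray(self.defined, dtype=bool)
        support = np.asarray(self.support, dtype=float)
        object.__setattr__(self, "probs", probs)
        object.__setattr__(self, "defined", defined)
        object.__setattr__(self, "support", support)
        n = self.grid.n_bins
        if self.abscissa is None:
            object.__setattr__(self, "abscissa", self.grid.centers)
        else:
            abscissa = np.asarray(self.abscissa, dtype=float)
            object.__setattr__(self, "abscissa", abscissa)
            if abscissa.shape != (n,):
                raise ValueError("abscissa must have one entry per bin")
        if probs.shape != (n, len(OUTLETS)):
            raise ValueError(f"probs must have shape ({n}, {len(OUTLETS)})")
        if defined.shape != (n,) or support.shape != (n,):
            raise ValueError("defined mask and support must have one entry per bin")
        d = probs[defined]
        if d.size and (np.any(d < -1e-12) or np.any(d > 1 + 1e-12)):
            raise ValueError("routing probabilities must lie in [0, 1]")
        if d.size and np.any(np.abs(d.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("each defined routing row must sum to 1")

    def column(self, outlet: str) -> np.ndarray:
        return self.probs[:, OUTLETS.index(outlet)]

    def to_rows(self) -> list[dict]:
        """Serializable per-bin view: center, P(S), P(M), P(L), defined flag."""
        centers = self.grid.centers
        return [
            {
                "bin_center_um": float(centers[i]),
                "p_small": float(self.probs[i, 0]),
                "p_medium": float(self.probs[i, 1]),
                "p_large": float(self.probs[i, 2]),
                "defined": bool(self.defined[i]),
            }
            for i in range(self.grid.n_bins)
        ]


def _check_common_grid(histograms: Mapping[str, SizeHistogram]) -> BinGrid:
    grids = [histograms[k].grid for k in OUTLETS]
    for g in grids[1:]:
        if g is not grids[0] and not grids[0].same_grid(g):
            raise ValueError("outlet histograms must share one common bin grid")
    return grids[0]


def _check_fractions(fractions: Mapping[str, float]) -> np.ndarray:
    p = np.asarray([float(fractions[k]) for k in OUTLETS])
    if np.any(p < 0):
        raise ValueError("outlet fractions must be nonnegative")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"outlet fractions must sum to 1, got {p.sum()!r}")
    return p


def routing_from_distributions(
    outlet_histograms: Mapping[str, SizeHistogram],
    fractions: Mapping[str, float],
) -> RoutingTable:
    """Routing table from outlet size distributions and outlet fractions.

    ``P(k | d_i) = P(k) P(d_i | k) / sum_j P(j) P(d_i | j)``; bins with a
    zero denominator are masked undefined.  The per-bin support is the
    reconstructed inlet mass ``sum_j P(j) P(d_i | j)``.
    """
    grid = _check_common_grid(outlet_histograms)
    p_k = _check_fractions(fractions)
    joint = np.stack([p_k[j] * outlet_histograms[k].pmf for j, k in enumerate(OUTLETS)], axis=1)
    denom = joint.sum(axis=1)
    defined = denom > 0
    probs = np.zeros_like(joint)
    probs[defined] = joint[defined] / denom[defined, None]
    # density-weighted abscissa from per-bin size sums where available
    weighted = np.zeros(grid.n_bins)
    for j, k in enumerate(OUTLETS):
        h = outlet_histograms[k]
        n_k = h.counts.sum()
        if n_k == 0:
            continue
        sums = h.size_sums if h.size_sums is not None else h.counts * grid.centers
        weighted += p_k[j] * sums / n_k
    abscissa = np.where(defined, np.divide(weighted, denom, out=grid.centers.copy(), where=defined), grid.centers)
    return RoutingTable(grid=grid, probs=probs, defined=defined, support=denom, abscissa=abscissa)


def routing_from_counts(count_table, grid: BinGrid | None = None) -> RoutingTable:
    """Routing table directly from per-bin, per-outlet counts.

    ``count_table`` is an ``(n_bins, 3)`` array of nonnegative counts in
    outlet order (small, medium, large).  Without a grid, a unit-width index
    grid is synthesised so the table can stand alone in tests.
    """
    counts = np.asarray(count_table, dtype=float)
    if counts.ndim != 2 or counts.shape[1] != len(OUTLETS):
        raise ValueError("count table must have one column per outlet (small, medium, large)")
    if np.any(counts < 0):
        raise ValueError("counts must be nonnegative")
    if grid is None:
        edges = np.arange(counts.shape[0] + 1, dtype=float)
        grid = BinGrid(edges=edges, width=1.0)
    elif grid.n_bins != counts.shape[0]:
        raise ValueError("count table length must match the grid")
    totals = counts.sum(axis=1)
    defined = totals > 0
    probs = np.zeros_like(counts)
    probs[defined] = counts[defined] / totals[defined, None]
    return RoutingTable(grid=grid, probs=probs, defined=defined, support=totals)


def reconstruct_inlet(
    outlet_histograms: Mapping[str, SizeHistogram],
    fractions: Mapping[str, float],
) -> SizeHistogram:
    """Inlet size distribution implied by the outlets under no loss.

    The mixture ``P(d_i) = sum_k P(k) P(d_i | k)`` is the inlet distribution
    the device must have seen if every particle reached an outlet.  Useful
    both as the yield weighting and as a consistency check against a
    separately measured inlet.
    """
    grid = _check_common_grid(outlet_histograms)
    p_k = _check_fractions(fractions)
    pmf = np.zeros(grid.n_bins)
    for j, k in enumerate(OUTLETS):
        pmf += p_k[j] * outlet_histograms[k].pmf
    return SizeHistogram(grid=grid, counts=pmf, reservoir="inlet")
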