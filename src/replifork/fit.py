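"""Fixed-knot piecewise-linear fit of the log2 replication profile.

The "connecting points" are fitted values of the log2 relative marker
frequency at the segment boundaries.  With the knot abscissae fixed at
those boundaries, minimising the root-mean-square deviation between the
retained bins and the piecewise-linear curve is an ordinary linear
least-squares problem on a hat-function (linear spline) basis: each bin
contributes weight ``1 - u`` to its upstream knot and ``u`` to its
downstream knot, where ``u`` is its fractional position inside the
segment.

The directed segments form a continuous chain around the circle —
continuity at their shared knots holds by construction.  The chain is
broken at the two ``ter`` boundaries: the termination zone contains a
V-shaped feature (forks converging from both sides, with an inverted
slope on the trapped-fork side in two-origin strains) that a single
straight line cannot follow, and welding its endpoints to the chain
would bias the neighbouring segments' knots.  ``ter`` is therefore
fitted with its own two endpoint values and only flagged, never used in
downstream averages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateDataError, InsufficientDataError
from .genome import FORWARD, SegmentSet
from .profiles import CorrectedProfile, bin_centers

MIN_BINS_PER_SEGMENT = 5


@dataclass(frozen=True)
class PiecewiseFit:
    """Connecting-point fit over a :class:`SegmentSet`.

    ``segment_names`` lists the segments in genomic order; ``segment_values``
    maps each to its fitted log2 values at its genomic (start, end) boundary
    and ``segment_slopes`` to its slope in log2 units per Mbp along the +1
    genomic direction.  Values at a shared boundary coincide for the directed
    segments; the ``ter`` endpoints are free.
    """

    segment_names: tuple[str, ...]
    segment_values: dict[str, tuple[float, float]]
    segment_slopes: dict[str, float]
    segment_bounds: dict[str, tuple[int, int]]
    rmsd: float
    n_bins_used: int
    genome_length: int

    @property
    def knot_positions(self) -> np.ndarray:
        return np.array([self.segment_bounds[n][0] for n in self.segment_names])

    @property
    def knot_values(self) -> np.ndarray:
        return np.array([self.segment_values[n][0] for n in self.segment_names])

    def predict(self, positions: np.ndarray) -> np.ndarray:
        """Evaluate the fitted piecewise-linear curve at genomic positions."""
        positions = np.atleast_1d(np.asarray(positions, dtype=float)) % self.genome_length
        out = np.full(positions.shape, np.nan)
        L = self.genome_length
        for name in self.segment_names:
            start, end = self.segment_bounds[name]
            length = (end - start) % L
            v0, v1 = self.segment_values[name]
            off = (positions - start) % L
            sel = off < length
            out[sel] = v0 + (v1 - v0) * off[sel] / length
        return out


def fit_connecting_points(
    profile: CorrectedProfile,
    segset: SegmentSet,
    min_bins: int = MIN_BINS_PER_SEGMENT,
) -> PiecewiseFit:
    """Least-squares connecting-point fit of ``profile`` over ``segset``.

    Raises :class:`InsufficientDataError` naming the first segment with fewer
    than ``min_bins`` retained bins, and :class:`DegenerateDataError` if the
    normal equations are singular (no interior data in some segment).
    """
    L = segset.genome_length
    ordered = segset.in_genomic_order()
    # Rotate so the chain starts right after ter and ends at ter.
    ter_idx = next(i for i, s in enumerate(ordered) if s.fork_direction is None)
    chain = ordered[ter_idx + 1:] + ordered[:ter_idx]
    ter = ordered[ter_idx]
    n_chain = len(chain)

    # Unknowns: chain knots 0..n_chain (open chain, shared boundaries),
    # then the two free ter endpoints.
    n_unknowns = n_chain + 1 + 2
    centers = bin_centers(profile.genome_length, profile.bin_size)
    use = profile.mask & np.isfinite(profile.log2_freq)
    x = centers[use]
    y = profile.log2_freq[use]
    n = len(x)
    A = np.zeros((n, n_unknowns))
    assigned = np.zeros(n, dtype=bool)

    def add_segment(seg, col0: int, col1: int) -> int:
        off = (x - seg.start) % L
        sel = (off < seg.length) & ~assigned
        assigned[sel] = True
        frac = off[sel] / seg.length
        rows = np.flatnonzero(sel)
        A[rows, col0] = 1.0 - frac
        A[rows, col1] = frac
        return int(sel.sum())

    for i, seg in enumerate(chain):
        c = add_segment(seg, i, i + 1)
        if c < min_bins:
            raise InsufficientDataError(
                f"segment {seg.name} has {c} retained bins (< {min_bins})"
            )
    c = add_segment(ter, n_chain + 1, n_chain + 2)
    if c < min_bins:
        raise InsufficientDataError(
            f"segment ter has {c} retained bins (< {min_bins})"
        )

    gram = A.T @ A
    if np.linalg.matrix_rank(gram) < n_unknowns:
        raise DegenerateDataError("singular connecting-point system")
    theta = np.linalg.solve(gram, A.T @ y)
    residuals = A @ theta - y
    rmsd = float(np.sqrt(np.mean(residuals**2)))

    names = tuple(s.name for s in ordered)
    values: dict[str, tuple[float, float]] = {}
    slopes: dict[str, float] = {}
    bounds: dict[str, tuple[int, int]] = {}
    for i, seg in enumerate(chain):
        v0, v1 = float(theta[i]), float(theta[i + 1])
        values[seg.name] = (v0, v1)
        slopes[seg.name] = (v1 - v0) / (seg.length / 1e6)
        bounds[seg.name] = (seg.start, seg.end)
    v0, v1 = float(theta[n_chain + 1]), float(theta[n_chain + 2])
    values[ter.name] = (v0, v1)
    slopes[ter.name] = (v1 - v0) / (ter.length / 1e6)
    bounds[ter.name] = (ter.start, ter.end)

    return PiecewiseFit(
        segment_names=names,
        segment_values=values,
        segment_slopes=slopes,
        segment_bounds=bounds,
        rmsd=rmsd,
        n_bins_used=n,
        genome_length=L,
    )


def segment_slopes(fit: PiecewiseFit, segset: SegmentSet) -> dict[str, float]:
    """Per-segment slope re-signed along the fork's travel direction.

    Positive means the log2 frequency decreases in the direction the fork
    moves (the orientation the marker-frequency equations expect).  Segments
    without a single fork direction (``ter``) are omitted.
    """
    out: dict[str, float] = {}
    for seg in segset:
        if seg.fork_direction is None:
            continue
        if seg.name not in fit.segment_slopes:
            raise KeyError(f"segment {seg.name} absent from fit")
        genomic = fit.segment_slopes[seg.name]
        out[seg.name] = -genomic if seg.fork_direction == FORWARD else genomic
    return out
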