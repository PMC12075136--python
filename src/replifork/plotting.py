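"""Semi-logarithmic replication-profile plots (log2 ordinate, per-segment
colouring, connecting points marked)."""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .fit import PiecewiseFit
from .genome import SegmentSet
from .profiles import CorrectedProfile, bin_centers

SEGMENT_COLORS = {
    "X_L": "#1f77b4", "X_R": "#9467bd", "C_L": "#d62728", "C_R": "#ff7f0e",
    "L2": "#2ca02c", "R2": "#17becf", "R3": "#8c564b", "ter": "#7f7f7f",
}


def plot_profiles(
    profiles: Sequence[CorrectedProfile],
    fits: Optional[Sequence[PiecewiseFit]],
    segset: SegmentSet,
    path,
) -> None:
    """One panel per sample: log2 relative frequency coloured by segment,
    with the fitted connecting lines and their knots overlaid."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    n = len(profiles)
    fig, axes = plt.subplots(n, 1, figsize=(10, 3 * n), squeeze=False, sharex=True)
    for row, profile in enumerate(profiles):
        ax = axes[row][0]
        x = bin_centers(profile.genome_length, profile.bin_size)
        for seg in segset:
            sel = profile.mask.copy()
            dist = (x - seg.start) % profile.genome_length
            sel &= dist < seg.length
            ax.plot(x[sel] / 1e6, profile.log2_freq[sel], ".", ms=1.5,
                    color=SEGMENT_COLORS.get(seg.name, "k"), label=seg.name)
        if fits is not None:
            fit = fits[row]
            grid = np.linspace(0, profile.genome_length - 1, 2000)
            ax.plot(grid / 1e6, fit.predict(grid), "-", color="0.4", lw=1)
            ax.plot(fit.knot_positions / 1e6, fit.knot_values, "o",
                    color="0.3", ms=5, mfc="0.7")
        ax.set_ylabel(f"{profile.sample_id}\nlog2 relative frequency")
        if row == 0:
            ax.legend(ncol=4, fontsize=7, markerscale=6)
    axes[-1][0].set_xlabel("genome position (Mbp)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
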