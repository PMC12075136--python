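"""Replication fork speed and derived statistics from marker frequencies.

The marker-frequency framework for a steady-state exponential culture:
the copy-number ratio of two loci at fractional replichore positions
``m_x < m_y`` is ``N_X/N_Y = 2**((m_y - m_x) * C / tau)`` where ``C`` is
the origin-to-terminus replication time and ``tau`` the doubling time.
Allowing the replication time to vary locally defines ``C_XY`` for an
interval, from which the local fork speed follows as
``v_XY = (M_Y - M_X) / (tau * log2(N_X/N_Y))`` with absolute positions M,
and in the shrinking-interval limit ``v = 1 / (tau * d(log2 N)/dM)``.

Derived indices
---------------
* **average RFS** — length-weighted mean of the per-segment speeds, ter
  excluded (optionally restricted to L2, X_L, C_R, R2).
* **O-P/O-D ratio** — length-weighted mean speed of the origin-proximal
  segments over the origin-distal ones; 1 means uniform speed.
* **synchrony index** — converging-over-diverging ratio of the fitted
  log2 gradient magnitudes of the four origin-proximal segments
  (equivalently, the diverging-over-converging ratio of apparent speeds).
  With both origins firing in every cell it is 1; initiation failure at
  one origin in a fraction of cells flattens the converging segments
  (X_R, C_L) relative to the diverging ones (X_L, C_R) and depresses the
  index below 1 — about 0.78 when a quarter of the cells fail.
* **origin ratio** — mean relative read density around oriX over oriC;
  close to 1 when both origins fire with equal efficiency.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np

from .errors import (
    ConfigurationError,
    DegenerateDataError,
    InsufficientDataError,
    NotApplicableError,
    OrientationError,
)
from .fit import PiecewiseFit, fit_connecting_points, segment_slopes
from .genome import (
    CONVERGING,
    DIVERGING,
    ORIGIN_DISTAL,
    ORIGIN_PROXIMAL,
    RESTRICTED,
    SegmentSet,
    StrainConfig,
)
from .profiles import CorrectedProfile, bin_centers

DEFAULT_PEAK_WINDOW = 20_000


# ---------------------------------------------------------------------------
# the marker-frequency equations
# ---------------------------------------------------------------------------

def marker_ratio(C: float, tau: float, m_x: float, m_y: float) -> float:
    """Copy-number ratio N_X/N_Y for loci at fractional positions m_x < m_y.

    Special case m_x=0, m_y=1 gives the origin/terminus ratio ``2**(C/tau)``.
    """
    if tau <= 0 or C < 0:
        raise ConfigurationError("require tau > 0 and C >= 0")
    if not (0 <= m_x < m_y <= 1):
        raise OrientationError(f"require 0 <= m_x < m_y <= 1, got {m_x}, {m_y}")
    return 2.0 ** ((m_y - m_x) * C / tau)


def local_replication_time(ratio: float, m_x: float, m_y: float, tau: float) -> float:
    """Local replication time C_XY from an observed marker ratio (inverse of
    :func:`marker_ratio`): the time to replicate a whole replichore if the
    speed seen between m_x and m_y were maintained throughout."""
    if tau <= 0:
        raise ConfigurationError("require tau > 0")
    if not (0 <= m_x < m_y <= 1):
        raise OrientationError(f"require 0 <= m_x < m_y <= 1, got {m_x}, {m_y}")
    if ratio <= 1:
        raise OrientationError(
            f"marker ratio {ratio} <= 1: frequency must decrease away from the origin"
        )
    return tau * math.log2(ratio) / (m_y - m_x)


def segment_rfs(M_x: float, M_y: float, ratio: float, tau: float) -> float:
    """Fork speed over an interval, ``(M_y - M_x) / (tau * log2(ratio))``.

    ``M_x`` and ``M_y`` are absolute positions along the fork path, ``ratio``
    the marker frequency ratio N_X/N_Y across them; the result carries the
    units of the positions per unit of ``tau`` (kbp and seconds give kbp/s).
    """
    if tau <= 0:
        raise ConfigurationError("require tau > 0")
    if M_y - M_x <= 0:
        raise OrientationError("require M_y > M_x along the fork path")
    if ratio <= 1:
        raise OrientationError(
            f"marker ratio {ratio} <= 1: frequency must decrease along the fork path"
        )
    return (M_y - M_x) / (tau * math.log2(ratio))


def instantaneous_rfs(slope: float, tau: float) -> float:
    """Instantaneous fork speed from the log2-frequency gradient along the
    fork direction (``slope`` in log2 units per bp, positive when frequency
    falls along fork travel).  Returns bp per time-unit of ``tau``."""
    if tau <= 0:
        raise ConfigurationError("require tau > 0")
    if slope <= 0:
        raise OrientationError(
            f"slope {slope} <= 0 along fork direction (orientation violation)"
        )
    return 1.0 / (tau * slope)


# ---------------------------------------------------------------------------
# aggregation over segments
# ---------------------------------------------------------------------------

def _weighted_mean(values: Sequence[float], weights: Sequence[float]) -> float:
    w = np.asarray(weights, dtype=float)
    v = np.asarray(values, dtype=float)
    return float((v * w).sum() / w.sum())


def weighted_average_rfs(
    segset: SegmentSet,
    per_segment_v: dict[str, float],
    mode: Literal["full", "restricted"] = "full",
) -> float:
    """Length-weighted average fork speed, ter always excluded.

    ``restricted`` uses only L2, X_L, C_R and R2 (for two-origin samples in
    which the converging segments are suspect)."""
    names = RESTRICTED if mode == "restricted" else [
        s.name for s in segset if s.name != "ter"
    ]
    missing = [n for n in names if n not in per_segment_v]
    if missing:
        raise InsufficientDataError(f"no speed for segments {missing}")
    if not names:
        raise DegenerateDataError("no segments to average")
    return _weighted_mean(
        [per_segment_v[n] for n in names], [segset[n].length for n in names]
    )


def op_od_ratio(
    segset: SegmentSet,
    per_segment_v: dict[str, float],
    mode: Literal["full", "restricted"] = "full",
) -> float:
    """Origin-proximal over origin-distal length-weighted mean fork speed.

    1 means equivalent speeds; below 1 means slower forks near the origin(s).
    ``restricted`` drops the converging segments and R3: {X_L, C_R} over
    {L2, R2}."""
    if mode == "restricted":
        op, od = DIVERGING, ("L2", "R2")
    else:
        op, od = ORIGIN_PROXIMAL, ORIGIN_DISTAL
    for n in (*op, *od):
        if n not in per_segment_v:
            raise InsufficientDataError(f"no speed for segment {n}")
    num = _weighted_mean([per_segment_v[n] for n in op], [segset[n].length for n in op])
    den = _weighted_mean([per_segment_v[n] for n in od], [segset[n].length for n in od])
    return num / den


def synchrony_index(segset: SegmentSet, slopes_along_fork: dict[str, float]) -> float:
    """Initiation-synchrony index of a two-origin strain.

    Length-weighted mean log2-gradient magnitude of the converging segments
    (X_R, C_L) divided by that of the diverging segments (X_L, C_R).  Equal
    gradients — every cell firing both origins — give 1; initiation failure
    at one origin flattens the converging segments and pushes the index
    below 1 (~0.78 at 25% failure).
    """
    if segset.strain_mode != "two-origin":
        raise NotApplicableError("synchrony index requires a two-origin strain")
    for n in (*CONVERGING, *DIVERGING):
        if n not in slopes_along_fork:
            raise InsufficientDataError(f"no fitted slope for segment {n}")
        if slopes_along_fork[n] <= 0:
            raise OrientationError(
                f"segment {n}: log2 frequency does not fall along the fork direction"
            )
    conv = _weighted_mean(
        [slopes_along_fork[n] for n in CONVERGING],
        [segset[n].length for n in CONVERGING],
    )
    div = _weighted_mean(
        [slopes_along_fork[n] for n in DIVERGING],
        [segset[n].length for n in DIVERGING],
    )
    return conv / div


def origin_ratio(
    profile: CorrectedProfile,
    config: StrainConfig,
    segset: SegmentSet,
    peak_window: int = DEFAULT_PEAK_WINDOW,
) -> float:
    """Mean relative read density around oriX divided by that around oriC.

    ``peak_window`` is the total window width (bp) centred on each origin;
    it must stay inside the origin-proximal segments.
    """
    if not config.two_origin:
        raise NotApplicableError("origin ratio requires a two-origin strain")
    half = peak_window / 2.0
    min_adjacent = min(segset[n].length for n in ORIGIN_PROXIMAL)
    if half > min_adjacent:
        raise ConfigurationError(
            f"peak_window {peak_window} overlaps beyond the origin-proximal "
            f"segments (adjacent segment length {min_adjacent})"
        )
    centers = bin_centers(profile.genome_length, profile.bin_size)
    L = profile.genome_length

    def peak_mean(pos: int) -> float:
        dist = np.abs((centers - pos + L / 2) % L - L / 2)
        sel = (dist <= half) & profile.mask
        if not sel.any():
            raise DegenerateDataError(f"no retained bins within {half} bp of {pos}")
        return float(np.nanmean(profile.rel_freq[sel]))

    return peak_mean(config.oriX_pos) / peak_mean(config.oriC_pos)


# ---------------------------------------------------------------------------
# doubling time
# ---------------------------------------------------------------------------

def doubling_time(times: Sequence[float], ods: Sequence[float]) -> tuple[float, float]:
    """Doubling time from log-linear regression of optical density on time.

    Requires at least eight readings in exponential phase.  Returns
    ``(tau, r_squared)`` with ``tau`` in the units of ``times``.
    """
    from scipy import stats

    t = np.asarray(times, dtype=float)
    od = np.asarray(ods, dtype=float)
    if len(t) != len(od):
        raise ConfigurationError("times and ODs differ in length")
    if len(t) < 8:
        raise InsufficientDataError(
            f"{len(t)} readings; at least eight are required"
        )
    if np.any(od <= 0):
        raise ConfigurationError("optical densities must be positive")
    if np.any(np.diff(t) <= 0):
        raise ConfigurationError("times must be strictly increasing")
    res = stats.linregress(t, np.log(od))
    if res.slope <= 0:
        raise DegenerateDataError("non-positive growth slope: culture not growing")
    return math.log(2) / res.slope, float(res.rvalue**2)


# ---------------------------------------------------------------------------
# end-to-end analysis of one corrected profile
# ---------------------------------------------------------------------------

@dataclass
class RFSResult:
    """Per-segment fork speeds and the derived indices for one sample."""

    sample_id: str
    tau: float
    per_segment_v: dict[str, float]  # kbp/s, ter excluded
    per_segment_C: dict[str, float]  # seconds (whole-replichore equivalent)
    average_v: float                 # kbp/s, length-weighted, ter excluded
    average_v_restricted: Optional[float]
    op_od: float
    op_od_restricted: Optional[float]
    synchrony: Optional[float]
    origin_ratio_value: Optional[float]
    rmsd: float
    fit: PiecewiseFit = field(repr=False)
    mode_flags: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "tau_s": self.tau,
            "per_segment_v_kbps": {k: round(v, 6) for k, v in self.per_segment_v.items()},
            "per_segment_C_s": {k: round(v, 3) for k, v in self.per_segment_C.items()},
            "average_v_kbps": round(self.average_v, 6),
            "average_v_restricted_kbps": (
                None if self.average_v_restricted is None
                else round(self.average_v_restricted, 6)
            ),
            "op_od_ratio": round(self.op_od, 6),
            "op_od_ratio_restricted": (
                None if self.op_od_restricted is None else round(self.op_od_restricted, 6)
            ),
            "synchrony_index": (
                None if self.synchrony is None else round(self.synchrony, 6)
            ),
            "origin_ratio": (
                None if self.origin_ratio_value is None
                else round(self.origin_ratio_value, 6)
            ),
            "fit_rmsd_log2": round(self.rmsd, 9),
            "mode_flags": self.mode_flags,
        }


def analyze_profile(
    profile: CorrectedProfile,
    segset: SegmentSet,
    tau: float,
    config: Optional[StrainConfig] = None,
    peak_window: int = DEFAULT_PEAK_WINDOW,
) -> RFSResult:
    """Fit connecting points and derive every fork-speed statistic.

    ``tau`` is the doubling time in seconds.  Orientation violations in
    non-ter segments raise :class:`OrientationError`; an inverted ter-region
    slope is expected in two-origin strains and only flagged.
    """
    if tau <= 0:
        raise ConfigurationError("tau must be positive")
    config = config or segset.config
    pw_fit = fit_connecting_points(profile, segset)
    slopes = segment_slopes(pw_fit, segset)  # log2 per Mbp along fork direction

    per_v: dict[str, float] = {}
    per_C: dict[str, float] = {}
    for seg in segset:
        if seg.name == "ter":
            continue
        s = slopes[seg.name]
        if s <= 0:
            raise OrientationError(
                f"segment {seg.name}: log2 frequency rises along the fork "
                "direction; check geometry/strain mode"
            )
        v_bps = instantaneous_rfs(s / 1e6, tau)  # slope per Mbp -> per bp
        per_v[seg.name] = v_bps / 1000.0  # kbp/s
        if config is not None:
            r_l = config.replichore_length(seg.origin_of_fork, seg.fork_direction)
            per_C[seg.name] = r_l / v_bps

    flags = {
        "segments": list(per_v),
        "ter_slope_genomic_log2_per_Mbp": pw_fit.segment_slopes.get("ter"),
    }

    two_origin = segset.strain_mode == "two-origin"
    synchrony = synchrony_index(segset, slopes) if two_origin else None
    ori_ratio = None
    if two_origin and config is not None and config.two_origin:
        ori_ratio = origin_ratio(profile, config, segset, peak_window)

    return RFSResult(
        sample_id=profile.sample_id,
        tau=tau,
        per_segment_v=per_v,
        per_segment_C=per_C,
        average_v=weighted_average_rfs(segset, per_v, "full"),
        average_v_restricted=(
            weighted_average_rfs(segset, per_v, "restricted") if two_origin else None
        ),
        op_od=op_od_ratio(segset, per_v, "full"),
        op_od_restricted=(
            op_od_ratio(segset, per_v, "restricted") if two_origin else None
        ),
        synchrony=synchrony,
        origin_ratio_value=ori_ratio,
        rmsd=pw_fit.rmsd,
        fit=pw_fit,
        mode_flags=flags,
    )
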