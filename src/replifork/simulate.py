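"""Steady-state cell-cycle coverage simulator for circular chromosomes.

A culture in balanced exponential growth has the cell-age density
``p(a) = (2 ln 2 / tau) * 2**(-a/tau)`` on ``[0, tau]``.  A locus whose
replication finishes at cell age ``a(m) = initiation_age + t(m)`` is
present in one copy in younger cells and two in older ones, so its
expected per-cell copy number is ``2 * 2**(-a(m)/tau)`` — the simulated
counterpart of the marker-frequency equation.  Growth is slow (doubling
time exceeds B + C): replication rounds never overlap, which the
simulator enforces.

Fork kinematics: forks move outward from each firing origin; converging
forks meet where their arrival times are equal; forks travelling along
the right replichore direction are arrested at *terC* and forks
travelling the other way at *terA* (a fork arriving at its trap waits for
the opposing fork).  The common fork speed may switch when the number of
moving forks changes (v4 -> v2 -> v1 in the two-origin strain).

Initiation-failure mixtures: a fraction ``f`` of cells fire only one of
the two origins.  All classes share the initiation age and must complete
replication within the cycle; their expected copy-number profiles are
mixed with class-independent proportionality (the per-cell copy number
``2 * 2**(-a(m)/tau)`` carries the same constant in every class), then
normalised once.

Per-bin read counts are Poisson draws around ``depth`` times the
bias-weighted expected frequencies, reproducible from a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import ConfigurationError, SimulationError
from .genome import StrainConfig, advance, circular_span
from .profiles import BinnedProfile, CorrectedProfile, bin_centers, n_bins

_POS_EPS = 1e-6  # bp tolerance for coincident event positions


@dataclass(frozen=True)
class SpeedProfile:
    """Fork speed (bp/s) as a function of the number of moving forks.

    ``v4`` applies while four or more forks move, ``v2`` for two or three,
    ``v1`` for a single fork.  Three moving forks is a transient state of
    asymmetric geometries and is assigned the two-fork speed.
    """

    v4: float
    v2: float
    v1: float

    def __post_init__(self) -> None:
        if min(self.v4, self.v2, self.v1) <= 0:
            raise ConfigurationError("fork speeds must be positive")

    @classmethod
    def constant(cls, v: float) -> "SpeedProfile":
        return cls(v, v, v)

    @classmethod
    def from_kbps(cls, v4: float, v2: float, v1: float) -> "SpeedProfile":
        return cls(v4 * 1000.0, v2 * 1000.0, v1 * 1000.0)

    def speed_for(self, n_moving: int) -> float:
        if n_moving >= 4:
            return self.v4
        if n_moving >= 2:
            return self.v2
        return self.v1


@dataclass(frozen=True)
class SimConfig:
    """Complete parameterisation of one simulated culture."""

    strain: StrainConfig
    tau: float                      # doubling time, seconds
    initiation_age: float = 0.0     # B period, seconds
    speeds: SpeedProfile = field(default_factory=lambda: SpeedProfile.constant(1000.0))
    failure_fraction: float = 0.0   # fraction of cells firing only one origin
    failure_split: float = 0.5      # share of failures that are oriC-only
    depth: int = 10_000_000
    bin_size: int = 1000
    bias_log2_sigma: float = 0.0
    noise: str = "poisson"          # "poisson" | "none"
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ConfigurationError("tau must be positive")
        if self.initiation_age < 0:
            raise ConfigurationError("initiation_age must be non-negative")
        if not (0.0 <= self.failure_fraction <= 1.0):
            raise ConfigurationError("failure_fraction must be in [0, 1]")
        if not (0.0 <= self.failure_split <= 1.0):
            raise ConfigurationError("failure_split must be in [0, 1]")
        if self.failure_fraction > 0 and not self.strain.two_origin:
            raise ConfigurationError(
                "initiation failure mixtures require a two-origin strain"
            )
        if self.noise not in ("poisson", "none"):
            raise ConfigurationError("noise must be 'poisson' or 'none'")
        if self.depth <= 0:
            raise ConfigurationError("depth must be positive")


@dataclass(frozen=True)
class PopulationClass:
    """One initiation class of the population with its replication schedule."""

    label: str                      # both-origins | oriC-only | oriX-only
    weight: float
    schedule: np.ndarray            # per-bin replication time t(m), seconds


# ---------------------------------------------------------------------------
# fork kinematics
# ---------------------------------------------------------------------------

@dataclass
class _Piece:
    start: float
    direction: int
    length: float
    t_start: float
    speed: float


class _Arc:
    """An unreplicated arc, consumed from both ends.

    ``lo`` is the end whose fork moves in the +right direction into the arc;
    ``hi`` the end whose fork moves the other way.  ``remaining`` is tracked
    explicitly so a single-origin full-circle arc (lo == hi) is well defined.
    """

    def __init__(self, lo_pos: float, hi_pos: float, d_right: int, L: int,
                 remaining: float):
        self.lo = float(lo_pos)
        self.hi = float(hi_pos)
        self.d = d_right
        self.L = L
        self.remaining = float(remaining)
        self.lo_moving = True
        self.hi_moving = True

    @property
    def done(self) -> bool:
        return self.remaining <= _POS_EPS

    def block_distance(self, end: str, site: float) -> Optional[float]:
        """Travel distance of the ``end`` fork to ``site``, if the site lies
        strictly inside the remaining unreplicated span, else None."""
        if end == "lo":
            dist = (self.d * (site - self.lo)) % self.L
        else:
            dist = (self.d * (self.hi - site)) % self.L
        if _POS_EPS < dist < self.remaining - _POS_EPS:
            return dist
        return None


def _simulate_forks(
    strain: StrainConfig,
    speeds: SpeedProfile,
    active_origins: Sequence[str],
) -> tuple[list[_Piece], float]:
    """Event-driven fork simulation; returns replication pieces and the
    completion time."""
    if not active_origins:
        raise ConfigurationError("need at least one active origin")
    L = strain.genome_length
    d = strain.right_direction
    positions = sorted(
        {strain.origin_position(o) for o in active_origins},
        key=lambda p: circular_span(strain.oriC_pos, p, d, L),
    )
    if len(positions) != len(set(active_origins)):
        raise ConfigurationError("active origins must be distinct loci")

    # Arcs between consecutive origins in the right direction; a single
    # origin owns the full circle.
    arcs: list[_Arc] = []
    k = len(positions)
    for i in range(k):
        lo = positions[i]
        hi = positions[(i + 1) % k]
        rem = float(L) if k == 1 else circular_span(lo, hi, d, L)
        arcs.append(_Arc(lo, hi, d, L, rem))

    # Trap sites: lo forks move in direction d (arrested at terC),
    # hi forks move in -d (arrested at terA).
    site_lo = strain.terC_pos
    site_hi = strain.terA_pos

    pieces: list[_Piece] = []
    t = 0.0
    guard = 0
    while any(not a.done for a in arcs):
        guard += 1
        if guard > 1000:
            raise SimulationError("fork simulation failed to converge")
        n_moving = sum(a.lo_moving + a.hi_moving for a in arcs if not a.done)
        if n_moving == 0:
            raise SimulationError(
                "unreplicated region with no moving fork (inconsistent traps)"
            )
        v = speeds.speed_for(n_moving)

        # Earliest event across arcs: a meeting or a trap arrival.
        events: list[tuple[float, _Arc, str]] = []
        for a in arcs:
            if a.done:
                continue
            closing = v * (a.lo_moving + a.hi_moving)
            if closing > 0:
                events.append((a.remaining / closing, a, "meet"))
            if a.lo_moving:
                b = a.block_distance("lo", site_lo)
                if b is not None:
                    events.append((b / v, a, "block_lo"))
            if a.hi_moving:
                b = a.block_distance("hi", site_hi)
                if b is not None:
                    events.append((b / v, a, "block_hi"))
        if not events:
            raise SimulationError("no progress possible in fork simulation")
        dt = min(e[0] for e in events)
        t_eps = dt * 1e-12 + 1e-12

        # Advance all moving forks by v*dt, recording replicated pieces.
        for a in arcs:
            if a.done:
                continue
            step = v * dt
            if a.lo_moving:
                pieces.append(_Piece(a.lo, a.d, step, t, v))
                a.lo = advance(a.lo, step, a.d, L)
                a.remaining -= step
            if a.hi_moving:
                pieces.append(_Piece(a.hi, -a.d, step, t, v))
                a.hi = advance(a.hi, step, -a.d, L)
                a.remaining -= step
        t += dt

        # Apply the state changes that fall at this time.
        for edt, a, kind in events:
            if edt > dt + t_eps:
                continue
            if kind == "meet" and a.done:
                a.lo_moving = a.hi_moving = False
            elif kind == "block_lo":
                a.lo_moving = False
            elif kind == "block_hi":
                a.hi_moving = False
    return pieces, t


def _eval_schedule(pieces: list[_Piece], positions: np.ndarray, L: int) -> np.ndarray:
    """Replication time at arbitrary positions; where two forks cover a
    boundary position the earlier arrival wins."""
    positions = np.asarray(positions, dtype=float) % L
    t = np.full(len(positions), np.inf)
    for p in pieces:
        if p.length <= 0:
            continue
        dist = (p.direction * (positions - p.start)) % L
        sel = dist <= p.length + _POS_EPS
        cand = p.t_start + dist / p.speed
        t[sel] = np.minimum(t[sel], cand[sel])
    return t


def fork_schedule(
    strain: StrainConfig,
    speeds: SpeedProfile,
    active_origins: Sequence[str],
    bin_size: int = 1000,
) -> np.ndarray:
    """Per-bin replication time t(m) (seconds after initiation), evaluated at
    bin centres."""
    pieces, _ = _simulate_forks(strain, speeds, active_origins)
    L = strain.genome_length
    t = _eval_schedule(pieces, bin_centers(L, bin_size), L)
    if not np.all(np.isfinite(t)):
        raise SimulationError("some bins were never replicated (unreachable)")
    return t


def segment_average_speeds(
    strain: StrainConfig,
    speeds: SpeedProfile,
    segset,
    active_origins: Sequence[str] = ("oriC", "oriX"),
) -> dict[str, float]:
    """Ground-truth average fork speed (bp/s) across each directed segment:
    segment length divided by the replication time spanned between its
    boundaries.  Equals the configured step speed exactly for segments
    replicated at a single speed; for segments straddling a speed switch it
    is the time-average the pipeline's per-segment estimate targets."""
    if not strain.two_origin:
        active_origins = ("oriC",)
    pieces, _ = _simulate_forks(strain, speeds, active_origins)
    L = strain.genome_length
    out: dict[str, float] = {}
    for seg in segset:
        if seg.fork_direction is None:
            continue
        t0, t1 = _eval_schedule(
            pieces, np.array([seg.entry_boundary, seg.exit_boundary], float), L
        )
        out[seg.name] = seg.length / abs(t1 - t0)
    return out


# ---------------------------------------------------------------------------
# expected profiles and mixtures
# ---------------------------------------------------------------------------

def _raw_copy_profile(schedule: np.ndarray, tau: float, initiation_age: float) -> np.ndarray:
    age = initiation_age + schedule
    if age.max() > tau + 1e-9:
        raise SimulationError(
            f"replication not completing within the cycle: initiation_age + "
            f"max t = {age.max():.1f} s > tau = {tau} s"
        )
    return np.power(2.0, -age / tau)


def expected_copy_profile(
    schedule: np.ndarray, tau: float, initiation_age: float = 0.0
) -> np.ndarray:
    """Expected relative marker frequency (mean 1) for one population class."""
    raw = _raw_copy_profile(schedule, tau, initiation_age)
    return raw / raw.mean()


def build_population(sim: SimConfig) -> list[PopulationClass]:
    """Initiation classes implied by the failure fraction and split."""
    f = sim.failure_fraction
    classes: list[tuple[str, float, tuple[str, ...]]] = []
    if sim.strain.two_origin:
        if 1 - f > 0:
            classes.append(("both-origins", 1 - f, ("oriC", "oriX")))
        if f * sim.failure_split > 0:
            classes.append(("oriC-only", f * sim.failure_split, ("oriC",)))
        if f * (1 - sim.failure_split) > 0:
            classes.append(("oriX-only", f * (1 - sim.failure_split), ("oriX",)))
    else:
        classes.append(("both-origins", 1.0, ("oriC",)))
    return [
        PopulationClass(
            label, weight, fork_schedule(sim.strain, sim.speeds, origins, sim.bin_size)
        )
        for label, weight, origins in classes
    ]


def mix_classes(
    classes: Sequence[PopulationClass], tau: float, initiation_age: float = 0.0
) -> np.ndarray:
    """Population expected profile: weight-averaged class copy-number profiles
    (class-independent proportionality constant), renormalised to mean 1."""
    weights = np.array([c.weight for c in classes], dtype=float)
    if abs(weights.sum() - 1.0) > 1e-9:
        raise ConfigurationError(f"class weights sum to {weights.sum()}, not 1")
    mixed = np.zeros_like(classes[0].schedule, dtype=float)
    for c in classes:
        mixed += c.weight * _raw_copy_profile(c.schedule, tau, initiation_age)
    return mixed / mixed.mean()


def expected_population_profile(sim: SimConfig) -> np.ndarray:
    """Noiseless expected relative frequency (mean 1) for a whole culture."""
    return mix_classes(build_population(sim), sim.tau, sim.initiation_age)


# ---------------------------------------------------------------------------
# read sampling
# ---------------------------------------------------------------------------

def make_bias_track(
    nb: int,
    log2_sigma: float,
    seed: Optional[int] = None,
    centered_window: Optional[int] = 30,
) -> np.ndarray:
    """Multiplicative per-bin bias, log2-normal with the given per-bin sigma.

    The track emulates bin-scale technical artifacts (mappability, local GC,
    library composition): each bin's log2 bias is drawn independently and
    then centred on its circular +-``centered_window`` neighbourhood mean, so
    the track carries no spurious long-range drift.  A raw independent draw
    (``centered_window=None``) additionally contains a random low-frequency
    component that is indistinguishable from a replication gradient and
    therefore cannot be removed by any windowed cross-sample correction.
    """
    rng = np.random.default_rng(seed)
    b = rng.normal(0.0, log2_sigma, nb)
    if centered_window:
        w = centered_window
        shifts = [k for k in range(-w, w + 1) if k != 0]
        b = b - np.mean([np.roll(b, k) for k in shifts], axis=0)
    return np.power(2.0, b)


def sample_reads(
    expected: np.ndarray,
    depth: int,
    genome_length: int,
    bin_size: int = 1000,
    bias_track: Optional[np.ndarray] = None,
    noise: str = "poisson",
    seed: Optional[int] = None,
    sample_id: str = "sim",
) -> BinnedProfile:
    """Draw per-bin read counts around ``depth * expected * bias``.

    Poisson noise by default; ``noise='none'`` rounds the expectations
    deterministically (largest remainders, so the total equals ``depth``).
    """
    expected = np.asarray(expected, dtype=float)
    if not np.all(np.isfinite(expected)) or np.any(expected < 0):
        raise SimulationError("expected profile must be finite and non-negative")
    if bias_track is not None:
        bias_track = np.asarray(bias_track, dtype=float)
        if np.any(bias_track <= 0):
            raise ConfigurationError("bias factors must be positive")
        weights = expected * bias_track
    else:
        weights = expected
    lam = depth * weights / weights.sum()
    if noise == "poisson":
        rng = np.random.default_rng(seed)
        counts = rng.poisson(lam)
    elif noise == "none":
        counts = np.floor(lam).astype(np.int64)
        shortfall = int(round(depth - counts.sum()))
        if shortfall > 0:
            order = np.argsort(-(lam - np.floor(lam)), kind="stable")
            counts[order[:shortfall]] += 1
    else:
        raise ConfigurationError("noise must be 'poisson' or 'none'")
    return BinnedProfile(sample_id, bin_size, genome_length, counts.astype(np.int64))


def simulate_sample(
    sim: SimConfig,
    sample_id: str = "sim",
    bias_track: Optional[np.ndarray] = None,
) -> tuple[BinnedProfile, np.ndarray]:
    """Simulate one sequencing sample; returns (counts, expected profile).

    A bias track is generated from ``bias_log2_sigma`` when none is supplied.
    """
    expected = expected_population_profile(sim)
    nb = n_bins(sim.strain.genome_length, sim.bin_size)
    rng = np.random.default_rng(sim.seed)
    if bias_track is None and sim.bias_log2_sigma > 0:
        bias_track = make_bias_track(nb, sim.bias_log2_sigma,
                                     int(rng.integers(2**31 - 1)))
    read_seed = int(rng.integers(2**31 - 1))
    profile = sample_reads(
        expected, sim.depth, sim.strain.genome_length, sim.bin_size,
        bias_track, sim.noise, read_seed, sample_id,
    )
    return profile, expected


def expected_as_profile(sim: SimConfig, sample_id: str = "expected") -> CorrectedProfile:
    """Noiseless expected profile wrapped as a :class:`CorrectedProfile`."""
    return CorrectedProfile.from_rel_freq(
        expected_population_profile(sim), sim.bin_size,
        sim.strain.genome_length, sample_id,
    )


# ---------------------------------------------------------------------------
# synchrony calibration curve
# ---------------------------------------------------------------------------

def synchrony_failure_curve(
    sim: SimConfig, f_values: Sequence[float]
) -> list[tuple[float, float]]:
    """Synchrony index of the noiseless mixture profile at each failure
    fraction — the calibration curve linking the index to f (1 at f=0,
    decreasing as more cells fail to fire one origin)."""
    from dataclasses import replace as _dc_replace

    from .fit import fit_connecting_points, segment_slopes
    from .genome import build_segments
    from .metrics import synchrony_index

    if not sim.strain.two_origin:
        raise ConfigurationError("synchrony curve requires a two-origin strain")
    segset = build_segments(sim.strain, sim.bin_size)
    out = []
    for f in f_values:
        if not (0.0 <= f <= 1.0):
            raise ConfigurationError(f"failure fraction {f} outside [0, 1]")
        sim_f = _dc_replace(sim, failure_fraction=f)
        profile = expected_as_profile(sim_f, sample_id=f"f={f}")
        pw = fit_connecting_points(profile, segset)
        out.append((f, synchrony_index(segset, segment_slopes(pw, segset))))
    return out
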