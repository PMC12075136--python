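"""Circular chromosome geometry and fork-count segmentation.

A bacterial chromosome is modelled as a circle of ``genome_length`` base
pairs with 0-based, half-open coordinates.  Replication initiates at one
origin (*oriC*) or two (*oriC* plus an ectopic *oriX* on the left
replichore) and terminates in the fork-trap zone between *terA* and
*terC*.  Forks travelling along the right replichore (rotational direction
``replichore_orientation``) pass *terA* freely and are arrested at *terC*;
forks travelling the other way pass *terC* and are arrested at *terA*.

The segmentation partitions the circle into eight named intervals by the
number of replisomes active while each is replicated in the two-origin
strain: the four equal-length origin-proximal segments ``X_L``, ``X_R``,
``C_L``, ``C_R`` (four forks), the equal-length pair ``L2``/``R2`` (two
forks), ``R3`` (one fork) and a ``ter`` termination zone.  The one-origin
strain reuses the same genomic boundaries, with the ``ter`` zone widened
to span the whole trap region, so that ratio statistics are computed over
identical regions in both strains.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Literal, Optional

from .errors import ConfigurationError, GeometryError

#: Rotational directions.  +1 is increasing genomic coordinate.
FORWARD = 1
REVERSE = -1

SEGMENT_NAMES = ("X_L", "X_R", "C_L", "C_R", "L2", "R2", "R3", "ter")

#: Origin-proximal segments (replicated while four forks are active in the
#: two-origin strain).
ORIGIN_PROXIMAL = ("X_L", "X_R", "C_L", "C_R")
#: Origin-distal segments.
ORIGIN_DISTAL = ("L2", "R2", "R3")
#: Segments whose forks converge between the two origins.
CONVERGING = ("X_R", "C_L")
#: Segments whose forks diverge away from the inter-origin region.
DIVERGING = ("X_L", "C_R")
#: Restricted segment set used when the converging segments are suspect.
RESTRICTED = ("L2", "X_L", "C_R", "R2")


def circular_span(a: int, b: int, direction: int = FORWARD, L: int = 0) -> int:
    """Arc length from ``a`` to ``b`` travelling in ``direction`` on a circle of
    circumference ``L``.  Result is in ``[0, L)``."""
    if L <= 0:
        raise GeometryError(f"genome length must be positive, got {L}")
    if direction not in (FORWARD, REVERSE):
        raise GeometryError(f"direction must be +1 or -1, got {direction}")
    if direction == FORWARD:
        return (b - a) % L
    return (a - b) % L


def advance(pos: float, dist: float, direction: int, L: int) -> float:
    """Position reached from ``pos`` after travelling ``dist`` in ``direction``."""
    if L <= 0:
        raise GeometryError(f"genome length must be positive, got {L}")
    return (pos + direction * dist) % L


@dataclass(frozen=True)
class StrainConfig:
    """Geometry of a strain's circular chromosome.

    The default coordinates exposed by :meth:`mg1655` / :meth:`mg1655_oriCX`
    come from the public U00096 (E. coli MG1655) genome annotation, not from
    any single experiment; override them for other references.  ``oriX`` is
    placed at the midpoint of the left replichore, which is only known
    approximately.
    """

    genome_length: int
    oriC_pos: int
    terA_pos: int
    terC_pos: int
    oriX_pos: Optional[int] = None
    ter_extension: int = 50_000
    #: Rotational direction of the right replichore leaving oriC.
    replichore_orientation: int = FORWARD
    name: str = "chromosome"

    def __post_init__(self) -> None:
        L = self.genome_length
        if L <= 0:
            raise GeometryError(f"genome length must be positive, got {L}")
        for label in ("oriC_pos", "terA_pos", "terC_pos"):
            v = getattr(self, label)
            if not (0 <= v < L):
                raise ConfigurationError(f"{label}={v} outside [0, {L})")
        if self.oriX_pos is not None:
            if not (0 <= self.oriX_pos < L):
                raise ConfigurationError(f"oriX_pos={self.oriX_pos} outside [0, {L})")
            if self.oriX_pos == self.oriC_pos:
                raise ConfigurationError("oriX_pos must differ from oriC_pos")
        if self.ter_extension < 0:
            raise ConfigurationError("ter_extension must be non-negative")
        if self.replichore_orientation not in (FORWARD, REVERSE):
            raise ConfigurationError("replichore_orientation must be +1 or -1")
        # terA must be reached before terC travelling right from oriC, and
        # terC before terA travelling left: the trap zone faces oriC.
        d = self.replichore_orientation
        if not (
            circular_span(self.oriC_pos, self.terA_pos, d, L)
            < circular_span(self.oriC_pos, self.terC_pos, d, L)
        ):
            raise ConfigurationError(
                "terA/terC must lie on the arc opposite oriC with terA on the "
                "right-replichore side and terC on the left-replichore side"
            )
        if self.oriX_pos is not None:
            # oriX sits on the left replichore, between oriC and terC.
            if not (
                circular_span(self.oriC_pos, self.oriX_pos, -d, L)
                < circular_span(self.oriC_pos, self.terC_pos, -d, L)
            ):
                raise ConfigurationError(
                    "oriX_pos must lie on the left replichore between oriC and terC"
                )

    # -- derived geometry ------------------------------------------------

    @property
    def right_direction(self) -> int:
        return self.replichore_orientation

    @property
    def left_direction(self) -> int:
        return -self.replichore_orientation

    @property
    def two_origin(self) -> bool:
        return self.oriX_pos is not None

    @property
    def ter_midpoint(self) -> float:
        """Midpoint of the fork-trap zone (terA -> terC, right direction)."""
        half = circular_span(self.terA_pos, self.terC_pos, self.right_direction,
                             self.genome_length) / 2.0
        return advance(self.terA_pos, half, self.right_direction, self.genome_length)

    def replichore_length(self, origin: str, direction: int) -> float:
        """Arc length from ``origin`` to the trap-zone midpoint along ``direction``.

        Used as the reference replichore length R_l when converting a local
        fork speed into a whole-replichore replication time.
        """
        pos = self.origin_position(origin)
        return circular_span(pos, round(self.ter_midpoint), direction, self.genome_length)

    def origin_position(self, origin: str) -> int:
        if origin == "oriC":
            return self.oriC_pos
        if origin == "oriX":
            if self.oriX_pos is None:
                raise ConfigurationError("strain has no oriX")
            return self.oriX_pos
        raise ConfigurationError(f"unknown origin {origin!r}")

    # -- stock geometries --------------------------------------------------

    @classmethod
    def mg1655(cls, **overrides) -> "StrainConfig":
        """One-origin E. coli MG1655 geometry (U00096 annotation coordinates)."""
        params = dict(
            genome_length=4_641_652,
            oriC_pos=3_925_744,
            terA_pos=1_286_235,
            terC_pos=1_609_157,
            name="U00096",
        )
        params.update(overrides)
        return cls(**params)

    @classmethod
    def mg1655_oriCX(cls, oriX_pos: int = 2_767_000, **overrides) -> "StrainConfig":
        """Two-origin (oriCX) geometry: oriX at the left-replichore midpoint."""
        return cls.mg1655(oriX_pos=oriX_pos, **overrides)


@dataclass(frozen=True)
class Segment:
    """A named chromosomal interval, 0-based half-open, possibly wrapping."""

    name: str
    start: int
    end: int
    genome_length: int
    #: Rotational direction of replication through the segment (None for ter).
    fork_direction: Optional[int]
    #: Replisomes active while this segment is replicated (None for ter).
    active_fork_count: Optional[int]
    #: Which origin's fork replicates the segment (None for ter).
    origin_of_fork: Optional[str]

    @property
    def length(self) -> int:
        return circular_span(self.start, self.end, FORWARD, self.genome_length)

    def contains(self, pos: float) -> bool:
        return circular_span(self.start, pos, FORWARD, self.genome_length) < self.length

    @property
    def entry_boundary(self) -> int:
        """Boundary through which the replicating fork enters the segment."""
        if self.fork_direction is None:
            raise GeometryError(f"segment {self.name} has no single fork direction")
        return self.start if self.fork_direction == FORWARD else self.end

    @property
    def exit_boundary(self) -> int:
        if self.fork_direction is None:
            raise GeometryError(f"segment {self.name} has no single fork direction")
        return self.end if self.fork_direction == FORWARD else self.start


@dataclass(frozen=True)
class SegmentSet:
    """Ordered, circle-covering collection of named segments."""

    strain_mode: Literal["one-origin", "two-origin"]
    segments: tuple[Segment, ...]
    bin_size: int
    genome_length: int
    config: StrainConfig = field(repr=False, compare=False, default=None)

    def __iter__(self) -> Iterator[Segment]:
        return iter(self.segments)

    def __getitem__(self, name: str) -> Segment:
        for seg in self.segments:
            if seg.name == name:
                return seg
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return any(seg.name == name for seg in self.segments)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(seg.name for seg in self.segments)

    def in_genomic_order(self) -> list[Segment]:
        return sorted(self.segments, key=lambda s: s.start)

    def to_bed(self, path, chrom: Optional[str] = None) -> None:
        """Write the segmentation as BED (wrap-around segments split in two)."""
        chrom = chrom or (self.config.name if self.config else "chromosome")
        with open(path, "w") as fh:
            for seg in self.in_genomic_order():
                if seg.start < seg.end:
                    fh.write(f"{chrom}\t{seg.start}\t{seg.end}\t{seg.name}\n")
                else:  # wraps through the coordinate origin
                    fh.write(f"{chrom}\t{seg.start}\t{self.genome_length}\t{seg.name}\n")
                    if seg.end > 0:
                        fh.write(f"{chrom}\t0\t{seg.end}\t{seg.name}\n")


def _snap(pos: int, bin_size: int, L: int) -> int:
    """Round a coordinate to the nearest bin edge on the circular grid."""
    return (round(pos / bin_size) * bin_size) % L


def build_segments(
    config: StrainConfig,
    bin_size: int = 1000,
    mode: Literal["auto", "one-origin", "two-origin"] = "auto",
) -> SegmentSet:
    """Partition the chromosome by active-fork count.

    Two-origin rules: ``X_R`` and ``C_L`` abut at the inter-origin midpoint
    and, with ``X_L``/``C_R`` extending outward, all four have equal length
    (the distance from each origin to the midpoint); ``L2`` runs from the end
    of ``X_L`` to the ``ter`` boundary and ``R2`` continues from ``C_R`` with
    the same length; ``R3`` covers the remainder; ``ter`` is centred on the
    termination site *terA* and extended by ``ter_extension`` on each side.
    One-origin mode keeps identical boundaries but widens ``ter`` to span the
    whole trap zone (terA - ext to terC + ext), truncating ``L2``.

    Anchor coordinates are snapped to the bin grid, and the inter-origin
    distance is rounded to an even number of bins (moving the oriC-side
    boundary by at most one bin) so the equal-length constraints hold exactly
    on the grid.
    """
    if bin_size <= 0:
        raise ConfigurationError("bin_size must be positive")
    if mode == "auto":
        mode = "two-origin" if config.two_origin else "one-origin"
    if mode == "two-origin" and not config.two_origin:
        raise ConfigurationError("two-origin segmentation requires oriX_pos")

    L = config.genome_length
    d_r = config.right_direction
    d_l = config.left_direction
    ext = round(config.ter_extension / bin_size) * bin_size

    oriC = _snap(config.oriC_pos, bin_size, L)
    terA = _snap(config.terA_pos, bin_size, L)
    terC = _snap(config.terC_pos, bin_size, L)
    if mode == "two-origin":
        oriX = _snap(config.oriX_pos, bin_size, L)
    else:
        # A virtual oriX at the snapped left-replichore midpoint keeps the
        # one-origin boundaries identical to the two-origin ones.
        half_left = circular_span(oriC, terC, d_l, L) / 2.0
        oriX = _snap(round(advance(oriC, half_left, d_l, L)), bin_size, L)

    inter = circular_span(oriX, oriC, d_r, L)
    if inter % bin_size:
        raise GeometryError("snapped origins not on the bin grid")
    if (inter // bin_size) % 2:
        oriC = int(advance(oriC, bin_size, d_r, L))
        inter += bin_size
    half = inter // 2

    mid = int(advance(oriX, half, d_r, L))
    xl_outer = int(advance(oriX, half, d_l, L))
    cr_outer = int(advance(oriC, half, d_r, L))
    b_left = int(advance(terA, ext, d_r, L))  # ter boundary on the trap-zone side
    b_right = int(advance(terA, ext, d_l, L))  # ter boundary on the R3 side
    if mode == "one-origin":
        ter_hi = int(advance(terC, ext, d_r, L))
    else:
        ter_hi = b_left

    len_L2 = circular_span(b_left, xl_outer, d_r, L)
    r2_end = int(advance(cr_outer, len_L2, d_r, L))

    def arc(name, frm, to, fork_dir, count, origin):
        """Interval travelled right (direction ``d_r``) from ``frm`` to ``to``."""
        start, end = (frm, to) if d_r == FORWARD else (to, frm)
        seg = Segment(name, start % L, end % L, L, fork_dir, count, origin)
        if circular_span(frm, to, d_r, L) <= 0:
            raise GeometryError(f"segment {name} has non-positive length "
                                "(origins too close to the terminus region?)")
        return seg

    counts4 = 4 if mode == "two-origin" else 2
    counts2 = 2
    counts1 = 1 if mode == "two-origin" else 2
    x_origin = "oriX" if mode == "two-origin" else "oriC"

    segments = (
        arc("X_L", xl_outer, oriX, d_l, counts4, x_origin),
        arc("X_R", oriX, mid, d_r if mode == "two-origin" else d_l,
            counts4, x_origin),
        arc("C_L", mid, oriC, d_l, counts4, "oriC"),
        arc("C_R", oriC, cr_outer, d_r, counts4, "oriC"),
        arc("L2", ter_hi, xl_outer, d_l, counts2, x_origin),
        arc("R2", cr_outer, r2_end, d_r, counts2, "oriC"),
        arc("R3", r2_end, b_right, d_r, counts1, "oriC"),
        arc("ter", b_right, ter_hi, None, None, None),
    )
    # Truncated L2 must still be positive and the distal arcs must not collide.
    total = sum(seg.length for seg in segments)
    if total != L:
        raise GeometryError(
            f"segments cover {total} bp of a {L} bp genome; geometry is "
            "inconsistent (ter zone overlapping origin-proximal segments?)"
        )
    # Sanity: R3 must not run past the ter boundary (r2_end upstream of b_right).
    if circular_span(cr_outer, b_right, d_r, L) <= len_L2:
        raise GeometryError("R2 reaches past the ter boundary; geometry invalid")

    return SegmentSet(
        strain_mode=mode,
        segments=segments,
        bin_size=bin_size,
        genome_length=L,
        config=config,
    )
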