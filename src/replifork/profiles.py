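"""Binned read-depth profiles and bias correction.

Read depth of an exponentially growing population decays from origin(s)
to terminus; after binning (1 kbp windows by default), normalising to a
mean relative marker frequency of 1 and removing the multiplicative bias
shared across samples, the log2 of the per-bin relative frequency is the
quantity the downstream piecewise-linear fit consumes.

The cross-sample correction follows the moving-window scheme used for
replication profile plots: each bin's deviation from the mean of the 30
preceding and 30 following retained bins (circularly wrapped) is computed
per sample on the log2 scale, the deviations are averaged across samples,
and that average is subtracted from every sample.  Subtraction on the
log2 scale equals division by a shared multiplicative bias on the linear
scale.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DegenerateDataError

DEFAULT_BIN_SIZE = 1000
DEFAULT_MAPQ_MIN = 20
DEFAULT_WINDOW = 30
#: Neighbour search never reaches farther than this many windows away.
MAX_REACH_FACTOR = 3


def n_bins(genome_length: int, bin_size: int) -> int:
    return -(-genome_length // bin_size)


def bin_centers(genome_length: int, bin_size: int) -> np.ndarray:
    """Midpoint coordinate of every bin (the last bin may be short)."""
    nb = n_bins(genome_length, bin_size)
    starts = np.arange(nb, dtype=float) * bin_size
    ends = np.minimum(starts + bin_size, genome_length)
    return (starts + ends) / 2.0


@dataclass
class BinnedProfile:
    """Integer read counts per bin tiling a circular genome."""

    sample_id: str
    bin_size: int
    genome_length: int
    counts: np.ndarray
    mask: np.ndarray = None  # True = retained

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        expected = n_bins(self.genome_length, self.bin_size)
        if len(self.counts) != expected:
            raise ConfigurationError(
                f"{self.sample_id}: {len(self.counts)} bins, expected {expected} "
                f"for genome_length={self.genome_length}, bin_size={self.bin_size}"
            )
        if np.any(self.counts < 0):
            raise ConfigurationError("counts must be non-negative")
        if self.mask is None:
            self.mask = np.ones(expected, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def n_retained(self) -> int:
        return int(self.mask.sum())


@dataclass
class CorrectedProfile:
    """Normalised (and optionally bias-corrected) relative marker frequencies.

    ``rel_freq`` averages 1 over retained bins; ``log2_freq`` is its log2;
    masked bins hold NaN.  ``correction`` records the cumulative log2
    correction applied by :func:`cross_sample_correct`.
    """

    sample_id: str
    bin_size: int
    genome_length: int
    rel_freq: np.ndarray
    log2_freq: np.ndarray
    mask: np.ndarray
    correction: Optional[np.ndarray] = None

    @property
    def n_retained(self) -> int:
        return int(self.mask.sum())

    @classmethod
    def from_rel_freq(
        cls,
        rel_freq: np.ndarray,
        bin_size: int,
        genome_length: int,
        sample_id: str = "expected",
        mask: Optional[np.ndarray] = None,
    ) -> "CorrectedProfile":
        """Wrap a positive relative-frequency array (e.g. a simulated
        expectation) as a profile, re-centred to mean 1 over retained bins."""
        rel = np.asarray(rel_freq, dtype=float).copy()
        if mask is None:
            mask = np.isfinite(rel) & (rel > 0)
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            raise DegenerateDataError("no retained bins")
        rel[~mask] = np.nan
        rel /= np.nanmean(rel[mask])
        with np.errstate(divide="ignore", invalid="ignore"):
            log2 = np.log2(rel)
        return cls(sample_id, bin_size, genome_length, rel, log2, mask)


# ---------------------------------------------------------------------------
# binning from alignments
# ---------------------------------------------------------------------------

def bin_reads(
    alignments,
    genome_length: int,
    bin_size: int = DEFAULT_BIN_SIZE,
    mapq_min: int = DEFAULT_MAPQ_MIN,
    sample_id: str = "sample",
    reference: Optional[str] = None,
) -> BinnedProfile:
    """Bin primary mapped reads from a SAM/BAM file by leftmost coordinate.

    Each primary, mapped read with mapping quality >= ``mapq_min`` increments
    the bin containing its leftmost aligned position; mates are counted
    independently.  Unmapped, secondary and supplementary records are ignored.
    ``alignments`` is a path or an open :class:`pysam.AlignmentFile`.
    """
    import pysam

    own = isinstance(alignments, (str, bytes)) or hasattr(alignments, "__fspath__")
    af = pysam.AlignmentFile(str(alignments), check_sq=False) if own else alignments
    try:
        refs = list(af.references)
        if reference is None:
            if len(refs) != 1:
                raise ConfigurationError(
                    f"alignment header has {len(refs)} references; specify one"
                )
            reference = refs[0]
        if reference not in refs:
            raise ConfigurationError(f"reference {reference!r} not in header")
        header_len = af.get_reference_length(reference)
        if header_len != genome_length:
            raise ConfigurationError(
                f"header length {header_len} != configured genome length "
                f"{genome_length} for {reference!r}"
            )
        counts = np.zeros(n_bins(genome_length, bin_size), dtype=np.int64)
        used = 0
        for read in af.fetch(until_eof=True):
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if read.mapping_quality < mapq_min:
                continue
            if read.reference_name != reference:
                continue
            counts[read.reference_start // bin_size] += 1
            used += 1
    finally:
        if own:
            af.close()
    if used == 0:
        raise DegenerateDataError("no usable reads in alignment input")
    return BinnedProfile(sample_id, bin_size, genome_length, counts)


# ---------------------------------------------------------------------------
# masking and normalisation
# ---------------------------------------------------------------------------

def mask_bins(
    profile: BinnedProfile,
    low_quantile: float = 0.001,
    high_quantile: float = 0.999,
) -> BinnedProfile:
    """Mask zero-coverage bins and count outliers outside a quantile band.

    Masking is recorded in the profile's mask, never by deleting bins, so the
    bin grid stays comparable across samples.
    """
    if not (0 <= low_quantile < high_quantile <= 1):
        raise ConfigurationError("require 0 <= low_quantile < high_quantile <= 1")
    mask = profile.mask & (profile.counts > 0)
    if not mask.any():
        raise DegenerateDataError(f"{profile.sample_id}: all bins zero or masked")
    retained = profile.counts[mask]
    lo = np.quantile(retained, low_quantile)
    hi = np.quantile(retained, high_quantile)
    mask &= (profile.counts >= lo) & (profile.counts <= hi)
    if not mask.any():
        raise DegenerateDataError(f"{profile.sample_id}: all bins masked")
    return replace(profile, mask=mask)


def normalize(profile: BinnedProfile) -> CorrectedProfile:
    """Convert counts into relative marker frequencies with retained-bin mean 1.

    Zero-count bins cannot carry a log2 frequency and are masked here if the
    caller has not masked them already.
    """
    mask = profile.mask & (profile.counts > 0)
    if not mask.any():
        raise DegenerateDataError(f"{profile.sample_id}: no retained bins")
    rel = np.full(len(profile.counts), np.nan)
    rel[mask] = profile.counts[mask] / profile.counts[mask].mean()
    with np.errstate(divide="ignore", invalid="ignore"):
        log2 = np.log2(rel)
    return CorrectedProfile(
        profile.sample_id, profile.bin_size, profile.genome_length, rel, log2, mask
    )


# ---------------------------------------------------------------------------
# cross-sample correction
# ---------------------------------------------------------------------------

def _local_deviation(profile: CorrectedProfile, window: int) -> np.ndarray:
    """Per-bin deviation of log2_freq from the mean of the nearest ``window``
    retained neighbours on each side (focal bin excluded, circular wrap).

    Neighbours farther than ``MAX_REACH_FACTOR * window`` bins away are not
    used, so sparse regions fall back on fewer neighbours.
    """
    nb = len(profile.log2_freq)
    idx = np.flatnonzero(profile.mask)
    vals = profile.log2_freq[idx]
    n = len(idx)
    if n < 2:
        raise DegenerateDataError("too few retained bins for local correction")
    reach = MAX_REACH_FACTOR * window
    neigh_vals = []
    neigh_ok = []
    for k in range(1, window + 1):
        for sign in (-1, 1):
            shifted_idx = np.roll(idx, -sign * k)
            shifted_val = np.roll(vals, -sign * k)
            dist = np.minimum((shifted_idx - idx) % nb, (idx - shifted_idx) % nb)
            ok = dist <= reach
            # Guard against tiny retained sets where the shift wraps onto the
            # focal bin itself.
            ok &= shifted_idx != idx
            neigh_vals.append(shifted_val)
            neigh_ok.append(ok)
    vmat = np.stack(neigh_vals)
    okmat = np.stack(neigh_ok)
    counts = okmat.sum(axis=0)
    if np.any(counts == 0):
        raise DegenerateDataError("isolated retained bins with no usable neighbours")
    local_mean = np.where(okmat, vmat, 0.0).sum(axis=0) / counts
    dev = np.full(nb, np.nan)
    dev[idx] = vals - local_mean
    return dev


def cross_sample_correct(
    profiles: Sequence[CorrectedProfile],
    window: int = DEFAULT_WINDOW,
) -> tuple[list[CorrectedProfile], np.ndarray]:
    """Remove the multiplicative bias pattern shared by all samples.

    Returns the corrected profiles (re-centred to retained-bin mean 1) and
    the per-bin log2 correction track that was subtracted.
    """
    if not profiles:
        raise ConfigurationError("need at least one profile")
    first = profiles[0]
    for p in profiles[1:]:
        if (p.bin_size, p.genome_length) != (first.bin_size, first.genome_length):
            raise ConfigurationError("bin grid differs between samples")
    for p in profiles:
        if window >= p.n_retained / 2:
            raise ConfigurationError(
                f"window={window} too large for {p.n_retained} retained bins"
            )
    devs = np.stack([_local_deviation(p, window) for p in profiles])
    finite = np.isfinite(devs)
    n_finite = finite.sum(axis=0)
    correction = np.where(
        n_finite > 0,
        np.where(finite, devs, 0.0).sum(axis=0) / np.maximum(n_finite, 1),
        np.nan,
    )
    corrected = []
    for p in profiles:
        log2 = p.log2_freq.copy()
        applied = np.where(np.isfinite(correction), correction, 0.0)
        log2 -= applied
        rel = np.power(2.0, log2)
        rel[~p.mask] = np.nan
        rel /= np.nanmean(rel[p.mask])
        with np.errstate(divide="ignore", invalid="ignore"):
            log2 = np.log2(rel)
        cumulative = applied if p.correction is None else p.correction + applied
        corrected.append(
            CorrectedProfile(
                p.sample_id, p.bin_size, p.genome_length, rel, log2, p.mask.copy(),
                correction=cumulative,
            )
        )
    return corrected, correction


# ---------------------------------------------------------------------------
# text IO (bedGraph-style TSV)
# ---------------------------------------------------------------------------

def _grid_frame(genome_length: int, bin_size: int, chrom: str) -> pd.DataFrame:
    nb = n_bins(genome_length, bin_size)
    starts = np.arange(nb, dtype=np.int64) * bin_size
    ends = np.minimum(starts + bin_size, genome_length)
    return pd.DataFrame({"chrom": chrom, "start": starts, "end": ends})


def write_bin_counts(profile: BinnedProfile, path, chrom: Optional[str] = None) -> None:
    """Write per-bin counts as headerless bedGraph (chrom, start, end, count)."""
    df = _grid_frame(profile.genome_length, profile.bin_size, chrom or "chromosome")
    df["count"] = profile.counts
    df.to_csv(path, sep="\t", header=False, index=False)


def read_bin_counts(
    path,
    sample_id: Optional[str] = None,
    genome_length: Optional[int] = None,
) -> BinnedProfile:
    """Read per-bin counts from TSV/bedGraph (chrom, start, end, count).

    Bins must be contiguous, 0-based half-open and cover the genome; the bin
    size is inferred from the first interval.
    """
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "count"], comment="#")
    if df.empty:
        raise DegenerateDataError(f"{path}: empty bin-count file")
    if df["chrom"].nunique() != 1:
        raise ConfigurationError(f"{path}: expected a single chromosome")
    df = df.sort_values("start").reset_index(drop=True)
    bin_size = int(df.loc[0, "end"] - df.loc[0, "start"])
    if bin_size <= 0 or int(df.loc[0, "start"]) != 0:
        raise ConfigurationError(f"{path}: bins must start at 0 with positive width")
    if not (df["start"].values[1:] == df["end"].values[:-1]).all():
        raise ConfigurationError(f"{path}: bins are not contiguous")
    inferred_length = int(df["end"].iloc[-1])
    if genome_length is not None and genome_length != inferred_length:
        raise ConfigurationError(
            f"{path}: bins cover {inferred_length} bp, expected {genome_length}"
        )
    counts = df["count"].to_numpy()
    if not np.issubdtype(counts.dtype, np.number):
        raise ConfigurationError(f"{path}: non-numeric counts")
    return BinnedProfile(
        sample_id or str(path), bin_size, inferred_length, counts.astype(np.int64)
    )


def write_corrected(profile: CorrectedProfile, path, chrom: Optional[str] = None) -> None:
    """Write rel_freq / log2_freq / retained flag / applied correction as TSV."""
    df = _grid_frame(profile.genome_length, profile.bin_size, chrom or "chromosome")
    df["rel_freq"] = np.round(profile.rel_freq, 9)
    df["log2_freq"] = np.round(profile.log2_freq, 9)
    df["retained"] = profile.mask.astype(int)
    corr = profile.correction
    df["correction_log2"] = 0.0 if corr is None else np.round(corr, 9)
    df.to_csv(path, sep="\t", index=False, float_format="%.9g")


def write_bedgraph(track: np.ndarray, path, genome_length: int, bin_size: int,
                   chrom: str = "chromosome") -> None:
    """Write a per-bin numeric track (e.g. the correction) as bedGraph."""
    df = _grid_frame(genome_length, bin_size, chrom)
    df["value"] = np.round(np.nan_to_num(np.asarray(track, dtype=float)), 9)
    df.to_csv(path, sep="\t", header=False, index=False, float_format="%.9g")
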