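"""Coverage pileups and anchor-centred averaged profiles.

The visualisation pipeline builds, per chromosome, a dense zero-filled
coverage track (every base gets a value, uncovered bases are exactly 0),
extracts a window of up to ``flank`` bp either side of each chromosome's
anchor (the centromeric CDEIII element in the yeast application), averages
the windows position-wise across chromosomes into a meta-profile, and
optionally expresses one sample's meta-profile as a percentage of a
reference (typically wild type).

Coordinates are 0-based half-open internally.  Window offsets run from
``-flank`` to ``+flank`` with the anchor at offset 0; offsets that fall
off a chromosome end are *missing* (NaN) and are excluded from averages
rather than zero-padded, which would deflate them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .genome import Genome
from .reads import AlignmentRecord


@dataclass
class PileupTrack:
    """Dense per-base coverage over one chromosome (zero-filled)."""

    chrom: str
    length: int
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != (self.length,):
            raise ValueError(
                f"track {self.chrom!r}: values shape {self.values.shape} != "
                f"({self.length},)"
            )
        if np.any(self.values < 0):
            raise ValueError(f"track {self.chrom!r}: negative coverage values")


class CalibratedTrack(PileupTrack):
    """A :class:`PileupTrack` whose values are in calibrated units
    (reads per million x OR)."""


@dataclass
class MetaProfile:
    """Mean signal at each offset in a +/-flank window around anchors.

    ``mean_signal`` is NaN at offsets where no chromosome contributes;
    ``n_contributing`` counts the chromosomes with data at each offset.
    """

    offsets: np.ndarray
    mean_signal: np.ndarray
    n_contributing: np.ndarray

    def __post_init__(self) -> None:
        self.offsets = np.asarray(self.offsets, dtype=int)
        self.mean_signal = np.asarray(self.mean_signal, dtype=float)
        self.n_contributing = np.asarray(self.n_contributing, dtype=int)
        if not (
            self.offsets.shape == self.mean_signal.shape == self.n_contributing.shape
        ):
            raise ValueError("offset/mean/count arrays must share one shape")
        if np.any(np.isnan(self.mean_signal) != (self.n_contributing == 0)):
            raise ValueError("mean must be NaN exactly where n_contributing is 0")

    @property
    def flank(self) -> int:
        return (len(self.offsets) - 1) // 2


def _read_length(rec: AlignmentRecord, read_len_map) -> int:
    if rec.length is not None:
        return rec.length
    if read_len_map is None:
        raise ValueError(f"no length for read {rec.read_id!r} and no read_len_map")
    if isinstance(read_len_map, int):
        return read_len_map
    return read_len_map[rec.read_id]


def pileup(
    alignments: Iterable[AlignmentRecord],
    genome: Genome,
    read_len_map: int | Mapping[str, int] | None = None,
) -> list[PileupTrack]:
    """Zero-filled per-chromosome coverage from mapped alignments.

    Each read increments coverage by one at every base it spans
    (``pos .. pos+len-1``, clipped at the chromosome end).  One track is
    returned per chromosome of ``genome`` — including all-zero tracks for
    chromosomes without reads.  Read lengths come from the records
    themselves or from ``read_len_map`` (a constant or a per-read mapping).
    """
    lengths = genome.lengths
    starts: dict[str, list[int]] = {c: [] for c in lengths}
    ends: dict[str, list[int]] = {c: [] for c in lengths}
    for rec in alignments:
        if not rec.mapped:
            raise ValueError(f"unmapped record {rec.read_id!r} in pileup input")
        if rec.chrom not in lengths:
            raise ValueError(f"alignment chromosome {rec.chrom!r} not in genome")
        span = _read_length(rec, read_len_map)
        starts[rec.chrom].append(rec.pos)
        ends[rec.chrom].append(min(rec.pos + span, lengths[rec.chrom]))

    tracks = []
    for chrom, _ in genome.chromosomes:
        n = lengths[chrom]
        delta = np.bincount(np.asarray(starts[chrom], dtype=int), minlength=n + 1)
        delta = delta[: n + 1].astype(np.int64)
        if ends[chrom]:
            delta_end = np.bincount(np.asarray(ends[chrom], dtype=int), minlength=n + 1)
            delta = delta - delta_end[: n + 1].astype(np.int64)
        tracks.append(PileupTrack(chrom, n, np.cumsum(delta)[:n]))
    return tracks


def anchor_windows(
    track_set: Sequence[PileupTrack],
    anchors: Mapping[str, int] | Iterable[tuple[str, int]],
    flank: int = 60_000,
) -> np.ndarray:
    """Extract the +/-flank window around each anchor.

    Returns an ``(n_anchors, 2*flank+1)`` float matrix; row order follows
    the anchor iteration order and column j holds offset ``j - flank``.
    Offsets falling outside the chromosome are NaN ("up to flank" windows).
    """
    if flank < 0:
        raise ValueError("flank must be non-negative")
    by_chrom = {t.chrom: t for t in track_set}
    items = list(anchors.items()) if isinstance(anchors, Mapping) else list(anchors)
    width = 2 * flank + 1
    windows = np.full((len(items), width), np.nan)
    for i, (chrom, pos) in enumerate(items):
        if chrom not in by_chrom:
            raise ValueError(f"anchor chromosome {chrom!r} has no track")
        track = by_chrom[chrom]
        if not 0 <= pos < track.length:
            raise ValueError(
                f"anchor {pos} outside chromosome {chrom!r} (length {track.length})"
            )
        lo, hi = pos - flank, pos + flank + 1
        src_lo, src_hi = max(lo, 0), min(hi, track.length)
        windows[i, src_lo - lo : src_hi - lo] = track.values[src_lo:src_hi]
    return windows


def meta_profile(windows: np.ndarray) -> MetaProfile:
    """Average windows position-wise across chromosomes.

    At each offset the mean is taken over the chromosomes with non-missing
    data there; chromosomes are weighted equally (not by read count).
    """
    windows = np.asarray(windows, dtype=float)
    if windows.ndim != 2 or windows.shape[0] < 1:
        raise ValueError("windows must be a non-empty 2-D matrix")
    if windows.shape[1] % 2 != 1:
        raise ValueError("window width must be odd (offsets -flank..+flank)")
    flank = (windows.shape[1] - 1) // 2
    present = ~np.isnan(windows)
    n = present.sum(axis=0)
    total = np.nansum(windows, axis=0)
    mean = np.full(windows.shape[1], np.nan)
    np.divide(total, n, out=mean, where=n > 0)
    return MetaProfile(np.arange(-flank, flank + 1), mean, n)


def percent_of_reference(profile: MetaProfile, reference: MetaProfile) -> MetaProfile:
    """Express ``profile`` as a percentage of ``reference``, offset-wise.

    ``value(offset) = 100 * profile.mean / reference.mean``; offsets where
    the reference is missing or zero (or the profile is missing) come out
    missing.
    """
    if not np.array_equal(profile.offsets, reference.offsets):
        raise ValueError("profiles are on different offset grids")
    ok = (
        (reference.n_contributing > 0)
        & (profile.n_contributing > 0)
        & (reference.mean_signal != 0)
    )
    mean = np.full(profile.mean_signal.shape, np.nan)
    np.divide(profile.mean_signal, reference.mean_signal, out=mean, where=ok)
    mean[ok] *= 100.0
    return MetaProfile(
        profile.offsets.copy(), mean, np.where(ok, profile.n_contributing, 0)
    )


def smooth(profile: MetaProfile, window: int = 1) -> MetaProfile:
    """Centred moving average honouring missing values.

    ``window`` must be odd; ``window=1`` is the identity.  Near edges and
    missing offsets, the average runs over the in-range non-missing points
    only.  Presentation aid; off by default in the pipeline.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("smoothing window must be odd and >= 1")
    if window == 1:
        return MetaProfile(
            profile.offsets.copy(),
            profile.mean_signal.copy(),
            profile.n_contributing.copy(),
        )
    present = ~np.isnan(profile.mean_signal)
    vals = np.where(present, profile.mean_signal, 0.0)
    kernel = np.ones(window)
    num = np.convolve(vals, kernel, mode="same")
    den = np.convolve(present.astype(float), kernel, mode="same")
    mean = np.full(vals.shape, np.nan)
    np.divide(num, den, out=mean, where=den > 0)
    n = np.where(den > 0, profile.n_contributing, 0)
    # a smoothed value can exist at an offset that had no direct data
    n = np.where((den > 0) & (n == 0), 1, n)
    return MetaProfile(profile.offsets.copy(), mean, n)
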