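"""Occupancy-ratio (OR) calibration.

In spike-in calibrated ChIP-seq every sample contains a fixed proportion of
cells from a second species, so genome-wide protein occupancy can be
compared across samples.  The per-sample scalar that makes this possible is
the occupancy ratio::

    OR = (wce_cal * ip_exp) / (wce_exp * ip_cal)

i.e. the IP enrichment of the experimental genome over the calibration
genome, corrected by the same ratio measured in the whole-cell extract
(which captures the realised cell-mixing ratio).  OR is invariant to the
sequencing depth of either library: scaling all IP counts or all WCE counts
by a common factor cancels.  Under a model where the calibration genome's
occupancy is flat, OR converges to the ratio of mean occupancies of the
two genomes.

A coverage track in raw read counts becomes a calibrated track by
multiplying by the sample's OR and normalising to one million
experimental-genome IP reads.
"""

from __future__ import annotations

from dataclasses import dataclass

from .profiles import CalibratedTrack, PileupTrack


class CalibrationError(ValueError):
    """Calibration cannot proceed (a required read count is zero)."""


@dataclass(frozen=True)
class PartitionCounts:
    """The four read totals from which OR is computed.

    ``ip_*`` / ``wce_*`` are the numbers of IP and whole-cell-extract reads
    assigned to the experimental (``_exp``) and calibration (``_cal``)
    genomes by the sequential partition.
    """

    ip_exp: int
    ip_cal: int
    wce_exp: int
    wce_cal: int

    def __post_init__(self) -> None:
        for name in ("ip_exp", "ip_cal", "wce_exp", "wce_cal"):
            v = getattr(self, name)
            if v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")


@dataclass(frozen=True)
class OccupancyRatio:
    """A sample's occupancy ratio; multiplying a per-million track by it
    yields calibrated occupancy."""

    value: float
    sample: str = ""

    def __post_init__(self) -> None:
        if not (self.value > 0 and self.value != float("inf")):
            raise ValueError(f"OR must be positive and finite, got {self.value}")


def occupancy_ratio(counts: PartitionCounts, sample: str = "") -> OccupancyRatio:
    """Compute OR = (wce_cal * ip_exp) / (wce_exp * ip_cal).

    Raises :class:`CalibrationError` naming the offending count if any of
    the four totals is zero (OR would be zero, infinite, or undefined).
    """
    for name in ("ip_cal", "wce_exp", "ip_exp", "wce_cal"):
        if getattr(counts, name) == 0:
            raise CalibrationError(
                f"cannot compute occupancy ratio: count {name} is zero"
            )
    value = (counts.wce_cal * counts.ip_exp) / (counts.wce_exp * counts.ip_cal)
    return OccupancyRatio(value=value, sample=sample)


def calibrate_track(
    track: PileupTrack,
    counts: PartitionCounts,
    or_: OccupancyRatio,
    per_reads: int = 1_000_000,
) -> CalibratedTrack:
    """Scale a raw coverage track into calibrated units.

    Every per-base value v becomes ``v * (per_reads / ip_exp) * OR`` where
    ``ip_exp`` is the number of experimental-genome IP reads constituting
    the track.  Normalising by the track's own read count makes the result
    independent of sequencing depth; values stay real-valued throughout.
    """
    if counts.ip_exp == 0:
        raise CalibrationError("cannot calibrate track: count ip_exp is zero")
    factor = per_reads / counts.ip_exp * or_.value
    return CalibratedTrack(track.chrom, track.length, track.values * factor)


def counts_from_partitions(ip, wce) -> PartitionCounts:
    """Assemble :class:`PartitionCounts` from the IP and WCE partitions."""
    from .reads import Bucket  # local import to avoid a cycle

    return PartitionCounts(
        ip_exp=ip.count(Bucket.EXPERIMENTAL),
        ip_cal=ip.count(Bucket.CALIBRATION),
        wce_exp=wce.count(Bucket.EXPERIMENTAL),
        wce_cal=wce.count(Bucket.CALIBRATION),
    )
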