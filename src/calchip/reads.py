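"""FASTQ preprocessing and read-to-genome assignment.

Preprocessing follows the calibrated ChIP-seq pipeline: the first
``head_trim`` bases of every read are removed along with any bases past
position ``max_end`` of the original read, and reads shorter than
``min_len`` after trimming are discarded ("shorter than" is strict: a
50 bp read survives the default 50 bp cutoff).

Assignment to a genome is done either by the internal exact-match aligner
(:func:`align_exact`, suitable for error-free synthetic reads) or by
reading externally produced SAM alignments (:func:`read_sam`).  The
species partition (:func:`partition_reads`) is sequential: reads are
aligned to the *calibration* genome first and only the leftovers are
offered to the experimental genome, so a read matching both species is
counted as calibration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Iterable, Sequence

import pysam

from .genome import Genome

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class SamParseError(ValueError):
    """A SAM file could not be parsed."""


@dataclass(frozen=True)
class Read:
    """A sequencing read: identifier, bases, and per-base quality string."""

    id: str
    sequence: str
    quality: str

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.quality):
            raise ValueError(
                f"read {self.id!r}: sequence length {len(self.sequence)} != "
                f"quality length {len(self.quality)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class AlignmentRecord:
    """Primary alignment of one read, in 0-based coordinates.

    ``mapped is False`` implies ``chrom``, ``pos`` and ``strand`` are all
    ``None``.  ``length`` is the aligned read length (used to span pileups).
    """

    read_id: str
    mapped: bool
    chrom: str | None = None
    pos: int | None = None
    strand: str | None = None
    length: int | None = None

    def __post_init__(self) -> None:
        if not self.mapped:
            if self.chrom is not None or self.pos is not None or self.strand is not None:
                raise ValueError(f"unmapped record {self.read_id!r} carries coordinates")
        else:
            if self.chrom is None or self.pos is None or self.strand not in ("+", "-"):
                raise ValueError(f"mapped record {self.read_id!r} missing coordinates")
            if self.pos < 0:
                raise ValueError(f"negative position for read {self.read_id!r}")


class Bucket(str, Enum):
    """Species assignment of a read after the sequential partition."""

    CALIBRATION = "calibration"
    EXPERIMENTAL = "experimental"
    UNMAPPED = "unmapped"


@dataclass
class PartitionedReads:
    """Outcome of the sequential two-genome partition.

    Every input read id appears exactly once in ``assignment``; the three
    buckets are disjoint and exhaustive.
    """

    assignment: dict[str, Bucket]
    alignments_exp: list[AlignmentRecord]
    alignments_cal: list[AlignmentRecord]

    def count(self, bucket: Bucket) -> int:
        return sum(1 for b in self.assignment.values() if b is bucket)

    def counts(self) -> dict[Bucket, int]:
        out = {b: 0 for b in Bucket}
        for b in self.assignment.values():
            out[b] += 1
        return out


def trim_reads(
    reads: Iterable[Read], head_trim: int = 10, max_end: int = 200
) -> list[Read]:
    """Remove the first ``head_trim`` bases and any bases after ``max_end``.

    Trimming is expressed on the original read coordinates: with the
    defaults, original bases 11..200 (1-based, inclusive) are kept, so the
    trimmed length is at most ``max_end - head_trim``.  Reads shorter than
    ``head_trim`` become empty reads; they are retained here and removed by
    :func:`filter_short`.
    """
    if head_trim < 0:
        raise ValueError("head_trim must be non-negative")
    if max_end <= head_trim:
        raise ValueError("max_end must exceed head_trim")
    return [
        Read(r.id, r.sequence[head_trim:max_end], r.quality[head_trim:max_end])
        for r in reads
    ]


def filter_short(reads: Iterable[Read], min_len: int = 50) -> list[Read]:
    """Drop reads strictly shorter than ``min_len``; order is preserved."""
    if min_len < 0:
        raise ValueError("min_len must be non-negative")
    kept = [r for r in reads if len(r) >= min_len]
    return kept


def preprocess(
    reads: Sequence[Read],
    head_trim: int = 10,
    max_end: int = 200,
    min_len: int = 50,
) -> list[Read]:
    """Trim then length-filter, logging how many reads were removed."""
    trimmed = trim_reads(reads, head_trim=head_trim, max_end=max_end)
    kept = filter_short(trimmed, min_len=min_len)
    logger.info(
        "preprocess: %d reads in, %d removed as shorter than %d bp, %d kept",
        len(trimmed), len(trimmed) - len(kept), min_len, len(kept),
    )
    return kept


def _align_one(read: Read, genome: Genome) -> AlignmentRecord:
    seq = read.sequence
    if not seq:
        return AlignmentRecord(read.id, False)
    rc = reverse_complement(seq)
    for chrom, ref in genome.chromosomes:
        candidates = []
        pos_fwd = ref.find(seq)
        if pos_fwd >= 0:
            candidates.append((pos_fwd, 0))
        pos_rev = ref.find(rc)
        if pos_rev >= 0:
            candidates.append((pos_rev, 1))
        if candidates:
            pos, strand_rank = min(candidates)
            return AlignmentRecord(
                read.id, True, chrom, pos, "+" if strand_rank == 0 else "-", len(seq)
            )
    return AlignmentRecord(read.id, False)


def align_exact(reads: Iterable[Read], genome: Genome) -> list[AlignmentRecord]:
    """Exact-match alignment of error-free reads.

    A read is mapped iff its sequence or reverse complement occurs verbatim
    in the genome.  The reported hit is the leftmost occurrence, searching
    chromosomes in genome order; within a chromosome, a forward and a
    reverse hit at the same position resolve to the forward strand.  Empty
    reads are unmapped.
    """
    return [_align_one(r, genome) for r in reads]


def partition_reads(
    reads: Sequence[Read],
    calibration: Genome,
    experimental: Genome,
    aligner: Callable[[Sequence[Read], Genome], list[AlignmentRecord]] = align_exact,
) -> PartitionedReads:
    """Sequentially partition reads between the two species.

    Reads are aligned to the calibration genome first; reads it claims are
    CALIBRATION regardless of whether they would also align to the
    experimental genome.  The remainder are aligned to the experimental
    genome; unmatched reads end up UNMAPPED.
    """
    ids = [r.id for r in reads]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate read ids in input")

    assignment: dict[str, Bucket] = {}
    alignments_cal: list[AlignmentRecord] = []
    leftovers: list[Read] = []
    for read, rec in zip(reads, aligner(reads, calibration)):
        if rec.mapped:
            assignment[read.id] = Bucket.CALIBRATION
            alignments_cal.append(rec)
        else:
            leftovers.append(read)

    alignments_exp: list[AlignmentRecord] = []
    for read, rec in zip(leftovers, aligner(leftovers, experimental)):
        if rec.mapped:
            assignment[read.id] = Bucket.EXPERIMENTAL
            alignments_exp.append(rec)
        else:
            assignment[read.id] = Bucket.UNMAPPED

    counts = {b: 0 for b in Bucket}
    for b in assignment.values():
        counts[b] += 1
    logger.info(
        "partition: %d calibration, %d experimental, %d unmapped of %d reads",
        counts[Bucket.CALIBRATION], counts[Bucket.EXPERIMENTAL],
        counts[Bucket.UNMAPPED], len(reads),
    )
    return PartitionedReads(assignment, alignments_exp, alignments_cal)


def partition_from_alignments(
    cal_records: Sequence[AlignmentRecord],
    exp_records: Sequence[AlignmentRecord],
) -> PartitionedReads:
    """Build a sequential partition from two pre-computed alignment sets.

    Real-data mode: ``cal_records`` and ``exp_records`` come from SAM files
    produced by an external aligner run against the calibration and
    experimental genomes respectively.  The calibration genome takes
    precedence, mirroring :func:`partition_reads`.
    """
    assignment: dict[str, Bucket] = {}
    alignments_cal = []
    for rec in cal_records:
        if rec.read_id in assignment:
            raise ValueError(f"duplicate read id {rec.read_id!r} in calibration SAM")
        if rec.mapped:
            assignment[rec.read_id] = Bucket.CALIBRATION
            alignments_cal.append(rec)
        else:
            assignment[rec.read_id] = Bucket.UNMAPPED
    alignments_exp = []
    for rec in exp_records:
        if assignment.get(rec.read_id) is Bucket.CALIBRATION:
            continue
        if rec.mapped:
            assignment[rec.read_id] = Bucket.EXPERIMENTAL
            alignments_exp.append(rec)
        else:
            assignment.setdefault(rec.read_id, Bucket.UNMAPPED)
    return PartitionedReads(assignment, alignments_exp, alignments_cal)


def read_sam(path: str, genome: Genome | None = None) -> list[AlignmentRecord]:
    """Read primary alignments from a SAM file.

    Secondary (0x100) and supplementary (0x800) records are skipped; FLAG
    0x4 yields an unmapped record.  SAM's 1-based POS is converted to the
    internal 0-based convention by the reader itself, so downstream code
    never sees 1-based coordinates.  If ``genome`` is given, reference
    names and positions are validated against it.
    """
    records: list[AlignmentRecord] = []
    n_secondary = 0
    try:
        with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
            for rec in sam:
                if rec.is_secondary or rec.is_supplementary:
                    n_secondary += 1
                    continue
                if rec.is_unmapped:
                    records.append(AlignmentRecord(rec.query_name, False))
                    continue
                length = rec.query_length or rec.infer_read_length()
                if genome is not None:
                    if rec.reference_name not in genome:
                        raise SamParseError(
                            f"{path}: read {rec.query_name!r} maps to unknown "
                            f"chromosome {rec.reference_name!r}"
                        )
                    if rec.reference_start >= len(genome.sequence(rec.reference_name)):
                        raise SamParseError(
                            f"{path}: read {rec.query_name!r} position "
                            f"{rec.reference_start} beyond chromosome end"
                        )
                records.append(
                    AlignmentRecord(
                        rec.query_name,
                        True,
                        rec.reference_name,
                        rec.reference_start,  # pysam already gives 0-based
                        "-" if rec.is_reverse else "+",
                        length,
                    )
                )
    except (ValueError, OSError) as exc:
        if isinstance(exc, SamParseError):
            raise
        raise SamParseError(f"cannot parse SAM file {path}: {exc}") from exc
    if n_secondary:
        logger.info("read_sam: skipped %d secondary/supplementary records", n_secondary)
    return records
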