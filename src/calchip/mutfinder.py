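"""Candidate suppressor-mutation identification from SNP call sets.

A suppressor screen isolates spontaneous mutants that restore growth to a
conditional mutant; the causal variant is then located by whole-genome
sequencing.  Given SNP sets called for the suppressor strain, its parental
strain, and backcrossed clones of the suppressor:

* SNPs shared with the parental strain are removed (they predate the
  suppressor event);
* only SNPs retained in *every* backcrossed clone are kept (causal
  variants co-segregate with the phenotype);
* SNPs lying outside annotated genes are dropped.

SNP identity is the triple ``(chrom, pos, alt)`` — matching on position
alone would conflate different substitutions at one site.  Only
single-nucleotide variants participate (indels are skipped at VCF reading
time, matching skip-indels calling upstream).  Genotype and quality fields
are ignored: filtering is by set membership only, and the number of
records skipped as non-SNVs is logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import pysam
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

_BASES = frozenset("ACGT")


class VcfParseError(ValueError):
    """A VCF file could not be parsed."""


@dataclass(frozen=True, order=True)
class Snp:
    """A single-nucleotide variant; ``pos`` is 0-based internally."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.ref not in _BASES or self.alt not in _BASES:
            raise ValueError(f"SNV alleles must be single A/C/G/T bases: {self}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt at {self.chrom}:{self.pos}")
        if self.pos < 0:
            raise ValueError(f"negative position: {self}")

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chrom, self.pos, self.alt)


class SnpSet:
    """A set of SNVs keyed by (chrom, pos, alt), supporting set algebra."""

    def __init__(self, snps: Iterable[Snp] = ()) -> None:
        self._by_key: dict[tuple[str, int, str], Snp] = {}
        for snp in snps:
            self.add(snp)

    def add(self, snp: Snp) -> None:
        existing = self._by_key.get(snp.key)
        if existing is not None and existing.ref != snp.ref:
            raise ValueError(f"conflicting ref alleles at {snp.chrom}:{snp.pos}")
        self._by_key[snp.key] = snp

    def __len__(self) -> int:
        return len(self._by_key)

    def __iter__(self) -> Iterator[Snp]:
        return iter(sorted(self._by_key.values()))

    def __contains__(self, snp: Snp) -> bool:
        return snp.key in self._by_key

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SnpSet):
            return NotImplemented
        return self._by_key == other._by_key

    def __repr__(self) -> str:
        return f"SnpSet({len(self)} SNVs)"

    def difference(self, other: "SnpSet") -> "SnpSet":
        return SnpSet(s for s in self if s not in other)

    def intersection(self, *others: "SnpSet") -> "SnpSet":
        return SnpSet(s for s in self if all(s in o for o in others))

    def union(self, *others: "SnpSet") -> "SnpSet":
        out = SnpSet(self)
        for other in others:
            for s in other:
                out.add(s)
        return out


@dataclass
class GeneModel:
    """Gene intervals, 0-based half-open, possibly overlapping."""

    intervals: tuple[tuple[str, int, int, str], ...]
    _trees: dict[str, IntervalTree] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.intervals = tuple(self.intervals)
        trees: dict[str, IntervalTree] = {}
        for chrom, start, end, name in self.intervals:
            if start >= end:
                raise ValueError(f"gene {name!r}: start {start} >= end {end}")
            if not name:
                raise ValueError("gene names must be non-empty")
            trees.setdefault(chrom, IntervalTree()).addi(start, end, name)
        self._trees = trees

    def __len__(self) -> int:
        return len(self.intervals)

    def overlapping(self, chrom: str, pos: int) -> list[str]:
        """Names of genes whose [start, end) interval contains ``pos``."""
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return sorted(iv.data for iv in tree.at(pos))


def read_vcf_snps(path: str) -> SnpSet:
    """Read biallelic SNVs from a VCF (v4.x) into a :class:`SnpSet`.

    Multi-allelic records are expanded to one SNV per ALT; records whose
    REF or an ALT is not a single base (indels, symbolic alleles) are
    skipped and counted in the log.  VCF's 1-based POS becomes 0-based.
    """
    snps = SnpSet()
    n_skipped = 0
    try:
        with pysam.VariantFile(str(path)) as vcf:
            for rec in vcf:
                ref = (rec.ref or "").upper()
                for alt in rec.alts or ():
                    alt = (alt or "").upper()
                    if len(ref) == 1 and ref in _BASES and len(alt) == 1 and alt in _BASES:
                        snps.add(Snp(rec.chrom, rec.start, ref, alt))
                    else:
                        n_skipped += 1
    except (ValueError, OSError) as exc:
        raise VcfParseError(f"cannot parse VCF {path}: {exc}") from exc
    if n_skipped:
        logger.info("read_vcf_snps: %s: skipped %d non-SNV alleles", path, n_skipped)
    return snps


def subtract_parental(suppressor: SnpSet, parental: SnpSet) -> SnpSet:
    """Remove SNPs also present in the parental strain (pre-existing
    background variants cannot be causal)."""
    return suppressor.difference(parental)


def intersect_backcross(suppressor: SnpSet, clones: Sequence[SnpSet]) -> SnpSet:
    """Keep only SNPs present in every backcrossed clone.

    The causal variant co-segregates with the suppression phenotype, so it
    survives each backcross; unlinked noise variants segregate away.
    """
    if not clones:
        raise ValueError("at least one backcrossed clone is required")
    return suppressor.intersection(*clones)


def annotate_and_filter(snps: SnpSet, genes: GeneModel) -> list[tuple[Snp, str]]:
    """Annotate SNPs with overlapping genes, dropping intergenic SNPs.

    Each SNP overlapping >= 1 gene yields one row per overlapping gene;
    rows come back sorted by (chrom, pos).  Interval membership is strict
    half-open: a SNP at ``end`` is outside ``[start, end)``.
    """
    rows: list[tuple[Snp, str]] = []
    for snp in snps:
        for gene in genes.overlapping(snp.chrom, snp.pos):
            rows.append((snp, gene))
    rows.sort(key=lambda r: (r[0].chrom, r[0].pos, r[0].alt, r[1]))
    return rows


def find_candidates(
    suppressor: SnpSet,
    parental: SnpSet,
    clones: Sequence[SnpSet],
    genes: GeneModel,
) -> list[tuple[Snp, str]]:
    """Full candidate-identification procedure.

    Parental subtraction, then backcross intersection (skipped when no
    clones are supplied — parental-only mode), then gene-overlap filtering.
    """
    remaining = subtract_parental(suppressor, parental)
    if clones:
        remaining = intersect_backcross(remaining, clones)
    candidates = annotate_and_filter(remaining, genes)
    logger.info(
        "find_candidates: %d suppressor SNVs -> %d after filtering -> "
        "%d annotated candidate rows",
        len(suppressor), len(remaining), len(candidates),
    )
    return candidates
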