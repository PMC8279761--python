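"""Readers and writers for the pipeline's on-disk formats.

Conventions: internal coordinates are 0-based half-open everywhere;
conversions to the 1-based conventions of SAM/VCF/GFF3 (and back) happen
only inside the readers and writers in this module and in
:func:`calchip.reads.read_sam` / :func:`calchip.mutfinder.read_vcf_snps`.
Anchor TSVs and BED are 0-based; bedGraph intervals are 0-based half-open.
bedGraph omits zero runs — zero-filling is restored at read time from the
chromosome lengths, mirroring how uncovered positions are defined to be
exactly zero.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .calibrate import OccupancyRatio, PartitionCounts
from .genome import Genome
from .mutfinder import GeneModel, Snp, SnpSet
from .profiles import CalibratedTrack, MetaProfile, PileupTrack
from .reads import Read


# ---------------------------------------------------------------- FASTA/FASTQ

def write_fasta(genome: Genome, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=chrom, description="")
        for chrom, seq in genome.chromosomes
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(
    path: str | Path, name: str, anchors: Mapping[str, int] | None = None
) -> Genome:
    chroms = tuple(
        (rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")
    )
    return Genome(name, chroms, anchors)


def write_fastq(reads: Iterable[Read], path: str | Path) -> None:
    def records():
        for r in reads:
            rec = SeqRecord(Seq(r.sequence), id=r.id, description="")
            rec.letter_annotations["phred_quality"] = [ord(q) - 33 for q in r.quality]
            yield rec

    SeqIO.write(records(), str(path), "fastq")


def read_fastq(path: str | Path) -> list[Read]:
    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        out.append(Read(rec.id, str(rec.seq).upper(), qual))
    return out


# ------------------------------------------------------------------- anchors

def write_anchors(anchors: Mapping[str, int], path: str | Path) -> None:
    """Anchor table: TSV of (chrom, position), 0-based."""
    df = pd.DataFrame(
        {"chrom": list(anchors.keys()), "position": list(anchors.values())}
    )
    df.to_csv(path, sep="\t", index=False)


def read_anchors(path: str | Path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "position": int})
    if list(df.columns) != ["chrom", "position"]:
        raise ValueError(f"{path}: expected columns 'chrom' and 'position'")
    return dict(zip(df["chrom"], df["position"]))


def write_chrom_sizes(lengths: Mapping[str, int], path: str | Path) -> None:
    pd.DataFrame(
        {"chrom": list(lengths.keys()), "length": list(lengths.values())}
    ).to_csv(path, sep="\t", index=False, header=False)


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"],
                     dtype={"chrom": str, "length": int})
    return dict(zip(df["chrom"], df["length"]))


# ------------------------------------------------------------ coverage tracks

def write_bedgraph(tracks: Sequence[PileupTrack], path: str | Path) -> None:
    """Write tracks to one bedGraph file (0-based half-open, zeros omitted)."""
    with open(path, "w") as fh:
        for track in tracks:
            vals = np.asarray(track.values)
            # run-length boundaries of constant value
            change = np.flatnonzero(vals[1:] != vals[:-1]) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [track.length]))
            for s, e in zip(starts, ends):
                v = vals[s]
                if v != 0:
                    fh.write(f"{track.chrom}\t{s}\t{e}\t{v:.10g}\n")


def read_bedgraph(
    path: str | Path, chrom_lengths: Mapping[str, int], calibrated: bool = True
) -> list[PileupTrack]:
    """Read a bedGraph back into dense zero-filled tracks.

    ``chrom_lengths`` supplies the full set of chromosomes (bedGraph does
    not carry lengths, and zero-only chromosomes are absent from the file).
    """
    arrays = {c: np.zeros(n) for c, n in chrom_lengths.items()}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("track", "#")):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 bedGraph columns")
            chrom, start, end, value = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
            if chrom not in arrays:
                raise ValueError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            if not 0 <= start < end <= chrom_lengths[chrom]:
                raise ValueError(f"{path}:{lineno}: interval outside chromosome")
            arrays[chrom][start:end] = value
    cls = CalibratedTrack if calibrated else PileupTrack
    return [cls(c, n, arrays[c]) for c, n in chrom_lengths.items()]


def write_wiggle(tracks: Sequence[PileupTrack], path: str | Path) -> None:
    """Fixed-step wiggle (1-based starts per the wiggle convention)."""
    with open(path, "w") as fh:
        for track in tracks:
            fh.write(f"fixedStep chrom={track.chrom} start=1 step=1\n")
            fh.write("\n".join(f"{v:.10g}" for v in track.values))
            fh.write("\n")


# ------------------------------------------------------------- meta-profiles

def write_meta_profile(profile: MetaProfile, path: str | Path) -> None:
    pd.DataFrame(
        {
            "offset": profile.offsets,
            "mean_signal": profile.mean_signal,
            "n_contributing": profile.n_contributing,
        }
    ).to_csv(path, sep="\t", index=False, na_rep="NA")


def read_meta_profile(path: str | Path) -> MetaProfile:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    return MetaProfile(
        df["offset"].to_numpy(int),
        df["mean_signal"].to_numpy(float),
        df["n_contributing"].to_numpy(int),
    )


# ------------------------------------------------- partition / OR reporting

def write_partition_tsv(
    counts: PartitionCounts, sample: str, path: str | Path, n_unmapped: Mapping[str, int] | None = None
) -> None:
    rows = [
        (sample, "ip", "experimental", counts.ip_exp),
        (sample, "ip", "calibration", counts.ip_cal),
        (sample, "wce", "experimental", counts.wce_exp),
        (sample, "wce", "calibration", counts.wce_cal),
    ]
    if n_unmapped:
        for library, n in n_unmapped.items():
            rows.append((sample, library, "unmapped", n))
    pd.DataFrame(rows, columns=["sample", "library", "bucket", "count"]).to_csv(
        path, sep="\t", index=False
    )


def write_or_report(
    counts: PartitionCounts, or_: OccupancyRatio, path: str | Path
) -> None:
    pd.DataFrame(
        [
            {
                "sample": or_.sample,
                "ip_exp": counts.ip_exp,
                "ip_cal": counts.ip_cal,
                "wce_exp": counts.wce_exp,
                "wce_cal": counts.wce_cal,
                "OR": or_.value,
            }
        ]
    ).to_csv(path, sep="\t", index=False)


# -------------------------------------------------------------------- VCF

def write_vcf(
    snps: SnpSet | Iterable[Snp],
    path: str | Path,
    contigs: Mapping[str, int] | None = None,
) -> None:
    """Minimal VCF v4.2 (SNVs only); internal 0-based POS becomes 1-based."""
    records = sorted(snps, key=lambda s: (s.chrom, s.pos, s.alt))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        if contigs:
            for chrom, length in contigs.items():
                fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for s in records:
            fh.write(f"{s.chrom}\t{s.pos + 1}\t.\t{s.ref}\t{s.alt}\t.\t.\t.\n")


# ---------------------------------------------------------------- gene models

def write_genes_bed(genes: GeneModel, path: str | Path) -> None:
    """BED4: 0-based half-open intervals with the gene name in column 4."""
    with open(path, "w") as fh:
        for chrom, start, end, name in genes.intervals:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\n")


def read_genes_bed(path: str | Path) -> GeneModel:
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{lineno}: BED gene records need 4 columns")
            intervals.append((parts[0], int(parts[1]), int(parts[2]), parts[3]))
    return GeneModel(tuple(intervals))


def read_genes_gff3(
    path: str | Path, feature_types: frozenset[str] = frozenset({"gene"})
) -> GeneModel:
    """Gene intervals from GFF3 (1-based inclusive -> 0-based half-open)."""
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ValueError(f"{path}:{lineno}: GFF3 records need 9 columns")
            if parts[2] not in feature_types:
                continue
            attrs = dict(
                kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
            )
            name = attrs.get("Name") or attrs.get("ID") or attrs.get("gene_id")
            if not name:
                raise ValueError(f"{path}:{lineno}: gene record without Name/ID")
            intervals.append((parts[0], int(parts[3]) - 1, int(parts[4]), name))
    return GeneModel(tuple(intervals))


def read_genes(path: str | Path) -> GeneModel:
    """Dispatch on extension: .bed -> BED, .gff/.gff3 -> GFF3."""
    suffix = Path(path).suffix.lower()
    if suffix == ".bed":
        return read_genes_bed(path)
    if suffix in (".gff", ".gff3"):
        return read_genes_gff3(path)
    raise ValueError(f"unrecognised gene-model extension {suffix!r} for {path}")


# ----------------------------------------------------------------- truth JSON

def write_truth_json(truth, path: str | Path) -> None:
    """Persist simulator ground truth (summary statistics, not full vectors)."""
    payload = {
        "true_or": truth.true_or,
        "mean_occ_exp": {
            c: float(np.mean(v)) for c, v in truth.occupancy_exp.items()
        },
        "mean_occ_cal": {
            c: float(np.mean(v)) for c, v in truth.occupancy_cal.items()
        },
        "planted_snp": list(truth.planted_snp) if truth.planted_snp else None,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_truth_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


# ------------------------------------------------------------- candidate TSV

def write_candidates(rows: Sequence[tuple[Snp, str]], path: str | Path) -> None:
    """Candidate table; POS reported 1-based for human consumption."""
    pd.DataFrame(
        [
            {"chrom": s.chrom, "pos": s.pos + 1, "ref": s.ref, "alt": s.alt,
             "gene": gene}
            for s, gene in rows
        ],
        columns=["chrom", "pos", "ref", "alt", "gene"],
    ).to_csv(path, sep="\t", index=False)
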