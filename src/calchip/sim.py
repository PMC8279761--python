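"""Synthetic two-species calibrated ChIP-seq experiments with known truth.

The generator emulates the spike-in experimental design: cells of the
experimental species are mixed with calibration-species cells at a fixed
ratio (default 3:1, matching 15 vs 5 OD units of culture), and two
libraries are sequenced per sample — the immunoprecipitate (IP) and the
whole-cell extract (WCE).  Both libraries contain reads from both genomes.

The occupancy landscape on the experimental genome is a flat background
plus a boxcar peak of configurable width and fold-amplitude centred on
each chromosome's anchor (the stand-in for a centromeric CDEIII element),
rescaled so the genome-wide mean equals ``mean_occ_exp``; the calibration
genome is flat at ``mean_occ_cal``.  WCE read starts are uniform over the
two genomes weighted by the cell mix; IP read starts are drawn with
probability proportional to occupancy times the same cell-mix weighting.
The boxcar shape keeps every expected read fraction analytically
computable, so downstream estimators can be tested against closed forms.

Reads are single-end, forward-strand, error-free by default (length
``read_len``); the true originating genome, chromosome and start position
are recorded in each read id, and :func:`true_alignments` /
:func:`true_counts` recover them, so ground truth never has to be
re-inferred by alignment.  Everything is a pure function of (config, seed).

The module also plants SNP-table fixtures for the suppressor-mutation
finder: a parental background, a suppressor strain carrying exactly one
causal SNV inside a gene, and backcrossed clones that retain the causal
SNV plus private noise.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .calibrate import PartitionCounts
from .genome import Genome
from .mutfinder import GeneModel, Snp, SnpSet
from .reads import AlignmentRecord, Read

_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASES = "ACGT"

EXP_GENOME_NAME = "exp"
CAL_GENOME_NAME = "cal"


class SimulationError(ValueError):
    """The generator cannot honour this configuration."""


@dataclass(frozen=True)
class SimConfig:
    """Shape and depth of a simulated calibrated ChIP-seq experiment.

    Defaults define the standard study conditions used throughout the test
    suite: a 16-chromosome experimental genome (one anchor per chromosome,
    as for the 16 budding-yeast centromeres), a smaller calibration
    genome, a 3:1 experimental:calibration cell mix, and 200,000 reads per
    library at 50 bp.
    """

    seed: int = 0
    n_chroms_exp: int = 16
    chrom_len_exp: int = 30_000
    n_chroms_cal: int = 4
    chrom_len_cal: int = 30_000
    cell_mix_exp_to_cal: float = 3.0
    mean_occ_exp: float = 1.0
    mean_occ_cal: float = 1.0
    peak_width: int = 2_000
    peak_amplitude: float = 8.0
    read_len: int = 50
    n_ip_reads: int = 200_000
    n_wce_reads: int = 200_000
    error_rate: float = 0.0

    def validate(self) -> None:
        positive = (
            "n_chroms_exp", "chrom_len_exp", "n_chroms_cal", "chrom_len_cal",
            "peak_width", "read_len", "n_ip_reads", "n_wce_reads",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise SimulationError(f"{name} must be positive")
        for name in ("cell_mix_exp_to_cal", "mean_occ_exp", "mean_occ_cal",
                     "peak_amplitude"):
            if getattr(self, name) <= 0:
                raise SimulationError(f"{name} must be positive")
        if not 0 <= self.error_rate < 1:
            raise SimulationError("error_rate must lie in [0, 1)")
        if self.peak_width >= self.chrom_len_exp:
            raise SimulationError("peak_width must be smaller than chrom_len_exp")
        if min(self.chrom_len_exp, self.chrom_len_cal) < self.read_len:
            raise SimulationError("chromosomes must be at least read_len long")


@dataclass(frozen=True)
class SimTruth:
    """Ground truth of one simulated experiment.

    ``true_or`` equals the ratio of mean occupancies of the two genomes —
    the value the occupancy-ratio estimator should recover.
    """

    true_or: float
    occupancy_exp: Mapping[str, np.ndarray]
    occupancy_cal: Mapping[str, np.ndarray]
    planted_snp: tuple[str, int, str, str] | None = None


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return _BASE_BYTES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")


def make_genomes(config: SimConfig) -> tuple[Genome, Genome]:
    """Generate the (experimental, calibration) genome pair.

    Sequences are i.i.d. uniform over A/C/G/T (no repeats, so exact-match
    alignment of >= 20 bp reads is unambiguous with overwhelming
    probability).  Each experimental chromosome receives one anchor, at
    least ``peak_width`` away from both ends so the enrichment peak fits.
    """
    config.validate()
    if config.chrom_len_exp < 2 * config.peak_width:
        raise SimulationError(
            f"cannot place an anchor >= peak_width={config.peak_width} from both "
            f"ends of a {config.chrom_len_exp} bp chromosome"
        )
    rng = np.random.default_rng(config.seed)
    exp_chroms = []
    anchors = {}
    for i in range(config.n_chroms_exp):
        name = f"{EXP_GENOME_NAME}_chr{i + 1:02d}"
        exp_chroms.append((name, _random_sequence(rng, config.chrom_len_exp)))
        anchors[name] = int(
            rng.integers(config.peak_width, config.chrom_len_exp - config.peak_width + 1)
        )
    cal_chroms = [
        (f"{CAL_GENOME_NAME}_chr{i + 1:02d}", _random_sequence(rng, config.chrom_len_cal))
        for i in range(config.n_chroms_cal)
    ]
    experimental = Genome(EXP_GENOME_NAME, tuple(exp_chroms), anchors)
    calibration = Genome(CAL_GENOME_NAME, tuple(cal_chroms), None)
    return experimental, calibration


def occupancy_vectors(
    genomes: tuple[Genome, Genome], config: SimConfig
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Per-base occupancy for both genomes.

    Experimental occupancy: background 1 with a boxcar of height
    ``peak_amplitude`` (fold over background) of width ``peak_width``
    centred on each anchor, scaled so the genome-wide mean is exactly
    ``mean_occ_exp``.  Calibration occupancy is flat at ``mean_occ_cal``.
    """
    experimental, calibration = genomes
    config.validate()
    shapes: dict[str, np.ndarray] = {}
    for chrom, seq in experimental.chromosomes:
        s = np.ones(len(seq))
        anchor = experimental.anchors[chrom]
        start = anchor - config.peak_width // 2
        s[max(start, 0) : min(start + config.peak_width, len(seq))] = config.peak_amplitude
        shapes[chrom] = s
    total = sum(len(s) for s in shapes.values())
    mass = sum(float(s.sum()) for s in shapes.values())
    scale = config.mean_occ_exp * total / mass
    occ_exp = {c: s * scale for c, s in shapes.items()}
    occ_cal = {
        c: np.full(len(seq), float(config.mean_occ_cal))
        for c, seq in calibration.chromosomes
    }
    return occ_exp, occ_cal


def _true_or(occ_exp: Mapping[str, np.ndarray], occ_cal: Mapping[str, np.ndarray]) -> float:
    mean_exp = sum(float(v.sum()) for v in occ_exp.values()) / sum(
        v.size for v in occ_exp.values()
    )
    mean_cal = sum(float(v.sum()) for v in occ_cal.values()) / sum(
        v.size for v in occ_cal.values()
    )
    return mean_exp / mean_cal


def _valid_start_weights(
    genome: Genome, occ: Mapping[str, np.ndarray], read_len: int
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Concatenated occupancy over valid start positions (reads must fit)."""
    names = list(genome.chrom_names)
    parts = [occ[c][: len(genome.sequence(c)) - read_len + 1] for c in names]
    weights = np.concatenate(parts)
    offsets = np.cumsum([0] + [p.size for p in parts])
    return names, weights, offsets


def _sample_flat(
    rng: np.random.Generator, n: int, weights: np.ndarray, uniform: bool
) -> np.ndarray:
    if n == 0:
        return np.empty(0, dtype=np.int64)
    if uniform:
        return rng.integers(0, weights.size, size=n)
    return rng.choice(weights.size, size=n, replace=True, p=weights / weights.sum())


@dataclass(frozen=True)
class _Draws:
    """Sampled start positions for one library, per genome."""

    exp_chrom_idx: np.ndarray
    exp_pos: np.ndarray
    cal_chrom_idx: np.ndarray
    cal_pos: np.ndarray

    @property
    def n_exp(self) -> int:
        return self.exp_pos.size

    @property
    def n_cal(self) -> int:
        return self.cal_pos.size


def _flat_to_chrom_pos(flat: np.ndarray, offsets: np.ndarray):
    idx = np.searchsorted(offsets, flat, side="right") - 1
    return idx, flat - offsets[idx]


def _draw_library(
    rng: np.random.Generator,
    n_reads: int,
    mix: float,
    exp_weights: np.ndarray,
    exp_offsets: np.ndarray,
    cal_weights: np.ndarray,
    cal_offsets: np.ndarray,
    uniform: bool,
) -> _Draws:
    w_exp = mix * float(exp_weights.sum())
    w_cal = float(cal_weights.sum())
    n_exp = int(rng.binomial(n_reads, w_exp / (w_exp + w_cal)))
    n_cal = n_reads - n_exp
    exp_idx, exp_pos = _flat_to_chrom_pos(
        _sample_flat(rng, n_exp, exp_weights, uniform), exp_offsets
    )
    cal_idx, cal_pos = _flat_to_chrom_pos(
        _sample_flat(rng, n_cal, cal_weights, uniform), cal_offsets
    )
    return _Draws(exp_idx, exp_pos, cal_idx, cal_pos)


def sample_positions(
    genomes: tuple[Genome, Genome], config: SimConfig
) -> tuple[_Draws, _Draws, SimTruth]:
    """Sample IP and WCE read-start positions (no sequences materialised)."""
    experimental, calibration = genomes
    config.validate()
    occ_exp, occ_cal = occupancy_vectors(genomes, config)
    rng = np.random.default_rng(config.seed + 1)  # distinct stream from make_genomes
    _, ip_w_exp, off_exp = _valid_start_weights(experimental, occ_exp, config.read_len)
    _, ip_w_cal, off_cal = _valid_start_weights(calibration, occ_cal, config.read_len)
    wce_w_exp = np.ones(ip_w_exp.size)
    wce_w_cal = np.ones(ip_w_cal.size)
    mix = config.cell_mix_exp_to_cal
    ip = _draw_library(rng, config.n_ip_reads, mix, ip_w_exp, off_exp,
                       ip_w_cal, off_cal, uniform=False)
    wce = _draw_library(rng, config.n_wce_reads, mix, wce_w_exp, off_exp,
                        wce_w_cal, off_cal, uniform=True)
    truth = SimTruth(_true_or(occ_exp, occ_cal), occ_exp, occ_cal)
    return ip, wce, truth


def simulate_counts(
    genomes: tuple[Genome, Genome], config: SimConfig
) -> tuple[PartitionCounts, SimTruth]:
    """Ground-truth partition counts of a simulated experiment.

    Equivalent to simulating full reads and counting their true genomes of
    origin, but without materialising sequences — handy at high depth.
    """
    ip, wce, truth = sample_positions(genomes, config)
    counts = PartitionCounts(
        ip_exp=ip.n_exp, ip_cal=ip.n_cal, wce_exp=wce.n_exp, wce_cal=wce.n_cal
    )
    return counts, truth


def _materialise(
    sample: str,
    genome: Genome,
    chrom_idx: np.ndarray,
    pos: np.ndarray,
    config: SimConfig,
    rng: np.random.Generator,
    serial_start: int,
) -> list[Read]:
    seqs = [s for _, s in genome.chromosomes]
    names = genome.chrom_names
    qual = "I" * config.read_len
    reads = []
    for serial, (ci, p) in enumerate(zip(chrom_idx, pos), start=serial_start):
        seq = seqs[ci][p : p + config.read_len]
        if config.error_rate > 0:
            seq = _inject_errors(seq, config.error_rate, rng)
        reads.append(
            Read(f"{sample}:{genome.name}:{names[ci]}:{int(p)}:{serial}", seq, qual)
        )
    return reads


def _inject_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    n_err = rng.binomial(len(seq), rate)
    if n_err == 0:
        return seq
    positions = rng.choice(len(seq), size=n_err, replace=False)
    chars = list(seq)
    for p in positions:
        alternatives = [b for b in _BASES if b != chars[p]]
        chars[p] = alternatives[rng.integers(0, 3)]
    return "".join(chars)


def simulate_experiment(
    genomes: tuple[Genome, Genome], config: SimConfig
) -> tuple[list[Read], list[Read], SimTruth]:
    """Simulate full IP and WCE read sets with ground truth.

    Returns ``(ip_reads, wce_reads, truth)``; read counts match
    ``n_ip_reads`` / ``n_wce_reads`` exactly.  Read ids have the form
    ``{sample}:{genome}:{chrom}:{start}:{serial}`` so the true origin of
    every read travels with it.
    """
    experimental, calibration = genomes
    ip, wce, truth = sample_positions(genomes, config)
    rng = np.random.default_rng(config.seed + 2)  # error-injection stream
    ip_reads = _materialise("ip", experimental, ip.exp_chrom_idx, ip.exp_pos,
                            config, rng, 0)
    ip_reads += _materialise("ip", calibration, ip.cal_chrom_idx, ip.cal_pos,
                             config, rng, ip.n_exp)
    wce_reads = _materialise("wce", experimental, wce.exp_chrom_idx, wce.exp_pos,
                             config, rng, 0)
    wce_reads += _materialise("wce", calibration, wce.cal_chrom_idx, wce.cal_pos,
                              config, rng, wce.n_exp)
    return ip_reads, wce_reads, truth


def true_origin(read: Read) -> tuple[str, str, str, int]:
    """Decode (sample, genome, chrom, start) from a simulated read's id."""
    sample, genome_name, chrom, pos, _serial = read.id.split(":")
    return sample, genome_name, chrom, int(pos)


def true_alignments(reads: Sequence[Read]) -> dict[str, list[AlignmentRecord]]:
    """Ground-truth alignments of simulated reads, keyed by genome name."""
    out: dict[str, list[AlignmentRecord]] = defaultdict(list)
    for r in reads:
        _, genome_name, chrom, pos = true_origin(r)
        out[genome_name].append(
            AlignmentRecord(r.id, True, chrom, pos, "+", len(r.sequence))
        )
    return dict(out)


def true_counts(ip_reads: Sequence[Read], wce_reads: Sequence[Read]) -> PartitionCounts:
    """Ground-truth partition counts from simulated read ids."""
    def tally(reads: Sequence[Read]) -> tuple[int, int]:
        n_exp = sum(1 for r in reads if true_origin(r)[1] == EXP_GENOME_NAME)
        return n_exp, len(reads) - n_exp

    ip_exp, ip_cal = tally(ip_reads)
    wce_exp, wce_cal = tally(wce_reads)
    return PartitionCounts(ip_exp=ip_exp, ip_cal=ip_cal, wce_exp=wce_exp, wce_cal=wce_cal)


def simulate_ip_alignments(
    genomes: tuple[Genome, Genome], config: SimConfig
) -> tuple[list[AlignmentRecord], PartitionCounts, SimTruth]:
    """Ground-truth experimental-genome IP alignments plus partition counts.

    Equivalent to ``simulate_experiment`` followed by perfect partitioning
    and ``true_alignments``, but skips sequence materialisation — the
    economical route to coverage tracks at high depth.
    """
    experimental, _ = genomes
    ip, wce, truth = sample_positions(genomes, config)
    names = experimental.chrom_names
    alignments = [
        AlignmentRecord(f"ip:{EXP_GENOME_NAME}:{names[ci]}:{int(p)}:{i}", True,
                        names[ci], int(p), "+", config.read_len)
        for i, (ci, p) in enumerate(zip(ip.exp_chrom_idx, ip.exp_pos))
    ]
    counts = PartitionCounts(
        ip_exp=ip.n_exp, ip_cal=ip.n_cal, wce_exp=wce.n_exp, wce_cal=wce.n_cal
    )
    return alignments, counts, truth


def simulate_gene_model(
    genome: Genome, n_genes: int = 20, gene_len: int = 800, seed: int = 0
) -> GeneModel:
    """Place ``n_genes`` gene intervals of ``gene_len`` bp on a genome."""
    if n_genes <= 0 or gene_len <= 0:
        raise SimulationError("n_genes and gene_len must be positive")
    rng = np.random.default_rng(seed)
    chroms = [(c, len(s)) for c, s in genome.chromosomes if len(s) > gene_len]
    if not chroms:
        raise SimulationError("no chromosome long enough to hold a gene")
    intervals = []
    for i in range(n_genes):
        chrom, length = chroms[i % len(chroms)]
        start = int(rng.integers(0, length - gene_len))
        intervals.append((chrom, start, start + gene_len, f"GENE{i + 1:04d}"))
    return GeneModel(tuple(intervals))


def simulate_snp_tables(
    seed: int,
    genome: Genome,
    gene_model: GeneModel,
    n_parental: int = 20,
    n_suppressor_private: int = 5,
    n_noise_per_clone: int = 5,
    n_clones: int = 2,
) -> tuple[SnpSet, SnpSet, list[SnpSet], Snp]:
    """Plant SNP tables for a suppressor screen with one causal SNV.

    The parental strain carries ``n_parental`` background SNVs, all also
    present in the suppressor.  The suppressor additionally carries exactly
    one planted causal SNV inside a gene plus ``n_suppressor_private``
    incidental SNVs.  Each backcrossed clone carries the causal SNV plus
    ``n_noise_per_clone`` private SNVs absent from every other table, so
    with >= 1 clone the causal SNV is the unique in-gene variant surviving
    parental subtraction and backcross intersection.
    """
    genes = [iv for iv in gene_model.intervals if iv[0] in genome.chrom_names]
    if not genes:
        raise SimulationError("gene model contains no gene on this genome")
    rng = np.random.default_rng(seed)

    lengths = genome.lengths
    names = list(genome.chrom_names)
    offsets = np.cumsum([0] + [lengths[c] for c in names])
    total = int(offsets[-1])

    g_chrom, g_start, g_end, _ = genes[int(rng.integers(len(genes)))]
    planted_pos = int(rng.integers(g_start, g_end))
    planted_flat = int(offsets[names.index(g_chrom)]) + planted_pos

    n_other = n_parental + n_suppressor_private + n_clones * n_noise_per_clone
    if n_other >= total:
        raise SimulationError("genome too small for the requested number of SNVs")
    flats = rng.choice(total, size=n_other + 1, replace=False)
    flats = [int(f) for f in flats if int(f) != planted_flat][:n_other]

    def snp_at(flat: int) -> Snp:
        idx = int(np.searchsorted(offsets, flat, side="right")) - 1
        chrom = names[idx]
        pos = flat - int(offsets[idx])
        ref = genome.sequence(chrom)[pos]
        alternatives = [b for b in _BASES if b != ref]
        return Snp(chrom, pos, ref, alternatives[int(rng.integers(0, 3))])

    planted_ref = genome.sequence(g_chrom)[planted_pos]
    planted = Snp(
        g_chrom, planted_pos, planted_ref,
        [b for b in _BASES if b != planted_ref][int(rng.integers(0, 3))],
    )
    others = [snp_at(f) for f in flats]
    parental = SnpSet(others[:n_parental])
    private = others[n_parental : n_parental + n_suppressor_private]
    suppressor = parental.union(SnpSet([planted]), SnpSet(private))
    clones = []
    base = n_parental + n_suppressor_private
    for k in range(n_clones):
        noise = others[base + k * n_noise_per_clone : base + (k + 1) * n_noise_per_clone]
        clones.append(SnpSet([planted] + noise))
    return parental, suppressor, clones, planted
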