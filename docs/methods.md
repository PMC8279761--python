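# Methods

## The calibration model

A calibrated ChIP-seq sample is a fixed-ratio mix of two species' cells
(default 3:1 experimental:calibration, set by `cell_mix_exp_to_cal`).
Two libraries are sequenced per sample: the immunoprecipitate (IP) and
the whole-cell extract (WCE). After sequential alignment — calibration
genome first, experimental genome on the unaligned remainder — each
library yields two read totals, giving the four counts
(`ip_exp`, `ip_cal`, `wce_exp`, `wce_cal`).

The occupancy ratio is computed as

    OR = (wce_cal · ip_exp) / (wce_exp · ip_cal).

This is the unique ratio-of-ratios with both properties the quantity
needs: (a) scaling all IP counts, or all WCE counts, by a common factor
leaves it unchanged (sequencing depth of either library cancels), and
(b) under the generative model below — flat occupancy on the calibration
genome, reads sampled proportionally to occupancy times cell-mix weight —
it converges to the ratio of mean occupancies of the two genomes. Both
properties are asserted by tests rather than assumed. The WCE term
corrects for the realised mixing ratio, so pipetting error in the 3:1 mix
drops out as well.

A raw coverage track v(x) becomes a calibrated track

    v_cal(x) = v(x) · (10⁶ / ip_exp) · OR,

i.e. per-million normalisation by the experimental-genome IP reads that
constitute the track, times OR. Division by the track's own read count is
what makes the calibrated track exactly depth-invariant: duplicating
every IP read multiplies the pileup by 2, the per-million factor by ½,
and leaves OR untouched (ip_exp and ip_cal scale together). Because the
factor of two is exact in binary floating point, the invariance is
bit-exact, not just approximate, and is tested as such. Whether OR should
be computed from all aligned reads or uniquely-aligning reads only is
underdetermined for real data; this pipeline computes it from the
partition it produces (every primary alignment it accepts), and the OR
report records the four counts used.

## Preprocessing and partitioning conventions

* Trimming keeps original bases 11–200 inclusive (`head_trim=10`,
  `max_end=200`), the semantics of `fastx_trimmer -f 11 -l 200`. Reads
  shorter than `head_trim` become empty and are removed by the length
  filter.
* "Shorter than 50 bp" is strict: a 50 bp read survives.
* The species partition is sequential and calibration-first; a read
  present in both genomes is CALIBRATION. This ordering is part of the
  method, not an implementation detail, and the partition is exhaustive:
  every read lands in exactly one of CALIBRATION / EXPERIMENTAL /
  UNMAPPED.
* Internal coordinates are 0-based half-open everywhere. SAM, VCF and
  GFF3 are converted at the readers/writers and nowhere else; BED,
  bedGraph and the anchor TSV are already 0-based.
* The internal aligner is exact-match only (forward or reverse
  complement; leftmost hit; chromosome order, then position, then "+"
  before "−" break ties). It is intended for error-free synthetic reads;
  real data should be aligned externally and supplied as SAM, from which
  only primary alignments are taken (secondary 0x100 and supplementary
  0x800 records are skipped, so no read is double-counted in OR).

## Profiles

Pileups are dense and zero-filled: every base of every chromosome has a
value, and uncovered bases are exactly 0. Windows run from −flank to
+flank (default 60,000 bp) around each chromosome's anchor in genomic
orientation; no arm-length or strand flipping is applied, since the
anchors are points and both sides are plotted. Offsets that fall off a
chromosome end are *missing*, not zero — zero-padding would deflate the
averages — and the per-offset count of contributing chromosomes is
reported alongside the mean. Chromosomes are weighted equally in the
average, not by read count. Calibration is applied to tracks before
windowing; because calibration is a scalar multiply, applying it after
averaging is mathematically identical (test-asserted).

Percent-of-reference divides one meta-profile by another, offset-wise,
×100; offsets where the reference is missing or zero are missing in the
output. An optional centred moving average (odd window, NaN-aware) is
available for presentation but off by default, as nothing in the method
requires smoothing.

## The synthetic-data generator

The generator emulates the experimental design, not any particular
dataset: the enrichment landscape of real cohesin ChIP is not modelled
(the field measures it; it does not simulate it), so the simulator's
distributional choices are deliberate stand-ins chosen for testability.

* **Occupancy**: flat background plus a boxcar of fold-amplitude
  `peak_amplitude` (default 8) and width `peak_width` (default 2,000 bp)
  centred on each experimental chromosome's anchor, rescaled so the
  genome-wide mean is `mean_occ_exp`; the calibration genome is flat at
  `mean_occ_cal`. True OR is therefore `mean_occ_exp / mean_occ_cal` by
  construction. The boxcar (rather than a smoother kernel) makes every
  expected read fraction a finite sum over the occupancy vector, so
  oracle tests can use closed forms.
* **Sampling**: a read's genome is chosen with probability proportional
  to cell-mix weight × total occupancy mass (IP) or cell-mix weight ×
  genome length (WCE); its start is then drawn from the per-position
  occupancy (IP) or uniformly (WCE). Occupancy applies at the 5′ start
  only, which decouples the sampling mathematics from read length; reads
  still span `read_len` bases in pileups. Starts are restricted to
  positions where a full read fits.
* **Reads**: single-end, forward-strand, error-free by default
  (`error_rate > 0` adds i.i.d. substitutions, but the exact-match
  aligner is only guaranteed for rate 0). Genome sequences are i.i.d.
  uniform A/C/G/T with no repeats, so ≥ 20 bp reads align uniquely with
  overwhelming probability. Read ids carry the true origin
  (`sample:genome:chrom:pos:serial`), and `true_alignments` /
  `true_counts` / `simulate_ip_alignments` decode it, so high-depth tests
  can use ground truth directly while alignment fidelity is proven
  separately against brute-force search.
* **Defaults as study conditions**: 16 experimental chromosomes (one
  anchor each, as for the 16 budding-yeast centromeres) of 30 kb, four
  calibration chromosomes of 30 kb, 3:1 cell mix, 200,000 reads per
  library at 50 bp. Chromosome lengths are desk-scale stand-ins (real
  chromosomes are 230 kb–1.5 Mb); depths were chosen so binomial error
  on the smallest partition count stays near 1%, well inside the 5%
  recovery band used in the tests.
* **SNP tables**: the parental strain gets `n_parental` background SNVs
  (all inherited by the suppressor); the suppressor gets one planted
  causal SNV inside a gene plus `n_suppressor_private` incidentals; each
  backcross clone gets the causal SNV plus `n_noise_per_clone` private
  noise SNVs. All positions are distinct, so with ≥ 1 clone the causal
  SNV is provably the unique survivor of the full filter — the
  uniqueness guarantee the recovery tests rely on.

What passing these tests shows — and does not show. They establish the
pipeline's arithmetic and bookkeeping: the estimator converges to the
constructed truth, the partition equals exhaustive search, pileups
conserve mass, and a 20% genome-wide occupancy change survives the whole
pipeline as a 120% percent-of-reference readout. They do not validate
behaviour under features the generator omits: sequencing errors coupled
with a mismatch-tolerant aligner, repeats and multi-mapping, GC and
fragment-length bias, PCR duplicates, paired ends, or diploid/low-quality
variant calls (the mutation finder uses every SNV record and ignores
genotype and quality fields, logging what it skips).

## Numerical choices and degenerate inputs

* OR requires all four counts positive; a zero count raises a
  calibration error naming the count rather than returning 0 or ∞.
* Calibrated values are double-precision reals end to end; nothing is
  rounded to integers.
* Missing data is NaN internally and `NA` in TSVs; means are taken over
  present values only, with `n_contributing` reported so a thin average
  is visible.
* bedGraph output omits zero runs; readers restore the dense zero-filled
  representation from the chromosome-sizes table, keeping the two
  representations interconvertible without loss.
* Empty reads are unmapped by definition (an empty string "occurs"
  everywhere, which is not an alignment).

## Problem sizes used in the automated checks

The test suite and `scripts/acceptance.py` run entirely on simulated
data: 200,000 reads per library where estimator accuracy is measured
(OR recovery, percent-of-reference), 10,000–60,000 reads for oracle
equivalence checks (partition vs string search, pileup vs recount), 10
seeds per OR setting, and 20 seeded suppressor screens. These sizes keep
the sampling error an order of magnitude below the tolerances being
asserted while completing in well under a minute per check.
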