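"""Reference genomes and their anchor points.

A :class:`Genome` bundles an ordered set of chromosome sequences with an
optional per-chromosome anchor position.  In calibrated ChIP-seq two genomes
play distinct roles: the *experimental* genome (the species under study,
e.g. *S. cerevisiae*) and the *calibration* genome (the spike-in species,
e.g. *C. glabrata*).  Anchors mark the reference point used for averaged
profiles — in budding yeast, the centromeric CDEIII element of each
chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Mapping


@dataclass(frozen=True)
class Genome:
    """An ordered collection of named chromosome sequences.

    Parameters
    ----------
    name
        Label for the genome (e.g. ``"exp"`` or ``"cal"``).
    chromosomes
        Ordered tuple of ``(chrom_name, sequence)`` pairs.  Sequences are
        upper-case A/C/G/T strings; chromosome order is significant (it
        breaks ties in exact alignment).
    anchors
        Optional mapping ``chrom_name -> position`` (0-based) giving one
        anchor per chromosome, e.g. CDEIII coordinates.
    """

    name: str
    chromosomes: tuple[tuple[str, str], ...]
    anchors: Mapping[str, int] | None = None

    def __post_init__(self) -> None:
        names = [c for c, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate chromosome names in genome {self.name!r}")
        for chrom, seq in self.chromosomes:
            if not seq:
                raise ValueError(f"empty sequence for chromosome {chrom!r}")
        if self.anchors is not None:
            lengths = {c: len(s) for c, s in self.chromosomes}
            for chrom, pos in self.anchors.items():
                if chrom not in lengths:
                    raise ValueError(f"anchor on unknown chromosome {chrom!r}")
                if not 0 <= pos < lengths[chrom]:
                    raise ValueError(
                        f"anchor {pos} outside chromosome {chrom!r} "
                        f"(length {lengths[chrom]})"
                    )
            # freeze to guard against accidental mutation of a frozen dataclass
            object.__setattr__(self, "anchors", MappingProxyType(dict(self.anchors)))

    @property
    def chrom_names(self) -> tuple[str, ...]:
        return tuple(c for c, _ in self.chromosomes)

    @property
    def lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.chromosomes}

    @property
    def total_length(self) -> int:
        return sum(len(s) for _, s in self.chromosomes)

    def sequence(self, chrom: str) -> str:
        for c, s in self.chromosomes:
            if c == chrom:
                return s
        raise KeyError(f"no chromosome {chrom!r} in genome {self.name!r}")

    def __contains__(self, chrom: str) -> bool:
        return any(c == chrom for c, _ in self.chromosomes)
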