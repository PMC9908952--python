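"""Core coordinate and track types shared by every pipeline stage.

All genomic coordinates are 0-based, half-open ``[start, end)``.  Strand is
always one of ``+``/``-`` -- strand-less features are rejected because every
computation in the pipeline (site extraction, windowed profiles, densities)
is strand-aware.  Transcript ("pre-mRNA") offsets count nucleotides from the
TSS along the template strand; "mature" offsets count only exonic
nucleotides.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

STRANDS = ("+", "-")

#: DRB-release time course: label -> minutes since release.  ``t00`` is the
#: still-blocked baseline; ``DMSO`` is the unsynchronised steady state,
#: treated as t = infinity.
DEFAULT_TIMEPOINTS: dict[str, float] = {
    "t00": 0.0,
    "t05": 5.0,
    "t10": 10.0,
    "t15": 15.0,
    "t20": 20.0,
    "t30": 30.0,
    "t45": 45.0,
    "t60": 60.0,
    "DMSO": math.inf,
}


@dataclass(frozen=True, slots=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.strand == other.strand
            and self.start < other.end
            and other.start < self.end
        )


class SiteTrack:
    """Per-(chrom, strand, position) weighted counts.

    The universal intermediate for all coverage maths: cross-link sites,
    3'CLIP termini and whole-read coverage all live in this container.
    Before scaling, the total weight equals the number of contributing
    reads; after scaling it equals reads x scale factor.
    """

    __slots__ = ("entries", "library_label", "timepoint_label", "dropped")

    def __init__(
        self,
        entries: Mapping[tuple[str, str, int], float] | None = None,
        library_label: str = "",
        timepoint_label: str = "",
    ) -> None:
        self.entries: dict[tuple[str, str, int], float] = dict(entries or {})
        for (chrom, strand, pos), w in self.entries.items():
            if w < 0:
                raise ValueError(f"negative weight at {chrom}:{pos}({strand})")
        self.library_label = library_label
        self.timepoint_label = timepoint_label
        #: reads whose site fell before position 0 and was discarded
        self.dropped: int = 0

    def add(self, chrom: str, strand: str, pos: int, weight: float = 1.0) -> None:
        key = (chrom, strand, pos)
        self.entries[key] = self.entries.get(key, 0.0) + weight

    def get(self, chrom: str, strand: str, pos: int) -> float:
        return self.entries.get((chrom, strand, pos), 0.0)

    def total(self) -> float:
        return sum(self.entries.values())

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[tuple[tuple[str, str, int], float]]:
        return iter(self.entries.items())

    def copy(self) -> "SiteTrack":
        out = SiteTrack(self.entries, self.library_label, self.timepoint_label)
        out.dropped = self.dropped
        return out


@dataclass(slots=True)
class AlignedPair:
    """One mapped, properly paired CLIP read after alignment.

    ``strand`` is the RNA strand, carried by read1 (FR layout: read1 maps to
    the template strand, read2 to its reverse complement).  Blocks are
    genomic ``(start, end)`` tuples, coordinate-sorted and non-overlapping;
    gaps between blocks are spliced-out (``N``) segments.  ``mismatches``
    lists ``(genomic_position, observed_base)`` for read1.
    """

    name: str
    umi: str
    barcode: str
    chrom: str
    strand: str
    read1_blocks: tuple[tuple[int, int], ...]
    read2_blocks: tuple[tuple[int, int], ...]
    mismatches: tuple[tuple[int, str], ...] = ()
    tlen: int = 0

    @property
    def read1_five_prime(self) -> int:
        """Genomic position of read1's first sequenced base (cDNA 3' end)."""
        if self.strand == "+":
            return self.read1_blocks[0][0]
        return self.read1_blocks[-1][1] - 1

    @property
    def read2_first_base(self) -> int:
        """Genomic position of read2's first sequenced base.

        Read2 is primed from the adapter ligated to the RNA fragment's
        3' end, so this position is the fragment 3' terminus.
        """
        if self.strand == "+":  # read2 on minus strand
            return self.read2_blocks[-1][1] - 1
        return self.read2_blocks[0][0]

    @property
    def read2_coordinate_last(self) -> int:
        """Highest genomic coordinate covered by read2 (strand-agnostic)."""
        return self.read2_blocks[-1][1] - 1

    @property
    def read1_length(self) -> int:
        return sum(e - s for s, e in self.read1_blocks)


@dataclass(slots=True)
class TranscriptionUnit:
    """A transcription unit with exon block structure (BED12 semantics)."""

    tu_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: tuple[tuple[int, int], ...]  # genomic-sorted (start, end)
    is_rrna: bool = False

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValueError(f"bad strand {self.strand!r} for {self.tu_id}")
        prev = self.start
        for s, e in self.exons:
            if s < prev or e <= s or e > self.end:
                raise ValueError(f"malformed exon blocks in {self.tu_id}")
            prev = e
        if self.exons[0][0] != self.start or self.exons[-1][1] != self.end:
            raise ValueError(f"exon blocks must span the TU in {self.tu_id}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def mature_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        """Inter-block gaps in genomic order."""
        return tuple(
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        )

    # -- coordinate transforms ------------------------------------------------

    def genome_to_premrna(self, pos: int) -> int:
        """TSS-anchored offset along the template strand."""
        if self.strand == "+":
            return pos - self.start
        return self.end - 1 - pos

    def premrna_to_genome(self, off: int) -> int:
        if self.strand == "+":
            return self.start + off
        return self.end - 1 - off

    def exons_stranded(self) -> list[tuple[int, int]]:
        """Exons in transcript (5'->3') order, still genomic (start, end)."""
        exons = list(self.exons)
        return exons if self.strand == "+" else exons[::-1]

    def introns_stranded(self) -> list[tuple[int, int]]:
        introns = list(self.introns)
        return introns if self.strand == "+" else introns[::-1]

    def genome_to_mature(self, pos: int) -> int | None:
        """Mature (exon-concatenated, 5'-anchored) offset, or None if intronic."""
        off = 0
        for s, e in self.exons_stranded():
            if s <= pos < e:
                if self.strand == "+":
                    return off + (pos - s)
                return off + (e - 1 - pos)
            off += e - s
        return None

    def junction_mature_offsets(self) -> list[int]:
        """Mature offsets of the last nt of each exon except the last."""
        offs = []
        cum = 0
        exons = self.exons_stranded()
        for s, e in exons[:-1]:
            cum += e - s
            offs.append(cum - 1)
        return offs


@dataclass(slots=True)
class IntronAnnotation:
    intron_id: str
    chrom: str
    start: int
    end: int
    strand: str
    tu_id: str
    rank: int  # 0-based in transcript order
    bp_pos: int | None = None  # genomic position of the branchpoint adenosine

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def three_prime_last_nt(self) -> int:
        """Genomic position of the intron's last nucleotide (the 3'SS side)."""
        return self.end - 1 if self.strand == "+" else self.start

    @property
    def five_prime_first_nt(self) -> int:
        """Genomic position of the first intronic nucleotide (the 5'SS side)."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def dist_bp_to_3ss(self) -> int | None:
        """Branchpoint-to-3'SS distance in nt (1 = BP is the last intronic nt)."""
        if self.bp_pos is None:
            return None
        if self.strand == "+":
            return self.end - self.bp_pos
        return self.bp_pos - self.start + 1


@dataclass(slots=True)
class SnoRNAAnnotation:
    sno_id: str
    chrom: str
    start: int
    end: int
    strand: str
    sno_class: str  # "CD" or "HACA"
    host_intron_id: str

    def __post_init__(self) -> None:
        if self.sno_class not in ("CD", "HACA"):
            raise ValueError(f"unknown snoRNA class {self.sno_class!r}")

    @property
    def three_prime_end(self) -> int:
        """Genomic position of the snoRNA's annotated last nucleotide."""
        return self.end - 1 if self.strand == "+" else self.start


@dataclass(slots=True)
class AnnotationBundle:
    """The full coordinate model every profile is anchored to."""

    tus: dict[str, TranscriptionUnit]
    introns: dict[str, IntronAnnotation]
    snornas: dict[str, SnoRNAAnnotation]
    chrom_sizes: dict[str, int] = field(default_factory=dict)

    @property
    def rrna_units(self) -> list[TranscriptionUnit]:
        return [tu for tu in self.tus.values() if tu.is_rrna]

    @property
    def rrna_intervals(self) -> list[GenomicInterval]:
        return [
            GenomicInterval(tu.chrom, tu.start, tu.end, tu.strand)
            for tu in self.rrna_units
        ]

    def multi_exonic(self) -> list[TranscriptionUnit]:
        return [
            tu for tu in self.tus.values() if tu.n_exons > 1 and not tu.is_rrna
        ]

    def introns_of(self, tu_id: str) -> list[IntronAnnotation]:
        out = [iv for iv in self.introns.values() if iv.tu_id == tu_id]
        out.sort(key=lambda iv: iv.rank)
        return out


def derive_introns(tu: TranscriptionUnit) -> list[IntronAnnotation]:
    """Introns of a TU as inter-block gaps, ranked in transcript order."""
    gaps = tu.introns
    ordered = gaps if tu.strand == "+" else gaps[::-1]
    return [
        IntronAnnotation(
            intron_id=f"{tu.tu_id}.i{rank}",
            chrom=tu.chrom,
            start=s,
            end=e,
            strand=tu.strand,
            tu_id=tu.tu_id,
            rank=rank,
        )
        for rank, (s, e) in enumerate(ordered)
    ]


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal-length strings")
    return sum(x != y for x, y in zip(a, b))
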