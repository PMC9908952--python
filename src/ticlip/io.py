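"""Readers/writers for the standard formats the pipeline touches.

Alignments travel as SAM/BAM-convention records (via pysam); annotation as
BED12 (transcription units) plus BED6 (branchpoints, snoRNAs, rRNA genes);
site tracks as per-strand bedGraph pairs.  The read-name dialect is
``name#BARCODE#UMI`` so that the simulator, demultiplexer and deduplicator
agree without a sidecar file.  Read1 mismatches ride in the local ``XM:Z``
tag as ``pos:base`` pairs (genomic position, observed base); when the tag is
absent they are recovered from the MD tag if present.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import pysam

from .core import (
    AlignedPair,
    AnnotationBundle,
    GenomicInterval,
    IntronAnnotation,
    SiteTrack,
    SnoRNAAnnotation,
    TranscriptionUnit,
    derive_introns,
)

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# alignments
# ---------------------------------------------------------------------------

def _parse_read_name(qname: str, record_idx: int) -> tuple[str, str, str]:
    parts = qname.rsplit("#", 2)
    if len(parts) != 3 or not parts[1] or not parts[2]:
        raise ValueError(
            f"record {record_idx}: read name {qname!r} does not follow the "
            "name#BARCODE#UMI dialect"
        )
    return parts[0], parts[1], parts[2]


def _mismatches_from_record(rec: pysam.AlignedSegment) -> tuple[tuple[int, str], ...]:
    if rec.has_tag("XM"):
        raw = str(rec.get_tag("XM"))
        if not raw:
            return ()
        out = []
        for item in raw.split(","):
            pos_s, base = item.split(":")
            out.append((int(pos_s), base))
        return tuple(out)
    if rec.has_tag("MD") and rec.query_sequence:
        out = []
        for qpos, rpos, ref in rec.get_aligned_pairs(with_seq=True):
            if qpos is None or rpos is None or ref is None:
                continue
            if ref.islower():
                out.append((rpos, rec.query_sequence[qpos]))
        return tuple(out)
    return ()


def read_alignments(path: str | Path) -> list[AlignedPair]:
    """Read primary, mapped, properly paired records into AlignedPairs.

    Secondary/supplementary and unmapped records are discarded.  Mates are
    paired by read name; orphans are skipped with a counted warning.  Output
    follows the file order of read1.
    """
    path = Path(path)
    mode = "rb" if path.suffix == ".bam" else "r"
    read1s: dict[str, tuple[int, pysam.AlignedSegment]] = {}
    read2s: dict[str, pysam.AlignedSegment] = {}
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as fh:
        for idx, rec in enumerate(fh):
            if rec.is_secondary or rec.is_supplementary:
                continue
            if rec.is_unmapped or rec.mate_is_unmapped or not rec.is_proper_pair:
                continue
            if rec.query_name is None or rec.reference_name is None:
                raise ValueError(f"record {idx}: missing read name or reference")
            if rec.is_read1:
                read1s[rec.query_name] = (idx, rec)
            else:
                read2s[rec.query_name] = rec

    orphans = 0
    pairs: list[AlignedPair] = []
    for qname, (idx, r1) in sorted(read1s.items(), key=lambda kv: kv[1][0]):
        r2 = read2s.get(qname)
        if r2 is None:
            orphans += 1
            continue
        base, barcode, umi = _parse_read_name(qname, idx)
        strand = "-" if r1.is_reverse else "+"
        pairs.append(
            AlignedPair(
                name=base,
                umi=umi,
                barcode=barcode,
                chrom=r1.reference_name,
                strand=strand,
                read1_blocks=tuple(r1.get_blocks()),
                read2_blocks=tuple(r2.get_blocks()),
                mismatches=_mismatches_from_record(r1),
                tlen=r1.template_length,
            )
        )
    orphans += len(read2s.keys() - read1s.keys())
    if orphans:
        log.warning("%s: skipped %d orphan mates", path.name, orphans)
    return pairs


def _blocks_to_cigar(blocks: Sequence[tuple[int, int]]) -> str:
    parts = []
    for i, (s, e) in enumerate(blocks):
        if i > 0:
            gap = s - blocks[i - 1][1]
            parts.append(f"{gap}N")
        parts.append(f"{e - s}M")
    return "".join(parts)


def write_alignments(
    pairs: Iterable[AlignedPair],
    path: str | Path,
    chrom_sizes: dict[str, int],
) -> None:
    """Write AlignedPairs as a coordinate-convention SAM/BAM file."""
    path = Path(path)
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": c, "LN": n} for c, n in chrom_sizes.items()],
    }
    ref_ids = {c: i for i, c in enumerate(chrom_sizes)}
    mode = "wb" if path.suffix == ".bam" else "w"
    with pysam.AlignmentFile(str(path), mode, header=header) as out:
        for p in pairs:
            qname = f"{p.name}#{p.barcode}#{p.umi}"
            rid = ref_ids[p.chrom]
            r1 = pysam.AlignedSegment()
            r2 = pysam.AlignedSegment()
            r1.query_name = qname
            r2.query_name = qname
            r1.reference_id = rid
            r2.reference_id = rid
            r1.next_reference_id = rid
            r2.next_reference_id = rid
            r1.reference_start = p.read1_blocks[0][0]
            r2.reference_start = p.read2_blocks[0][0]
            r1.next_reference_start = r2.reference_start
            r2.next_reference_start = r1.reference_start
            r1.cigarstring = _blocks_to_cigar(p.read1_blocks)
            r2.cigarstring = _blocks_to_cigar(p.read2_blocks)
            r1.mapping_quality = 60
            r2.mapping_quality = 60
            if p.strand == "+":
                r1.flag = 99  # paired, proper, mate reverse, first
                r2.flag = 147
                r1.template_length = abs(p.tlen)
                r2.template_length = -abs(p.tlen)
            else:
                r1.flag = 83
                r2.flag = 163
                r1.template_length = -abs(p.tlen)
                r2.template_length = abs(p.tlen)
            if p.mismatches:
                r1.set_tag(
                    "XM", ",".join(f"{pos}:{base}" for pos, base in p.mismatches)
                )
            out.write(r1)
            out.write(r2)


# ---------------------------------------------------------------------------
# bedGraph
# ---------------------------------------------------------------------------

def write_bedgraph(track: SiteTrack, path_prefix: str | Path) -> tuple[Path, Path]:
    """Write a SiteTrack as a per-strand bedGraph pair.

    Adjacent positions with equal value are merged into one interval; lines
    are sorted by (chrom, start); values use up to 6 significant digits.
    """
    prefix = Path(path_prefix)
    paths = {}
    for strand, suffix in (("+", "plus"), ("-", "minus")):
        out_path = prefix.parent / f"{prefix.name}.{suffix}.bedgraph"
        items = sorted(
            (chrom, pos, w)
            for (chrom, s, pos), w in track.entries.items()
            if s == strand and w != 0
        )
        with open(out_path, "w") as fh:
            run: list | None = None  # [chrom, start, end, value]
            for chrom, pos, w in items:
                if (
                    run is not None
                    and run[0] == chrom
                    and run[2] == pos
                    and run[3] == w
                ):
                    run[2] = pos + 1
                    continue
                if run is not None:
                    fh.write(f"{run[0]}\t{run[1]}\t{run[2]}\t{run[3]:.6g}\n")
                run = [chrom, pos, pos + 1, w]
            if run is not None:
                fh.write(f"{run[0]}\t{run[1]}\t{run[2]}\t{run[3]:.6g}\n")
        paths[strand] = out_path
    return paths["+"], paths["-"]


def read_bedgraph(
    plus_path: str | Path,
    minus_path: str | Path,
    library_label: str = "",
    timepoint_label: str = "",
) -> SiteTrack:
    track = SiteTrack(library_label=library_label, timepoint_label=timepoint_label)
    for path, strand in ((plus_path, "+"), (minus_path, "-")):
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith(("track", "#")):
                    continue
                fields = line.split("\t")
                if len(fields) != 4:
                    raise ValueError(f"{path}:{ln}: expected 4 bedGraph columns")
                chrom, start, end, value = fields
                for pos in range(int(start), int(end)):
                    track.add(chrom, strand, pos, float(value))
    return track


# ---------------------------------------------------------------------------
# annotation (BED12 + BED6)
# ---------------------------------------------------------------------------

def _write_bed6(records: Iterable[tuple[str, int, int, str, str]], path: Path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, name, strand in records:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t0\t{strand}\n")


def write_annotation(bundle: AnnotationBundle, out_dir: str | Path) -> dict[str, Path]:
    """Write an annotation bundle as tus.bed12 / bp.bed / sno.bed / rrna.bed
    plus a chrom sizes table; returns the path map."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "tus": out_dir / "tus.bed12",
        "bp": out_dir / "bp.bed",
        "sno": out_dir / "sno.bed",
        "rrna": out_dir / "rrna.bed",
        "chrom_sizes": out_dir / "chrom.sizes",
    }
    with open(paths["tus"], "w") as fh:
        for tu in bundle.tus.values():
            sizes = ",".join(str(e - s) for s, e in tu.exons)
            starts = ",".join(str(s - tu.start) for s, e in tu.exons)
            fh.write(
                f"{tu.chrom}\t{tu.start}\t{tu.end}\t{tu.tu_id}\t0\t{tu.strand}\t"
                f"{tu.start}\t{tu.end}\t0\t{len(tu.exons)}\t{sizes},\t{starts},\n"
            )
    _write_bed6(
        (
            (iv.chrom, iv.bp_pos, iv.bp_pos + 1, iv.intron_id, iv.strand)
            for iv in bundle.introns.values()
            if iv.bp_pos is not None
        ),
        paths["bp"],
    )
    _write_bed6(
        (
            (s.chrom, s.start, s.end, f"{s.sno_class}|{s.sno_id}", s.strand)
            for s in bundle.snornas.values()
        ),
        paths["sno"],
    )
    _write_bed6(
        (
            (tu.chrom, tu.start, tu.end, tu.tu_id, tu.strand)
            for tu in bundle.rrna_units
        ),
        paths["rrna"],
    )
    with open(paths["chrom_sizes"], "w") as fh:
        for chrom, size in bundle.chrom_sizes.items():
            fh.write(f"{chrom}\t{size}\n")
    return paths


def _read_bed6(path: str | Path) -> list[tuple[str, int, int, str, str]]:
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("track", "#")):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise ValueError(f"{path}:{ln}: expected >=6 BED columns")
            out.append((f[0], int(f[1]), int(f[2]), f[3], f[5]))
    return out


def read_annotation(
    tu_path: str | Path,
    bp_path: str | Path | None = None,
    sno_path: str | Path | None = None,
    rrna_path: str | Path | None = None,
    chrom_sizes_path: str | Path | None = None,
) -> AnnotationBundle:
    """Read BED12 TUs plus BED6 branchpoints/snoRNAs into a bundle.

    Introns are derived as inter-exon gaps; every branchpoint must fall
    inside an intron of its named TU; snoRNA class is parsed from the BED
    name field (``CD|id`` / ``HACA|id``).
    """
    rrna_ids: set[str] = set()
    if rrna_path is not None:
        rrna_ids = {name for _, _, _, name, _ in _read_bed6(rrna_path)}

    tus: dict[str, TranscriptionUnit] = {}
    with open(tu_path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("track", "#")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ValueError(f"{tu_path}:{ln}: expected 12 BED12 columns")
            chrom, start, end = f[0], int(f[1]), int(f[2])
            name, strand = f[3], f[5]
            n_blocks = int(f[9])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            if len(sizes) != n_blocks or len(starts) != n_blocks:
                raise ValueError(f"{tu_path}:{ln}: malformed block sums")
            exons = tuple(
                (start + bs, start + bs + sz) for bs, sz in zip(starts, sizes)
            )
            tus[name] = TranscriptionUnit(
                tu_id=name,
                chrom=chrom,
                start=start,
                end=end,
                strand=strand,
                exons=exons,
                is_rrna=name in rrna_ids,
            )

    introns: dict[str, IntronAnnotation] = {}
    for tu in tus.values():
        for iv in derive_introns(tu):
            introns[iv.intron_id] = iv

    if bp_path is not None:
        for chrom, start, end, name, strand in _read_bed6(bp_path):
            pos = start
            host = None
            for iv in introns.values():
                if iv.chrom == chrom and iv.strand == strand and iv.start <= pos < iv.end:
                    host = iv
                    break
            if host is None:
                raise ValueError(
                    f"branchpoint {name} at {chrom}:{pos}({strand}) lies outside "
                    "every annotated intron"
                )
            host.bp_pos = pos

    snornas: dict[str, SnoRNAAnnotation] = {}
    if sno_path is not None:
        for chrom, start, end, name, strand in _read_bed6(sno_path):
            if "|" in name:
                cls, sno_id = name.split("|", 1)
            else:  # prefix convention CDxxx / HACAxxx
                cls = "HACA" if name.startswith("HACA") else "CD"
                sno_id = name
            host = None
            for iv in introns.values():
                if (
                    iv.chrom == chrom
                    and iv.strand == strand
                    and iv.start <= start
                    and end <= iv.end
                ):
                    host = iv
                    break
            if host is None:
                raise ValueError(
                    f"snoRNA {name} at {chrom}:{start}-{end}({strand}) is not "
                    "contained in any annotated intron"
                )
            snornas[sno_id] = SnoRNAAnnotation(
                sno_id=sno_id,
                chrom=chrom,
                start=start,
                end=end,
                strand=strand,
                sno_class=cls,
                host_intron_id=host.intron_id,
            )

    chrom_sizes: dict[str, int] = {}
    if chrom_sizes_path is not None:
        with open(chrom_sizes_path) as fh:
            for line in fh:
                if line.strip():
                    chrom, size = line.split()
                    chrom_sizes[chrom] = int(size)
    else:
        for tu in tus.values():
            chrom_sizes[tu.chrom] = max(chrom_sizes.get(tu.chrom, 0), tu.end + 1000)

    return AnnotationBundle(
        tus=tus, introns=introns, snornas=snornas, chrom_sizes=chrom_sizes
    )
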