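"""Demultiplexing, UMI deduplication, and read deconstruction.

A paired CLIP read is deconstructed into one of three single-nucleotide
representations: the cross-link site (one nt upstream of read1's 5' end,
where the reverse transcriptase truncated at the cross-linked peptide), the
3'CLIP site (the fragment's 3' terminus, read from the adapter-primed mate
and reported on the RNA strand), or whole-read coverage (read1 aligned
blocks).
"""

from __future__ import annotations

import logging
from collections import defaultdict
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .core import AlignedPair, SiteTrack, hamming

log = logging.getLogger(__name__)

UNDETERMINED = "undetermined"


def demultiplex(
    pairs: Iterable[AlignedPair],
    barcode_table: Mapping[str, str],
    max_mismatch: int = 0,
) -> dict[str, list[AlignedPair]]:
    """Assign pairs to samples by in-line barcode within Hamming distance.

    Ambiguous or unmatched pairs go to the ``undetermined`` bin.  Two table
    barcodes within 2 x max_mismatch of each other are a configuration
    error (their assignment would be ambiguous by construction).
    """
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    barcodes = list(barcode_table)
    lengths = {len(b) for b in barcodes}
    if len(lengths) > 1:
        raise ValueError("barcodes must be of equal length")
    for i, a in enumerate(barcodes):
        for b in barcodes[i + 1 :]:
            if hamming(a, b) <= 2 * max_mismatch:
                raise ValueError(
                    f"barcode collision: {a!r} and {b!r} are within "
                    f"{2 * max_mismatch} mismatches of each other"
                )
    out: dict[str, list[AlignedPair]] = defaultdict(list)
    for sample in barcode_table.values():
        out[sample]
    out[UNDETERMINED]
    for p in pairs:
        if p.barcode in barcode_table:  # exact fast path
            out[barcode_table[p.barcode]].append(p)
            continue
        hits = [
            sample
            for bc, sample in barcode_table.items()
            if len(bc) == len(p.barcode) and hamming(bc, p.barcode) <= max_mismatch
        ]
        out[hits[0] if len(hits) == 1 else UNDETERMINED].append(p)
    return dict(out)


def deduplicate(pairs: Sequence[AlignedPair]) -> list[AlignedPair]:
    """Collapse PCR duplicates on (UMI, chrom, read1 5' coordinate, strand).

    The first-encountered pair per key is kept; output preserves input
    order.  Idempotent.
    """
    seen: set[tuple[str, str, int, str]] = set()
    out: list[AlignedPair] = []
    for p in pairs:
        key = (p.umi, p.chrom, p.read1_five_prime, p.strand)
        if key in seen:
            continue
        seen.add(key)
        out.append(p)
    return out


def crosslink_sites(
    pairs: Iterable[AlignedPair],
    library_label: str = "",
    timepoint_label: str = "",
) -> SiteTrack:
    """Cross-link site track: unit weight 1 nt upstream (in transcript
    orientation) of read1's first sequenced base.

    Plus-strand read1 starting at p puts a site at p-1; minus-strand read1
    whose first sequenced base is p puts a site at p+1.  Sites before
    position 0 are dropped and counted on ``track.dropped``.
    """
    track = SiteTrack(library_label=library_label, timepoint_label=timepoint_label)
    for p in pairs:
        five = p.read1_five_prime
        site = five - 1 if p.strand == "+" else five + 1
        if site < 0:
            track.dropped += 1
            continue
        track.add(p.chrom, p.strand, site)
    return track


def five_prime_end_track(
    pairs: Iterable[AlignedPair],
    library_label: str = "",
    timepoint_label: str = "",
) -> SiteTrack:
    """Raw (unshifted) read1 5'-end positions.

    Used for cDNA-truncation analysis, where the diagnostic positions are
    the truncated cDNA ends themselves (e.g. on the branchpoint), not the
    inferred cross-link one nt upstream.
    """
    track = SiteTrack(library_label=library_label, timepoint_label=timepoint_label)
    for p in pairs:
        track.add(p.chrom, p.strand, p.read1_five_prime)
    return track


def three_prime_sites(
    pairs: Iterable[AlignedPair],
    library_label: str = "",
    timepoint_label: str = "",
    convention: str = "fragment_end",
) -> SiteTrack:
    """3'CLIP site track: the RNA fragment's 3' terminus on the RNA strand.

    ``fragment_end`` (default) takes read2's first sequenced base -- read2
    is primed from the adapter ligated to the RNA 3' end, so its first base
    is the fragment terminus regardless of strand.  ``coordinate_last``
    instead takes read2's highest genomic coordinate (the coordinate-sorted
    "last" base); the two differ for minus-strand fragments.
    """
    if convention not in ("fragment_end", "coordinate_last"):
        raise ValueError(f"unknown 3'CLIP convention {convention!r}")
    track = SiteTrack(library_label=library_label, timepoint_label=timepoint_label)
    for p in pairs:
        pos = (
            p.read2_first_base
            if convention == "fragment_end"
            else p.read2_coordinate_last
        )
        track.add(p.chrom, p.strand, pos)
    return track


def whole_read_coverage(
    pairs: Iterable[AlignedPair],
    library_label: str = "",
    timepoint_label: str = "",
) -> SiteTrack:
    """Unit weight at every read1-aligned position (block gaps excluded)."""
    track = SiteTrack(library_label=library_label, timepoint_label=timepoint_label)
    for p in pairs:
        for s, e in p.read1_blocks:
            for pos in range(s, e):
                track.add(p.chrom, p.strand, pos)
    return track


def exon_junction_table(annotation) -> list[tuple]:
    """Rows for :func:`classify_splice_status` from an annotation bundle:
    every first/internal exon of a multi-exonic TU with its downstream exon."""
    rows = []
    for tu in annotation.tus.values():
        if tu.n_exons < 2 or tu.is_rrna:
            continue
        exons = tu.exons_stranded()
        for rank in range(len(exons) - 1):
            es, ee = exons[rank]
            ds, de = exons[rank + 1]
            category = "first" if rank == 0 else "internal"
            rows.append(
                (
                    f"{tu.tu_id}.e{rank}",
                    tu.chrom,
                    tu.strand,
                    es,
                    ee,
                    ds,
                    de,
                    category,
                )
            )
    return rows


def classify_splice_status(
    pairs: Iterable[AlignedPair],
    exon_junctions: Sequence[tuple],
) -> pd.DataFrame:
    """Per-exon spliced / non-spliced read counts at exon 3' ends.

    ``exon_junctions`` rows are ``(exon_id, chrom, strand, exon_start,
    exon_end, downstream_exon_start, downstream_exon_end, category)`` with
    category 'first' or 'internal'.  A read1 covering the exon's last
    nucleotide is *spliced* if a block gap joins the exon end to the
    annotated downstream exon start, *non_spliced* if the alignment runs
    contiguously >=1 nt into the intron; reads ending exactly at the exon
    end count in neither class.
    """
    # index exon-last-nt positions for O(1) lookup per read block
    by_pos: dict[tuple[str, str, int], list[dict]] = defaultdict(list)
    counts: dict[str, dict] = {}
    for row in exon_junctions:
        (exon_id, chrom, strand, es, ee, ds, de, category) = row
        if ds is None:
            log.warning("exon %s has no downstream partner; skipped", exon_id)
            continue
        last_nt = ee - 1 if strand == "+" else es
        down_first = ds if strand == "+" else de - 1
        rec = {
            "exon_id": exon_id,
            "strand": strand,
            "exon_start": es,
            "exon_end": ee,
            "down_first": down_first,
            "category": category,
        }
        by_pos[(chrom, strand, last_nt)].append(rec)
        counts[exon_id] = {
            "exon_id": exon_id,
            "category": category,
            "spliced": 0,
            "non_spliced": 0,
        }

    for p in pairs:
        for bi, (bs, be) in enumerate(p.read1_blocks):
            for pos in range(bs, be):
                for rec in by_pos.get((p.chrom, p.strand, pos), ()):
                    cls = _classify_at_exon_end(p, bi, rec)
                    if cls:
                        counts[rec["exon_id"]][cls] += 1
    return pd.DataFrame(counts.values())


def _classify_at_exon_end(p: AlignedPair, block_idx: int, rec: dict) -> str | None:
    blocks = p.read1_blocks
    bs, be = blocks[block_idx]
    es, ee = rec["exon_start"], rec["exon_end"]
    if p.strand == "+":
        if be > ee:
            return "non_spliced"  # runs contiguously into the intron
        if be == ee:
            if block_idx + 1 < len(blocks) and blocks[block_idx + 1][0] == rec["down_first"]:
                return "spliced"
            return None  # ends exactly at the exon end
        return None
    else:
        if bs < es:
            return "non_spliced"
        if bs == es:
            if block_idx > 0 and blocks[block_idx - 1][1] - 1 == rec["down_first"]:
                return "spliced"
            return None
        return None
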