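"""Branchpoint-centred analysis of intron lariat cDNA truncation.

Reverse transcription cannot read through the 2'-5' phosphodiester bond
that joins the branchpoint (BP) adenosine to the intron 5' end.  cDNAs
primed inside the circularised part of the lariat run around the circle and
terminate *on* the BP, incorporating one untemplated (mismatched) terminal
base against the 2'-5' linkage; cDNAs primed from the linear tail stop one
nucleotide downstream of the BP with a correctly matched terminal base.
The resulting 5'-end pile-ups at BP offsets 0 and +1, and the first-base
mismatch excess at offset 0, are the diagnostic lariat signatures.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .core import AlignedPair, AnnotationBundle, IntronAnnotation, SiteTrack
from .profiles import ProfileMatrix, window_profile
from .reads import five_prime_end_track


@dataclass(frozen=True, slots=True)
class BranchpointRecord:
    intron_id: str
    chrom: str
    bp_pos: int
    strand: str
    dist_to_3ss: int


@dataclass(slots=True)
class TruncationSignature:
    anchor: str
    offsets: np.ndarray            # -half .. +half, transcript orientation
    five_prime_end_counts: np.ndarray
    peak_offsets: list[int]        # offsets whose count > mean + 3 SD


@dataclass(slots=True)
class MismatchProfile:
    anchor: str
    offsets: np.ndarray            # -10 .. +10
    read_5p_count: np.ndarray
    mismatch_count: np.ndarray

    @property
    def rate(self) -> np.ndarray:
        """First-base mismatch rate per offset; NaN where no 5' ends."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(
                self.read_5p_count > 0,
                self.mismatch_count / self.read_5p_count,
                np.nan,
            )


def branchpoint_records(
    annotation: AnnotationBundle,
    distance_range: tuple[int, int] = (18, 38),
) -> list[BranchpointRecord]:
    out = []
    lo, hi = distance_range
    for iv in annotation.introns.values():
        d = iv.dist_bp_to_3ss
        if d is not None and lo <= d <= hi:
            out.append(
                BranchpointRecord(iv.intron_id, iv.chrom, iv.bp_pos, iv.strand, d)
            )
    return out


def bp_window_matrix(
    track: SiteTrack,
    bps: Sequence[BranchpointRecord],
    window: int = 101,
    distance_range: tuple[int, int] = (18, 38),
) -> ProfileMatrix:
    """Mean windowed signal around BPs, one row per BP-3'SS distance.

    Rows are ordered by ascending distance; columns are transcript-oriented
    offsets with the BP at 0.  With a 3'CLIP track the peak tracks the
    diagonal offset = distance (the last intronic nt); with cross-link or
    raw 5'-end tracks the lariat truncation signal sits at offsets 0/+1.
    """
    if window % 2 != 1:
        raise ValueError("window must be odd")
    half = window // 2
    offsets = list(range(-half, half + 1))
    lo, hi = distance_range
    rows = []
    row_ids = []
    for d in range(lo, hi + 1):
        anchors = [
            (bp.chrom, bp.bp_pos, bp.strand) for bp in bps if bp.dist_to_3ss == d
        ]
        rows.append(window_profile(track, anchors, offsets))
        row_ids.append(d)
    return ProfileMatrix(
        row_ids=row_ids,
        col_labels=offsets,
        values=np.vstack(rows),
        anchor="branchpoint",
        timepoint_label=track.timepoint_label,
    )


def _anchor_positions(
    annotation: AnnotationBundle, anchor_class: str
) -> list[tuple[str, int, str]]:
    if anchor_class == "BP":
        return [
            (iv.chrom, iv.bp_pos, iv.strand)
            for iv in annotation.introns.values()
            if iv.bp_pos is not None
        ]
    if anchor_class == "intron_5p":
        return [
            (iv.chrom, iv.five_prime_first_nt, iv.strand)
            for iv in annotation.introns.values()
        ]
    if anchor_class == "exon_3p":
        anchors = []
        for tu in annotation.tus.values():
            if tu.n_exons < 2 or tu.is_rrna:
                continue
            for s, e in tu.exons_stranded()[:-1]:
                pos = e - 1 if tu.strand == "+" else s
                anchors.append((tu.chrom, pos, tu.strand))
        return anchors
    raise ValueError(f"unknown anchor class {anchor_class!r}")


def truncation_signature(
    pairs_or_track: Iterable[AlignedPair] | SiteTrack,
    annotation: AnnotationBundle,
    anchor_classes: Sequence[str] = ("BP", "intron_5p", "exon_3p"),
    window: int = 101,
    peak_sd: float = 3.0,
) -> dict[str, TruncationSignature]:
    """Aggregate raw read-5'-end counts around each anchor class.

    The 5' ends are used unshifted (truncation products end *at* the
    blocking structure, so shifting by 1 nt would displace the diagnostic
    peak).  Peaks are offsets whose count exceeds mean + ``peak_sd`` x SD of
    the window.
    """
    if window % 2 != 1:
        raise ValueError("window must be odd")
    track = (
        pairs_or_track
        if isinstance(pairs_or_track, SiteTrack)
        else five_prime_end_track(pairs_or_track)
    )
    half = window // 2
    offsets = np.arange(-half, half + 1)
    out = {}
    for cls in anchor_classes:
        anchors = _anchor_positions(annotation, cls)
        counts = window_profile(
            track, anchors, offsets.tolist(), normalize_by_n=False
        )
        thresh = counts.mean() + peak_sd * counts.std()
        peaks = [int(offsets[i]) for i in np.nonzero(counts > thresh)[0]]
        out[cls] = TruncationSignature(
            anchor=cls,
            offsets=offsets,
            five_prime_end_counts=counts,
            peak_offsets=peaks,
        )
    return out


def mismatch_profile(
    pairs: Iterable[AlignedPair],
    annotation: AnnotationBundle,
    anchor_classes: Sequence[str] = ("BP", "exon_3p"),
    window: int = 21,
) -> dict[str, MismatchProfile]:
    """First-base mismatch rates of read 5' ends in a window over anchors.

    For every read whose read1 5' end falls within the (odd) window around
    an anchor, the 5' end is counted at its transcript-oriented offset, and
    additionally as a mismatch when the read's first base is mismatched.
    Offsets with zero 5' ends yield NaN rates (undefined, not 0).
    """
    if window % 2 != 1:
        raise ValueError("window must be odd")
    half = window // 2
    offsets = np.arange(-half, half + 1)

    # (chrom, strand, genomic pos) -> list of (class, offset index)
    lookup: dict[tuple[str, str, int], list[tuple[str, int]]] = {}
    for cls in anchor_classes:
        for chrom, pos, strand in _anchor_positions(annotation, cls):
            sgn = 1 if strand == "+" else -1
            for i, off in enumerate(offsets):
                p = pos + sgn * int(off)
                if p >= 0:
                    lookup.setdefault((chrom, strand, p), []).append((cls, i))

    read5p = {cls: np.zeros(len(offsets)) for cls in anchor_classes}
    mism = {cls: np.zeros(len(offsets)) for cls in anchor_classes}
    for p in pairs:
        five = p.read1_five_prime
        hits = lookup.get((p.chrom, p.strand, five))
        if not hits:
            continue
        first_is_mismatch = any(pos == five for pos, _base in p.mismatches)
        for cls, i in hits:
            read5p[cls][i] += 1
            if first_is_mismatch:
                mism[cls][i] += 1

    return {
        cls: MismatchProfile(
            anchor=cls,
            offsets=offsets,
            read_5p_count=read5p[cls],
            mismatch_count=mism[cls],
        )
        for cls in anchor_classes
    }


def circular_origin_fraction(signature: TruncationSignature) -> float:
    """Estimate the circular-origin fraction from a BP truncation signature
    as mass(offset 0) / (mass(0) + mass(+1))."""
    idx0 = int(np.nonzero(signature.offsets == 0)[0][0])
    m0 = float(signature.five_prime_end_counts[idx0])
    m1 = float(signature.five_prime_end_counts[idx0 + 1])
    if m0 + m1 == 0:
        raise ValueError("no truncation mass at BP offsets 0/+1")
    return m0 / (m0 + m1)
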