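"""Library-size normalization via rRNA read counts, and region densities.

Libraries from different timepoints recover very different amounts of
RNA-protein complexes, so read-per-million scaling (which assumes equal RNA
input) is inappropriate.  Instead, each library's count of reads mapping to
rRNA genes -- whose recovery is expected to be constant across the time
course -- is divided by an arbitrary 30,000 to form an "rRNA factor";
dividing all track weights by this factor equalizes recovery across
libraries (deeper rRNA recovery scales a library down).
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .core import AlignedPair, GenomicInterval, SiteTrack

log = logging.getLogger(__name__)

DEFAULT_DIVISOR = 30_000


@dataclass(frozen=True, slots=True)
class NormalizationFactor:
    rrna_read_count: int
    divisor: int = DEFAULT_DIVISOR

    def __post_init__(self) -> None:
        if self.rrna_read_count < 0:
            raise ValueError("rRNA read count must be non-negative")
        if self.divisor <= 0:
            raise ValueError("divisor must be positive")

    @property
    def factor(self) -> float:
        return self.rrna_read_count / self.divisor


class _IntervalIndex:
    """Per-(chrom, strand) sorted interval lookup for overlap tests."""

    def __init__(self, intervals: Iterable[GenomicInterval]) -> None:
        self._by_key: dict[tuple[str, str], tuple[list[int], list[int]]] = {}
        grouped: dict[tuple[str, str], list[GenomicInterval]] = {}
        for iv in intervals:
            grouped.setdefault((iv.chrom, iv.strand), []).append(iv)
        for key, ivs in grouped.items():
            ivs.sort(key=lambda iv: iv.start)
            self._by_key[key] = (
                [iv.start for iv in ivs],
                [iv.end for iv in ivs],
            )

    def overlaps(self, chrom: str, strand: str, start: int, end: int) -> bool:
        entry = self._by_key.get((chrom, strand))
        if entry is None:
            return False
        starts, ends = entry
        i = bisect_right(starts, end - 1) - 1
        # scan left while intervals might still reach into [start, end)
        while i >= 0 and ends[i] > start:
            if starts[i] < end:
                return True
            i -= 1
        return False

    def contains(self, chrom: str, strand: str, pos: int) -> bool:
        return self.overlaps(chrom, strand, pos, pos + 1)


def rrna_factor(
    pairs: Iterable[AlignedPair],
    rrna_annotation: Sequence[GenomicInterval],
    divisor: int = DEFAULT_DIVISOR,
) -> NormalizationFactor:
    """Count pairs whose read1 overlaps (>=1 nt, strand-aware) any rRNA
    interval, divided by the divisor.  Zero rRNA reads is an error -- the
    library cannot be normalized."""
    index = _IntervalIndex(rrna_annotation)
    count = 0
    for p in pairs:
        if any(
            index.overlaps(p.chrom, p.strand, s, e) for s, e in p.read1_blocks
        ):
            count += 1
    if count == 0:
        raise ValueError(
            "no reads map to the rRNA annotation; library cannot be normalized"
        )
    return NormalizationFactor(rrna_read_count=count, divisor=divisor)


def scale_track(
    track: SiteTrack,
    nf: NormalizationFactor | float,
    direction: str = "divide",
) -> SiteTrack:
    """Scale all weights by the rRNA factor.

    ``divide`` (default) divides weights by the factor so libraries with
    more rRNA recovery are scaled down; ``multiply`` applies the factor the
    other way around for compatibility with multiplicative `-scale`-style
    options.
    """
    factor = nf.factor if isinstance(nf, NormalizationFactor) else float(nf)
    if factor <= 0:
        raise ValueError("scale factor must be positive")
    if direction not in ("divide", "multiply"):
        raise ValueError(f"unknown scale direction {direction!r}")
    mult = 1.0 / factor if direction == "divide" else factor
    out = SiteTrack(
        {k: w * mult for k, w in track.entries.items()},
        library_label=track.library_label,
        timepoint_label=track.timepoint_label,
    )
    out.dropped = track.dropped
    return out


def expression_normalize(
    per_tu_values: Mapping[str, float],
    expression: Mapping[str, float],
) -> dict[str, float]:
    """Divide per-TU coverage by per-TU expression.

    TUs missing from the expression table, or with non-positive expression,
    are skipped with a warning.
    """
    out: dict[str, float] = {}
    skipped = 0
    for tu_id, value in per_tu_values.items():
        expr = expression.get(tu_id)
        if expr is None or expr <= 0:
            skipped += 1
            continue
        out[tu_id] = value / expr
    if skipped:
        log.warning(
            "expression_normalize: skipped %d TUs with missing or "
            "non-positive expression", skipped,
        )
    return out


def region_density(
    track: SiteTrack,
    regions: Mapping[str, Sequence[GenomicInterval]],
) -> dict[str, float]:
    """Reads per kb per region group: (sum of track weight inside the
    group's intervals) / (sum of interval lengths / 1000)."""
    out: dict[str, float] = {}
    for group, ivs in regions.items():
        if not ivs:
            raise ValueError(f"region group {group!r} is empty")
        total_len = sum(len(iv) for iv in ivs)
        if total_len == 0:
            raise ValueError(f"region group {group!r} has zero total length")
        index = _IntervalIndex(ivs)
        mass = sum(
            w
            for (chrom, strand, pos), w in track.entries.items()
            if index.contains(chrom, strand, pos)
        )
        out[group] = mass / (total_len / 1000.0)
    return out
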