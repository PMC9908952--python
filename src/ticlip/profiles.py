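"""Metagene profiles: spatiotemporal heatmaps and elongation-wave velocity,
exon-anchored windows, 3'CLIP exon-end histograms, mature-RNA profiles with
k-means grouping, junction densities and exon-rank densities.

The spatiotemporal heatmap stratifies TUs by length in 10 kb increments
(0-10, ..., 290-300 kb, plus a >=300 kb group), segments each TU into 1 kb
bins from TSS to TES, averages binned signal across group members and
normalizes each group by its maximum.  The wave front at each timepoint is
the farthest bin with appreciable smoothed signal; ordinary least squares on
front position versus minutes after release estimates the invasion velocity
in kb/min, to be compared with the canonical ~3.5 kb/min RNAPII elongation
rate.
"""

from __future__ import annotations

import logging
import math
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .core import GenomicInterval, SiteTrack, TranscriptionUnit
from .normalize import region_density

log = logging.getLogger(__name__)


@dataclass(slots=True)
class ProfileMatrix:
    """Rows = anchored units (TUs / groups / distances), columns = bins or
    offsets; NaN marks bins beyond a row's extent."""

    row_ids: list
    col_labels: list
    values: np.ndarray
    anchor: str = ""
    timepoint_label: str = ""
    normalized: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_ids, columns=self.col_labels)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")


@dataclass(slots=True)
class WaveEstimate:
    velocity_kb_per_min: float
    intercept_kb: float
    front_kb_by_timepoint: dict[float, float]
    r_squared: float


@dataclass(slots=True)
class MatureProfile:
    tu_id: str
    bin_values: np.ndarray | None
    excluded_reason: str | None = None  # None | "length" | "reads"

    @property
    def excluded(self) -> bool:
        return self.excluded_reason is not None


@dataclass(slots=True)
class ClusterGroups:
    groups: dict[str, set[str]]
    provenance: list[str] = field(default_factory=list)
    per_replicate_labels: dict[str, dict[str, int]] = field(default_factory=dict)


class _TuLocator:
    """Position -> TU lookup via per-(chrom, strand) sorted starts.

    Assumes TUs do not overlap on the same chrom+strand (true for the
    simulator; for overlapping real annotation the left-most match wins).
    """

    def __init__(self, tus: Iterable[TranscriptionUnit]) -> None:
        self._by_key: dict[tuple[str, str], tuple[list[int], list]] = {}
        grouped: dict[tuple[str, str], list[TranscriptionUnit]] = {}
        for tu in tus:
            grouped.setdefault((tu.chrom, tu.strand), []).append(tu)
        for key, members in grouped.items():
            members.sort(key=lambda t: t.start)
            self._by_key[key] = ([t.start for t in members], members)

    def find(self, chrom: str, strand: str, pos: int) -> TranscriptionUnit | None:
        entry = self._by_key.get((chrom, strand))
        if entry is None:
            return None
        starts, members = entry
        i = bisect_right(starts, pos) - 1
        if i >= 0 and members[i].start <= pos < members[i].end:
            return members[i]
        return None


def _length_group(length: int) -> str:
    kb = length / 1000.0
    if kb >= 300:
        return ">=300kb"
    lo = int(kb // 10) * 10
    return f"[{lo},{lo + 10})kb"


def length_group_order(labels: Iterable[str]) -> list[str]:
    def key(lbl: str) -> int:
        if lbl == ">=300kb":
            return 300
        return int(lbl.split(",")[0][1:])

    return sorted(set(labels), key=key)


def spatiotemporal_matrix(
    track: SiteTrack,
    tus: Sequence[TranscriptionUnit],
    read_scope: str = "all",
    bin_size: int = 1000,
) -> ProfileMatrix:
    """Length-stratified 1 kb-binned group-mean profiles, max-normalized.

    Rows are 10 kb length groups; column ``i`` is the mean signal of group
    members in their TSS-anchored bin ``[i*1kb, (i+1)*1kb)``, TES-truncated
    (TUs shorter than a bin do not contribute to it), divided by the group
    maximum.  ``read_scope='intronic_only'`` restricts the signal to
    intron-overlapping positions.
    """
    if read_scope not in ("all", "intronic_only"):
        raise ValueError(f"unknown read_scope {read_scope!r}")
    tus = [tu for tu in tus if not tu.is_rrna]
    locator = _TuLocator(tus)

    n_bins = {tu.tu_id: -(-tu.length // bin_size) for tu in tus}
    counts: dict[str, np.ndarray] = {
        tu.tu_id: np.zeros(n_bins[tu.tu_id]) for tu in tus
    }
    intron_sets: dict[str, list[tuple[int, int]]] = {}
    if read_scope == "intronic_only":
        intron_sets = {tu.tu_id: list(tu.introns) for tu in tus}

    for (chrom, strand, pos), w in track.entries.items():
        tu = locator.find(chrom, strand, pos)
        if tu is None:
            continue
        if read_scope == "intronic_only" and not any(
            s <= pos < e for s, e in intron_sets[tu.tu_id]
        ):
            continue
        off = tu.genome_to_premrna(pos)
        if 0 <= off < tu.length:
            counts[tu.tu_id][off // bin_size] += w

    groups: dict[str, list[str]] = {}
    for tu in tus:
        groups.setdefault(_length_group(tu.length), []).append(tu.tu_id)

    labels = length_group_order(groups)
    max_cols = max(
        (max(n_bins[t] for t in groups[g]) for g in labels), default=0
    )
    values = np.full((len(labels), max_cols), np.nan)
    kept_labels = []
    for gi, g in enumerate(labels):
        members = groups[g]
        if not members:
            log.warning("length group %s empty; omitted", g)
            continue
        g_cols = max(n_bins[t] for t in members)
        sums = np.zeros(g_cols)
        denom = np.zeros(g_cols)
        for t in members:
            nb = n_bins[t]
            sums[:nb] += counts[t]
            denom[:nb] += 1
        mean = np.where(denom > 0, sums / np.maximum(denom, 1), np.nan)
        gmax = np.nanmax(mean) if np.any(np.isfinite(mean)) else 0.0
        if gmax > 0:
            mean = mean / gmax
        values[gi, :g_cols] = mean
        kept_labels.append(g)

    keep = [labels.index(g) for g in kept_labels]
    return ProfileMatrix(
        row_ids=kept_labels,
        col_labels=list(range(values.shape[1])),
        values=values[keep],
        anchor="TSS (1kb bins)",
        timepoint_label=track.timepoint_label,
        normalized=True,
    )


def estimate_wave_velocity(
    matrices: Mapping[float, ProfileMatrix],
    tau: float = 0.1,
    smooth_bins: int = 3,
    fit_minutes: tuple[float, float] = (5.0, 60.0),
    mass_quantile: float = 0.99,
    saturation_margin: int | None = None,
) -> WaveEstimate:
    """Estimate the elongation-wave velocity from per-timepoint heatmaps.

    Keyed by minutes after release.  Per length group, bins whose
    moving-average-smoothed, group-normalized value falls below ``tau`` are
    treated as background and masked; the group's front is the bin by which
    ``mass_quantile`` of the remaining signal mass has accumulated (a
    single-threshold "last bin above tau" front is fragile in sparsely
    covered long groups, where chance zero-runs fire it well short of the
    true front).  Groups whose front comes within ``saturation_margin``
    bins of their own end are excluded: their front is gene-length-limited,
    not wave-limited.  The margin defaults to the 10-bin stratum width plus
    the smoothing window -- group members differ by up to one stratum in
    length, so a fully invaded group's mean profile can fall off that far
    before the longest member's TES.  The per-timepoint front is the median
    over usable groups, and velocity is the OLS slope of front (kb) versus
    minutes over release timepoints only (t00 and the steady-state sample
    carry no wave information).
    """
    if saturation_margin is None:
        saturation_margin = 10 + smooth_bins
    fronts: dict[float, float] = {}
    kernel = np.ones(smooth_bins) / smooth_bins
    for minutes, pm in matrices.items():
        if not (fit_minutes[0] <= minutes <= fit_minutes[1]) or math.isinf(minutes):
            continue
        group_fronts = []
        for row in pm.values:
            valid = np.isfinite(row)
            n_valid = int(valid.sum())
            if n_valid < smooth_bins + 1:
                continue
            prof = np.where(valid, row, 0.0)[:n_valid]
            smoothed = np.convolve(prof, kernel, mode="same")
            masked = np.where(smoothed >= tau, prof, 0.0)
            total = masked.sum()
            if total <= 0:
                continue
            cum = np.cumsum(masked)
            front = int(np.searchsorted(cum, mass_quantile * total))
            if front >= n_valid - saturation_margin:
                continue  # saturated: wave has reached the group's TES
            group_fronts.append(front + 1.0)  # kb (bin end)
        if group_fronts:
            fronts[minutes] = float(np.median(group_fronts))

    if len(fronts) < 3:
        raise ValueError(
            f"only {len(fronts)} usable wave fronts; >=3 timepoints required"
        )
    t = np.array(sorted(fronts))
    y = np.array([fronts[m] for m in t])
    slope, intercept = np.polyfit(t, y, 1)
    pred = slope * t + intercept
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return WaveEstimate(
        velocity_kb_per_min=float(slope),
        intercept_kb=float(intercept),
        front_kb_by_timepoint=dict(fronts),
        r_squared=r2,
    )


# ---------------------------------------------------------------------------
# windowed aggregation around anchors
# ---------------------------------------------------------------------------

def window_profile(
    track: SiteTrack,
    anchors: Sequence[tuple[str, int, str]],
    offsets: Sequence[int],
    normalize_by_n: bool = True,
) -> np.ndarray:
    """Sum track weight at anchor+offset in transcript orientation.

    ``anchors`` are (chrom, genomic position, strand); positive offsets run
    downstream along the RNA.  Divides by the number of anchors when
    ``normalize_by_n``; anchors near chromosome starts simply contribute
    zeros at out-of-range offsets.
    """
    prof = np.zeros(len(offsets))
    entries = track.entries
    for chrom, pos, strand in anchors:
        sgn = 1 if strand == "+" else -1
        for i, off in enumerate(offsets):
            p = pos + sgn * off
            if p >= 0:
                w = entries.get((chrom, strand, p))
                if w:
                    prof[i] += w
    if normalize_by_n and anchors:
        prof /= len(anchors)
    return prof


def exon_anchor_positions(
    tus: Sequence[TranscriptionUnit],
    which: str,
    end: str,
) -> list[tuple[str, int, str]]:
    """Anchors at the first/internal/last exon 5'/3' ends of multi-exonic TUs."""
    if which not in ("first", "internal", "last"):
        raise ValueError(f"unknown exon category {which!r}")
    if end not in ("5p", "3p"):
        raise ValueError(f"end must be '5p' or '3p', got {end!r}")
    anchors = []
    for tu in tus:
        if tu.n_exons < 2 or tu.is_rrna:
            continue
        exons = tu.exons_stranded()
        if which == "first":
            chosen = [exons[0]]
        elif which == "last":
            chosen = [exons[-1]]
        else:
            chosen = exons[1:-1]
        for s, e in chosen:
            if tu.strand == "+":
                pos = s if end == "5p" else e - 1
            else:
                pos = e - 1 if end == "5p" else s
            anchors.append((tu.chrom, pos, tu.strand))
    return anchors


def exon_anchored_profile(
    track: SiteTrack,
    tus: Sequence[TranscriptionUnit],
    which: str,
    end: str,
    window: int = 201,
) -> tuple[np.ndarray, np.ndarray]:
    """Aggregate profile over a window centred on exon ends.

    Returns (offsets, profile) with offsets -(window//2)..window//2 in
    transcript orientation; window must be odd.
    """
    if window % 2 != 1:
        raise ValueError("window must be odd")
    half = window // 2
    offsets = np.arange(-half, half + 1)
    anchors = exon_anchor_positions(tus, which, end)
    return offsets, window_profile(track, anchors, offsets.tolist())


def three_prime_end_histogram(
    track: SiteTrack,
    tus: Sequence[TranscriptionUnit],
    window: int = 76,
) -> tuple[np.ndarray, np.ndarray, float]:
    """3'CLIP aggregate over an even window at first-exon 3' ends.

    The centre is placed so offset 0 is the exon's last nucleotide; offsets
    run -(window//2)..window//2 - 1.  Returns (offsets, profile, value at
    offset 0) -- the offset-0 value quantifies fragments whose 3' terminus
    is the free first-exon end, i.e. RNAs caught between the two
    transesterification steps of first-intron splicing.
    """
    half = window // 2
    offsets = np.arange(-half, window - half)
    anchors = exon_anchor_positions(tus, "first", "3p")
    prof = window_profile(track, anchors, offsets.tolist())
    at_zero = float(prof[np.nonzero(offsets == 0)[0][0]])
    return offsets, prof, at_zero


def exon_rank_density(
    track: SiteTrack,
    tus: Sequence[TranscriptionUnit],
) -> dict[str, float]:
    """Reads/kb over the first 4, the last 4 and any internal exons of
    multi-exonic TUs."""
    regions: dict[str, list[GenomicInterval]] = {
        "first4": [],
        "last4": [],
        "internal": [],
    }
    for tu in tus:
        if tu.n_exons < 2 or tu.is_rrna:
            continue
        exons = tu.exons_stranded()
        n = len(exons)
        for rank, (s, e) in enumerate(exons):
            iv = GenomicInterval(tu.chrom, s, e, tu.strand)
            if rank < 4:
                regions["first4"].append(iv)
            elif rank >= n - 4:
                regions["last4"].append(iv)
            else:
                regions["internal"].append(iv)
    regions = {k: v for k, v in regions.items() if v}
    return region_density(track, regions)


# ---------------------------------------------------------------------------
# mature-RNA profiles and clustering
# ---------------------------------------------------------------------------

def mature_profile(
    track: SiteTrack,
    tu: TranscriptionUnit,
    n_bins: int = 100,
    min_length: int = 200,
    min_reads: int = 20,
) -> MatureProfile:
    """Length-normalized cross-link profile over the mature (exonic) TU.

    Exonic positions are projected onto mature coordinates, binned into
    ``n_bins`` equal bins (position p -> floor(p*n_bins/mature_length),
    last position clamped), and divided by the TU total.  TUs with mature
    length <= ``min_length`` nt or <= ``min_reads`` mapped reads are
    excluded (strict inequalities).
    """
    mlen = tu.mature_length
    if mlen <= min_length:
        return MatureProfile(tu.tu_id, None, "length")
    bins = np.zeros(n_bins)
    total = 0.0
    for (chrom, strand, pos), w in track.entries.items():
        if chrom != tu.chrom or strand != tu.strand:
            continue
        m = tu.genome_to_mature(pos)
        if m is None:
            continue
        b = min(m * n_bins // mlen, n_bins - 1)
        bins[b] += w
        total += w
    if total <= min_reads:
        return MatureProfile(tu.tu_id, None, "reads")
    return MatureProfile(tu.tu_id, bins / total)


def mature_profiles(
    track: SiteTrack,
    tus: Sequence[TranscriptionUnit],
    **kwargs,
) -> dict[str, MatureProfile]:
    return {tu.tu_id: mature_profile(track, tu, **kwargs) for tu in tus}


def _greedy_match(ref_centers: np.ndarray, centers: np.ndarray) -> dict[int, int]:
    """Greedy max-cosine-similarity matching of cluster centres to the
    reference replicate's centres; returns {replicate cluster -> ref cluster}."""

    def unit(v: np.ndarray) -> np.ndarray:
        n = np.linalg.norm(v)
        return v / n if n > 0 else v

    sim = np.array(
        [[float(unit(c) @ unit(r)) for r in ref_centers] for c in centers]
    )
    mapping: dict[int, int] = {}
    used_ref: set[int] = set()
    order = np.dstack(np.unravel_index(np.argsort(-sim, axis=None), sim.shape))[0]
    for ci, ri in order:
        if ci in mapping or ri in used_ref:
            continue
        mapping[int(ci)] = int(ri)
        used_ref.add(int(ri))
    return mapping


def kmeans_profile_groups(
    profiles_by_replicate: Mapping[str, Mapping[str, np.ndarray]],
    k: int = 3,
    seed: int = 0,
    report_background: bool = False,
) -> ClusterGroups:
    """Per-replicate k-means on mature profiles, intersected across
    replicates into bona fide profile groups.

    Each replicate is clustered independently (Euclidean distance on raw
    profile vectors, 10 restarts, fixed seed); clusters are matched across
    replicates by maximal centroid cosine similarity (greedy); a TU belongs
    to a final group only if it is assigned to matched clusters in every
    replicate.  The largest intersected cluster is treated as the
    unstructured background and not reported unless ``report_background``.
    Reported groups are labelled group1, group2, ... ordered by the bin of
    their reference-replicate centroid maximum (5'-most first).
    """
    reps = list(profiles_by_replicate)
    if len(reps) < 2:
        raise ValueError("at least two replicates required for intersection")
    common = set.intersection(
        *(set(profiles_by_replicate[r]) for r in reps)
    )
    tu_ids = sorted(common)
    if k > len(tu_ids):
        raise ValueError(f"k={k} exceeds the {len(tu_ids)} shared profiles")

    labels_by_rep: dict[str, np.ndarray] = {}
    centers_by_rep: dict[str, np.ndarray] = {}
    for i, rep in enumerate(reps):
        X = np.vstack([profiles_by_replicate[rep][t] for t in tu_ids])
        km = KMeans(n_clusters=k, n_init=10, random_state=seed + i)
        labels_by_rep[rep] = km.fit_predict(X)
        centers_by_rep[rep] = km.cluster_centers_

    ref = reps[0]
    mapped: dict[str, np.ndarray] = {ref: labels_by_rep[ref]}
    for rep in reps[1:]:
        m = _greedy_match(centers_by_rep[ref], centers_by_rep[rep])
        mapped[rep] = np.array([m[int(c)] for c in labels_by_rep[rep]])

    consensus: dict[int, set[str]] = {c: set() for c in range(k)}
    for idx, tu_id in enumerate(tu_ids):
        assigned = {int(mapped[rep][idx]) for rep in reps}
        if len(assigned) == 1:
            consensus[assigned.pop()].add(tu_id)

    sizes = {c: len(m) for c, m in consensus.items()}
    background = max(sizes, key=lambda c: (sizes[c], -c))
    ordered = [
        c
        for c in sorted(
            (c for c in consensus if report_background or c != background),
            key=lambda c: int(np.argmax(centers_by_rep[ref][c])),
        )
    ]
    groups: dict[str, set[str]] = {}
    for n, c in enumerate(ordered, 1):
        label = f"group{n}"
        if report_background and c == background:
            label = "background"
        groups[label] = consensus[c]
    per_rep = {
        rep: {t: int(mapped[rep][i]) for i, t in enumerate(tu_ids)}
        for rep in reps
    }
    return ClusterGroups(groups=groups, provenance=reps, per_replicate_labels=per_rep)


def junction_density_profile(
    tus: Sequence[TranscriptionUnit],
    n_bins: int = 100,
) -> np.ndarray:
    """Average exon-exon junction density in mature coordinates.

    Per TU, junction positions are binned into ``n_bins`` bins and
    normalized by the TU's junction count; mono-exonic TUs contribute
    zeros; the group average is returned.
    """
    if not tus:
        return np.zeros(n_bins)
    acc = np.zeros(n_bins)
    for tu in tus:
        offs = tu.junction_mature_offsets()
        if not offs:
            continue
        per_tu = np.zeros(n_bins)
        mlen = tu.mature_length
        for m in offs:
            per_tu[min(m * n_bins // mlen, n_bins - 1)] += 1
        acc += per_tu / len(offs)
    return acc / len(tus)
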