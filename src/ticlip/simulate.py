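"""Generative model of a DRB-release CLIP time course with ground truth.

The simulator emits annotation plus paired-end alignments whose latent
structure matches what the analysis assumes: nascent transcription invades
each TU at a configurable velocity after release of the elongation block,
cross-links are placed by a factor-specific anchoring density, splicing of
fully transcribed introns follows single-exponential kinetics, excised
introns persist as lariats whose reverse transcription truncates at the
branchpoint (circular origin, with a mismatched terminal base) or one
nucleotide downstream of it (linear origin), and snoRNA-hosting introns emit
3'-extended precursor intermediates whose fragment termini sit at the
snoRNA 3' end plus a class-specific offset.  Every emitted read pair has
exactly one ground-truth record keyed by read name, so each downstream
operation can be tested against the latent variables that produced its
input.

Coordinates follow the package-wide 0-based half-open convention.  Mates
fully overlap (short CLIP fragments sequenced from both ends), so read1 and
read2 cover the same blocks and |TLEN| equals the genomic fragment span.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import (
    AlignedPair,
    AnnotationBundle,
    DEFAULT_TIMEPOINTS,
    IntronAnnotation,
    SnoRNAAnnotation,
    TranscriptionUnit,
    derive_introns,
)

FACTOR_MODELS = (
    "CAP_ANCHORED",
    "EXON3P_EJC",
    "INTRON3P_LARIAT_SNORNA",
    "UNIFORM_NASCENT",
)

DEFAULT_BARCODES = (
    "AACCG",
    "TTGGC",
    "CATGA",
    "GTCAT",
    "AGGTC",
    "TCAAG",
    "GCTTA",
    "CGAAT",
)

_BASES = "ACGT"


@dataclass(slots=True)
class SimConfig:
    """Study conditions for the simulated time course.

    Velocity defaults to the canonical RNAPII elongation rate of
    3.5 kb/min; extension offsets default to the H/ACA {9, 25} nt
    intermediates and the <=25 nt variable CD-box extensions.  Fragment
    lengths respect the ~20 nt lower mapping limit of short inserts.
    """

    seed: int = 0
    velocity_kb_per_min: float = 3.5
    timepoints: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TIMEPOINTS)
    )
    factor_model: str = "UNIFORM_NASCENT"
    splice_halflife_min: float = 4.0
    step2_halflife_min: float = 5.0
    lariat_fraction: float = 0.3
    circular_origin_fraction: float = 0.5
    haca_extension_offsets: tuple[int, ...] = (9, 25)
    cd_extension_max: int = 25
    rrna_fraction: float = 0.05
    pcr_dup_rate: float = 0.1
    reads_per_library: int = 20000
    umi_length: int = 8
    barcodes: tuple[str, ...] = DEFAULT_BARCODES
    fragment_length_range: tuple[int, int] = (25, 75)
    n_replicates: int = 2
    # geometry of the generative model
    pause_offset_nt: int = 300  # cap-proximal RNA made during the block
    cap_anchor_scale_nt: float = 50.0
    ejc_anchor_upstream_nt: int = 25
    ejc_anchor_sd_nt: float = 8.0
    intron3p_zone: tuple[int, int] = (100, 20)  # -100..-20 nt from intron end
    sno_host_fraction: float = 0.15
    sno_intermediate_fraction: float = 0.5
    mono_exonic_fraction: float = 0.25
    tu_length_range: tuple[int, int] = (600, 320_000)
    n_rrna_units: int = 4

    def __post_init__(self) -> None:
        for name in (
            "lariat_fraction",
            "circular_origin_fraction",
            "rrna_fraction",
            "pcr_dup_rate",
            "sno_host_fraction",
            "sno_intermediate_fraction",
            "mono_exonic_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.velocity_kb_per_min <= 0:
            raise ValueError("velocity must be positive")
        if self.fragment_length_range[0] < 20:
            raise ValueError(
                "minimum fragment length below the 20 nt mapping limit"
            )
        if self.fragment_length_range[0] > self.fragment_length_range[1]:
            raise ValueError("fragment_length_range must be (min, max)")
        if self.factor_model not in FACTOR_MODELS:
            raise ValueError(f"unknown factor model {self.factor_model!r}")
        if self.reads_per_library < 1:
            raise ValueError("reads_per_library must be >= 1")
        if not self.barcodes:
            raise ValueError("at least one barcode required")


# ---------------------------------------------------------------------------
# annotation generator
# ---------------------------------------------------------------------------

_MIN_INTRON = 150
_SNO_MIN_INTRON = 400  # room for a snoRNA body plus a clean 3' flank


def make_annotation(
    n_tu: int, seed: int, config: SimConfig | None = None
) -> AnnotationBundle:
    """Generate mono- and multi-exonic TUs spanning length strata up to
    >300 kb, introns with branchpoints 18-38 nt upstream of their 3'SS,
    intron-hosted snoRNAs (CD / H/ACA, equal odds), and dedicated rRNA
    units.  Deterministic for a fixed (n_tu, seed, config)."""
    if n_tu < 1:
        raise ValueError("n_tu must be >= 1")
    config = config or SimConfig()
    rng = np.random.default_rng([seed, 0xA0])

    tus: dict[str, TranscriptionUnit] = {}
    introns: dict[str, IntronAnnotation] = {}
    snornas: dict[str, SnoRNAAnnotation] = {}

    lo, hi = config.tu_length_range
    log_lo, log_hi = math.log(lo), math.log(hi)
    cursor = 1000
    chrom = "chrS1"
    chrom_sizes: dict[str, int] = {}
    sno_counter = 0

    for i in range(n_tu):
        length = int(math.exp(rng.uniform(log_lo, log_hi)))
        strand = "+" if rng.random() < 0.5 else "-"
        start = cursor
        end = start + length
        tu_id = f"TU{i:04d}"
        mono = length < 1200 or rng.random() < config.mono_exonic_fraction
        if mono:
            exons = ((start, end),)
        else:
            # walk 5'->3' in transcript coordinates: exon/intron alternation
            bounds: list[tuple[int, int]] = []  # premRNA offsets of exons
            off = 0
            first_len = int(rng.integers(150, 400))
            bounds.append((off, min(off + first_len, length)))
            off = bounds[-1][1]
            while True:
                intron_len = int(rng.integers(_MIN_INTRON, 8000))
                exon_len = int(rng.integers(80, 250))
                if off + intron_len + exon_len + 80 > length:
                    break
                off += intron_len
                bounds.append((off, off + exon_len))
                off += exon_len
            # extend the last exon to the TES
            s_last, _ = bounds[-1]
            bounds[-1] = (s_last, length)
            if len(bounds) == 1:
                exons = ((start, end),)
            elif strand == "+":
                exons = tuple((start + a, start + b) for a, b in bounds)
            else:
                exons = tuple(
                    sorted((end - b, end - a) for a, b in bounds)
                )
        tu = TranscriptionUnit(
            tu_id=tu_id, chrom=chrom, start=start, end=end, strand=strand,
            exons=exons,
        )
        tus[tu_id] = tu
        for iv in derive_introns(tu):
            # branchpoint 18-38 nt upstream of the 3'SS (uniform)
            dist = int(rng.integers(18, 39))
            if iv.strand == "+":
                iv.bp_pos = iv.end - dist
            else:
                iv.bp_pos = iv.start + dist - 1
            introns[iv.intron_id] = iv
            # a subset of long introns hosts one snoRNA
            if (
                iv.length >= _SNO_MIN_INTRON
                and rng.random() < config.sno_host_fraction
            ):
                sno_len = int(rng.integers(60, 131))
                # keep the 35 nt extension window clear of the intron-3'
                # anchoring zone and of the BP region
                max_flank3 = iv.length - sno_len - 20
                if max_flank3 < 140:
                    continue
                flank3 = int(rng.integers(140, min(201, max_flank3 + 1)))
                if iv.strand == "+":
                    s_end = iv.end - flank3
                    s_start = s_end - sno_len
                else:
                    s_start = iv.start + flank3
                    s_end = s_start + sno_len
                cls = "CD" if rng.random() < 0.5 else "HACA"
                sno_id = f"SNO{sno_counter:03d}"
                sno_counter += 1
                snornas[sno_id] = SnoRNAAnnotation(
                    sno_id=sno_id, chrom=iv.chrom, start=s_start, end=s_end,
                    strand=iv.strand, sno_class=cls,
                    host_intron_id=iv.intron_id,
                )
        cursor = end + 1000
    chrom_sizes[chrom] = cursor + 1000

    # dedicated rRNA units on their own chromosome
    r_cursor = 1000
    for j in range(config.n_rrna_units):
        length = int(rng.integers(2000, 6001))
        tu_id = f"rRNA{j}"
        tus[tu_id] = TranscriptionUnit(
            tu_id=tu_id, chrom="chrR", start=r_cursor, end=r_cursor + length,
            strand="+", exons=((r_cursor, r_cursor + length),), is_rrna=True,
        )
        r_cursor += length + 1000
    chrom_sizes["chrR"] = r_cursor + 1000

    return AnnotationBundle(
        tus=tus, introns=introns, snornas=snornas, chrom_sizes=chrom_sizes
    )


# ---------------------------------------------------------------------------
# time-course read generator
# ---------------------------------------------------------------------------

@dataclass(slots=True)
class _TuModel:
    """Per-TU precomputation in pre-mRNA (TSS-anchored) offsets."""

    tu: TranscriptionUnit
    introns: list[IntronAnnotation]        # transcript order
    intron_offs: list[tuple[int, int]]     # premRNA [start, end) per intron
    bp_offs: list[int]                     # premRNA offset of each BP
    sno_by_intron: dict[int, SnoRNAAnnotation]
    sno_3p_offs: dict[int, int]


def _build_models(annotation: AnnotationBundle) -> list[_TuModel]:
    sno_by_iid: dict[str, SnoRNAAnnotation] = {
        s.host_intron_id: s for s in annotation.snornas.values()
    }
    models = []
    for tu in annotation.tus.values():
        if tu.is_rrna:
            continue
        ivs = annotation.introns_of(tu.tu_id)
        intron_offs = []
        bp_offs = []
        sno_by_intron: dict[int, SnoRNAAnnotation] = {}
        sno_3p_offs: dict[int, int] = {}
        for k, iv in enumerate(ivs):
            if tu.strand == "+":
                a, b = iv.start - tu.start, iv.end - tu.start
            else:
                a, b = tu.end - iv.end, tu.end - iv.start
            intron_offs.append((a, b))
            bp_offs.append(
                tu.genome_to_premrna(iv.bp_pos) if iv.bp_pos is not None else -1
            )
            sno = sno_by_iid.get(iv.intron_id)
            if sno is not None:
                sno_by_intron[k] = sno
                sno_3p_offs[k] = tu.genome_to_premrna(sno.three_prime_end)
        models.append(
            _TuModel(tu, ivs, intron_offs, bp_offs, sno_by_intron, sno_3p_offs)
        )
    return models


def _premrna_interval_to_blocks(
    tu: TranscriptionUnit, a: int, b: int
) -> tuple[tuple[int, int], ...]:
    """Map the pre-mRNA offset interval [a, b) to a genomic block."""
    if tu.strand == "+":
        return ((tu.start + a, tu.start + b),)
    return ((tu.end - b, tu.end - a),)


def _molecule_to_blocks(
    tu: TranscriptionUnit,
    segments: list[tuple[int, int]],
    m_start: int,
    m_end: int,
) -> tuple[tuple[int, int], ...]:
    """Map a molecule-coordinate interval onto genomic blocks.

    ``segments`` are the molecule's pre-mRNA offset intervals in transcript
    order; the molecule coordinate concatenates them.
    """
    blocks: list[tuple[int, int]] = []
    cum = 0
    for a, b in segments:
        seg_len = b - a
        lo = max(m_start - cum, 0)
        hi = min(m_end - cum, seg_len)
        if hi > lo:
            blocks.extend(_premrna_interval_to_blocks(tu, a + lo, a + hi))
        cum += seg_len
        if cum >= m_end:
            break
    blocks.sort()
    # merge abutting blocks (can arise when an excised intron had length 0)
    merged: list[tuple[int, int]] = []
    for s, e in blocks:
        if merged and merged[-1][1] == s:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    return tuple(merged)


def _molecule_coord_to_premrna(segments: list[tuple[int, int]], m: int) -> int:
    cum = 0
    for a, b in segments:
        if m < cum + (b - a):
            return a + (m - cum)
        cum += b - a
    raise ValueError("molecule coordinate out of range")


class _LibrarySim:
    """Single-library read generator (one timepoint x replicate)."""

    def __init__(
        self,
        annotation: AnnotationBundle,
        models: list[_TuModel],
        config: SimConfig,
        minutes: float,
        rng: np.random.Generator,
    ) -> None:
        self.annotation = annotation
        self.config = config
        self.minutes = minutes
        self.rng = rng
        self.v_nt_per_min = config.velocity_kb_per_min * 1000.0
        self.models = models
        self._last_rec_by_name: dict[str, dict] = {}
        self.lt = np.array(
            [self._transcribed_extent(m.tu) for m in models], dtype=float
        )
        self.weights = self.lt / self.lt.sum()
        self._cum_weights = np.cumsum(self.weights)
        self.rrna_units = annotation.rrna_units

    def _transcribed_extent(self, tu: TranscriptionUnit) -> int:
        if math.isinf(self.minutes):
            return tu.length
        return min(
            tu.length,
            self.config.pause_offset_nt
            + int(self.v_nt_per_min * self.minutes),
        )

    def _splice_prob(self, dt: float) -> float:
        if dt <= 0:
            return 0.0
        if math.isinf(dt):
            return 1.0
        return 1.0 - 2.0 ** (-dt / self.config.splice_halflife_min)

    def _post1_prob(self, dt: float) -> float:
        if math.isinf(dt):
            return 0.0
        return 2.0 ** (-dt / self.config.step2_halflife_min)

    def _intron_dt(self, model: _TuModel, k: int) -> float:
        """Minutes elapsed since intron k became fully transcribed."""
        if math.isinf(self.minutes):
            return math.inf
        end_off = model.intron_offs[k][1]
        born = max(0.0, (end_off - self.config.pause_offset_nt) / self.v_nt_per_min)
        return self.minutes - born

    def _fraglen(self) -> int:
        lo, hi = self.config.fragment_length_range
        return int(self.rng.integers(lo, hi + 1))

    # -- read constructors ---------------------------------------------------

    def _rrna_read(self) -> dict:
        unit = self.rrna_units[int(self.rng.integers(len(self.rrna_units)))]
        fl = self._fraglen()
        start = int(self.rng.integers(unit.start, max(unit.start + 1, unit.end - fl)))
        end = min(start + fl, unit.end)
        blocks = ((start, end),)
        return {
            "tu_id": unit.tu_id,
            "blocks": blocks,
            "strand": unit.strand,
            "chrom": unit.chrom,
            "mismatches": (),
            "xl_pos": start - 1 if unit.strand == "+" else end,
            "frag3p_pos": end - 1 if unit.strand == "+" else start,
            "splice_state": "",
            "lariat_origin": "none",
            "extension_offset": None,
            "intron_id": "",
            "sno_id": "",
            "is_rrna": True,
        }

    def _draw_intron_states(self, model: _TuModel, lt: int) -> list[str]:
        """Per-read splice state of each fully transcribed intron.

        States: 'unspliced', 'post1' (branch formed, exons unligated),
        'spliced' (post 2nd step; lariat fate decided downstream).
        """
        states = []
        for k, (a, b) in enumerate(model.intron_offs):
            if b > lt:
                states.append("na")
                continue
            dt = self._intron_dt(model, k)
            if self.rng.random() >= self._splice_prob(dt):
                states.append("unspliced")
            elif self.rng.random() < self._post1_prob(dt):
                states.append("post1")
            else:
                states.append("spliced")
        return states

    def _molecule_segments(
        self, model: _TuModel, lt: int, states: list[str]
    ) -> tuple[list[tuple[int, int]], str]:
        """Cap-anchored molecule: pre-mRNA segments after excising spliced
        introns, truncated at the first post-1st-step intron (its upstream
        exon 3' end is still unligated) and at the transcribed extent."""
        segments: list[tuple[int, int]] = []
        pos = 0
        overall = "pre-1st-step"
        for k, (a, b) in enumerate(model.intron_offs):
            if b > lt:
                break
            state = states[k]
            if state == "post1":
                if a > pos:
                    segments.append((pos, a))
                return segments or [(0, max(1, min(a, lt)))], "post-1st-step"
            if state == "spliced":
                if a > pos:
                    segments.append((pos, a))
                pos = b
                overall = "post-2nd-step"
        if lt > pos:
            segments.append((pos, lt))
        return segments, overall

    def _nascent_read(self, model: _TuModel) -> dict:
        """CAP_ANCHORED / EXON3P_EJC / UNIFORM_NASCENT read placement."""
        tu = model.tu
        lt = self._transcribed_extent(tu)
        fm = self.config.factor_model

        if fm == "UNIFORM_NASCENT":
            segments = [(0, lt)]
            state = "pre-1st-step"
        else:
            states = self._draw_intron_states(model, lt)
            segments, state = self._molecule_segments(model, lt, states)
        mlen = sum(b - a for a, b in segments)
        if mlen < 2:
            segments, mlen, state = [(0, max(2, lt))], max(2, lt), "pre-1st-step"

        if fm == "CAP_ANCHORED":
            x = min(
                int(self.rng.exponential(self.config.cap_anchor_scale_nt)),
                mlen - 1,
            )
        elif fm == "EXON3P_EJC":
            x = self._ejc_crosslink(model, segments, mlen, states)
        else:
            x = int(self.rng.integers(0, mlen))

        fl = self._fraglen()
        m_start = x + 1
        m_end = min(m_start + fl, mlen)
        if m_end <= m_start:  # cross-link at the molecule 3' terminus
            m_start = max(0, mlen - fl)
            m_end = mlen
            x = m_start - 1
        blocks = _molecule_to_blocks(tu, segments, m_start, m_end)
        xl_pre = (
            _molecule_coord_to_premrna(segments, x) if x >= 0 else -1
        )
        frag3p_pre = _molecule_coord_to_premrna(segments, m_end - 1)
        return {
            "tu_id": tu.tu_id,
            "blocks": blocks,
            "strand": tu.strand,
            "chrom": tu.chrom,
            "mismatches": (),
            "xl_pos": tu.premrna_to_genome(xl_pre) if xl_pre >= 0 else -1,
            "frag3p_pos": tu.premrna_to_genome(frag3p_pre),
            "splice_state": state,
            "lariat_origin": "none",
            "extension_offset": None,
            "intron_id": "",
            "sno_id": "",
            "is_rrna": False,
        }

    def _ejc_crosslink(
        self,
        model: _TuModel,
        segments: list[tuple[int, int]],
        mlen: int,
        states: list[str],
    ) -> int:
        """Gaussian anchor ~25 nt upstream of spliced-exon 3' ends."""
        # junction molecule coordinates = cumulative boundary between segments
        junctions = []
        cum = 0
        for a, b in segments[:-1]:
            cum += b - a
            junctions.append(cum)  # first nt of the downstream exon
        if not junctions:
            return int(self.rng.integers(0, mlen))
        j = junctions[int(self.rng.integers(len(junctions)))]
        e3 = j - 1  # molecule coord of the upstream exon's last nt
        mu = e3 - self.config.ejc_anchor_upstream_nt
        x = int(round(self.rng.normal(mu, self.config.ejc_anchor_sd_nt)))
        return max(0, min(x, e3))

    def _intron3p_read(self, model: _TuModel) -> dict:
        """INTRON3P_LARIAT_SNORNA read placement."""
        tu = model.tu
        lt = self._transcribed_extent(tu)
        candidates = [
            k for k, (a, b) in enumerate(model.intron_offs) if b <= lt
        ]
        if not candidates:
            # TU not yet past its first intron: uniform nascent fallback
            cfg = self.config
            x = int(self.rng.integers(0, max(1, lt - 1)))
            fl = self._fraglen()
            a, b = x + 1, min(x + 1 + fl, lt)
            if b <= a:
                a, b = max(0, lt - fl), lt
                x = a - 1
            return {
                "tu_id": tu.tu_id,
                "blocks": _premrna_interval_to_blocks(tu, a, b),
                "strand": tu.strand,
                "chrom": tu.chrom,
                "mismatches": (),
                "xl_pos": tu.premrna_to_genome(x) if x >= 0 else -1,
                "frag3p_pos": tu.premrna_to_genome(b - 1),
                "splice_state": "pre-1st-step",
                "lariat_origin": "none",
                "extension_offset": None,
                "intron_id": "",
                "sno_id": "",
                "is_rrna": False,
            }
        k = candidates[int(self.rng.integers(len(candidates)))]
        iv = model.introns[k]
        i_a, i_b = model.intron_offs[k]
        dt = self._intron_dt(model, k)
        spliced = self.rng.random() < self._splice_prob(dt)

        cfg = self.config
        if spliced and k in model.sno_by_intron and (
            self.rng.random() < cfg.sno_intermediate_fraction
        ):
            return self._sno_read(model, k)

        zone_far, zone_near = cfg.intron3p_zone  # -100 .. -20 from intron end
        lo = max(i_a, i_b - zone_far)
        hi = max(lo + 1, i_b - zone_near)
        x = int(self.rng.integers(lo, hi))
        fl = self._fraglen()

        if not spliced:
            # contiguous pre-mRNA read; may run past the 3'SS
            a, b = x + 1, min(x + 1 + fl, lt)
            return self._simple_intron_dict(
                model, k, a, b, x, "pre-1st-step", "none", ()
            )

        lariat = self.rng.random() < cfg.lariat_fraction
        if lariat:
            circular = self.rng.random() < cfg.circular_origin_fraction
            bp_off = model.bp_offs[k]
            start_off = bp_off if circular else bp_off + 1
            end_off = i_b  # fragment 3' terminus is the intron's last nt + 1
            mism: tuple[tuple[int, str], ...] = ()
            if circular:
                g = tu.premrna_to_genome(bp_off)
                mism = ((g, _BASES[int(self.rng.integers(4))]),)
            return self._simple_intron_dict(
                model, k, start_off, end_off, start_off - 1,
                "post-2nd-step", "circular" if circular else "linear", mism,
            )
        # debranched excised intron: read clamped inside the intron
        a, b = x + 1, min(x + 1 + fl, i_b)
        if b <= a:
            a, b = max(i_a, i_b - fl), i_b
            x = a - 1
        return self._simple_intron_dict(
            model, k, a, b, x, "debranched", "none", ()
        )

    def _simple_intron_dict(
        self, model, k, a, b, x, state, origin, mismatches
    ) -> dict:
        tu = model.tu
        return {
            "tu_id": tu.tu_id,
            "blocks": _premrna_interval_to_blocks(tu, a, b),
            "strand": tu.strand,
            "chrom": tu.chrom,
            "mismatches": mismatches,
            "xl_pos": tu.premrna_to_genome(x) if x >= 0 else -1,
            "frag3p_pos": tu.premrna_to_genome(b - 1),
            "splice_state": state,
            "lariat_origin": origin,
            "extension_offset": None,
            "intron_id": model.introns[k].intron_id,
            "sno_id": "",
            "is_rrna": False,
        }

    def _sno_read(self, model: _TuModel, k: int) -> dict:
        """3'-extended pre-snoRNA intermediate."""
        cfg = self.config
        tu = model.tu
        sno = model.sno_by_intron[k]
        sno3p = model.sno_3p_offs[k]
        if sno.sno_class == "HACA":
            offs = cfg.haca_extension_offsets
            offset = int(offs[int(self.rng.integers(len(offs)))])
        else:
            offset = int(self.rng.integers(1, cfg.cd_extension_max + 1))
        end_off = sno3p + offset + 1  # fragment covers ..= sno3p+offset
        fl = self._fraglen()
        a = max(model.intron_offs[k][0], end_off - fl)
        x = a - 1
        d = self._simple_intron_dict(
            model, k, a, end_off, x, "post-2nd-step", "none", ()
        )
        d["sno_id"] = sno.sno_id
        d["extension_offset"] = offset
        return d

    # -- library assembly ----------------------------------------------------

    def generate(self, lib_prefix: str, barcode: str) -> tuple[list[AlignedPair], list[dict]]:
        cfg = self.config
        pairs: list[AlignedPair] = []
        records: list[dict] = []
        uniques: list[int] = []  # indices into pairs usable as dup templates
        fm = cfg.factor_model
        umi_codes = self.rng.integers(
            0, 4, size=(cfg.reads_per_library, cfg.umi_length)
        )
        for i in range(cfg.reads_per_library):
            name = f"{lib_prefix}_{i:06d}"
            if uniques and self.rng.random() < cfg.pcr_dup_rate:
                src = pairs[uniques[int(self.rng.integers(len(uniques)))]]
                dup = AlignedPair(
                    name=name,
                    umi=src.umi,
                    barcode=barcode,
                    chrom=src.chrom,
                    strand=src.strand,
                    read1_blocks=src.read1_blocks,
                    read2_blocks=src.read2_blocks,
                    mismatches=src.mismatches,
                    tlen=src.tlen,
                )
                pairs.append(dup)
                rec = dict(self._last_rec_by_name[src.name])
                rec["name"] = name
                rec["is_pcr_duplicate"] = True
                records.append(rec)
                continue
            if self.rrna_units and self.rng.random() < cfg.rrna_fraction:
                d = self._rrna_read()
            else:
                model = self.models[
                    int(
                        np.searchsorted(
                            self._cum_weights, self.rng.random(), side="right"
                        )
                    )
                ]
                if fm == "INTRON3P_LARIAT_SNORNA":
                    d = self._intron3p_read(model)
                else:
                    d = self._nascent_read(model)
            umi = "".join(_BASES[b] for b in umi_codes[i])
            span = d["blocks"][-1][1] - d["blocks"][0][0]
            pair = AlignedPair(
                name=name,
                umi=umi,
                barcode=barcode,
                chrom=d["chrom"],
                strand=d["strand"],
                read1_blocks=d["blocks"],
                read2_blocks=d["blocks"],
                mismatches=d["mismatches"],
                tlen=span,
            )
            pairs.append(pair)
            uniques.append(len(pairs) - 1)
            rec = {
                "name": name,
                "is_pcr_duplicate": False,
                **{
                    key: d[key]
                    for key in (
                        "tu_id", "intron_id", "sno_id", "xl_pos",
                        "frag3p_pos", "splice_state", "lariat_origin",
                        "extension_offset", "is_rrna",
                    )
                },
                "xl_chrom": d["chrom"],
                "xl_strand": d["strand"],
            }
            records.append(rec)
            self._last_rec_by_name[name] = rec
        return pairs, records


def simulate_timecourse(
    annotation: AnnotationBundle, config: SimConfig
) -> tuple[dict[tuple[str, str], list[AlignedPair]], pd.DataFrame]:
    """Simulate one library per (timepoint, replicate) plus ground truth.

    Returns ``(libraries, ground_truth)`` where ``libraries`` maps
    ``(timepoint_label, replicate_label)`` to its AlignedPairs (exactly
    ``reads_per_library`` each, PCR duplicates included) and
    ``ground_truth`` is a DataFrame with one row per emitted read.
    """
    if not annotation.tus:
        raise ValueError("empty annotation")
    models = _build_models(annotation)
    if not models:
        raise ValueError("annotation contains no non-rRNA transcription units")

    libraries: dict[tuple[str, str], list[AlignedPair]] = {}
    all_records: list[dict] = []
    lib_idx = 0
    for tp_label, minutes in config.timepoints.items():
        for rep in range(config.n_replicates):
            rep_label = f"rep{rep + 1}"
            rng = np.random.default_rng([config.seed, 0xB1, lib_idx])
            sim = _LibrarySim(annotation, models, config, minutes, rng)
            barcode = config.barcodes[lib_idx % len(config.barcodes)]
            pairs, records = sim.generate(f"L{lib_idx}", barcode)
            for r in records:
                r["timepoint"] = tp_label
                r["replicate"] = rep_label
                r["barcode"] = barcode
            libraries[(tp_label, rep_label)] = pairs
            all_records.extend(records)
            lib_idx += 1

    gt = pd.DataFrame(all_records)
    return libraries, gt
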