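import numpy as np
import pytest

from ticlip.core import (
    AlignedPair,
    AnnotationBundle,
    SiteTrack,
    SnoRNAAnnotation,
    TranscriptionUnit,
    derive_introns,
)
from ticlip.reads import deduplicate
from ticlip.simulate import SimConfig, make_annotation, simulate_timecourse

SHORT_TIMEPOINTS = {"t00": 0.0, "t15": 15.0, "t30": 30.0, "t60": 60.0, "DMSO": float("inf")}


def make_pair(
    name="r0",
    umi="AAAA",
    barcode="AACCG",
    chrom="c1",
    strand="+",
    r1=((100, 130),),
    r2=None,
    mismatches=(),
    tlen=0,
):
    r1 = tuple(r1)
    r2 = tuple(r2) if r2 is not None else r1
    if tlen == 0:
        tlen = max(r1[-1][1], r2[-1][1]) - min(r1[0][0], r2[0][0])
    return AlignedPair(
        name=name, umi=umi, barcode=barcode, chrom=chrom, strand=strand,
        read1_blocks=r1, read2_blocks=r2, mismatches=tuple(mismatches),
        tlen=tlen,
    )


@pytest.fixture(scope="session")
def tiny_bundle():
    """Two hand-built TUs (one per strand) with a branchpoint and a snoRNA."""
    tu_plus = TranscriptionUnit(
        tu_id="TUP", chrom="c1", start=0, end=1000, strand="+",
        exons=((0, 100), (600, 1000)),
    )
    tu_minus = TranscriptionUnit(
        tu_id="TUM", chrom="c1", start=2000, end=3000, strand="-",
        exons=((2000, 2400), (2900, 3000)),
    )
    introns = {}
    for tu in (tu_plus, tu_minus):
        for iv in derive_introns(tu):
            introns[iv.intron_id] = iv
    # BP 20 nt upstream of the 3'SS in each intron
    introns["TUP.i0"].bp_pos = 600 - 20     # intron [100, 600), + strand
    introns["TUM.i0"].bp_pos = 2400 + 19    # intron [2400, 2900), - strand
    snornas = {
        "SNOX": SnoRNAAnnotation(
            sno_id="SNOX", chrom="c1", start=200, end=300, strand="+",
            sno_class="HACA", host_intron_id="TUP.i0",
        )
    }
    return AnnotationBundle(
        tus={"TUP": tu_plus, "TUM": tu_minus},
        introns=introns,
        snornas=snornas,
        chrom_sizes={"c1": 4000},
    )


@pytest.fixture(scope="session")
def intron_sim():
    """Moderate INTRON3P_LARIAT_SNORNA time course with ground truth."""
    cfg = SimConfig(
        seed=11,
        reads_per_library=8000,
        factor_model="INTRON3P_LARIAT_SNORNA",
        lariat_fraction=0.5,
        circular_origin_fraction=0.5,
        timepoints=dict(SHORT_TIMEPOINTS),
        n_replicates=1,
    )
    annotation = make_annotation(40, 11, cfg)
    libraries, gt = simulate_timecourse(annotation, cfg)
    return cfg, annotation, libraries, gt


@pytest.fixture(scope="session")
def intron_sim_pairs(intron_sim):
    """All deduplicated pairs pooled across the intron simulation."""
    _cfg, _ann, libraries, _gt = intron_sim
    return [p for pairs in libraries.values() for p in deduplicate(pairs)]


def pool_tracks(tracks):
    pooled = SiteTrack()
    for t in tracks:
        for (c, s, pos), w in t.entries.items():
            pooled.add(c, s, pos, w)
    return pooled
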