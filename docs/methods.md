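# Methods

This note documents the models and conventions implemented in `ticlip`, the
parameters that matter, what the synthetic data generator does and does not
emulate, and the numerical choices made where the design was genuinely
open.

## Coordinate and read conventions

All genomic coordinates are 0-based half-open; strand is mandatory (`+` or
`-`) because every computation is strand-aware. Reads follow the FR paired
layout: read1 carries the RNA strand, read2 its reverse complement. Three
single-nucleotide deconstructions of a pair are supported:

- **cross-link site** — one nt upstream, in transcript orientation, of
  read1's first sequenced base. iCLIP cDNAs truncate at the cross-linked
  peptide, so the contact is the nucleotide immediately 5' of the cDNA
  end. Sites that would fall before position 0 are dropped and counted
  (clamping would fabricate a position-0 peak).
- **3'CLIP site** — the fragment's 3' terminus, taken as read2's first
  sequenced base (read2 is primed from the adapter ligated to the RNA 3'
  end) and reported on the RNA strand. An alternative
  `convention="coordinate_last"` takes read2's highest genomic coordinate
  instead; the two differ for minus-strand fragments, and the
  fragment-terminus reading is the default because 3'CLIP is used to read
  the 3' ends of processing intermediates.
- **whole-read coverage** — unit weight at every read1-aligned position;
  block gaps (spliced-out segments) contribute nothing.

Raw (unshifted) read1 5' ends are used for cDNA-truncation analysis only:
truncation products end *at* the blocking structure, so the 1 nt cross-link
shift would displace the diagnostic branchpoint peaks from offsets 0/+1 to
-1/0.

Demultiplexing assigns pairs by in-line barcode within a configurable
Hamming distance (default 0); two table barcodes within twice that distance
are rejected as a configuration error. Deduplication keys on (UMI, chrom,
read1 5' coordinate, strand), keeps the first-encountered pair, and is
idempotent. This treats two distinct molecules that happen to share a UMI
and 5' coordinate as duplicates — the same in-principle limit any
UMI-based scheme has.

## Library normalization

Library depth is normalized by an rRNA factor: the count of deduplicated
pairs whose read1 overlaps (>=1 nt, strand-aware) any rRNA gene, divided by
30,000 (an arbitrary divisor that keeps factors near unity for typical
depths). Track weights are **divided** by the factor, scaling libraries
with more rRNA recovery down; read-per-million scaling is deliberately
avoided because CLIP timepoints recover very different amounts of RNA while
rRNA recovery is expected constant. A `multiply` direction is provided for
compatibility with multiplicative scale options. A library with zero rRNA
reads cannot be normalized and is an error, not a silent factor of 0.

## Spatiotemporal heatmaps and wave velocity

TUs are stratified by length in 10 kb increments (0-10 through 290-300 kb,
plus one >=300 kb group) and segmented into 1 kb bins from TSS to TES.
Per group, the mean binned signal across members (TES-truncated: a TU only
contributes to bins it spans) is divided by the group maximum, giving
values in [0, 1] with at least one bin at 1.

The elongation-wave velocity is estimated from per-timepoint heatmaps.
Per group, bins whose 3-bin moving-average falls below `tau = 0.1` of the
group maximum are masked as background; the group's **front** is the bin by
which 99% of the remaining signal mass has accumulated. A single-threshold
"last bin above tau" front was tried first and proved fragile: in sparsely
covered long-gene groups, chance zero-runs fire it well short of the true
front. The cumulative-mass front is robust to such gaps while the tau mask
still suppresses diffuse background. Groups whose front comes within
13 bins of their own end (the 10-bin stratum width plus the smoothing
window) are excluded as TES-saturated — their front measures gene length,
not the wave. The per-timepoint front is the median over usable groups,
and the velocity is the OLS slope of front (kb) versus minutes after
release, using release timepoints only: the blocked sample (t = 0) and the
unsynchronised steady state carry no wave information. On simulated data
this recovers velocities of 1.5-5 kb/min within ~1%; the estimate is
reported with its intercept (which absorbs the pause-region offset and
front-quantile bias) and R².

## Mature profiles, clustering, junction density

Mature profiles project exonic cross-link positions onto exon-concatenated
coordinates, bin them into 100 equal bins (position p maps to
floor(p x 100 / mature length), last position clamped to bin 99) and divide
by the TU total, so retained profiles sum to 1. TUs with mature length
<= 200 nt or <= 20 mapped reads are excluded — strict inequalities — with a
machine-readable reason rather than an error.

Clustering runs k-means (k = 3, Euclidean distance on raw 100-dim profiles,
10 restarts, fixed seed) independently per biological replicate, matches
clusters across replicates by greedy maximal centroid cosine similarity,
and keeps a TU only if it lands in matched clusters in every replicate.
The largest intersected cluster is treated as unstructured background and
not reported (set `report_background=True` to include it); reported groups
are labelled group1, group2, ... ordered by the bin of their
reference-replicate centroid maximum, 5'-most first, which makes labels
deterministic. Junction-density profiles bin exon-exon junction positions
in mature coordinates, normalize per TU by junction count (mono-exonic TUs
contribute zeros) and average over the group.

## Branchpoint truncation and mismatch profiles

Branchpoints (BPs) are annotation inputs; records with BP-to-3'SS distances
of 18-38 nt (distance 1 = BP is the last intronic nt) enter the stratified
101 nt window heatmap, one row per distance, signal strand-oriented with
the BP at offset 0. With a 3'CLIP track, the row maximum tracks the
intron's last nucleotide along the diagonal offset = distance - 1.

Truncation signatures aggregate raw read1 5' ends around BPs, intron 5'
ends and exon 3' ends; peaks are offsets exceeding the window mean + 3 SD
(a deliberately conservative call for sharp truncation spikes). The
circular-origin fraction is estimated as mass(offset 0) / (mass(0) +
mass(+1)). Mismatch profiles count, per offset in a 21 nt window, read 5'
ends and the subset whose first base is mismatched; offsets with no 5' ends
report NaN (undefined), never 0.

## snoRNA 3'-extensions

Per-class (CD / H/ACA) aggregates are taken over 101 nt windows centred on
snoRNA 3' ends or on the host intron's 3'SS, normalized by the number of
contributing snoRNAs (per-snoRNA-count normalization; a global
normalization would let a few deep snoRNAs dominate the class profile).
Extension peaks are local maxima in the +1..+35 nt flank exceeding the
range mean + 2 SD — a laxer threshold than the 3 SD truncation call because
extension peaks sit on an elevated flank baseline — and the maximum
extension is the largest offset with signal above 10% of the range maximum.
Top-N heatmaps rank snoRNAs by cumulative 3'CLIP signal in the 35 nt flank,
ties broken lexicographically by id for determinism.

## The synthetic time course

The generator is the package's verification instrument: it emits the exact
latent structure the analysis assumes, plus one ground-truth record per
read.

**Annotation.** TU lengths are log-uniform over 0.6-320 kb (covering every
10 kb stratum including >=300 kb), ~25% mono-exonic, exon/intron
alternation with 150-400 nt first exons, 80-250 nt internal exons and
0.15-8 kb introns. Every intron gets a BP uniformly 18-38 nt upstream of
its 3'SS. Introns >=400 nt host a snoRNA with probability 0.15 (CD or
H/ACA, equal odds; 60-130 nt body) placed with a >=140 nt 3' flank so the
35 nt extension window stays clear of the intron-3' anchoring zone.
Dedicated rRNA units (default 4, 2-6 kb) live on their own chromosome.

**Kinetics.** At t minutes after release, transcription extends
min(TU length, 300 nt pause offset + velocity x t) from the TSS (velocity
default 3.5 kb/min; the 300 nt pause offset represents cap-proximal RNA
made during the block). Each fully transcribed intron is spliced with
probability 1 - 2^(-dt / halflife) (halflife 4 min), where dt is the time
since its 3' end was transcribed; a spliced intron is still in the
post-1st-step state with probability 2^(-dt / 5 min), which truncates the
cap-anchored molecule at the upstream exon 3' end (free exon end, not yet
ligated) and produces the transient first-exon-end 3'CLIP signal that
rises and falls across the course. Post-2nd-step introns persist as
lariats with probability `lariat_fraction`, else they are debranched. The
steady-state (DMSO) label sets t = infinity: everything at equilibrium.

**Anchoring models.** One per simulated factor class: `CAP_ANCHORED`
(exponential from the 5' end, 50 nt scale), `EXON3P_EJC` (Gaussian 25 nt
upstream of spliced-exon 3' ends, sigma 8 nt), `INTRON3P_LARIAT_SNORNA`
(uniform over the intron's last 100 nt minus the 3'-terminal 19 nt — the
mapping shadow of fragments under the ~20 nt limit), and `UNIFORM_NASCENT`
(uniform over unspliced nascent sequence). Lariat reads truncate at the
BP: circular-origin 5' ends sit on the BP with one mismatched terminal
base (reverse transcription incorporates an untemplated nucleotide against
the 2'-5' linkage); linear-origin 5' ends sit 1 nt downstream, mismatch
free; both terminate at the intron's last nucleotide. snoRNA-host introns
emit 3'-extended precursor intermediates whose termini are exactly the
snoRNA 3' end + 9 or 25 nt (H/ACA, equal odds) or + uniform 1-25 nt (CD).

**Library structure.** Fragments are 25-75 nt; mates fully overlap (short
CLIP inserts sequenced from both ends), so |TLEN| equals the genomic
fragment span. Each library carries its barcode in read names
(`name#BARCODE#UMI`), 8 nt UMIs, a 10% PCR duplication rate (duplicates
copy UMI and coordinates under a new name), and 5% rRNA background. Every
library contains exactly `reads_per_library` reads, duplicates included.
All randomness flows from one seed; identical (annotation, config) gives
byte-identical output.

**What is not emulated**: base composition and sequence motifs (reads
carry no sequence; mismatches are coordinate-level annotations in a SAM
tag), RNA secondary structure, mapping ambiguity/multimappers, soft
clipping, the 1-2 nt upstream shifts of real BP truncation points, or
cross-link-site sequence bias. Passing tests therefore demonstrate that
the analysis recovers the planted coordinate-level structure, not that it
is robust to alignment artefacts of real libraries.

## QC calculators

The co-migration rule converts a gel migration gap (kDa) into the minimum
cross-linked RNA length using 70 nt per 20 kDa, taking the ceiling (227.5
retarding nucleotides means 228 whole nt) and subtracting the 29 nt
adapter for the RNA-only figure. Median insert sizes use |TLEN| with zeros
excluded; an even count takes the mean of the two middle values; empty
libraries report a missing value.

## Problem sizes

The test suite and `scripts/acceptance.py` use desk-scale simulations
chosen to make every statistical check well-powered while keeping runs
fast: 200 TUs x 8 timepoints x 10,000 reads/library for wave-velocity
recovery, 40 TUs x 8,000 reads/library for branchpoint and snoRNA
signatures (several thousand lariat reads, ~50 snoRNAs), 200 planted
profiles plus background for clustering. The full suite runs in under a
minute on one core.

## Known limitations

- Overlapping TUs on the same chromosome and strand are resolved
  left-most-first in position-to-TU lookups; the simulator never generates
  overlaps, but dense real annotations should be flattened upstream.
- The wave estimator assumes the binding front is coverage-limited, not
  affinity-limited; a factor whose binding saturates behind the polymerase
  (e.g. strictly cap-anchored) yields a stationary front and a slope near
  zero by design.
- The circular-origin estimator ignores truncation shifts; on real data,
  where truncation points shift 1-2 nt upstream, the 0/+1 mass split will
  blur and the estimate becomes a lower bound on resolvable asymmetry.
- `read_alignments` holds a library in memory; libraries of tens of
  millions of pairs should be processed per chromosome.
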