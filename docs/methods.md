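# Methods

This note documents the models and procedural choices behind `ribarch`:
what each stage assumes, which parameters matter, what the synthetic-data
generator does and does not emulate, and where the design was genuinely
open.

## Coordinates and tracks

All public coordinates are 1-based inclusive on the forward strand.
bedGraph I/O uses the format's native 0-based half-open dialect and GFF3
its 1-based inclusive one; overlapping bedGraph intervals sum, so
write∘read is the identity on any track.  Tracks are per-strand
non-negative real arrays over the genome; three flavours are used:
center-weighted ribosome-footprint density (`ribo`), RNA-seq coverage
(`rna_cov`) and RNA-seq 5′-nucleotide counts (`rna_5p`).  Chromosomes are
circular by default; sequence fetches wrap modulo the length.

Center-weighting distributes each footprint's read count uniformly over
its interval after trimming a flank from both ends, suppressing the
nuclease-determined fragment ends.  The flank default is 11 nt per side
(configurable): for the 20–40-nt footprints typical of bacterial
ribosome profiling this leaves the central core of the fragment, and
reads shorter than 2·flank+1 keep their whole weight at their central
nucleotide (policy `center`, default) or are dropped.  Mass is conserved
exactly under the default policy.

## Anti-SD annealing energy

The Shine-Dalgarno score of a sequence window is the minimum annealing
free energy between the window and the anti-SD 5′-CACCUCCU-3′ over every
contiguous antiparallel helix: Watson–Crick plus G:U wobble pairs,
published Turner ΔG°37 RNA/RNA nearest-neighbor stacking parameters,
bimolecular initiation +4.10 kcal/mol, +0.50 kcal/mol per terminal AU/GU
pair, minimum helix 3 bp, no bulges, internal loops or dangling ends.
Positive optima are clamped to 0 ("no duplex").  DNA input is
transcribed T→U.  The implementation scans each alignment offset in
linear time with a prefix-sum running minimum; the test suite checks it
against a brute-force enumeration of every (offset, helix start, helix
length) placement for all 65,536 possible 8-mer windows.

A start codon is SD-led when the minimum ΔG° within the initiation
window is strictly below −4.4 kcal/mol.  Two readings of "a window
between −20 and −5 nt upstream" are implemented: the default anchors the
8-mer's 5′-most nucleotide anywhere in [−20, −5] (16 offsets; random
background sequences are therefore 23-mers), the alternative
(`window_mode="duplex_inside"`) requires the whole 8-mer inside the
window (9 offsets, 16-mers).  The default was selected by the Monte-Carlo
calibration the model is built around: at per-base GC 0.6717 the
5′-anchored convention yields 19.2% SD-positive random sequences with the
unmodified published energy parameters, whereas the fully-inside reading
yields ~12.8%.  Given a 5′ UTR length, windows upstream of the transcript
5′ end are excluded, so a leaderless start can never be SD-led.

Hexamer analysis counts all 4096 hexamers over CDS sense strands
(including zero counts, so depletion is expressible), normalizes by total
windows and by the expectation under the genome's mononucleotide
composition, and attaches each hexamer's annealing ΔG.

## Start-codon calling

Start calling is stop-anchored: the stop codon and frame of an existing
annotation are taken as reliable and the start is re-derived from the
footprint data.  Walking upstream in-frame from the stop (bounded by the
previous in-frame stop, by the 3′ end of the nearest upstream same-strand
feature, and by a 1000-codon cap), a candidate codon qualifies when:

1. **density** — mean footprint density over the 15 nt downstream exceeds
   `min_density_ratio` (default 1/20) of the gene-body mean, where the
   body mean is computed over covered positions between candidate and
   stop;
2. **continuity** — no internal zero-coverage run between candidate and
   stop exceeds `gap_tol` (default 30 nt);
3. **onset** — the first covered nucleotide lies within `onset_tol`
   (default 2 nt) of the candidate, **or** a TSS coincides with the
   candidate and coverage begins 6–20 nt downstream (the leaderless
   signature: footprints of 5′-loaded ribosomes are short, so
   center-weighted density starts 12–18 nt into the CDS).

The onset condition is the load-bearing one on GC-rich genomes: a
forward-window density test alone is satisfied by chance in-frame
near-cognate codons a few codons upstream of the true start (their
windows overlap the CDS), which would cap exact-nucleotide recovery near
85%.  Requiring density to begin at the candidate — which is how
footprint data actually behave at real starts — removes that failure
mode.  The most upstream qualifying candidate wins, with one exception: a
TSS-rescued (leaderless) candidate is overruled when a plainly qualifying
candidate sits exactly at the coverage onset the rescue points to, since
ordinary leadered initiation there explains the same data without
invoking the rarer mechanism.  This resolves, in favour of the leadered
reading, the genuinely ambiguous case of a frame-aligned 12–18-nt 5′ UTR
whose TSS lands on a codon from the start set; the cost is that a true
leaderless mRNA with a chance start codon at its footprint onset is
called 4–6 codons short (a few percent of leaderless genes; leaderless
*precision* is unaffected).

Candidate tiers follow the evidence hierarchy: ATG/GTG/TTG/CTG
unconditionally; single 2nd/3rd-position mismatches of ATG (AAG, ACG,
AGG, ATA, ATC, ATT) and then arbitrary double mismatches only at codons
anchored by an N-terminal tryptic peptide (> 20 aa, preceding residue not
Lys/Arg; a peptide at codon 1 preceded by Met anchors codon 0 as an
fMet-cleaved start).

New CDSs are sought in annotation-free footprint blocks (internal gaps ≤
`gap_tol` bridged): the block is matched to the start→stop ORF on its
strand that best explains it, and accepted only when ≥ 90% of the block's
mass lies inside the ORF, the block covers ≥ 50% of the ORF, the ORF
overlaps existing annotation < 20%, and the ORF is ≥ 10 codons.  Density
running across a stop codon into another frame therefore disqualifies a
block.  Records are pruned before mapping: a CDS whose antisense
footprint mass exceeds its sense mass is strand-corrected, and a
hypothetical CDS overlapping an opposite-strand CDS or tRNA by > 50% of
the shorter feature is deleted.

## Transcripts, UTRs, ncRNAs

Transcript units are covered blocks (coverage > 1 read/nt, internal gaps
≤ 20 nt bridged) of ≥ 50 nt averaging ≥ 5 reads/nt — the expression
floor is a deliberate conservative default since no principled universal
threshold exists.  The 5′ end is the TSS when one lies within 3 nt of the
block's upstream edge (TSS beats a 5′-end peak when both exist);
otherwise a position near the edge where the 5′-nucleotide track exceeds
5× the block's mean 5′-end rate; otherwise the block edge, labelled
`estimated`.  The 3′ end is the last position holding ≥ 10% of the body
mean — a deterministic stand-in for changepoint detection on the 3′
drop.

5′ UTR length is the distance from the transcript 5′ end to the start
codon for transcript-initial CDSs, valid up to 300 nt (longer spans are
flagged for manual review); operon-internal CDSs take an internal TSS
within min(300 nt, 30% into the upstream CDS plus the gap) when one
exists.  Leaderless CDSs have UTR 0 by definition.

A CDS-free transcript is non-coding when its footprint density stays
below 10% of its expected translated level — its RNA coverage scaled by
the global footprint-to-RNA mass ratio of coding transcripts — and is
labelled antisense when ≥ 50% of its length lies opposite a CDS.  The
TSS metagene averages per-window-normalized 5′-end profiles (each window
normalized to sum 1, so the average sums to 1).

## Operons

Same-strand CDS runs merge when overlapping or separated by < 40 nt;
gaps in [40, 260) merge only when a single mapped transcript covers both
CDSs and carry a review flag (the mechanized form of manual inspection);
gaps ≥ 260 nt never merge.  Junction splitting requires all three of:
intergenic gap > 40 nt, > 20 reads/nt, and > 10-fold CDS-to-intergenic
RNA coverage ratio (all strict).  The coverage criterion is attached to
the flanking CDS bodies (both must exceed 20 reads/nt) — the published
wording leaves the referent ambiguous and the CDS-body reading makes the
criterion independent of the fold criterion; the ratio uses the upstream
CDS body mean over the intergenic mean.  Splitting is idempotent.
Operon statistics report the size distribution, TSSs per operon (inside
the span or within 300 nt upstream of the 5′ end), polarity junctions
(≥ 5-fold RNA step-down between consecutive members), and an isoform
estimate of 1 + internal TSSs + polarity junctions.

## Expression and translation efficiency

RPKM is reads per kilobase of (trimmed) CDS per million mapped reads,
with the library size defaulting to the track's total mass.  Footprint
RPKM excludes the first 10 and last 5 codons, where initiating and
terminating ribosomes accumulate independently of elongation flux; RNA
RPKM is untrimmed by default (a flag trims it identically — whether the
published analysis trimmed the RNA channel is not stated).  TE is
footprint-RPKM / RNA-RPKM, undefined (NaN, flagged) at zero RNA.
Differential translation between two conditions requires ≥ 30 reads in
each assay of each sample and a strictly > 2-fold TE change in either
direction; the read filter is applied per assay per sample, the stricter
of the readings the published wording admits.

## Pausing and the SD cross-correlation

Occupancy profiles divide footprint density by the gene mean over the
trimmed CDS (same 10/5-codon trimming), so profiles average to 1 and
pauses appear as peaks.  Genes qualify at > 10 reads/codon; the
cross-correlation additionally requires > 160 nt.  The center-weighted
position is treated as the A-site (offset 0, configurable).  Internal SD
affinity tracks assign max(0, −ΔG) of each 8-mer to the window's 3′-most
nucleotide, the mRNA position nearest the ribosome when the element
engages the aSD; a binary mode (ΔG < −4.4) exists for thresholded
analyses.  For each qualifying gene both series are z-scored and
ccf(lag) = mean over positions of z_occ[p]·z_sd[p−lag]; per-gene
functions are averaged (per-gene normalization, then averaging, was
chosen over global normalization so long genes do not dominate).  A pause
d nt downstream of SD 3′ ends peaks at lag +d.  The affinity-occupancy
scatter pairs each internal SD site with the occupancy a fixed offset
downstream (default 11 nt) and reports raw and binned Pearson r.  Raw
Pearson r saturates for strong multiplicative pauses, so tests assert
departure from the null rather than monotonicity in the pause strength.

## The synthetic-data generator

`simulate_genome` plants operons (sizes 1–5, P = .55/.20/.12/.08/.05) on
an i.i.d. GC-weighted background at GC 0.6717, with start-codon usage
74.3/14.5/10.3/0.7% (ATG/GTG/TTG/CTG), uniform stop-codon choice, CDS
lengths log-normal around 140 codons (clipped 40–600), 9.6% leaderless
transcripts, 5′ UTRs with 57% of mass in 15–60 nt and a tail beyond
100 nt, 3′ UTRs uniform 20–80 nt, intra-operon gaps mostly 3–35 nt (12%
in 60–200 nt to exercise the review-merge path), inter-operon gaps
300–700 nt, 5% small ORFs (12–35 codons) left out of the input
annotation, and ~30 ncRNAs (80–300 nt, 20% antisense).  Expression is
log-normal with median 10 reads/nt (σ = 0.5 in log space) — roughly 30
reads/codon on the footprint track for a median gene, comparable to a
well-sequenced bacterial profiling library — with per-gene ribosome
loading scattered log-normally (σ = 0.25) around the RNA level.

Per-nucleotide counts are negative-binomial with dispersion 0.3
(variance = m + 0.3 m²), the standard overdispersed count model;
dispersion 0 switches to noise-free means for deterministic tests.
Footprint profiles carry 5× start and 2× stop peaks over the terminal
9 nt; leaderless genes have zero footprint density over their first
12–18 nt (uniform).  Internal SD-like sites (ΔG < −4.4, local minimum
within ±4 nt) receive a pause of strength exp(−β·ΔG) at 11 nt downstream
of the site's 3′ end (β = 0.3 per kcal/mol — an invented but monotone
link sufficient to test recovery).  RNA coverage is piecewise-constant
per transcript with 10⁻¹-scale polarity step-downs (factor 8 by default,
in 15% of multi-CDS operons) and internal-TSS step-ups (factor 2, 15%);
the 5′-end channel has a shear background of 0.02 ends per covered
nucleotide and TSS spikes bringing the rate at the TSS to 8× the body
5′-end rate (jitter 0, matching single-nucleotide 5′-RACE-style
evidence).  Proteins are cleaved after every Lys/Arg, fragments ≥ 6 aa
are detected independently at p = 0.3, the initiator Met is removed with
p = 0.5, and ~3% of genes carry a peptide-evidenced internal ATG start.
The input annotation is perturbed realistically: 15% of starts shifted in
frame, four records strand-flipped, five spurious antisense
hypotheticals added.

What the generator does **not** emulate: sequence-dependent library
biases (ligation/PCR), rRNA contamination, codon-specific dwell times,
transcription-translation coupling, condition-dependent regulation, TSS
jitter (available but off by default), and footprint-length variation
(tracks are already center-weighted densities).  Passing recovery tests
therefore demonstrates the correctness and calibration of the inference
rules under the stated statistical assumptions, not robustness to every
artefact of real libraries.

## Problem sizes and numerics

The default verification bundle plants 500 genes (~390 kb genome); the
test suite uses 150-gene bundles for integration tests and noise-free
40–60-gene bundles for closed-form checks, sizes chosen to exercise every
code path with comfortable statistics.  The Monte-Carlo SD background
uses 10,000 draws (binomial standard error ~0.4 pp).  Energy evaluations
are cached per 8-mer; all randomness flows from a single master seed via
spawned child seeds, and equality tolerances on floats are 1e-9 except
where a test asserts exact conservation.

## Known limitations

* Start calls inside regions where an upstream same-strand gene's ORF
  extends across a short intergenic gap rely on the upstream feature's
  annotated 3′ end being correct.
* The 40–260-nt review band is resolved by transcript coverage alone;
  genuinely ambiguous junctions are only flagged, not adjudicated.
* The SD energy model is deliberately minimal (no bulges or loops); its
  absolute ΔG values differ from full hybridization models, which is why
  the −4.4 kcal/mol cutoff is always paired with the same model that
  calibrated it.
* `differential_translation` implements the fold-change rule only; no
  significance testing is layered on top.
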