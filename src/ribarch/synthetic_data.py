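"""Synthetic genomes with planted coding/noncoding architecture.

Generates a GC-rich bacterial chromosome with planted operons, leaderless
mRNAs, small ORFs and ncRNAs, then simulates the four evidence channels the
analysis consumes — center-weighted ribosome-footprint density, RNA-seq
coverage, RNA-seq 5'-end counts with TSS spikes, and stochastically
detected tryptic peptides — with known ground truth for every stage.

The statistical structure mirrors what the analysis assumes about real
data: log-normal gene expression, negative-binomial per-nucleotide count
noise, ribosome-density peaks at start and (smaller) stop codons,
elongation pauses downstream of internal SD-like sites with strength
exp(-beta * dG), leaderless mRNAs whose footprint density begins 12-18 nt
into the CDS, polarity step-downs and internal-TSS step-ups within
operons, and trypsin cleavage after Lys/Arg with independent peptide
detection.  Everything is deterministic given the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .core_io import (
    AnnotationRecord,
    DensityTrack,
    Genome,
    Peptide,
    TSSRecord,
    revcomp,
    write_annotation,
    write_track,
)
from . import sd_energy

__all__ = [
    "SimulationConfig",
    "PlantedGene",
    "PlantedTranscript",
    "PlantedNcRNA",
    "PauseSite",
    "Truth",
    "Bundle",
    "simulate_genome",
    "simulate_ribo_track",
    "simulate_rna_tracks",
    "simulate_peptides",
    "simulate_bundle",
    "make_input_annotation",
    "write_bundle",
]

_STOPS = ("TAA", "TAG", "TGA")

_CODON_TABLE = {}  # filled lazily from Bio.Data below


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the generator.

    Defaults encode the architecture statistics of a *Caulobacter*-like
    genome: GC 67.17%, start-codon usage 74.3/14.5/10.3/0.7% for
    ATG/GTG/TTG/CTG, 9.6% leaderless transcripts, and 5' UTRs with 57% of
    their mass between 15 and 60 nt and a tail beyond 100 nt.  Expression
    is log-normal with a median of 10 RNA reads/nt (30 reads/codon on the
    footprint track for an average gene), overdispersed per nucleotide
    with a negative-binomial dispersion of 0.3.
    """

    genome_length: int | None = None  # None: sized to fit the planted genes
    gc: float = 0.6717
    n_genes: int = 500
    # P(operon has 1, 2, ... CDSs)
    operon_size_probs: tuple = (0.55, 0.20, 0.12, 0.08, 0.05)
    start_codon_mix: tuple = (
        ("ATG", 0.743), ("GTG", 0.145), ("TTG", 0.103), ("CTG", 0.007),
    )
    leaderless_fraction: float = 0.096  # per transcript
    small_orf_fraction: float = 0.05  # small ORFs left out of the input annotation
    # CDS length (codons): log-normal, clipped
    cds_codons_mu: float = math.log(140.0)
    cds_codons_sigma: float = 0.45
    cds_codons_min: int = 40
    cds_codons_max: int = 600
    small_orf_codons: tuple = (12, 35)
    # expression / noise
    expression_mu: float = math.log(10.0)  # log reads/nt of RNA coverage
    expression_sigma: float = 0.5
    te_sigma: float = 0.25  # per-gene log-normal ribosome-loading scatter
    nb_dispersion: float = 0.3  # var = m + a*m^2; 0 disables sampling noise
    # footprint profile shape
    start_peak_multiplier: float = 5.0
    stop_peak_multiplier: float = 2.0
    peak_width: int = 9  # nt
    sd_pause_beta: float = 0.3  # per kcal/mol
    sd_pause_offset: int = 11  # nt from SD 3' end to the paused A-site
    leaderless_footprint_delay: tuple = (12, 18)  # uniform, inclusive
    # RNA-seq 5'-end channel
    rna5p_shear_rate: float = 0.02  # background 5' ends per covered nt
    tss_peak_multiplier: float = 8.0  # spike over the body 5'-end rate
    tss_jitter: int = 0
    # operon-level regulation
    polarity_fraction: float = 0.15  # of multi-CDS operons
    polarity_step: float = 8.0
    internal_tss_fraction: float = 0.15  # of multi-CDS operons
    internal_tss_step: float = 2.0
    # peptides
    peptide_detection_prob: float = 0.3
    fmet_cleavage_prob: float = 0.5
    peptide_min_report_aa: int = 6
    internal_start_fraction: float = 0.03
    # layout
    utr3_range: tuple = (20, 80)
    intra_operon_gap: tuple = (3, 35)
    intra_operon_long_gap: tuple = (60, 200)  # review-band gaps, same transcript
    intra_operon_long_gap_frac: float = 0.12
    inter_operon_gap: tuple = (300, 700)
    ncrna_count: int = 30
    ncrna_length: tuple = (80, 300)
    ncrna_antisense_fraction: float = 0.2
    # input-annotation perturbations
    start_misannotation_fraction: float = 0.15
    start_misannotation_codons: tuple = (1, 10)
    wrong_strand_n: int = 4
    spurious_hypothetical_n: int = 5
    te_multipliers: tuple = ()  # ((locus, factor), ...) for condition contrasts

    def __post_init__(self) -> None:
        total = sum(p for _, p in self.start_codon_mix)
        if not math.isclose(total, 1.0, abs_tol=0.01):
            raise ValueError(f"start_codon_mix sums to {total}")
        if not 0 <= self.gc <= 1:
            raise ValueError("gc must be in [0,1]")
        for name in ("leaderless_fraction", "small_orf_fraction",
                     "polarity_fraction", "internal_tss_fraction",
                     "peptide_detection_prob", "fmet_cleavage_prob"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} outside [0,1]")


@dataclass
class PlantedGene:
    locus: str
    left: int
    right: int
    strand: str
    start_codon: str
    codons: int
    operon_id: str
    transcript_id: str
    leaderless: bool = False
    leaderless_delay: int | None = None
    utr5: int | None = None  # transcript-first genes only
    rna_level: float = 0.0  # reads/nt at this gene
    ribo_rate: float = 0.0  # reads/nt footprint density
    protein: str = ""
    is_small: bool = False
    internal_start_codon: int | None = None  # 0-based codon index

    @property
    def start_pos(self) -> int:
        """Genomic position of the start codon's first nt."""
        return self.left if self.strand == "+" else self.right

    @property
    def stop_end(self) -> int:
        """Genomic position of the stop codon's last nt."""
        return self.right if self.strand == "+" else self.left

    @property
    def length(self) -> int:
        return self.right - self.left + 1


@dataclass
class PlantedTranscript:
    id: str
    left: int
    right: int
    strand: str
    tss: int
    members: list
    level: float
    internal_tss: list = field(default_factory=list)
    polarity_junctions: list = field(default_factory=list)  # member index i: drop after member i

    @property
    def five_prime(self) -> int:
        return self.left if self.strand == "+" else self.right


@dataclass
class PlantedNcRNA:
    id: str
    left: int
    right: int
    strand: str
    level: float
    kind: str  # 'intergenic' | 'antisense'
    tss: int = 0


@dataclass
class PauseSite:
    locus: str
    position: int  # genomic nt of the paused A-site
    dG: float  # annealing dG of the upstream SD-like site
    multiplier: float


@dataclass
class Truth:
    genes: list
    transcripts: list
    operons: list  # list of lists of locus ids
    ncrnas: list
    tss_records: list
    pause_sites: list

    def gene(self, locus: str) -> PlantedGene:
        return self._index()[locus]

    def _index(self) -> dict:
        if not hasattr(self, "_idx"):
            self._idx = {g.locus: g for g in self.genes}
        return self._idx


@dataclass
class Bundle:
    """Everything one simulated experiment produces."""

    config: SimulationConfig
    genome: Genome
    truth: Truth
    ribo: DensityTrack
    rna_cov: DensityTrack
    rna_5p: DensityTrack
    tss: list
    peptides: list
    annotation: list  # perturbed input annotation


# ---------------------------------------------------------------------------
# sequence helpers


def _base_probs(gc: float) -> np.ndarray:
    return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])


_BASES = np.array(list("ACGT"))


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    return "".join(_BASES[rng.choice(4, size=n, p=_base_probs(gc))])


def _random_codon(rng: np.random.Generator, gc: float) -> str:
    p = _base_probs(gc)
    while True:
        codon = "".join(_BASES[rng.choice(4, size=3, p=p)])
        if codon not in _STOPS:
            return codon


def _translate(codons: Sequence[str]) -> str:
    global _CODON_TABLE
    if not _CODON_TABLE:
        from Bio.Data import CodonTable

        table = CodonTable.unambiguous_dna_by_id[11]
        _CODON_TABLE = dict(table.forward_table)
    # the initiator is always fMet regardless of codon identity
    aas = ["M"]
    for c in codons[1:]:
        aas.append(_CODON_TABLE.get(c, "X"))
    return "".join(aas)


def _draw_utr5(rng: np.random.Generator) -> int:
    """5' UTR length: 57% of mass in 15-60 nt, a tail beyond 100 nt."""
    u = rng.random()
    if u < 0.57:
        return int(rng.integers(15, 61))
    if u < 0.85:
        return int(rng.integers(61, 101))
    if u < 0.95:
        return int(rng.integers(101, 250))
    return int(rng.integers(8, 15))


# ---------------------------------------------------------------------------
# genome + truth


def simulate_genome(config: SimulationConfig, seed: int) -> tuple[Genome, Truth]:
    """Plant operons, ncRNAs and evidence-relevant structure on a random
    GC-weighted background genome.  Deterministic given (config, seed)."""
    rng = np.random.default_rng(seed)
    genes: list[PlantedGene] = []
    transcripts: list[PlantedTranscript] = []
    operons: list[list[str]] = []
    chunks: list[str] = []
    cursor = 1  # next free genomic position (1-based)
    lead = int(rng.integers(*config.inter_operon_gap))
    chunks.append(_random_seq(rng, lead, config.gc))
    cursor += lead

    codon_names = [c for c, _ in config.start_codon_mix]
    codon_probs = np.array([p for _, p in config.start_codon_mix])
    codon_probs = codon_probs / codon_probs.sum()

    gene_no = 0
    op_no = 0
    n_small_target = int(round(config.n_genes * config.small_orf_fraction))
    small_planted = 0
    while gene_no < config.n_genes:
        size = int(rng.choice(len(config.operon_size_probs),
                              p=np.array(config.operon_size_probs))) + 1
        size = min(size, config.n_genes - gene_no)
        strand = "+" if rng.random() < 0.5 else "-"
        op_no += 1
        op_id = f"op{op_no:04d}"

        # transcript-local layout (coordinates 0-based along the mRNA)
        make_small = small_planted < n_small_target and size == 1 and rng.random() < 0.5
        leaderless = rng.random() < config.leaderless_fraction
        utr5 = 0 if leaderless else _draw_utr5(rng)
        utr3 = int(rng.integers(*config.utr3_range))
        local_parts: list[str] = []
        local_genes: list[dict] = []
        pos = 0
        local_parts.append(_random_seq(rng, utr5, config.gc))
        pos += utr5
        gaps_after: list[int] = []
        for k in range(size):
            if make_small:
                n_codons = int(rng.integers(config.small_orf_codons[0],
                                            config.small_orf_codons[1] + 1))
            else:
                n_codons = int(np.clip(
                    round(rng.lognormal(config.cds_codons_mu, config.cds_codons_sigma)),
                    config.cds_codons_min, config.cds_codons_max))
            start_codon = codon_names[rng.choice(len(codon_names), p=codon_probs)]
            body = [_random_codon(rng, config.gc) for _ in range(n_codons - 2)]
            stop = _STOPS[rng.integers(0, 3)]
            codons = [start_codon] + body + [stop]
            seq = "".join(codons)
            local_genes.append({
                "local_start": pos,
                "local_end": pos + len(seq) - 1,
                "codons": n_codons,
                "start_codon": start_codon,
                "protein": _translate(codons[:-1]),
            })
            local_parts.append(seq)
            pos += len(seq)
            if k < size - 1:
                if rng.random() < config.intra_operon_long_gap_frac:
                    gap = int(rng.integers(*config.intra_operon_long_gap))
                else:
                    gap = int(rng.integers(*config.intra_operon_gap))
                gaps_after.append(gap)
                local_parts.append(_random_seq(rng, gap, config.gc))
                pos += gap
        local_parts.append(_random_seq(rng, utr3, config.gc))
        pos += utr3
        local_seq = "".join(local_parts)
        t_len = pos

        # operon-level regulation at inter-CDS junctions
        level = float(rng.lognormal(config.expression_mu, config.expression_sigma))
        polarity_after: set[int] = set()
        internal_tss_local: list[int] = []
        if size > 1:
            wide = [j for j, g in enumerate(gaps_after) if g >= 26]
            if wide and rng.random() < config.polarity_fraction:
                polarity_after.add(int(rng.choice(wide)))
            if wide and rng.random() < config.internal_tss_fraction:
                j = int(rng.choice(wide))
                # internal TSS sits in the gap, 20 nt upstream of the next CDS
                internal_tss_local.append(local_genes[j + 1]["local_start"] - 20)

        # per-gene RNA level after junction effects
        levels = []
        cur = level
        for k in range(size):
            if k > 0 and (k - 1) in polarity_after:
                cur = cur / config.polarity_step
            if any(t <= local_genes[k]["local_start"] for t in internal_tss_local):
                eff = cur * config.internal_tss_step
            else:
                eff = cur
            levels.append(eff)

        # paste into the genome
        left = cursor
        chunks.append(local_seq if strand == "+" else revcomp(local_seq))
        cursor += t_len

        def to_genomic(local: int) -> int:
            return left + local if strand == "+" else left + (t_len - 1 - local)

        t_id = f"t{op_no:04d}"
        member_ids = []
        delay = None
        for k, lg in enumerate(local_genes):
            gene_no += 1
            locus = f"g{gene_no:04d}"
            member_ids.append(locus)
            a, b = to_genomic(lg["local_start"]), to_genomic(lg["local_end"])
            is_first = k == 0
            is_leaderless = leaderless and is_first
            if is_leaderless:
                delay = int(rng.integers(config.leaderless_footprint_delay[0],
                                         config.leaderless_footprint_delay[1] + 1))
            te = float(rng.lognormal(0.0, config.te_sigma))
            genes.append(PlantedGene(
                locus=locus, left=min(a, b), right=max(a, b), strand=strand,
                start_codon=lg["start_codon"], codons=lg["codons"],
                operon_id=op_id, transcript_id=t_id,
                leaderless=is_leaderless,
                leaderless_delay=delay if is_leaderless else None,
                utr5=(0 if is_leaderless else utr5) if is_first else None,
                rna_level=levels[k], ribo_rate=levels[k] * te,
                protein=lg["protein"], is_small=make_small,
            ))
        if make_small:
            small_planted += 1
        operons.append(member_ids)
        g_lo, g_hi = to_genomic(0), to_genomic(t_len - 1)
        transcripts.append(PlantedTranscript(
            id=t_id, left=min(g_lo, g_hi), right=max(g_lo, g_hi), strand=strand,
            tss=to_genomic(0), members=member_ids, level=level,
            internal_tss=[to_genomic(t) for t in internal_tss_local],
            polarity_junctions=sorted(polarity_after),
        ))
        gap = int(rng.integers(*config.inter_operon_gap))
        chunks.append(_random_seq(rng, gap, config.gc))
        cursor += gap

    # ncRNAs planted into fresh intergenic space (or antisense to an mRNA)
    ncrnas: list[PlantedNcRNA] = []
    mrna_pool = [t for t in transcripts if t.right - t.left > 400]
    for i in range(config.ncrna_count):
        length = int(rng.integers(*config.ncrna_length))
        level = float(rng.lognormal(config.expression_mu, config.expression_sigma))
        antisense = bool(mrna_pool) and rng.random() < config.ncrna_antisense_fraction
        if antisense:
            host = mrna_pool[int(rng.integers(0, len(mrna_pool)))]
            left = int(rng.integers(host.left + 20, host.right - length - 20))
            strand = "-" if host.strand == "+" else "+"
            kind = "antisense"
        else:
            gap = int(rng.integers(100, 200))
            left = cursor + gap
            chunks.append(_random_seq(rng, gap + length, config.gc))
            cursor = left + length
            strand = "+" if rng.random() < 0.5 else "-"
            kind = "intergenic"
        right = left + length - 1
        tss = left if strand == "+" else right
        ncrnas.append(PlantedNcRNA(
            id=f"nc{i + 1:03d}", left=left, right=right, strand=strand,
            level=level, kind=kind, tss=tss,
        ))

    tail = int(rng.integers(*config.inter_operon_gap))
    chunks.append(_random_seq(rng, tail, config.gc))
    sequence = "".join(chunks)
    if config.genome_length is not None:
        if config.genome_length < len(sequence):
            raise ValueError(
                f"genome_length {config.genome_length} too short for "
                f"{config.n_genes} genes (needs {len(sequence)})")
        sequence += _random_seq(rng, config.genome_length - len(sequence), config.gc)
    genome = Genome(id="synthetic", sequence=sequence, circular=True)

    # planted internal (alternative) starts: an in-frame internal ATG whose
    # upstream residue is not Lys/Arg, to be hit by an isoform peptide
    n_internal = int(round(len(genes) * config.internal_start_fraction))
    eligible = [g for g in genes if g.codons >= 60]
    rng.shuffle(eligible)
    for g in eligible:
        if n_internal == 0:
            break
        seq = genome.fetch(g.left, g.right, g.strand)

        def _nterm_frag_len(c: int) -> int:
            tail = g.protein[c:]
            for i, aa in enumerate(tail):
                if aa in "KR":
                    return i + 1
            return len(tail)

        hits = [
            c for c in range(30, g.codons - 25)
            if seq[3 * c : 3 * c + 3] == "ATG"
            and g.protein[c - 1] not in "RK"
            and _nterm_frag_len(c) >= config.peptide_min_report_aa
        ]
        if hits:
            g.internal_start_codon = int(hits[0])
            n_internal -= 1

    # SD-like internal sites and the pauses they cause
    pause_sites = _plant_pause_sites(genome, genes, config)

    tss_records = [
        TSSRecord(t.tss, t.strand, support=1.0) for t in transcripts
    ] + [
        TSSRecord(p, t.strand, support=1.0)
        for t in transcripts for p in t.internal_tss
    ] + [
        TSSRecord(nc.tss, nc.strand, support=1.0) for nc in ncrnas
    ]

    truth = Truth(genes=genes, transcripts=transcripts, operons=operons,
                  ncrnas=ncrnas, tss_records=tss_records,
                  pause_sites=pause_sites)
    return genome, truth


def _plant_pause_sites(genome: Genome, genes: list,
                       config: SimulationConfig) -> list:
    """Find internal SD-like sites (annealing dG below the SD cutoff, local
    minimum within +/-4 nt) in each CDS and attach a pause of strength
    exp(-beta * dG) at sd_pause_offset nt downstream of the site's 3' end."""
    if config.sd_pause_beta == 0:
        return []
    out: list[PauseSite] = []
    k = len(sd_energy.ASD_SEQUENCE)
    for g in genes:
        seq = genome.fetch(g.left, g.right, g.strand)
        L = len(seq)
        dgs = np.array([
            sd_energy.duplex_dG(window=seq[i : i + k]) for i in range(L - k + 1)
        ])
        for i in range(len(dgs)):
            if dgs[i] >= sd_energy.SD_CUTOFF:
                continue
            lo, hi = max(0, i - 4), min(len(dgs), i + 5)
            if dgs[i] > dgs[lo:hi].min() + 1e-12:
                continue
            if i > 0 and np.isclose(dgs[i - 1], dgs[i]):
                continue  # plateau: keep the 5'-most position only
            pause_local = i + k - 1 + config.sd_pause_offset
            if pause_local >= L - 15:
                continue
            mult = math.exp(-config.sd_pause_beta * dgs[i])
            pos = (g.left + pause_local if g.strand == "+"
                   else g.right - pause_local)
            out.append(PauseSite(g.locus, pos, float(dgs[i]), mult))
    return out


# ---------------------------------------------------------------------------
# noise


def _nb_sample(rng: np.random.Generator, mean: np.ndarray,
               dispersion: float) -> np.ndarray:
    """Negative-binomial counts with var = m + a*m^2; a=0 returns the mean
    itself (noise-free)."""
    mean = np.asarray(mean, float)
    if dispersion <= 0:
        return mean.copy()
    r = 1.0 / dispersion
    p = r / (r + np.maximum(mean, 1e-12))
    out = rng.negative_binomial(r, p).astype(float)
    out[mean <= 0] = 0.0
    return out


# ---------------------------------------------------------------------------
# evidence channels


def simulate_ribo_track(genome: Genome, truth: Truth, config: SimulationConfig,
                        seed: int) -> DensityTrack:
    """Center-weighted footprint density over every planted CDS."""
    rng = np.random.default_rng(seed)
    track = DensityTrack(genome.length, label="ribo")
    pauses_by_locus: dict[str, list] = {}
    for p in truth.pause_sites:
        pauses_by_locus.setdefault(p.locus, []).append(p)
    mult_map = dict(config.te_multipliers)
    for g in truth.genes:
        L = g.length
        rate = g.ribo_rate * mult_map.get(g.locus, 1.0)
        profile = np.full(L, rate)  # sense orientation, index 0 = start codon nt 1
        w = min(config.peak_width, L)
        profile[:w] *= config.start_peak_multiplier
        profile[L - w :] *= config.stop_peak_multiplier
        for p in pauses_by_locus.get(g.locus, ()):
            local = (p.position - g.left if g.strand == "+"
                     else g.right - p.position)
            profile[local] *= p.multiplier
        if g.leaderless:
            profile[: g.leaderless_delay] = 0.0
        counts = _nb_sample(rng, profile, config.nb_dispersion)
        arr = track.array(g.strand)
        if g.strand == "+":
            arr[g.left - 1 : g.right] += counts
        else:
            arr[g.left - 1 : g.right] += counts[::-1]
    return track


def simulate_rna_tracks(genome: Genome, truth: Truth, config: SimulationConfig,
                        seed: int) -> tuple[DensityTrack, DensityTrack, list]:
    """RNA-seq coverage and 5'-end tracks plus the planted TSS list."""
    rng = np.random.default_rng(seed)
    cov = DensityTrack(genome.length, label="rna_cov")
    fivep = DensityTrack(genome.length, label="rna_5p")
    gene_level = {g.locus: g.rna_level for g in truth.genes}

    for t in truth.transcripts:
        L = t.right - t.left + 1
        level = np.full(L, t.level)  # sense orientation
        # piecewise level: genes already carry their effective level; fill
        # the spans between boundaries from the member levels
        members = [truth.gene(m) for m in t.members]
        for g in members:
            lo = (g.left - t.left) if t.strand == "+" else (t.right - g.right)
            hi = lo + g.length
            level[lo:hi] = gene_level[g.locus]
        # propagate each gene's level through the following gap/UTR
        prev_hi = 0
        prev_level = t.level
        for g in members:
            lo = (g.left - t.left) if t.strand == "+" else (t.right - g.right)
            level[prev_hi:lo] = prev_level
            prev_hi = lo + g.length
            prev_level = gene_level[g.locus]
        level[prev_hi:] = prev_level
        # the internal-TSS step-up begins at the TSS itself, inside the gap
        for itss in t.internal_tss:
            local = (itss - t.left) if t.strand == "+" else (t.right - itss)
            downstream = [
                (g.left - t.left) if t.strand == "+" else (t.right - g.right)
                for g in members
                if ((g.left - t.left) if t.strand == "+" else (t.right - g.right))
                >= local
            ]
            if downstream:
                nxt = min(downstream)
                level[local:nxt] = level[nxt]
        counts = _nb_sample(rng, level, config.nb_dispersion)
        arr = cov.array(t.strand)
        if t.strand == "+":
            arr[t.left - 1 : t.right] += counts
        else:
            arr[t.left - 1 : t.right] += counts[::-1]
        # 5'-end channel: shear background + TSS spikes
        shear = level * config.rna5p_shear_rate
        e5 = _nb_sample(rng, shear, config.nb_dispersion)
        # the spike brings the 5'-end rate AT the TSS to
        # tss_peak_multiplier times the transcript-body 5'-end rate
        spike = (config.tss_peak_multiplier - 1.0) * t.level \
            * config.rna5p_shear_rate
        tss_positions = [t.tss] + list(t.internal_tss)
        arr5 = fivep.array(t.strand)
        if t.strand == "+":
            arr5[t.left - 1 : t.right] += e5
        else:
            arr5[t.left - 1 : t.right] += e5[::-1]
        for pos in tss_positions:
            jit = int(rng.integers(-config.tss_jitter, config.tss_jitter + 1)) \
                if config.tss_jitter else 0
            p = min(max(pos + jit, 1), genome.length)
            arr5[p - 1] += spike if config.nb_dispersion <= 0 \
                else float(rng.poisson(spike))

    for nc in truth.ncrnas:
        L = nc.right - nc.left + 1
        counts = _nb_sample(rng, np.full(L, nc.level), config.nb_dispersion)
        arr = cov.array(nc.strand)
        arr[nc.left - 1 : nc.right] += counts if nc.strand == "+" else counts[::-1]
        e5 = _nb_sample(rng, np.full(L, nc.level * config.rna5p_shear_rate),
                        config.nb_dispersion)
        arr5 = fivep.array(nc.strand)
        arr5[nc.left - 1 : nc.right] += e5 if nc.strand == "+" else e5[::-1]
        spike = (config.tss_peak_multiplier - 1.0) * nc.level \
            * config.rna5p_shear_rate
        arr5[nc.tss - 1] += spike if config.nb_dispersion <= 0 \
            else float(rng.poisson(spike))

    tss_list = [
        TSSRecord(r.position, r.strand,
                  support=float(fivep.array(r.strand)[r.position - 1]))
        for r in truth.tss_records
    ]
    return cov, fivep, tss_list


def simulate_peptides(truth: Truth, config: SimulationConfig,
                      seed: int) -> list[Peptide]:
    """Trypsin-digest every planted protein and detect fragments at random.

    Cleavage occurs after every Lys/Arg; the N-terminal fragment loses its
    initiator fMet with probability ``fmet_cleavage_prob`` (the peptide
    then starts at codon 2 and its recorded preceding residue is the Met).
    Planted alternative-start isoforms contribute an extra N-terminal-like
    fragment at their internal ATG.
    """
    rng = np.random.default_rng(seed)
    out: list[Peptide] = []

    def digest(protein: str, codon0: int, preceding: str | None, locus: str,
               first_always: bool = False):
        frags: list[tuple[int, str, str | None]] = []
        start = 0
        prev = preceding
        for i, aa in enumerate(protein):
            if aa in "KR":
                frags.append((start, protein[start : i + 1], prev))
                prev = aa
                start = i + 1
        if start < len(protein):
            frags.append((start, protein[start:], prev))
        for k, (off, seq, prev_res) in enumerate(frags):
            if len(seq) < config.peptide_min_report_aa:
                continue
            detected = rng.random() < config.peptide_detection_prob
            if first_always and k == 0:
                detected = True  # a planted isoform is defined by its peptide
            if detected:
                out.append(Peptide(seq, locus, codon0 + off, prev_res))

    for g in truth.genes:
        protein = g.protein
        if rng.random() < config.fmet_cleavage_prob and len(protein) > 1:
            digest(protein[1:], 1, "M", g.locus)
        else:
            digest(protein, 0, None, g.locus)
        if g.internal_start_codon is not None:
            c = g.internal_start_codon
            digest(g.protein[c:], c, g.protein[c - 1], g.locus,
                   first_always=True)
    return out


# ---------------------------------------------------------------------------
# input annotation with realistic imperfections


def make_input_annotation(genome: Genome, truth: Truth,
                          config: SimulationConfig, seed: int) -> list:
    """Build the 'existing annotation' the mapper starts from: planted small
    ORFs are missing, a few records sit on the wrong strand, some starts are
    shifted in frame, and a few spurious hypothetical CDSs overlap real
    genes on the opposite strand."""
    rng = np.random.default_rng(seed)
    records: list[AnnotationRecord] = []
    real = [g for g in truth.genes if not g.is_small]
    flip = set(rng.choice(len(real), size=min(config.wrong_strand_n, len(real)),
                          replace=False).tolist())
    for i, g in enumerate(real):
        strand = g.strand
        left, right = g.left, g.right
        if i in flip:
            strand = "-" if strand == "+" else "+"
        elif rng.random() < config.start_misannotation_fraction:
            shift = int(rng.integers(config.start_misannotation_codons[0],
                                     config.start_misannotation_codons[1] + 1)) * 3
            if rng.random() < 0.5:
                shift = -shift
            shift = min(shift, (g.length - 60) // 3 * 3)  # keep most of the CDS
            if g.strand == "+":
                left = max(1, left + shift)
            else:
                right = min(genome.length, right - shift)
        records.append(AnnotationRecord(
            locus=g.locus, start=left, end=right, strand=strand, feature="CDS",
            hypothetical=False,
        ))
    big = [g for g in real if g.length > 400]
    for j in range(config.spurious_hypothetical_n):
        host = big[int(rng.integers(0, len(big)))]
        length = int(rng.integers(150, min(300, host.length - 60)))
        left = int(rng.integers(host.left + 10, host.right - length - 10))
        strand = "-" if host.strand == "+" else "+"
        records.append(AnnotationRecord(
            locus=f"hyp{j + 1:02d}", start=left, end=left + length - 1,
            strand=strand, feature="CDS", hypothetical=True,
        ))
    return sorted(records, key=lambda r: r.start)


# ---------------------------------------------------------------------------
# bundles


def simulate_bundle(config: SimulationConfig | None = None,
                    seed: int = 0) -> Bundle:
    """Run all four simulators off one master seed and assemble a bundle."""
    config = config or SimulationConfig()
    ss = np.random.SeedSequence(seed)
    s_genome, s_ribo, s_rna, s_pep, s_ann = [
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(5)
    ]
    genome, truth = simulate_genome(config, s_genome)
    ribo = simulate_ribo_track(genome, truth, config, s_ribo)
    rna_cov, rna_5p, tss = simulate_rna_tracks(genome, truth, config, s_rna)
    peptides = simulate_peptides(truth, config, s_pep)
    annotation = make_input_annotation(genome, truth, config, s_ann)
    return Bundle(config=config, genome=genome, truth=truth, ribo=ribo,
                  rna_cov=rna_cov, rna_5p=rna_5p, tss=tss, peptides=peptides,
                  annotation=annotation)


def write_bundle(bundle: Bundle, outdir: str | Path) -> dict:
    """Write a bundle to disk as FASTA + bedGraph pairs + evidence TSVs +
    truth GFF3/JSON; returns the path manifest."""
    import json

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {"genome": outdir / "genome.fasta"}
    with open(paths["genome"], "w") as fh:
        fh.write(f">{bundle.genome.id}\n")
        seq = bundle.genome.sequence
        for i in range(0, len(seq), 70):
            fh.write(seq[i : i + 70] + "\n")
    for name, track in (("ribo", bundle.ribo), ("rna_cov", bundle.rna_cov),
                        ("rna_5p", bundle.rna_5p)):
        p_plus = outdir / f"{name}.plus.bedgraph"
        p_minus = outdir / f"{name}.minus.bedgraph"
        write_track(track, p_plus, p_minus, chrom=bundle.genome.id)
        paths[f"{name}_plus"], paths[f"{name}_minus"] = p_plus, p_minus
    paths["tss"] = outdir / "tss.tsv"
    with open(paths["tss"], "w") as fh:
        fh.write("position\tstrand\treads\n")
        for r in bundle.tss:
            fh.write(f"{r.position}\t{r.strand}\t{r.support:g}\n")
    paths["peptides"] = outdir / "peptides.tsv"
    with open(paths["peptides"], "w") as fh:
        fh.write("peptide\tcds_id\tcodon_offset\tpreceding_residue\n")
        for p in bundle.peptides:
            fh.write(f"{p.sequence}\t{p.cds_id or '.'}\t{p.codon_offset}"
                     f"\t{p.preceding_residue or '.'}\n")
    paths["annotation"] = outdir / "annotation.gff3"
    write_annotation(bundle.annotation, paths["annotation"],
                     seqid=bundle.genome.id)
    truth_records = [
        AnnotationRecord(
            locus=g.locus, start=g.left, end=g.right, strand=g.strand,
            feature="CDS",
            attrs={"start_codon": g.start_codon,
                   "leaderless": str(g.leaderless).lower(),
                   "operon": g.operon_id, "transcript": g.transcript_id},
        )
        for g in bundle.truth.genes
    ]
    paths["truth_gff"] = outdir / "truth.gff3"
    write_annotation(truth_records, paths["truth_gff"], seqid=bundle.genome.id)
    paths["truth_json"] = outdir / "truth.json"
    with open(paths["truth_json"], "w") as fh:
        json.dump({
            "operons": bundle.truth.operons,
            "leaderless": [g.locus for g in bundle.truth.genes if g.leaderless],
            "small_orfs": [g.locus for g in bundle.truth.genes if g.is_small],
            "ncrnas": [[n.id, n.left, n.right, n.strand, n.kind]
                       for n in bundle.truth.ncrnas],
            "pause_offset": bundle.config.sd_pause_offset,
        }, fh, indent=1)
    return {k: str(v) for k, v in paths.items()}
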