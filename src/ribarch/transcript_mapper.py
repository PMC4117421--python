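"""Transcript boundary mapping, 5' UTR assignment and ncRNA calling.

Transcript 5' ends come from TSS evidence when a mapped TSS sits at the
upstream edge of an RNA-seq-covered block (TSS beats a 5'-end peak when
both exist); otherwise from a position where the RNA-seq 5'-nucleotide
track spikes above its local background; otherwise the covered block edge
is used as an estimate.  3' ends are taken as the last position holding at
least a fixed fraction of the transcript-body coverage, a deterministic
stand-in for changepoint detection on the 3' drop.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_io import DensityTrack, TSSRecord

__all__ = [
    "TranscriptParams",
    "TranscriptUnit",
    "map_transcript_bounds",
    "assign_members",
    "assign_utr5",
    "call_ncrnas",
    "tss_metagene",
]


@dataclass(frozen=True)
class TranscriptParams:
    expression_floor: float = 5.0  # mean reads/nt over the block
    min_length: int = 50  # nt
    coverage_floor: float = 1.0  # a nt is covered when cov > this
    gap_bridge: int = 20  # nt of internal gap bridged within a block
    tss_tol: int = 3  # nt between block edge and a matching TSS
    five_peak_k: float = 5.0  # rna_5p spike over local background
    three_q: float = 0.1  # 3' end: last nt with cov >= q * body mean
    utr5_max: int = 300  # longer 5' UTRs are flagged for review
    upstream_cds_frac: float = 0.3  # search span may reach this far into the upstream CDS


@dataclass
class TranscriptUnit:
    id: str
    left: int
    right: int
    strand: str
    five_prime_source: str = "estimated"  # TSS-matched | rna5p-peak | estimated
    member_cds: list = field(default_factory=list)  # ordered 5'->3'
    type: str = "mRNA"  # mRNA | ncRNA | antisense
    utr5: int | None = None
    utr3: int | None = None
    mean_coverage: float = 0.0

    @property
    def five_prime(self) -> int:
        return self.left if self.strand == "+" else self.right

    @property
    def three_prime(self) -> int:
        return self.right if self.strand == "+" else self.left

    @property
    def length(self) -> int:
        return self.right - self.left + 1


def _covered_blocks(arr: np.ndarray, floor: float, bridge: int) -> list:
    idx = np.flatnonzero(arr > floor)
    if len(idx) == 0:
        return []
    blocks = []
    start = prev = idx[0]
    for i in idx[1:]:
        if i - prev > bridge + 1:
            blocks.append((start, prev))
            start = i
        prev = i
    blocks.append((start, prev))
    return blocks


def map_transcript_bounds(rna_cov: DensityTrack, rna_5p: DensityTrack,
                          tss_list: list,
                          params: TranscriptParams = TranscriptParams()) -> list:
    """Call transcript units from stranded coverage, 5'-end peaks and TSSs."""
    units: list[TranscriptUnit] = []
    counter = 0
    for strand in "+-":
        arr = rna_cov.array(strand)
        arr5 = rna_5p.array(strand)
        tss_here = sorted(t.position for t in tss_list if t.strand == strand)
        tss_arr = np.array(tss_here, dtype=int)
        for lo, hi in _covered_blocks(arr, params.coverage_floor, params.gap_bridge):
            block = arr[lo : hi + 1]
            if len(block) < params.min_length or block.mean() < params.expression_floor:
                continue
            left, right = lo + 1, hi + 1  # genomic
            edge5 = left if strand == "+" else right
            # 5' end: a TSS at the upstream edge wins
            source = "estimated"
            five = edge5
            if len(tss_arr):
                near = tss_arr[np.abs(tss_arr - edge5) <= params.tss_tol]
                if len(near):
                    five = int(near[np.argmin(np.abs(near - edge5))])
                    source = "TSS-matched"
            if source == "estimated":
                # 5'-nucleotide spike above the block's background 5'-end rate
                body5 = arr5[lo : hi + 1]
                background = body5.mean() if body5.size else 0.0
                span = range(lo, min(lo + 6, hi + 1)) if strand == "+" \
                    else range(hi, max(hi - 6, lo - 1), -1)
                for i in span:
                    if background > 0 and arr5[i] > params.five_peak_k * background:
                        five = i + 1
                        source = "rna5p-peak"
                        break
            # 3' end: last position holding >= q * body mean
            body_mean = block.mean()
            thresh = params.three_q * body_mean
            if strand == "+":
                good = np.flatnonzero(arr[lo : hi + 1] >= thresh)
                three = lo + 1 + int(good[-1]) if len(good) else right
            else:
                good = np.flatnonzero(arr[lo : hi + 1] >= thresh)
                three = lo + 1 + int(good[0]) if len(good) else left
            counter += 1
            uleft = min(five, three)
            uright = max(five, three)
            units.append(TranscriptUnit(
                id=f"tu{counter:04d}", left=uleft, right=uright, strand=strand,
                five_prime_source=source,
                mean_coverage=float(arr[uleft - 1 : uright].mean()),
            ))
    return sorted(units, key=lambda u: u.left)


def assign_members(transcripts: list, cds_set: list) -> None:
    """Attach CDSs lying within each unit (same strand), ordered 5'->3',
    and classify units carrying none as ncRNA candidates."""
    for t in transcripts:
        inside = [
            c for c in cds_set
            if c.strand == t.strand and c.left >= t.left - 5 and c.right <= t.right + 5
        ]
        inside.sort(key=lambda c: c.left, reverse=(t.strand == "-"))
        t.member_cds = inside


def assign_utr5(transcripts: list, cds_set: list, tss_list: list | None = None,
                params: TranscriptParams = TranscriptParams()) -> dict:
    """5' UTR length for every CDS that a mapped 5' end can serve.

    A transcript-initial CDS takes the distance from the transcript 5' end
    to its start codon, provided the 5' end lies within the allowed search
    span (at most ``utr5_max`` nt upstream, and not further than 30% into
    an upstream CDS); longer distances are flagged for manual review.  An
    operon-internal CDS takes an internal TSS within its span when one
    exists.  Leaderless CDSs get 0.
    """
    out: dict[str, dict] = {}
    tss_list = tss_list or []
    for t in transcripts:
        members = t.member_cds
        for rank, cds in enumerate(members):
            if cds.locus in out:
                continue
            if rank == 0:
                d = abs(cds.start_pos - t.five_prime)
                upstream_ok = (cds.start_pos - t.five_prime >= 0) if t.strand == "+" \
                    else (t.five_prime - cds.start_pos >= 0)
                if not upstream_ok:
                    out[cds.locus] = {"utr5": None, "flag": "five-prime-inside-cds"}
                elif d > params.utr5_max:
                    out[cds.locus] = {"utr5": None, "flag": "manual-review-long"}
                else:
                    out[cds.locus] = {"utr5": int(d),
                                      "flag": "leaderless" if d == 0 else None}
            else:
                upstream = members[rank - 1]
                span = min(params.utr5_max,
                           int(params.upstream_cds_frac * upstream.length)
                           + _gap_between(upstream, cds))
                hit = None
                for ts in tss_list:
                    if ts.strand != t.strand:
                        continue
                    d = (cds.start_pos - ts.position) if t.strand == "+" \
                        else (ts.position - cds.start_pos)
                    if 0 < d <= span:
                        hit = int(d) if hit is None else min(hit, int(d))
                if hit is not None:
                    out[cds.locus] = {"utr5": hit, "flag": "internal-tss"}
                else:
                    out[cds.locus] = {"utr5": None, "flag": "operon-internal"}
        t.utr5 = out[members[0].locus]["utr5"] if members else None
    return out


def _gap_between(upstream, downstream) -> int:
    if downstream.left > upstream.right:
        return downstream.left - upstream.right - 1
    return upstream.left - downstream.right - 1


def call_ncrnas(transcripts: list, cds_set: list, ribo: DensityTrack,
                translation_floor: float = 0.1) -> list:
    """Label CDS-free transcripts as ncRNA when they are not translated.

    The translation expectation of a transcript is its RNA coverage scaled
    by the global footprint-to-RNA ratio of coding transcripts; a CDS-free
    unit whose footprint density stays below ``translation_floor`` of that
    expectation is non-coding.  Units mostly antisense to a CDS are
    labelled ``antisense``.
    """
    coding = [t for t in transcripts if t.member_cds]
    ribo_mass = sum(
        float(ribo.slice(t.left, t.right, t.strand).sum()) for t in coding
    )
    rna_mass = sum(t.mean_coverage * t.length for t in coding)
    global_ratio = ribo_mass / rna_mass if rna_mass > 0 else 1.0
    out = []
    for t in transcripts:
        if t.member_cds:
            t.type = "mRNA"
            continue
        ribo_per_nt = float(ribo.slice(t.left, t.right, t.strand).mean())
        expectation = t.mean_coverage * global_ratio
        if expectation > 0 and ribo_per_nt >= translation_floor * expectation:
            t.type = "mRNA"  # translated but no CDS mapped: leave unlabelled
            continue
        anti_strand = "-" if t.strand == "+" else "+"
        anti_overlap = 0
        for c in cds_set:
            if c.strand != anti_strand:
                continue
            ov = min(t.right, c.right) - max(t.left, c.left) + 1
            if ov > 0:
                anti_overlap += ov
        t.type = "antisense" if anti_overlap >= 0.5 * t.length else "ncRNA"
        out.append(t)
    return out


def tss_metagene(rna_5p: DensityTrack, tss_list: list, halfwidth: int = 50,
                 circular: bool = True) -> tuple[np.ndarray, int]:
    """Average per-TSS-normalized 5'-end profile around TSS positions.

    Each TSS window (oriented 5'->3' on its strand) is normalized to sum
    1 and the normalized windows are averaged; the profile therefore sums
    to 1.  Returns (profile of length 2*halfwidth+1, number of windows
    skipped for falling off a linear genome or holding zero signal).
    """
    if not tss_list:
        raise ValueError("empty TSS list")
    n = rna_5p.length
    width = 2 * halfwidth + 1
    acc = np.zeros(width)
    used = 0
    skipped = 0
    for t in tss_list:
        offsets = np.arange(-halfwidth, halfwidth + 1)
        if t.strand == "+":
            pos = t.position + offsets
        else:
            pos = t.position - offsets
        if circular:
            pos = (pos - 1) % n + 1
        elif pos.min() < 1 or pos.max() > n:
            skipped += 1
            continue
        vals = rna_5p.array(t.strand)[pos - 1]
        s = vals.sum()
        if s <= 0:
            skipped += 1
            continue
        acc += vals / s
        used += 1
    if used == 0:
        raise ValueError("no usable TSS windows")
    return acc / used, skipped
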