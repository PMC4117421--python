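"""Operon assembly, coverage-based splitting and operon-level statistics.

Same-strand CDS runs are merged into operons by gap rules: overlapping
CDSs or gaps under 40 nt always merge; gaps of 40-260 nt merge only when a
single mapped transcript covers both CDSs (and carry a review flag, the
mechanized form of manual inspection); gaps of 260 nt and more never
merge.  Assembled operons are then split at junctions where the RNA-seq
coverage says two transcription units were fused: the intergenic region
must exceed 40 nt, both flanking CDS bodies must exceed 20 reads per
nucleotide, and the upstream CDS must exceed the intergenic coverage more
than 10-fold.  All three thresholds are strict inequalities and the split
operator is idempotent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_io import DensityTrack

__all__ = [
    "OperonParams",
    "Operon",
    "assemble_operons",
    "split_operons",
    "operon_stats",
]


@dataclass(frozen=True)
class OperonParams:
    merge_gap: int = 40  # gaps below this always merge, nt
    review_gap: int = 260  # gaps up to this merge only with transcript support
    split_gap: int = 40  # criterion 1: intergenic length must exceed this
    split_coverage: float = 20.0  # criterion 2: CDS-body reads/nt must exceed this
    split_fold: float = 10.0  # criterion 3: CDS/intergenic coverage ratio
    polarity_fold: float = 5.0  # inter-CDS RNA drop calling a polarity junction


@dataclass
class Operon:
    id: str
    members: list  # CDSRecords, ordered 5'->3'
    strand: str
    review: bool = False
    splits_applied: list = field(default_factory=list)
    tss_positions: list = field(default_factory=list)
    polarity_junctions: list = field(default_factory=list)
    isoform_estimate: int = 1

    @property
    def left(self) -> int:
        return min(c.left for c in self.members)

    @property
    def right(self) -> int:
        return max(c.right for c in self.members)

    @property
    def size(self) -> int:
        return len(self.members)


def _gap(a, b) -> int:
    """Intergenic gap between two non-overlapping sorted-by-left CDSs
    (negative when they overlap)."""
    return b.left - a.right - 1


def assemble_operons(cds_set: list, transcripts: list | None = None,
                     params: OperonParams = OperonParams()) -> list:
    """Merge same-strand CDS runs into operons by the gap rules."""
    covering: list = transcripts or []
    operons: list[Operon] = []
    counter = 0
    for strand in "+-":
        run: list = []
        review = False
        genes = sorted((c for c in cds_set if c.strand == strand),
                       key=lambda c: c.left)

        def flush() -> None:
            nonlocal counter, run, review
            if run:
                counter += 1
                members = run if strand == "+" else run[::-1]
                operons.append(Operon(id=f"opn{counter:04d}", members=members,
                                      strand=strand, review=review))
            run = []
            review = False

        for cds in genes:
            if not run:
                run.append(cds)
                continue
            gap = _gap(run[-1], cds)
            if gap < params.merge_gap:
                run.append(cds)
            elif gap < params.review_gap and _one_transcript_covers(
                    covering, run[-1], cds):
                run.append(cds)
                review = True
            else:
                flush()
                run.append(cds)
        flush()
    return sorted(operons, key=lambda o: o.left)


def _one_transcript_covers(transcripts: list, a, b) -> bool:
    lo, hi = min(a.left, b.left), max(a.right, b.right)
    return any(
        t.strand == a.strand and t.left <= lo and t.right >= hi
        for t in transcripts
    )


def split_decision(gap_len: int, upstream_cov: float, downstream_cov: float,
                   intergenic_cov: float,
                   params: OperonParams = OperonParams()) -> bool:
    """The three-criteria junction test (all strict inequalities)."""
    if not gap_len > params.split_gap:
        return False
    if not (upstream_cov > params.split_coverage
            and downstream_cov > params.split_coverage):
        return False
    ratio = upstream_cov / intergenic_cov if intergenic_cov > 0 else np.inf
    return ratio > params.split_fold


def split_operons(operons: list, rna_cov: DensityTrack,
                  params: OperonParams = OperonParams()) -> tuple[list, list]:
    """Split assembled operons where the RNA coverage shows a junction.

    Returns (new operon list, split report).  Applying the operator twice
    changes nothing: every junction that survives a split was already
    tested with the same per-CDS coverage values.
    """
    out: list[Operon] = []
    report: list[dict] = []
    counter = 0
    for op in operons:
        members_lr = sorted(op.members, key=lambda c: c.left)
        segments: list[list] = [[members_lr[0]]]
        for a, b in zip(members_lr, members_lr[1:]):
            gap_len = _gap(a, b)
            up, down = (a, b) if op.strand == "+" else (b, a)
            up_cov = float(rna_cov.slice(up.left, up.right, op.strand).mean())
            down_cov = float(rna_cov.slice(down.left, down.right, op.strand).mean())
            inter_cov = (
                float(rna_cov.slice(a.right + 1, b.left - 1, op.strand).mean())
                if gap_len > 0 else np.inf
            )
            if split_decision(gap_len, up_cov, down_cov, inter_cov, params):
                report.append({
                    "operon": op.id, "upstream": up.locus, "downstream": down.locus,
                    "gap": gap_len, "upstream_cov": up_cov,
                    "intergenic_cov": inter_cov,
                })
                segments.append([b])
            else:
                segments[-1].append(b)
        if len(segments) == 1:
            out.append(op)
            continue
        for seg in segments:
            counter += 1
            members = seg if op.strand == "+" else seg[::-1]
            out.append(Operon(
                id=f"{op.id}.{counter}", members=members, strand=op.strand,
                review=op.review,
                splits_applied=[r for r in report if r["operon"] == op.id],
            ))
    return sorted(out, key=lambda o: o.left), report


def operon_stats(operons: list, tss_list: list, rna_levels: dict,
                 params: OperonParams = OperonParams()) -> dict:
    """Operon-level summary: size distribution, TSSs per operon, polarity
    junctions (>= polarity_fold inter-CDS RNA drops, 5'->3'), the fraction
    of operons with >2-fold internal RNA differences, and a crude isoform
    estimate (1 + internal TSSs + polarity junctions per operon).
    """
    sizes = [op.size for op in operons]
    tss_counts = []
    polarity_total = 0
    multi_with_diff = 0
    multi = 0
    for op in operons:
        lo, hi = op.left, op.right
        five = lo if op.strand == "+" else hi
        inside = [
            t for t in tss_list
            if t.strand == op.strand
            and (lo <= t.position <= hi
                 or (_is_upstream(t.position, op)
                     and abs(t.position - five) <= 300))
        ]
        tss_counts.append(len(inside))
        op.tss_positions = sorted(t.position for t in inside)
        internal = [
            t for t in inside
            if (op.strand == "+" and t.position > op.members[0].left)
            or (op.strand == "-" and t.position < op.members[0].right)
        ]
        junctions = []
        levels = [rna_levels.get(c.locus, 0.0) for c in op.members]
        for j, (a, b) in enumerate(zip(levels, levels[1:])):
            if b > 0 and a / b >= params.polarity_fold:
                junctions.append(j)
        op.polarity_junctions = junctions
        polarity_total += len(junctions)
        op.isoform_estimate = 1 + len(internal) + len(junctions)
        if op.size > 1:
            multi += 1
            pos_levels = [l for l in levels if l > 0]
            if pos_levels and max(pos_levels) > 2 * min(pos_levels):
                multi_with_diff += 1
    return {
        "n_operons": len(operons),
        "n_multi_cds": multi,
        "size_distribution": dict(zip(*np.unique(sizes, return_counts=True))),
        "max_size": int(max(sizes)) if sizes else 0,
        "mean_tss_per_operon": float(np.mean(tss_counts)) if tss_counts else 0.0,
        "n_polarity_junctions": polarity_total,
        "operons_with_polarity": sum(
            1 for op in operons if op.polarity_junctions),
        "frac_multi_with_2fold_diff": multi_with_diff / multi if multi else 0.0,
        "mean_isoform_estimate": float(np.mean(
            [op.isoform_estimate for op in operons])) if operons else 0.0,
    }


def _is_upstream(pos: int, op: Operon) -> bool:
    return pos <= op.left if op.strand == "+" else pos >= op.right


def operon_membership_rand_index(called: list, truth_operons: list) -> float:
    """Adjusted-for-chance-free Rand index between called operon
    memberships and planted ones, over the loci present in both."""
    truth_label = {}
    for i, members in enumerate(truth_operons):
        for locus in members:
            truth_label[locus] = i
    call_label = {}
    for i, op in enumerate(called):
        for c in op.members:
            call_label[c.locus] = i
    loci = sorted(set(truth_label) & set(call_label))
    n = len(loci)
    if n < 2:
        return 1.0
    agree = 0
    total = 0
    for i in range(n):
        for j in range(i + 1, n):
            same_t = truth_label[loci[i]] == truth_label[loci[j]]
            same_c = call_label[loci[i]] == call_label[loci[j]]
            agree += same_t == same_c
            total += 1
    return agree / total
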