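"""Start-codon calling and CDS map refinement.

The mapper works stop-anchored: a CDS's stop codon and reading frame are
the trustworthy part of an existing annotation, so start codons are
re-called by walking upstream in-frame from the stop and asking which
candidate codon the ribosome-footprint density supports.  A candidate
qualifies when

* its downstream window carries more than ``min_density_ratio`` (default
  1/20) of the gene-body footprint density,
* footprint coverage is continual from the candidate to the stop (no gap
  longer than ``gap_tol``), and
* coverage actually begins at the candidate (first covered nucleotide
  within ``onset_tol`` of it) — or, for leaderless mRNAs, a TSS coincides
  with the candidate and the center-weighted footprints begin 12-18 nt
  downstream, the shorter-footprint signature of a 5'-end-bound ribosome.

The most upstream qualifying candidate wins; of two adjacent qualifying
candidates the upstream one is kept.  Candidates are tried in tiers:
canonical {ATG, GTG, TTG, CTG} first; single 2nd/3rd-position mismatches
of ATG and then double mismatches only where an N-terminal tryptic
peptide anchors the codon.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_io import (
    AnnotationRecord,
    DensityTrack,
    Genome,
    Peptide,
    TSSRecord,
)

__all__ = [
    "StartCallParams",
    "CDSRecord",
    "CANONICAL_STARTS",
    "NEAR_COGNATE_STARTS",
    "peptide_start_anchors",
    "map_start_codon",
    "discover_new_cds",
    "prune_conflicting_cds",
    "detect_leaderless",
    "internal_starts",
    "map_all_starts",
]

CANONICAL_STARTS = ("ATG", "GTG", "TTG", "CTG")
# single mismatches of ATG at the 2nd or 3rd codon position
NEAR_COGNATE_STARTS = ("AAG", "ACG", "AGG", "ATA", "ATC", "ATT")
_STOPS = ("TAA", "TAG", "TGA")


@dataclass(frozen=True)
class StartCallParams:
    """Tunables of the start-codon density rules."""

    min_density_ratio: float = 0.05  # the ">1/20 of body density" rule
    density_window: int = 15  # nt downstream of the candidate
    gap_tol: int = 30  # longest tolerated zero-coverage run, nt
    onset_tol: int = 2  # coverage must begin within this many nt of the start
    leaderless_onset: tuple = (6, 20)  # onset window for TSS-rescued starts
    max_upstream_codons: int = 1000  # search bound upstream from the stop
    coverage_floor: float = 0.0  # a nucleotide is 'covered' when density > floor


@dataclass
class CDSRecord:
    """A called coding region.

    ``left``/``right`` bound the CDS on the forward strand (1-based,
    inclusive, start codon first nt through stop codon last nt);
    ``start_pos`` is the biological first nucleotide of the start codon.
    """

    locus: str
    left: int
    right: int
    strand: str
    start_codon: str
    start_class: str = "canonical"  # canonical | near_cognate | double_mismatch
    evidence: set = field(default_factory=set)
    mean_density: float = 0.0
    provenance: str = "original"  # original | corrected | new
    unresolved: bool = False
    utr5: int | None = None
    leaderless: bool = False

    @property
    def start_pos(self) -> int:
        return self.left if self.strand == "+" else self.right

    @property
    def stop_end(self) -> int:
        return self.right if self.strand == "+" else self.left

    @property
    def length(self) -> int:
        return self.right - self.left + 1

    def to_annotation(self) -> AnnotationRecord:
        return AnnotationRecord(
            locus=self.locus, start=self.left, end=self.right,
            strand=self.strand, feature="CDS",
            attrs={
                "start_codon": self.start_codon,
                "start_class": self.start_class,
                "leaderless": str(self.leaderless).lower(),
                "evidence": self.evidence,
                "provenance": self.provenance,
            },
        )


# ---------------------------------------------------------------------------
# peptide anchors


def peptide_start_anchors(peptides: list, annotation=None,
                          min_len_aa: int = 20) -> dict:
    """Codon indices anchored by N-terminal-like tryptic peptides.

    A peptide anchors a start when it is longer than ``min_len_aa`` amino
    acids and its preceding residue is not Arg/Lys (so it cannot be an
    ordinary trypsin product).  A peptide at codon 1 whose upstream
    residue is the initiator Met is the product of fMet cleavage and
    anchors codon 0.  Returns {cds_id: sorted list of anchored codon
    indices}; unmapped peptides are skipped.
    """
    anchors: dict[str, set] = {}
    for pep in peptides:
        if pep.cds_id is None:
            continue
        if len(pep.sequence) <= min_len_aa:
            continue
        if pep.preceding_residue in ("R", "K"):
            continue
        idx = pep.codon_offset
        if idx == 1 and pep.preceding_residue == "M":
            idx = 0  # fMet-cleaved N-terminus anchors the initiator codon
        anchors.setdefault(pep.cds_id, set()).add(idx)
    return {k: sorted(v) for k, v in anchors.items()}


# ---------------------------------------------------------------------------
# start-codon walk


def _sense_pos(pos: int, k: int, strand: str) -> int:
    """Genomic position k nt downstream (3'-ward) of pos on the strand."""
    return pos + k if strand == "+" else pos - k


def _codon(genome: Genome, first_nt: int, strand: str) -> str:
    if strand == "+":
        return genome.fetch(first_nt, first_nt + 2, "+")
    return genome.fetch(first_nt - 2, first_nt, "-")


def _sense_slice(arr: np.ndarray, pos: int, length: int, strand: str,
                 n: int) -> np.ndarray:
    """Density over [pos, pos+length) in sense orientation, clipped to the
    genome."""
    if strand == "+":
        lo, hi = pos, pos + length - 1
        lo, hi = max(1, lo), min(n, hi)
        return arr[lo - 1 : hi]
    lo, hi = pos - length + 1, pos
    lo, hi = max(1, lo), min(n, hi)
    return arr[lo - 1 : hi][::-1]


def map_start_codon(genome: Genome, ribo: DensityTrack, stop_end: int,
                    strand: str, locus: str = "cds",
                    anchor: int | None = None,
                    tss_positions: set | None = None,
                    params: StartCallParams = StartCallParams(),
                    upstream_limit: int | None = None,
                    annotated_start: int | None = None) -> CDSRecord:
    """Call the start codon of the stop-anchored ORF ending at ``stop_end``.

    ``stop_end`` is the genomic position of the stop codon's last
    nucleotide; ``upstream_limit`` (genomic position) truncates the search
    so it cannot run into an upstream same-strand feature; ``anchor`` is
    an optional peptide-anchored codon index counted from the annotated
    start (requires ``annotated_start``).
    """
    arr = ribo.array(strand)
    n = genome.length
    tss_positions = tss_positions or set()

    # enumerate in-frame codon first-nt positions from the stop upstream
    stop_first = _sense_pos(stop_end, -2, strand)
    codons: list[int] = []  # genomic first-nt, stop codon excluded, upstream order
    p = stop_first
    for _ in range(params.max_upstream_codons):
        p = _sense_pos(p, -3, strand)
        if strand == "+" and (p < 1 or (upstream_limit and p < upstream_limit)):
            break
        if strand == "-" and (p > n or (upstream_limit and p > upstream_limit)):
            break
        if strand == "+" and p + 2 > n:
            break
        if strand == "-" and p - 2 < 1:
            break
        codon = _codon(genome, p, strand)
        if codon in _STOPS:
            break  # left the ORF
        codons.append(p)

    anchor_pos = None
    if anchor is not None and annotated_start is not None:
        anchor_pos = _sense_pos(annotated_start, 3 * anchor, strand)

    def qualifies(pos: int) -> tuple[bool, bool]:
        """(qualifies, used_leaderless_rescue) for a candidate first nt."""
        win = _sense_slice(arr, pos, params.density_window, strand, n)
        stop_dist = abs(stop_end - pos) + 1
        body = _sense_slice(arr, pos, stop_dist, strand, n)
        covered = body > params.coverage_floor
        if not covered.any():
            return False, False
        body_mean = body[covered].mean() if covered.any() else 0.0
        if win.mean() <= params.min_density_ratio * body_mean:
            # the 1/20 rule uses the mean density of the (covered) gene body
            if pos not in tss_positions:
                return False, False
        onset = int(np.argmax(covered))  # distance to first covered nt
        # continual density: no internal zero-run longer than gap_tol
        gaps = _longest_gap(covered)
        if gaps > params.gap_tol:
            return False, False
        if onset <= params.onset_tol:
            return True, False
        if pos in tss_positions and \
                params.leaderless_onset[0] <= onset <= params.leaderless_onset[1]:
            return True, True
        return False, False

    tiers: list[tuple[str, list[int]]] = [("canonical", list(CANONICAL_STARTS))]
    if anchor_pos is not None:
        tiers.append(("near_cognate", list(NEAR_COGNATE_STARTS)))
        tiers.append(("double_mismatch", None))  # any codon at the anchor

    for start_class, allowed in tiers:
        best_plain = None
        best_rescued = None
        search = codons
        if start_class != "canonical":
            # mismatch candidates only at the peptide-anchored codon
            search = [p for p in codons if p == anchor_pos]
        for pos in search:  # upstream order: later entries are more upstream
            codon = _codon(genome, pos, strand)
            if allowed is not None and codon not in allowed:
                continue
            if start_class != "canonical" and pos != anchor_pos:
                continue
            ok, rescue = qualifies(pos)
            if ok:
                if rescue:
                    best_rescued = pos
                else:
                    best_plain = pos
        # most upstream wins — except that a TSS-rescued candidate loses to
        # a plain candidate sitting at the very coverage onset the rescue
        # points to: there, leadered initiation at the onset explains the
        # data without invoking the rarer leaderless mechanism
        if best_plain is None or best_rescued is None:
            best = best_plain if best_rescued is None else best_rescued
            best_rescue = best_plain is None and best_rescued is not None
        else:
            d = (best_plain - best_rescued) if strand == "+" \
                else (best_rescued - best_plain)
            span = abs(stop_end - best_rescued) + 1
            resc_body = _sense_slice(arr, best_rescued, span, strand, n)
            resc_onset = int(np.argmax(resc_body > params.coverage_floor))
            if d > 0 and abs(d - resc_onset) <= params.onset_tol:
                best, best_rescue = best_plain, False
            elif d > 0:
                best, best_rescue = best_rescued, True
            else:
                best, best_rescue = best_plain, False
        if best is not None:
            left = min(best, stop_end)
            right = max(best, stop_end)
            body = _sense_slice(arr, best, abs(stop_end - best) + 1, strand, n)
            ev = {"ribo_density"}
            if anchor_pos is not None:
                ev.add("peptide_anchor")
            if best_rescue:
                ev.add("leaderless")
            return CDSRecord(
                locus=locus, left=left, right=right, strand=strand,
                start_codon=_codon(genome, best, strand),
                start_class=start_class, evidence=ev,
                mean_density=float(body.mean()),
            )

    # no qualifying candidate: keep the annotated extent, flagged
    fallback = annotated_start if annotated_start is not None else stop_first
    left, right = min(fallback, stop_end), max(fallback, stop_end)
    return CDSRecord(
        locus=locus, left=left, right=right, strand=strand,
        start_codon=_codon(genome, fallback, strand) if 3 <= fallback <= n - 2
        else "NNN",
        evidence=set(), unresolved=True,
    )


def _longest_gap(covered: np.ndarray) -> int:
    """Longest internal run of uncovered positions (leading/trailing runs
    are handled by the onset rules, not the gap rule)."""
    idx = np.flatnonzero(covered)
    if len(idx) < 2:
        return 0
    return int(np.max(np.diff(idx)) - 1)


# ---------------------------------------------------------------------------
# whole-annotation driver


def map_all_starts(genome: Genome, ribo: DensityTrack, annotation: list,
                   peptides: list | None = None,
                   tss_list: list | None = None,
                   params: StartCallParams = StartCallParams()) -> list:
    """Re-call the start codon of every annotated CDS.

    The upstream search of each CDS is bounded by the 3' end of the
    nearest upstream same-strand feature, so calls cannot run into a
    neighbouring gene of the same operon.
    """
    anchors = peptide_start_anchors(peptides or [])
    tss_pos = {
        (t.position, t.strand) for t in (tss_list or [])
    }
    cds_records = [r for r in annotation if r.feature == "CDS"]
    by_strand = {
        s: sorted((r for r in cds_records if r.strand == s), key=lambda r: r.start)
        for s in "+-"
    }
    out = []
    for strand, recs in by_strand.items():
        for i, rec in enumerate(recs):
            if strand == "+":
                stop_end = rec.end
                annotated_start = rec.start
                limit = recs[i - 1].end + 1 if i > 0 else None
            else:
                stop_end = rec.start
                annotated_start = rec.end
                limit = recs[i + 1].start - 1 if i + 1 < len(recs) else None
            gene_anchor = min(anchors[rec.locus]) if rec.locus in anchors else None
            called = map_start_codon(
                genome, ribo, stop_end, strand, locus=rec.locus,
                anchor=gene_anchor,
                tss_positions={p for p, s in tss_pos if s == strand},
                params=params, upstream_limit=limit,
                annotated_start=annotated_start,
            )
            if not called.unresolved and called.start_pos != annotated_start:
                called.provenance = "corrected"
            called.evidence |= rec.attrs.get("evidence", set())
            out.append(called)
    return sorted(out, key=lambda r: r.left)


# ---------------------------------------------------------------------------
# new CDS discovery


def discover_new_cds(ribo: DensityTrack, annotation: list, genome: Genome,
                     min_block_mean: float = 1.0,
                     f_in: float = 0.9,
                     min_codons: int = 10,
                     params: StartCallParams = StartCallParams()) -> list:
    """Find unannotated CDSs in intergenic ribosome density.

    Contiguous intergenic density blocks (internal gaps up to ``gap_tol``
    bridged) are intersected with start->stop ORFs on the block's strand;
    a block becomes a new CDS only when at least ``f_in`` of its footprint
    mass lies strictly inside one ORF — density crossing a stop codon into
    another frame disqualifies it.
    """
    n = genome.length
    occupied = np.zeros(n, bool)
    for rec in annotation:
        occupied[rec.start - 1 : rec.end] = True
    out = []
    for strand in "+-":
        arr = ribo.array(strand)
        free = (~occupied) & (arr > 0)
        blocks = _merge_blocks(np.flatnonzero(free), gap=params.gap_tol)
        for lo, hi in blocks:  # 0-based inclusive indices
            block = arr[lo : hi + 1]
            if block.mean() < min_block_mean or block.sum() <= 0:
                continue
            orf = _best_orf(genome, strand, lo + 1, hi + 1, min_codons, params, arr)
            if orf is None:
                continue
            left, right, start_pos, start_codon = orf
            # a real new CDS, not the unmasked fringe of an annotated gene
            if occupied[left - 1 : right].mean() > 0.2:
                continue
            if (hi - lo + 1) < 0.5 * (right - left + 1):
                continue
            inside = arr[left - 1 : right].sum()
            if inside < f_in * block.sum():
                continue
            body = ribo.slice(left, right, strand)
            out.append(CDSRecord(
                locus=f"new_{strand}{left}", left=left, right=right,
                strand=strand, start_codon=start_codon,
                evidence={"ribo_density", "new"}, provenance="new",
                mean_density=float(body.mean()),
            ))
    return sorted(out, key=lambda r: r.left)


def _merge_blocks(idx: np.ndarray, gap: int) -> list:
    if len(idx) == 0:
        return []
    out = []
    start = prev = idx[0]
    for i in idx[1:]:
        if i - prev > gap + 1:
            out.append((start, prev))
            start = i
        prev = i
    out.append((start, prev))
    return out


def _best_orf(genome: Genome, strand: str, lo: int, hi: int, min_codons: int,
              params: StartCallParams, arr: np.ndarray):
    """The ORF (start->stop, >= min_codons) that best explains a density
    block, with its start called by the usual onset rule."""
    n = genome.length
    pad = 3 * min_codons
    best = None
    search_lo, search_hi = max(1, lo - pad), min(n, hi + pad)
    if strand == "+":
        for frame in range(3):
            p = search_lo + frame
            while p + 2 <= min(search_hi + 60, n):
                codon = genome.fetch(p, p + 2, "+")
                if codon in _STOPS and p > lo:
                    # stop downstream of the block start: try this ORF
                    rec = map_start_codon(
                        genome, DensityTrackView(arr, strand, n), p + 2, "+",
                        params=params)
                    if not rec.unresolved and rec.length >= 3 * min_codons \
                            and rec.left <= hi:
                        cover = arr[rec.left - 1 : rec.right].sum()
                        if best is None or cover > best[-1]:
                            best = (rec.left, rec.right, rec.start_pos,
                                    rec.start_codon, cover)
                    if p > hi:
                        break
                p += 3
    else:
        for frame in range(3):
            p = search_hi - frame
            while p - 2 >= max(search_lo - 60, 1):
                codon = genome.fetch(p - 2, p, "-")
                if codon in _STOPS and p < hi:
                    rec = map_start_codon(
                        genome, DensityTrackView(arr, strand, n), p - 2, "-",
                        params=params)
                    if not rec.unresolved and rec.length >= 3 * min_codons \
                            and rec.right >= lo:
                        cover = arr[rec.left - 1 : rec.right].sum()
                        if best is None or cover > best[-1]:
                            best = (rec.left, rec.right, rec.start_pos,
                                    rec.start_codon, cover)
                    if p < lo:
                        break
                p -= 3
    if best is None:
        return None
    return best[:4]


class DensityTrackView:
    """A single-strand adapter so ORF scoring can reuse map_start_codon."""

    def __init__(self, arr: np.ndarray, strand: str, length: int) -> None:
        self._arr = arr
        self._strand = strand
        self.length = length

    def array(self, strand: str) -> np.ndarray:
        if strand == self._strand:
            return self._arr
        return np.zeros(self.length)


# ---------------------------------------------------------------------------
# pruning


def prune_conflicting_cds(annotation: list, ribo: DensityTrack,
                          overlap_frac: float = 0.5) -> dict:
    """Flag annotation records that the footprint data contradict.

    Returns {locus: set of flags}: ``strand_corrected`` when antisense
    footprint mass over the record exceeds sense mass; ``deleted`` when a
    hypothetical CDS overlaps an opposite-strand CDS or a tRNA by more
    than ``overlap_frac`` of the shorter feature.
    """
    flags: dict[str, set] = {rec.locus: set() for rec in annotation}
    for rec in annotation:
        if rec.feature != "CDS":
            continue
        sense = ribo.array(rec.strand)[rec.start - 1 : rec.end].sum()
        anti_strand = "-" if rec.strand == "+" else "+"
        anti = ribo.array(anti_strand)[rec.start - 1 : rec.end].sum()
        if anti > sense:
            flags[rec.locus].add("strand_corrected")
    for rec in annotation:
        if rec.feature != "CDS" or not rec.hypothetical:
            continue
        for other in annotation:
            if other.locus == rec.locus:
                continue
            opposite_cds = other.feature == "CDS" and other.strand != rec.strand
            trna = other.feature == "tRNA"
            if not (opposite_cds or trna):
                continue
            ov = min(rec.end, other.end) - max(rec.start, other.start) + 1
            shorter = min(rec.length, other.length)
            if ov > overlap_frac * shorter:
                flags[rec.locus].add("deleted")
                break
    return flags


# ---------------------------------------------------------------------------
# leaderless detection


def detect_leaderless(cds: CDSRecord, tss_list: list, rna_5p: DensityTrack,
                      ribo: DensityTrack,
                      peptide_anchors: dict | None = None,
                      tol: int = 0,
                      onset_range: tuple = (6, 20),
                      peak_k: float = 5.0) -> tuple[bool, dict]:
    """Decide whether a CDS sits on a leaderless mRNA.

    Requires (a) a TSS — or a dominant RNA-seq 5'-end peak — coinciding
    with the first nucleotide of the start codon (within ``tol`` nt), and
    (b) corroboration: an N-terminal peptide anchor at codon 0, or
    center-weighted footprints that begin 12-18 nt into the CDS, the
    signature of ribosomes loaded at an mRNA 5' end.
    """
    start = cds.start_pos
    evidence: dict = {}
    tss_hit = any(
        t.strand == cds.strand and abs(t.position - start) <= tol
        for t in tss_list
    )
    evidence["tss_at_start"] = tss_hit
    peak_hit = False
    if not tss_hit:
        arr5 = rna_5p.array(cds.strand)
        val = arr5[start - 1]
        lo, hi = max(1, cds.left - 50), min(rna_5p.length, cds.right + 50)
        neighborhood = arr5[lo - 1 : hi]
        background = np.median(neighborhood[neighborhood > 0]) \
            if (neighborhood > 0).any() else 0.0
        peak_hit = background > 0 and val > peak_k * background
        evidence["rna5p_peak_at_start"] = peak_hit
    if not (tss_hit or peak_hit):
        return False, evidence

    anchors = (peptide_anchors or {}).get(cds.locus, [])
    anchor_hit = 0 in anchors or 1 in anchors
    evidence["peptide_anchor"] = anchor_hit
    body = ribo.slice(cds.left, cds.right, cds.strand)
    covered = body > 0
    onset = int(np.argmax(covered)) if covered.any() else None
    evidence["footprint_onset"] = onset
    onset_hit = onset is not None and onset_range[0] <= onset <= onset_range[1]
    return bool(anchor_hit or onset_hit), evidence


# ---------------------------------------------------------------------------
# internal alternative starts


def internal_starts(peptides: list, cds_set: list, genome: Genome) -> list:
    """Alternative (internal) start codons evidenced by peptides.

    A peptide whose N-terminal residue maps to an internal in-frame ATG
    (or the codon after it, for fMet-cleaved products) and whose upstream
    residue is not Arg/Lys marks an internal initiation site.  Only ATG
    is accepted for internal starts.
    """
    by_locus = {c.locus: c for c in cds_set}
    out = []
    seen = set()
    for pep in peptides:
        if pep.cds_id not in by_locus or pep.tryptic_internal:
            continue
        cds = by_locus[pep.cds_id]
        n_codons = cds.length // 3
        for idx in (pep.codon_offset, pep.codon_offset - 1):
            if idx < 2 or idx >= n_codons - 1:
                continue  # offsets 0/1 are the primary start, not internal
            first_nt = _sense_pos(cds.start_pos, 3 * idx, cds.strand)
            if _codon(genome, first_nt, cds.strand) == "ATG":
                key = (cds.locus, idx)
                if key not in seen:
                    seen.add(key)
                    out.append({"locus": cds.locus, "codon_index": idx,
                                "position": first_nt, "peptide": pep.sequence})
                break
    return out
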