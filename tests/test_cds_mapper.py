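"""Start-codon calling, discovery, pruning, leaderless and internal starts."""

import numpy as np
import pytest

from ribarch.core_io import (
    AnnotationRecord,
    DensityTrack,
    Genome,
    Peptide,
    TSSRecord,
)
from ribarch.cds_mapper import (
    StartCallParams,
    detect_leaderless,
    discover_new_cds,
    internal_starts,
    map_all_starts,
    map_start_codon,
    peptide_start_anchors,
    prune_conflicting_cds,
)


# --------------------------------------------------------------------------
# peptide anchors


def test_anchor_requires_length_and_no_upstream_kr():
    long_pep = "A" * 25
    peps = [
        Peptide(long_pep, "g1", 30, "K"),   # ordinary tryptic product
        Peptide(long_pep, "g2", 30, "G"),   # anchor
        Peptide("A" * 15, "g3", 30, "G"),   # too short
        Peptide(long_pep, None, 30, "G"),   # unmapped
    ]
    anchors = peptide_start_anchors(peps)
    assert anchors == {"g2": [30]}


def test_fmet_cleaved_peptide_anchors_initiator_codon():
    peps = [Peptide("A" * 25, "g1", 1, "M")]
    assert peptide_start_anchors(peps) == {"g1": [0]}


# --------------------------------------------------------------------------
# map_start_codon on constructed genomes


def _orf_genome(upstream, codons, downstream="", strand="+"):
    """Linear genome holding one ORF; returns (genome, stop_end, cds_span)."""
    body = "".join(codons)
    seq = upstream + body + downstream
    left = len(upstream) + 1
    right = len(upstream) + len(body)
    from ribarch.core_io import revcomp

    if strand == "-":
        seq = revcomp(seq)
        n = len(seq)
        left, right = n - right + 1, n - left + 1
    g = Genome(id="t", sequence=seq, circular=False)
    stop_end = right if strand == "+" else left
    return g, stop_end, (left, right)


def _uniform_track(n, left, right, strand, value=20.0):
    track = DensityTrack(n, "ribo")
    track.array(strand)[left - 1 : right] = value
    return track


NEUTRAL = "CCC"  # codes Pro; never a start or stop


def test_uniform_coverage_calls_the_planted_atg():
    codons = ["ATG"] + [NEUTRAL] * 20 + ["TAA"]
    g, stop_end, (left, right) = _orf_genome("A" * 60, codons)
    ribo = _uniform_track(g.length, left, right, "+")
    rec = map_start_codon(g, ribo, stop_end, "+")
    assert rec.start_pos == left
    assert rec.start_codon == "ATG"
    assert rec.start_class == "canonical"


def test_upstream_atg_without_coverage_loses_to_covered_gtg():
    """An in-frame ATG upstream of where footprints begin fails the density
    rules; the GTG at the coverage onset is called instead."""
    codons = ["ATG"] + [NEUTRAL] * 17 + ["GTG"] + [NEUTRAL] * 20 + ["TAA"]
    g, stop_end, (left, right) = _orf_genome("A" * 60, codons)
    gtg_pos = left + 18 * 3
    ribo = _uniform_track(g.length, gtg_pos, right, "+")
    rec = map_start_codon(g, ribo, stop_end, "+")
    assert rec.start_pos == gtg_pos
    assert rec.start_codon == "GTG"


def test_adding_upstream_coverage_never_moves_call_downstream():
    codons = ["ATG"] + [NEUTRAL] * 17 + ["GTG"] + [NEUTRAL] * 20 + ["TAA"]
    g, stop_end, (left, right) = _orf_genome("A" * 60, codons)
    gtg_pos = left + 18 * 3
    partial = _uniform_track(g.length, gtg_pos, right, "+")
    full = _uniform_track(g.length, left, right, "+")
    call_partial = map_start_codon(g, partial, stop_end, "+")
    call_full = map_start_codon(g, full, stop_end, "+")
    assert call_full.start_pos <= call_partial.start_pos  # moved upstream
    assert call_full.start_codon == "ATG"


def test_double_mismatch_gtc_needs_peptide_anchor():
    codons = ["GTC"] + [NEUTRAL] * 20 + ["TAA"]
    g, stop_end, (left, right) = _orf_genome("A" * 60, codons)
    ribo = _uniform_track(g.length, left, right, "+")
    no_anchor = map_start_codon(g, ribo, stop_end, "+")
    assert no_anchor.unresolved or no_anchor.start_codon != "GTC"
    with_anchor = map_start_codon(g, ribo, stop_end, "+",
                                  anchor=0, annotated_start=left)
    assert with_anchor.start_pos == left
    assert with_anchor.start_codon == "GTC"
    assert with_anchor.start_class == "double_mismatch"
    assert "peptide_anchor" in with_anchor.evidence


def test_minus_strand_call_mirrors_plus():
    codons = ["ATG"] + [NEUTRAL] * 20 + ["TAA"]
    g, stop_end, (left, right) = _orf_genome("A" * 60, codons, strand="-")
    ribo = _uniform_track(g.length, left, right, "-")
    rec = map_start_codon(g, ribo, stop_end, "-")
    assert rec.start_pos == right
    assert rec.start_codon == "ATG"


def test_leaderless_rescue_requires_tss_and_delayed_onset():
    codons = ["ATG"] + [NEUTRAL] * 20 + ["TAA"]
    g, stop_end, (left, right) = _orf_genome("A" * 60, codons)
    ribo = DensityTrack(g.length, "ribo")
    ribo.plus[left - 1 + 15 : right] = 20.0  # onset 15 nt into the CDS
    without_tss = map_start_codon(g, ribo, stop_end, "+")
    assert without_tss.start_pos != left
    with_tss = map_start_codon(g, ribo, stop_end, "+", tss_positions={left})
    assert with_tss.start_pos == left
    assert "leaderless" in with_tss.evidence


# --------------------------------------------------------------------------
# planted-truth recovery


def test_start_recovery_on_planted_bundle(bundle150, called150):
    truth = {g.locus: g for g in bundle150.truth.genes}
    hits = sum(
        1 for c in called150
        if c.locus in truth and c.start_pos == truth[c.locus].start_pos
        and c.strand == truth[c.locus].strand
    )
    assert hits / len(called150) >= 0.95
    for c in called150:
        if not c.unresolved:
            assert c.length % 3 == 0
            last = bundle150.genome.fetch(c.left, c.right, c.strand)[-3:]
            assert last in ("TAA", "TAG", "TGA")


# --------------------------------------------------------------------------
# new-CDS discovery


def test_discovery_recovers_unannotated_small_orfs(bundle150):
    small = [g for g in bundle150.truth.genes if g.is_small]
    assert small, "bundle should plant small ORFs"
    found = discover_new_cds(bundle150.ribo, bundle150.annotation,
                             bundle150.genome)
    found_spans = {(c.left, c.right, c.strand) for c in found}
    exact = sum((g.left, g.right, g.strand) in found_spans for g in small)
    assert exact >= 0.8 * len(small)
    for c in found:
        assert c.provenance == "new"


def test_discovery_rejects_density_crossing_a_stop():
    """A density block continuing across a stop codon into another frame
    is not 'strictly within start-to-stop' and must be rejected."""
    codons = ["ATG"] + [NEUTRAL] * 12 + ["TAA"]
    g, stop_end, (left, right) = _orf_genome(
        "A" * 120, codons, downstream="A" * 120)
    ribo = DensityTrack(g.length, "ribo")
    # block spills 40 nt past the stop codon
    ribo.plus[left - 1 : right + 40] = 10.0
    found = discover_new_cds(ribo, [], g)
    assert found == []


def test_discovery_empty_without_intergenic_density(bundle150):
    empty = DensityTrack(bundle150.genome.length, "ribo")
    assert discover_new_cds(empty, bundle150.annotation, bundle150.genome) == []


# --------------------------------------------------------------------------
# pruning


def test_prune_flags_wrong_strand_and_spurious_hypotheticals(bundle150):
    flags = prune_conflicting_cds(bundle150.annotation, bundle150.ribo)
    truth = {g.locus: g for g in bundle150.truth.genes}
    for rec in bundle150.annotation:
        f = flags[rec.locus]
        if rec.hypothetical:
            assert "deleted" in f
        elif rec.locus in truth and rec.strand != truth[rec.locus].strand:
            assert "strand_corrected" in f
        elif rec.locus in truth:
            assert "strand_corrected" not in f and "deleted" not in f


def test_prune_deletes_mostly_overlapped_hypothetical():
    ribo = DensityTrack(2000, "ribo")
    ribo.plus[99:1000] = 10.0
    ann = [
        AnnotationRecord("real", 100, 1000, "+", "CDS"),
        AnnotationRecord("hyp", 300, 550, "-", "CDS", hypothetical=True),
    ]
    flags = prune_conflicting_cds(ann, ribo)
    assert "deleted" in flags["hyp"]
    assert "deleted" not in flags["real"]


# --------------------------------------------------------------------------
# leaderless


def test_leaderless_detection_on_planted_genes(bundle150, called150,
                                               anchors150):
    truth = {g.locus: g for g in bundle150.truth.genes}
    called_ll = set()
    for c in called150:
        ok, _ = detect_leaderless(c, bundle150.tss, bundle150.rna_5p,
                                  bundle150.ribo, anchors150)
        if ok:
            called_ll.add(c.locus)
    true_ll = {g.locus for g in bundle150.truth.genes if g.leaderless}
    tp = len(called_ll & true_ll)
    assert tp / max(len(called_ll), 1) >= 0.95  # precision
    # zero false positives among genes with a real 5' UTR of >= 15 nt
    for locus in called_ll - true_ll:
        utr = truth[locus].utr5
        assert utr is None or utr < 15


def test_tss_far_upstream_is_not_leaderless():
    codons = ["ATG"] + [NEUTRAL] * 20 + ["TAA"]
    g, stop_end, (left, right) = _orf_genome("A" * 60, codons)
    from ribarch.cds_mapper import CDSRecord

    cds = CDSRecord("g", left, right, "+", "ATG")
    ribo = _uniform_track(g.length, left, right, "+")
    fivep = DensityTrack(g.length, "rna_5p")
    ok, _ = detect_leaderless(cds, [TSSRecord(left - 25, "+", 5)], fivep, ribo)
    assert not ok


def test_tss_at_start_but_immediate_onset_is_not_leaderless():
    codons = ["ATG"] + [NEUTRAL] * 20 + ["TAA"]
    g, stop_end, (left, right) = _orf_genome("A" * 60, codons)
    from ribarch.cds_mapper import CDSRecord

    cds = CDSRecord("g", left, right, "+", "ATG")
    ribo = _uniform_track(g.length, left, right, "+")  # onset 0
    fivep = DensityTrack(g.length, "rna_5p")
    ok, ev = detect_leaderless(cds, [TSSRecord(left, "+", 5)], fivep, ribo)
    assert ev["tss_at_start"] and not ok


# --------------------------------------------------------------------------
# internal starts


def test_internal_starts_recovered_from_bundle(bundle150, called150):
    planted = {(g.locus, g.internal_start_codon)
               for g in bundle150.truth.genes
               if g.internal_start_codon is not None}
    assert planted, "bundle should plant internal starts"
    found = {(a["locus"], a["codon_index"])
             for a in internal_starts(bundle150.peptides, called150,
                                      bundle150.genome)}
    assert planted <= found


def test_internal_start_rules():
    codons = ["ATG"] + [NEUTRAL] * 9 + ["ATG"] + [NEUTRAL] * 4 + ["GTG"] \
        + [NEUTRAL] * 5 + ["TAA"]
    g, stop_end, (left, right) = _orf_genome("A" * 30, codons)
    from ribarch.cds_mapper import CDSRecord

    cds = CDSRecord("g", left, right, "+", "ATG")
    ok = Peptide("P" * 10, "g", 10, "G")       # internal ATG, clean N-term
    after_k = Peptide("P" * 10, "g", 10, "K")  # tryptic product: excluded
    at_gtg = Peptide("P" * 10, "g", 15, "G")   # GTG: not accepted internally
    found = internal_starts([ok, after_k, at_gtg], [cds], g)
    assert [(a["locus"], a["codon_index"]) for a in found] == [("g", 10)]
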