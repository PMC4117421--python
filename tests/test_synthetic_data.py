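"""The generator: determinism, planted statistics, channel construction."""

import math

import numpy as np
import pytest

from ribarch.core_io import compute_gc
from ribarch.synthetic_data import (
    PlantedGene,
    SimulationConfig,
    Truth,
    simulate_bundle,
    simulate_genome,
    simulate_peptides,
    simulate_ribo_track,
    simulate_rna_tracks,
)


def test_fixed_seed_reproduces_everything(bundle150):
    again = simulate_bundle(bundle150.config, seed=1)
    assert again.genome.sequence == bundle150.genome.sequence
    assert np.array_equal(again.ribo.plus, bundle150.ribo.plus)
    assert np.array_equal(again.rna_5p.minus, bundle150.rna_5p.minus)
    assert [p.sequence for p in again.peptides] == \
        [p.sequence for p in bundle150.peptides]
    assert [(t.position, t.strand) for t in again.tss] == \
        [(t.position, t.strand) for t in bundle150.tss]


def test_genome_gc_matches_config():
    cfg = SimulationConfig(n_genes=50, genome_length=200_000, ncrna_count=0)
    genome, _ = simulate_genome(cfg, seed=2)
    assert genome.length == 200_000
    assert compute_gc(genome) == pytest.approx(0.6717, abs=0.01)


def test_genome_length_capacity_error():
    with pytest.raises(ValueError, match="too short"):
        simulate_genome(SimulationConfig(n_genes=100, genome_length=5000), 1)


def test_start_codon_mix_recovered():
    """Planted start codons follow the configured usage (74.3% ATG).

    Pooling 3000 genes keeps the Monte-Carlo error near 0.8 pp, so the
    3-pp band is a comfortable >3.5-sigma binomial check.
    """
    fracs = []
    for seed in (3, 4, 5):
        cfg = SimulationConfig(n_genes=1000, ncrna_count=0)
        _, truth = simulate_genome(cfg, seed=seed)
        fracs.append(sum(g.start_codon == "ATG" for g in truth.genes) / 1000)
    assert np.mean(fracs) == pytest.approx(0.743, abs=0.03)


def test_leaderless_fraction_recovered():
    cfg = SimulationConfig(n_genes=800, ncrna_count=0)
    _, truth = simulate_genome(cfg, seed=4)
    n_t = len(truth.transcripts)
    n_ll = sum(1 for t in truth.transcripts
               if truth.gene(t.members[0]).leaderless)
    p = 0.096
    sd = math.sqrt(p * (1 - p) / n_t)
    assert n_ll / n_t == pytest.approx(p, abs=3.5 * sd)


def test_truth_internally_consistent(bundle150):
    truth = bundle150.truth
    t_index = {t.id: t for t in truth.transcripts}
    for g in truth.genes:
        t = t_index[g.transcript_id]
        assert t.left <= g.left and g.right <= t.right and t.strand == g.strand
        if g.leaderless:
            assert g.utr5 == 0
            assert t.tss == g.start_pos
        body = bundle150.genome.fetch(g.left, g.right, g.strand)
        assert len(body) % 3 == 0
        assert body[:3] == g.start_codon
        assert body[-3:] in ("TAA", "TAG", "TGA")
        internal = [body[i : i + 3] for i in range(3, len(body) - 3, 3)]
        assert not any(c in ("TAA", "TAG", "TGA") for c in internal)


# --------------------------------------------------------------------------
# footprint track


def _one_gene_bundle(**kw):
    cfg = SimulationConfig(
        n_genes=1, ncrna_count=0, leaderless_fraction=0.0,
        small_orf_fraction=0.0, start_misannotation_fraction=0.0,
        wrong_strand_n=0, spurious_hypothetical_n=0,
        internal_start_fraction=0.0, **kw)
    genome, truth = simulate_genome(cfg, seed=5)
    return cfg, genome, truth


def test_noise_free_profile_is_flat_with_peaks():
    cfg, genome, truth = _one_gene_bundle(nb_dispersion=0.0, sd_pause_beta=0.0)
    track = simulate_ribo_track(genome, truth, cfg, seed=1)
    g = truth.genes[0]
    body = track.slice(g.left, g.right, g.strand)
    w = cfg.peak_width
    rate = g.ribo_rate
    assert np.allclose(body[:w], rate * cfg.start_peak_multiplier)
    assert np.allclose(body[-w:], rate * cfg.stop_peak_multiplier)
    assert np.allclose(body[w:-w], rate)
    # no footprint density outside the CDS
    assert track.total_mass() == pytest.approx(body.sum())


def test_pause_multipliers_follow_boltzmann_link():
    """Planted pause strength is exp(-beta * dG), so two sites differing
    in dG differ in multiplier by the closed-form ratio."""
    cfg = SimulationConfig(n_genes=40, ncrna_count=0, sd_pause_beta=0.3)
    _, truth = simulate_genome(cfg, seed=6)
    assert truth.pause_sites, "GC-rich coding sequence should contain SD-like sites"
    for site in truth.pause_sites:
        assert site.multiplier == pytest.approx(math.exp(-0.3 * site.dG))
        assert site.dG < -4.4
    a, b = truth.pause_sites[0], truth.pause_sites[1]
    assert a.multiplier / b.multiplier == pytest.approx(
        math.exp(-0.3 * (a.dG - b.dG)))


def test_pause_visible_in_noise_free_track():
    cfg, genome, truth = _one_gene_bundle(nb_dispersion=0.0)
    track = simulate_ribo_track(genome, truth, cfg, seed=1)
    g = truth.genes[0]
    body = track.slice(g.left, g.right, g.strand)
    for site in truth.pause_sites:
        local = (site.position - g.left) if g.strand == "+" \
            else (g.right - site.position)
        if cfg.peak_width <= local < len(body) - cfg.peak_width:
            assert body[local] == pytest.approx(g.ribo_rate * site.multiplier)


def test_leaderless_gene_has_delayed_onset():
    cfg = SimulationConfig(n_genes=30, ncrna_count=0, leaderless_fraction=1.0,
                           nb_dispersion=0.0)
    genome, truth = simulate_genome(cfg, seed=7)
    track = simulate_ribo_track(genome, truth, cfg, seed=1)
    for t in truth.transcripts:
        g = truth.gene(t.members[0])
        body = track.slice(g.left, g.right, g.strand)
        assert np.all(body[: g.leaderless_delay] == 0)
        assert 12 <= g.leaderless_delay <= 18
        assert body[g.leaderless_delay] > 0


def test_track_mass_scales_with_expression():
    cfg, genome, truth = _one_gene_bundle(nb_dispersion=0.0, sd_pause_beta=0.0)
    track1 = simulate_ribo_track(genome, truth, cfg, seed=1)
    for g in truth.genes:
        g.ribo_rate *= 2
    track2 = simulate_ribo_track(genome, truth, cfg, seed=1)
    assert track2.total_mass() == pytest.approx(2 * track1.total_mass())


# --------------------------------------------------------------------------
# RNA tracks


def test_tss_spike_is_multiplier_times_body_rate():
    cfg, genome, truth = _one_gene_bundle(nb_dispersion=0.0,
                                          tss_peak_multiplier=5.0)
    cov, fivep, tss = simulate_rna_tracks(genome, truth, cfg, seed=1)
    t = truth.transcripts[0]
    body_rate = t.level * cfg.rna5p_shear_rate
    at_tss = fivep.array(t.strand)[t.tss - 1]
    assert at_tss == pytest.approx(5.0 * body_rate)
    assert [r.position for r in tss] == [t.tss]


def test_polarity_step_down_in_coverage():
    cfg = SimulationConfig(n_genes=40, ncrna_count=0, nb_dispersion=0.0,
                           polarity_fraction=1.0, polarity_step=10.0,
                           internal_tss_fraction=0.0)
    genome, truth = simulate_genome(cfg, seed=8)
    cov, _, _ = simulate_rna_tracks(genome, truth, cfg, seed=1)
    checked = 0
    for t in truth.transcripts:
        for j in t.polarity_junctions:
            up = truth.gene(t.members[j])
            down = truth.gene(t.members[j + 1])
            up_cov = cov.slice(up.left, up.right, t.strand).mean()
            down_cov = cov.slice(down.left, down.right, t.strand).mean()
            assert up_cov / down_cov == pytest.approx(10.0)
            checked += 1
    assert checked > 0


def test_no_transcripts_zero_tracks():
    cfg = SimulationConfig(n_genes=1, ncrna_count=0)
    genome, truth = simulate_genome(cfg, seed=9)
    empty = Truth(genes=[], transcripts=[], operons=[], ncrnas=[],
                  tss_records=[], pause_sites=[])
    cov, fivep, tss = simulate_rna_tracks(genome, empty, cfg, seed=1)
    assert cov.total_mass() == 0 and fivep.total_mass() == 0 and tss == []


# --------------------------------------------------------------------------
# peptides


def _protein_truth(protein):
    gene = PlantedGene(
        locus="gX", left=1, right=3 * (len(protein) + 1), strand="+",
        start_codon="ATG", codons=len(protein) + 1, operon_id="op",
        transcript_id="t", protein=protein)
    return Truth(genes=[gene], transcripts=[], operons=[], ncrnas=[],
                 tss_records=[], pause_sites=[])


def test_trypsin_cuts_after_k_and_r():
    truth = _protein_truth("MKAAARCCCCCCDDDDDD")
    cfg = SimulationConfig(peptide_detection_prob=1.0, fmet_cleavage_prob=0.0,
                           peptide_min_report_aa=1)
    peps = simulate_peptides(truth, cfg, seed=1)
    assert [(p.sequence, p.codon_offset, p.preceding_residue) for p in peps] == [
        ("MK", 0, None),
        ("AAAR", 2, "K"),
        ("CCCCCCDDDDDD", 6, "R"),
    ]


def test_fmet_cleavage_shifts_nterm_fragment():
    truth = _protein_truth("MKAAAR")
    cfg = SimulationConfig(peptide_detection_prob=1.0, fmet_cleavage_prob=1.0,
                           peptide_min_report_aa=1)
    peps = simulate_peptides(truth, cfg, seed=1)
    assert peps[0].sequence == "K"
    assert peps[0].codon_offset == 1
    assert peps[0].preceding_residue == "M"


def test_detection_probability_binomial():
    protein = "AAAAAK" * 200  # 200 identical 6-aa fragments
    truth = _protein_truth(protein)
    cfg = SimulationConfig(peptide_detection_prob=0.5, fmet_cleavage_prob=0.0,
                           peptide_min_report_aa=1)
    counts = [len(simulate_peptides(truth, cfg, seed=s)) for s in range(20)]
    mean = np.mean(counts)
    # 20 x Binomial(200, .5): SEM ~ 1.6
    assert mean == pytest.approx(100, abs=6)
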