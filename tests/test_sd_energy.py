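"""Anneal-energy model: oracle equivalence, classification and background."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ribarch.core_io import AlphabetError, Genome, revcomp
from ribarch.sd_energy import (
    ASD_SEQUENCE,
    DEFAULT_MODEL,
    SD_CUTOFF,
    classify_sd,
    duplex_dG,
    hexamer_sd_occurrence,
    random_sd_background,
    sliding_sd_profile,
)

# --------------------------------------------------------------------------
# independent oracle: enumerate every (alignment, helix start, helix length)


def oracle_dG(asd, window, model=DEFAULT_MODEL):
    """Brute-force minimum over all contiguous antiparallel helix placements."""
    pairs = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C"),
             ("G", "U"), ("U", "G")}
    weak = {("A", "U"), ("U", "A"), ("G", "U"), ("U", "G")}
    asd = asd.replace("T", "U")
    window = window.replace("T", "U")
    ra = asd[::-1]
    n, m = len(window), len(ra)
    best = 0.0
    for off in range(-(m - 1), n):
        for s in range(max(0, off), min(n, off + m)):
            for e in range(s + model.min_helix - 1, min(n, off + m)):
                placement = [(window[i], ra[i - off]) for i in range(s, e + 1)]
                if any(p not in pairs for p in placement):
                    continue
                g = model.init_penalty
                for i in range(s, e):
                    g += model.stack_dG(window[i], ra[i - off],
                                        window[i + 1], ra[i + 1 - off])
                for p in (placement[0], placement[-1]):
                    if p in weak:
                        g += model.terminal_penalty
                best = min(best, g)
    return best


def test_perfect_complement_is_global_minimum():
    """The aSD's exact reverse complement reaches the deepest dG the model
    allows for an 8-mer window, far below the SD cutoff."""
    perfect = revcomp(ASD_SEQUENCE.replace("U", "T")).replace("T", "U")
    assert perfect == "AGGAGGUG"
    dg = duplex_dG(window=perfect)
    assert dg == pytest.approx(oracle_dG(ASD_SEQUENCE, perfect))
    assert dg < SD_CUTOFF
    rng = np.random.default_rng(0)
    bases = np.array(list("ACGU"))
    for _ in range(300):
        w = "".join(rng.choice(bases, 8))
        assert duplex_dG(window=w) >= dg


def test_no_helix_means_zero():
    assert duplex_dG(window="AAAAAAAA") == 0.0
    # the aSD contains no G, so an all-C window cannot pair at all
    assert duplex_dG(window="CCC") == 0.0
    assert oracle_dG(ASD_SEQUENCE, "CCC") == 0.0


@settings(max_examples=400, derandomize=True, deadline=None)
@given(st.text(alphabet="ACGU", min_size=3, max_size=12))
def test_duplex_matches_oracle_on_random_windows(window):
    assert duplex_dG(window=window) == pytest.approx(
        oracle_dG(ASD_SEQUENCE, window))


def test_extending_helix_never_raises_dG():
    """Growing a Watson-Crick helix monotonically deepens the minimum."""
    perfect = "AGGAGGUG"
    prev = 0.0
    for k in range(3, 9):
        dg = duplex_dG(window=perfect[:k])
        assert dg <= prev
        prev = dg


def test_dna_input_transcribed_and_bad_alphabet_rejected():
    assert duplex_dG(window="AGGAGGTG") == duplex_dG(window="AGGAGGUG")
    with pytest.raises(AlphabetError):
        duplex_dG(window="AGGNGGUG")


# --------------------------------------------------------------------------
# classification


def _genome_with(seq_at, offset, background="A", n=400):
    """Linear genome of `background` with `seq_at` planted so that its 5'
    nt sits `offset` nt upstream of position 201 (the reference start)."""
    seq = list(background * n)
    start = 201
    first = start + offset  # offset negative = upstream
    for i, b in enumerate(seq_at):
        seq[first - 1 + i] = b
    return Genome(id="t", sequence="".join(seq), circular=False), start


def test_classify_sd_detects_planted_site():
    g, start = _genome_with("AGGAGGTG", -12)
    score = classify_sd(g, start, "+")
    assert score.is_sd
    assert score.window_min == pytest.approx(duplex_dG(window="AGGAGGUG"))


def test_classify_sd_leaderless_empty_window():
    g, start = _genome_with("AGGAGGTG", -12)
    assert not classify_sd(g, start, "+", utr5=0).is_sd
    assert not classify_sd(g, start, "+", utr5=4).is_sd


def test_classify_sd_cutoff_is_strict():
    g, start = _genome_with("AGGAGGTG", -12)
    wmin = classify_sd(g, start, "+").window_min
    assert not classify_sd(g, start, "+", cutoff=wmin).is_sd
    assert classify_sd(g, start, "+", cutoff=wmin + 1e-9).is_sd


def test_classify_sd_site_outside_window_not_called():
    g, start = _genome_with("AGGAGGTG", -40)
    assert not classify_sd(g, start, "+").is_sd


def test_classify_sd_strand_symmetric():
    """The same start scored on the reverse-complemented genome at the
    mirrored position gives the identical score."""
    rng = np.random.default_rng(3)
    seq = "".join(rng.choice(list("ACGT"), 500))
    g = Genome(id="f", sequence=seq, circular=False)
    g_rc = Genome(id="r", sequence=revcomp(seq), circular=False)
    start = 260
    fwd = classify_sd(g, start, "+")
    rev = classify_sd(g_rc, len(seq) - start + 1, "-")
    assert fwd.window_min == pytest.approx(rev.window_min)
    assert fwd.is_sd == rev.is_sd


def test_sliding_profile_minimum_at_planted_site():
    g, start = _genome_with("AGGAGGTG", -12)
    prof = sliding_sd_profile(g, start, "+", span=(-60, 60))
    assert prof.positions[np.argmin(prof.track)] == -12
    g0, s0 = _genome_with("", 0)
    flat = sliding_sd_profile(g0, s0, "+", span=(-60, 60))
    assert np.all(flat.track == 0.0)


# --------------------------------------------------------------------------
# Monte-Carlo background


def test_background_reproducible_and_gc_sensitive():
    a = random_sd_background(400, 0.6717, seed=5)
    b = random_sd_background(400, 0.6717, seed=5)
    assert a == b
    assert random_sd_background(400, 0.0, seed=5) == 0.0  # A/U only: no SD


# --------------------------------------------------------------------------
# hexamer occurrence vs affinity


def test_hexamer_occurrence_conserves_window_count():
    rng = np.random.default_rng(1)
    seq = "".join(rng.choice(list("ACGT"), 6000))
    g = Genome(id="h", sequence=seq, circular=False)
    cds = [(101, 2100, "+"), (2501, 4500, "-")]
    table = hexamer_sd_occurrence(g, cds)
    expected_windows = sum(b - a + 1 - 5 for a, b, _ in cds)
    assert table["count"].sum() == expected_windows
    assert table["occurrence"].sum() == pytest.approx(1.0)


def test_hexamer_affinity_uncorrelated_on_iid_genome():
    from scipy.stats import spearmanr

    rng = np.random.default_rng(2)
    p = [0.1654, 0.3346, 0.3346, 0.1654]
    seq = "".join(rng.choice(list("ACGT"), 60000, p=p))
    g = Genome(id="n", sequence=seq, circular=False)
    table = hexamer_sd_occurrence(g, [(1, 60000, "+")])
    sub = table[table["count"] >= 5]
    rho, _ = spearmanr(sub["dG"], sub["normalized_occurrence"])
    assert abs(rho) < 0.1


def test_hexamer_depletion_yields_positive_correlation():
    """A genome whose CDSs were scrubbed of strongly annealing windows
    shows occurrence rising with dG (stronger binding = rarer)."""
    from scipy.stats import spearmanr

    from ribarch.sd_energy import duplex_dG as dg

    rng = np.random.default_rng(4)
    p = [0.1654, 0.3346, 0.3346, 0.1654]
    seq = list(rng.choice(list("ACGT"), 40000, p=p))
    # remove every window that anneals at all strongly
    i = 0
    while i < len(seq) - 5:
        if dg(window="".join(seq[i : i + 6])) < -2.0:
            seq[i : i + 6] = rng.choice(list("ACGT"), 6, p=p)
            i = max(0, i - 5)
        else:
            i += 1
    g = Genome(id="d", sequence="".join(seq), circular=False)
    table = hexamer_sd_occurrence(g, [(1, len(seq), "+")])
    assert table[table["dG"] < SD_CUTOFF]["occurrence"].sum() == 0.0
    rho, _ = spearmanr(table["dG"], table["normalized_occurrence"])
    assert rho > 0.1
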