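"""Ribosome pausing: occupancy profiles, codon occupancy and the pause/SD
cross-correlation.

A gene's occupancy profile is its footprint density divided by the gene
mean (computed over the trimmed CDS, first 10 / last 5 codons excluded),
so elongation pauses appear as peaks above 1.  Genes qualify for global
analyses when they average more than 10 reads per codon; the
cross-correlation additionally requires genes over 160 nt.

The pause/SD link is quantified two ways: a normalized cross-correlation
between per-gene z-scored occupancy and z-scored internal aSD-annealing
affinity (its peak lag localizes the paused A-site relative to the SD
site), and a direct correlation between the affinity of each internal SD
site and the ribosome occupancy a fixed offset downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import DensityTrack, Genome
from . import sd_energy

__all__ = [
    "PauseProfile",
    "pause_profiles",
    "codon_occupancy",
    "build_sd_tracks",
    "sd_crosscorr",
    "sd_affinity_vs_occupancy",
]

_TRIM5_NT = 30  # first 10 codons
_TRIM3_NT = 15  # last 5 codons


@dataclass
class PauseProfile:
    locus: str
    occupancy: np.ndarray  # sense 5'->3' over the trimmed CDS, mean 1
    gene_mean: float  # reads/nt over the trimmed CDS
    qualifying: bool
    offset_nt: int = _TRIM5_NT  # genomic offset of occupancy[0] from the start codon


def pause_profiles(ribo: DensityTrack, cds_set: list,
                   min_reads_per_codon: float = 10.0) -> list:
    """Mean-normalized occupancy per CDS (trimmed); profiles whose mean
    coverage is at or below ``min_reads_per_codon`` are marked
    non-qualifying."""
    out = []
    for cds in cds_set:
        if cds.length <= _TRIM5_NT + _TRIM3_NT + 3:
            continue
        body = ribo.slice(cds.left, cds.right, cds.strand)
        trimmed = body[_TRIM5_NT : len(body) - _TRIM3_NT]
        mean = float(trimmed.mean())
        occupancy = trimmed / mean if mean > 0 else np.zeros_like(trimmed)
        out.append(PauseProfile(
            locus=cds.locus, occupancy=occupancy, gene_mean=mean,
            qualifying=bool(mean * 3 > min_reads_per_codon),
        ))
    return out


def codon_occupancy(profiles: list, genome: Genome, cds_set: list,
                    a_site_offset: int = 0) -> pd.DataFrame:
    """Mean A-site occupancy and genomic abundance for the 61 sense codons.

    The center-weighted position is taken as the A-site by default;
    ``a_site_offset`` (nt, positive = downstream) shifts the assignment.
    Codon occupancy is the average profile value over each codon's three
    nucleotides across every qualifying gene.
    """
    by_locus = {c.locus: c for c in cds_set}
    occ_sum: dict[str, float] = {}
    occ_n: dict[str, int] = {}
    abundance: dict[str, int] = {}
    for prof in profiles:
        if not prof.qualifying or prof.locus not in by_locus:
            continue
        cds = by_locus[prof.locus]
        seq = genome.fetch(cds.left, cds.right, cds.strand)
        L = len(prof.occupancy)
        for codon_start in range(_TRIM5_NT, _TRIM5_NT + L - 2, 3):
            codon = seq[codon_start : codon_start + 3]
            if len(codon) < 3 or codon in ("TAA", "TAG", "TGA"):
                continue
            abundance[codon] = abundance.get(codon, 0) + 1
            lo = codon_start - _TRIM5_NT - a_site_offset
            if 0 <= lo and lo + 3 <= L:
                val = float(prof.occupancy[lo : lo + 3].mean())
                occ_sum[codon] = occ_sum.get(codon, 0.0) + val
                occ_n[codon] = occ_n.get(codon, 0) + 1
    total = sum(abundance.values())
    rows = [
        {
            "codon": codon,
            "mean_occupancy": occ_sum.get(codon, np.nan) / occ_n[codon]
            if occ_n.get(codon) else np.nan,
            "n_sites": occ_n.get(codon, 0),
            "abundance": abundance.get(codon, 0) / total if total else 0.0,
        }
        for codon in sorted(abundance)
    ]
    return pd.DataFrame(rows)


def build_sd_tracks(genome: Genome, cds_set: list,
                    model: sd_energy.EnergyModel = sd_energy.DEFAULT_MODEL,
                    binary: bool = False,
                    cutoff: float = sd_energy.SD_CUTOFF) -> dict:
    """Per-gene internal SD-affinity tracks aligned to the pause profiles.

    The affinity (-dG clamped at 0, kcal/mol; or a 0/1 indicator when
    ``binary``) of each 8-mer window is assigned to the window's 3'-most
    nucleotide — the mRNA position nearest the ribosome when the SD-like
    element engages the aSD — on the same trimmed coordinate system as
    :func:`pause_profiles`.
    """
    k = len(sd_energy.ASD_SEQUENCE)
    out: dict[str, np.ndarray] = {}
    for cds in cds_set:
        if cds.length <= _TRIM5_NT + _TRIM3_NT + 3:
            continue
        seq = genome.fetch(cds.left, cds.right, cds.strand)
        L = len(seq)
        affinity = np.zeros(L)
        for i in range(L - k + 1):
            dg = sd_energy.duplex_dG(window=seq[i : i + k], model=model)
            if binary:
                affinity[i + k - 1] = 1.0 if dg < cutoff else 0.0
            else:
                affinity[i + k - 1] = max(0.0, -dg)
        out[cds.locus] = affinity[_TRIM5_NT : L - _TRIM3_NT]
    return out


def _zscore(x: np.ndarray) -> np.ndarray | None:
    sd = x.std()
    if sd == 0:
        return None
    return (x - x.mean()) / sd


def sd_crosscorr(profiles: list, sd_tracks: dict, max_lag: int = 30,
                 min_len: int = 160,
                 min_reads_per_codon: float = 10.0) -> pd.DataFrame:
    """Averaged normalized cross-correlation of occupancy against SD affinity.

    For each qualifying gene both series are z-scored and
    ``ccf(lag) = mean_p z_occ[p] * z_sd[p - lag]`` is computed, so a pause
    sitting ``d`` nt downstream of SD sites peaks at lag ``+d``.  Values
    lie in [-1, 1]; the table holds the across-gene mean per lag and the
    number of genes contributing.
    """
    lags = np.arange(-max_lag, max_lag + 1)
    acc = np.zeros(len(lags))
    n_genes = 0
    for prof in profiles:
        if not prof.qualifying:
            continue
        if prof.gene_mean * 3 <= min_reads_per_codon:
            continue
        sd = sd_tracks.get(prof.locus)
        if sd is None or len(sd) != len(prof.occupancy):
            continue
        if len(prof.occupancy) + _TRIM5_NT + _TRIM3_NT < min_len:
            continue
        z_occ = _zscore(prof.occupancy)
        z_sd = _zscore(sd)
        if z_occ is None or z_sd is None:
            continue
        L = len(z_occ)
        gene_ccf = np.empty(len(lags))
        for i, lag in enumerate(lags):
            if lag >= 0:
                a, b = z_occ[lag:], z_sd[: L - lag]
            else:
                a, b = z_occ[:L + lag], z_sd[-lag:]
            gene_ccf[i] = float((a * b).mean()) if len(a) else 0.0
        acc += gene_ccf
        n_genes += 1
    if n_genes < 2:
        raise ValueError(f"only {n_genes} qualifying genes; need >= 2")
    return pd.DataFrame({"lag": lags, "ccf": acc / n_genes,
                         "n_genes": n_genes})


def sd_affinity_vs_occupancy(profiles: list, sd_tracks: dict,
                             offset: int = 11, n_bins: int = 10) -> dict:
    """Pair each internal SD site's affinity with the occupancy ``offset``
    nt downstream; report the raw Pearson r, binned means, and the pair
    count."""
    affs: list[float] = []
    occs: list[float] = []
    for prof in profiles:
        if not prof.qualifying:
            continue
        sd = sd_tracks.get(prof.locus)
        if sd is None or len(sd) != len(prof.occupancy):
            continue
        sites = np.flatnonzero(sd > 0)
        for s in sites:
            p = s + offset
            if p < len(prof.occupancy):
                affs.append(float(sd[s]))
                occs.append(float(prof.occupancy[p]))
    affs_arr = np.array(affs)
    occs_arr = np.array(occs)
    if len(affs_arr) < 3 or affs_arr.std() == 0 or occs_arr.std() == 0:
        r = 0.0
    else:
        r = float(np.corrcoef(affs_arr, occs_arr)[0, 1])
    binned = None
    if len(affs_arr) >= n_bins:
        edges = np.quantile(affs_arr, np.linspace(0, 1, n_bins + 1))
        idx = np.clip(np.searchsorted(edges, affs_arr, side="right") - 1,
                      0, n_bins - 1)
        binned = pd.DataFrame({
            "affinity_mean": [affs_arr[idx == b].mean() if (idx == b).any()
                              else np.nan for b in range(n_bins)],
            "occupancy_mean": [occs_arr[idx == b].mean() if (idx == b).any()
                               else np.nan for b in range(n_bins)],
        })
    return {"r": r, "n_pairs": len(affs_arr), "binned": binned}
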