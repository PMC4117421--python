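"""Trimmed RPKM, translation efficiency and differential-translation calls.

Expression is measured as reads per kilobase of CDS per million mapped
reads (RPKM).  Footprint RPKM excludes the first 10 and last 5 codons,
where initiating and terminating ribosomes pile up independently of the
elongation flux; RNA RPKM is untrimmed by default.  Translation
efficiency (TE) is the ratio footprint-RPKM / RNA-RPKM, and a gene is
called differentially translated between two conditions when it carries
at least ``min_reads`` in every sample and its TE changes more than
``fold``-fold (strict) in either direction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import DensityTrack

__all__ = [
    "rpkm_trimmed",
    "translation_efficiency",
    "te_table",
    "differential_translation",
]

TRIM5_CODONS = 10
TRIM3_CODONS = 5


def _trimmed_bounds(cds, trim5: int, trim3: int) -> tuple[int, int]:
    """Genomic (left, right) of the CDS after trimming codons from the
    biological 5' and 3' ends."""
    if cds.length <= 3 * (trim5 + trim3):
        raise ValueError(
            f"{cds.locus}: CDS of {cds.length} nt too short to trim "
            f"{trim5}+{trim3} codons")
    if cds.strand == "+":
        return cds.left + 3 * trim5, cds.right - 3 * trim3
    return cds.left + 3 * trim3, cds.right - 3 * trim5


def rpkm_trimmed(track: DensityTrack, cds, library_total: float | None = None,
                 trim5: int = TRIM5_CODONS, trim3: int = TRIM3_CODONS) -> float:
    """RPKM of a CDS with the initiation/termination codons excluded.

    ``library_total`` defaults to the total mapped mass of the track.
    Pass ``trim5=0, trim3=0`` for untrimmed (RNA-style) RPKM.
    """
    if library_total is None:
        library_total = track.total_mass()
    if library_total <= 0:
        return 0.0
    if trim5 or trim3:
        left, right = _trimmed_bounds(cds, trim5, trim3)
    else:
        left, right = cds.left, cds.right
    reads = float(track.slice(left, right, cds.strand).sum())
    kb = (right - left + 1) / 1000.0
    return reads / kb / (library_total / 1e6)


def translation_efficiency(ribo_rpkm: float, rna_rpkm: float) -> float:
    """TE = footprint RPKM / RNA RPKM; undefined (NaN) when RNA RPKM is 0."""
    if rna_rpkm <= 0:
        return float("nan")
    return ribo_rpkm / rna_rpkm


def te_table(ribo: DensityTrack, rna: DensityTrack, cds_set: list,
             condition: str = "cond",
             trim_rna: bool = False,
             library_ribo: float | None = None,
             library_rna: float | None = None) -> pd.DataFrame:
    """Per-gene expression/TE table for one condition."""
    lib_ribo = ribo.total_mass() if library_ribo is None else library_ribo
    lib_rna = rna.total_mass() if library_rna is None else library_rna
    rows = []
    for cds in cds_set:
        if cds.length <= 3 * (TRIM5_CODONS + TRIM3_CODONS):
            continue
        ribo_reads = float(ribo.slice(*_trimmed_bounds(cds, TRIM5_CODONS,
                                                       TRIM3_CODONS),
                                      cds.strand).sum())
        rna_reads = float(rna.slice(cds.left, cds.right, cds.strand).sum())
        r_rpkm = rpkm_trimmed(ribo, cds, lib_ribo)
        n_rpkm = rpkm_trimmed(rna, cds, lib_rna,
                              trim5=TRIM5_CODONS if trim_rna else 0,
                              trim3=TRIM3_CODONS if trim_rna else 0)
        rows.append({
            "locus": cds.locus,
            "condition": condition,
            "ribo_reads": ribo_reads,
            "rna_reads": rna_reads,
            "ribo_rpkm": r_rpkm,
            "rna_rpkm": n_rpkm,
            "te": translation_efficiency(r_rpkm, n_rpkm),
        })
    return pd.DataFrame(rows)


def differential_translation(records_a: pd.DataFrame, records_b: pd.DataFrame,
                             min_reads: float = 30.0,
                             fold: float = 2.0) -> pd.DataFrame:
    """Genes whose TE changes more than ``fold``-fold between conditions.

    Genes with fewer than ``min_reads`` in any assay of either sample are
    removed before testing; the fold-change test is strict in both
    directions.
    """
    merged = records_a.merge(records_b, on="locus", suffixes=("_a", "_b"))
    ok = (
        (merged["ribo_reads_a"] >= min_reads)
        & (merged["rna_reads_a"] >= min_reads)
        & (merged["ribo_reads_b"] >= min_reads)
        & (merged["rna_reads_b"] >= min_reads)
        & merged["te_a"].notna() & merged["te_b"].notna()
        & (merged["te_b"] > 0)
    )
    merged = merged[ok].copy()
    merged["te_fold"] = merged["te_a"] / merged["te_b"]
    hit = (merged["te_fold"] > fold) | (merged["te_fold"] < 1.0 / fold)
    return merged[hit][["locus", "ribo_rpkm_a", "rna_rpkm_a", "te_a",
                        "ribo_rpkm_b", "rna_rpkm_b", "te_b", "te_fold"]] \
        .reset_index(drop=True)
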