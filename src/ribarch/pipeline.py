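"""End-to-end orchestration: evidence in, annotated architecture out.

Stages run in a fixed order — I/O, CDS pruning and start calling, new-CDS
discovery, leaderless detection, transcript mapping, operon assembly and
splitting, expression/TE, SD classification, pausing — and every stage's
headline counts are recorded in a machine-readable manifest.  All
randomness (only the simulate path has any) flows from the single run
seed, so a run is reproducible bit for bit.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cds_mapper, expression_te, operon_builder, pausing, sd_energy, \
    synthetic_data, transcript_mapper
from .core_io import (
    AnnotationRecord,
    compute_gc,
    read_annotation,
    read_genome,
    read_peptides,
    read_track,
    read_tss,
    write_annotation,
)

__all__ = ["load_config", "run_pipeline"]

log = logging.getLogger("ribarch")


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if "inputs" not in cfg and "simulate" not in cfg:
        raise ValueError("config needs an 'inputs' or a 'simulate' block")
    return cfg


def _setup_logging(outdir: Path, level: str = "INFO") -> None:
    handlers = [logging.StreamHandler()]
    handlers.append(logging.FileHandler(outdir / "run.log"))
    logging.basicConfig(
        level=getattr(logging, level.upper(), logging.INFO),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        handlers=handlers, force=True,
    )


def _load_inputs(cfg: dict, seed: int):
    """Either simulate a bundle or read the four evidence channels."""
    if "simulate" in cfg:
        sim_kwargs = dict(cfg["simulate"] or {})
        known = {f.name for f in fields(synthetic_data.SimulationConfig)}
        bad = set(sim_kwargs) - known
        if bad:
            raise ValueError(f"unknown simulate keys: {sorted(bad)}")
        for key in ("start_codon_mix", "te_multipliers"):
            if key in sim_kwargs:
                sim_kwargs[key] = tuple(map(tuple, sim_kwargs[key]))
        sim = synthetic_data.SimulationConfig(**sim_kwargs)
        bundle = synthetic_data.simulate_bundle(sim, seed=seed)
        return bundle
    inp = cfg["inputs"]
    genome = read_genome(inp["genome"], replicon=inp.get("replicon"))
    n = genome.length
    ribo = read_track(inp["ribo_plus"], inp["ribo_minus"], n, "ribo")
    rna_cov = read_track(inp["rna_cov_plus"], inp["rna_cov_minus"], n, "rna_cov")
    rna_5p = read_track(inp["rna_5p_plus"], inp["rna_5p_minus"], n, "rna_5p")
    tss = read_tss(inp["tss"], n) if inp.get("tss") else []
    peptides = read_peptides(inp["peptides"]) if inp.get("peptides") else []
    annotation = read_annotation(inp["annotation"]) if inp.get("annotation") else []
    return synthetic_data.Bundle(
        config=None, genome=genome, truth=None, ribo=ribo, rna_cov=rna_cov,
        rna_5p=rna_5p, tss=tss, peptides=peptides, annotation=annotation,
    )


def run_pipeline(cfg: dict, outdir: str | Path, seed: int = 0) -> dict:
    """Run every stage and return (and write) the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_logging(outdir, cfg.get("log_level", "INFO"))
    params = cfg.get("params", {})
    manifest: dict = {"seed": seed, "stages": {}, "parameters": params}
    t_start = time.time()

    # ---- stage: inputs -------------------------------------------------
    t0 = time.time()
    bundle = _load_inputs(cfg, seed)
    genome = bundle.genome
    log.info("inputs ready in %.1fs: genome %d nt, %d annotation records",
             time.time() - t0, genome.length, len(bundle.annotation))
    manifest["genome"] = {"id": genome.id, "length": genome.length,
                          "gc": round(float(compute_gc(genome)), 4)}
    if "simulate" in cfg:
        synthetic_data.write_bundle(bundle, outdir / "bundle")

    # ---- stage: cds_mapper --------------------------------------------
    t0 = time.time()
    start_params = cds_mapper.StartCallParams(**{
        k: params[k] for k in (
            "min_density_ratio", "density_window", "gap_tol", "onset_tol",
        ) if k in params
    })
    flags = cds_mapper.prune_conflicting_cds(bundle.annotation, bundle.ribo)
    kept = []
    n_flip = n_del = 0
    for rec in bundle.annotation:
        f = flags.get(rec.locus, set())
        if "deleted" in f:
            n_del += 1
            continue
        if "strand_corrected" in f:
            rec.strand = "-" if rec.strand == "+" else "+"
            rec.attrs.setdefault("evidence", set()).add("strand_corrected")
            n_flip += 1
        kept.append(rec)
    called = cds_mapper.map_all_starts(
        genome, bundle.ribo, kept, peptides=bundle.peptides,
        tss_list=bundle.tss, params=start_params)
    new_cds = cds_mapper.discover_new_cds(
        bundle.ribo, bundle.annotation, genome, params=start_params)
    cds_set = sorted(called + new_cds, key=lambda c: c.left)
    anchors = cds_mapper.peptide_start_anchors(bundle.peptides)
    n_leaderless = 0
    for cds in cds_set:
        is_ll, _ = cds_mapper.detect_leaderless(
            cds, bundle.tss, bundle.rna_5p, bundle.ribo, anchors)
        cds.leaderless = is_ll
        if is_ll:
            cds.evidence.add("leaderless")
            cds.utr5 = 0
            n_leaderless += 1
    alt_starts = cds_mapper.internal_starts(bundle.peptides, cds_set, genome)
    manifest["stages"]["cds_mapper"] = {
        "cds_mapped": len(cds_set),
        "starts_corrected": sum(1 for c in called if c.provenance == "corrected"),
        "unresolved": sum(1 for c in cds_set if c.unresolved),
        "new_cds": len(new_cds),
        "deleted": n_del,
        "strand_corrected": n_flip,
        "leaderless": n_leaderless,
        "internal_starts": len(alt_starts),
    }
    log.info("cds_mapper done in %.1fs: %s", time.time() - t0,
             manifest["stages"]["cds_mapper"])

    # ---- stage: transcript_mapper -------------------------------------
    t0 = time.time()
    t_params = transcript_mapper.TranscriptParams(**{
        k: params[k] for k in ("expression_floor", "three_q", "five_peak_k")
        if k in params
    })
    transcripts = transcript_mapper.map_transcript_bounds(
        bundle.rna_cov, bundle.rna_5p, bundle.tss, t_params)
    transcript_mapper.assign_members(transcripts, cds_set)
    utr5 = transcript_mapper.assign_utr5(transcripts, cds_set, bundle.tss,
                                         t_params)
    for cds in cds_set:
        if not cds.leaderless and cds.locus in utr5:
            cds.utr5 = utr5[cds.locus]["utr5"]
    ncrnas = transcript_mapper.call_ncrnas(transcripts, cds_set, bundle.ribo)
    utr_values = [v["utr5"] for v in utr5.values() if v["utr5"] is not None]
    manifest["stages"]["transcript_mapper"] = {
        "transcripts": len(transcripts),
        "ncrnas": sum(1 for t in ncrnas if t.type == "ncRNA"),
        "antisense": sum(1 for t in ncrnas if t.type == "antisense"),
        "utr5_assigned": len(utr_values),
        "utr5_median": float(np.median(utr_values)) if utr_values else None,
    }
    log.info("transcript_mapper done in %.1fs: %s", time.time() - t0,
             manifest["stages"]["transcript_mapper"])

    # ---- stage: operon_builder ----------------------------------------
    t0 = time.time()
    o_params = operon_builder.OperonParams(**{
        k: params[k] for k in ("merge_gap", "review_gap", "split_fold",
                               "split_coverage") if k in params
    })
    mrna_cds = [c for c in cds_set if not c.unresolved]
    operons = operon_builder.assemble_operons(mrna_cds, transcripts, o_params)
    operons, split_report = operon_builder.split_operons(
        operons, bundle.rna_cov, o_params)
    rna_levels = {
        c.locus: float(bundle.rna_cov.slice(c.left, c.right, c.strand).mean())
        for c in mrna_cds
    }
    op_stats = operon_builder.operon_stats(operons, bundle.tss, rna_levels,
                                           o_params)
    manifest["stages"]["operon_builder"] = {
        "operons": int(op_stats["n_operons"]),
        "multi_cds_operons": int(op_stats["n_multi_cds"]),
        "splits": len(split_report),
        "mean_tss_per_operon": round(op_stats["mean_tss_per_operon"], 3),
        "polarity_junctions": int(op_stats["n_polarity_junctions"]),
    }
    log.info("operon_builder done in %.1fs: %s", time.time() - t0,
             manifest["stages"]["operon_builder"])

    # ---- stage: expression_te -----------------------------------------
    t0 = time.time()
    te = expression_te.te_table(bundle.ribo, bundle.rna_cov, mrna_cds)
    te.to_csv(outdir / "te.tsv", sep="\t", index=False)
    manifest["stages"]["expression_te"] = {
        "genes_quantified": int(len(te)),
        "median_te": round(float(te["te"].median()), 4) if len(te) else None,
    }
    log.info("expression_te done in %.1fs", time.time() - t0)

    # ---- stage: sd_energy ---------------------------------------------
    t0 = time.time()
    sd_rows = []
    for cds in mrna_cds:
        score = sd_energy.classify_sd(genome, cds.start_pos, cds.strand,
                                      utr5=cds.utr5)
        sd_rows.append({"locus": cds.locus,
                        "window_min_dG": round(score.window_min, 2),
                        "is_sd": score.is_sd})
    sd_df = pd.DataFrame(sd_rows)
    sd_df.to_csv(outdir / "sd.tsv", sep="\t", index=False)
    sd_frac = float(sd_df["is_sd"].mean()) if len(sd_df) else 0.0
    manifest["stages"]["sd_energy"] = {
        "starts_scored": int(len(sd_df)),
        "sd_led_fraction": round(sd_frac, 4),
    }
    bg_n = int(cfg.get("sd_background_n", 0))
    if bg_n:
        frac = sd_energy.random_sd_background(
            bg_n, manifest["genome"]["gc"], seed=seed)
        manifest["stages"]["sd_energy"]["background_fraction"] = round(frac, 4)
    log.info("sd_energy done in %.1fs", time.time() - t0)

    # ---- stage: pausing -------------------------------------------------
    t0 = time.time()
    if cfg.get("pausing", True):
        profiles = pausing.pause_profiles(bundle.ribo, mrna_cds)
        sd_tracks = pausing.build_sd_tracks(genome, mrna_cds)
        n_qual = sum(1 for p in profiles if p.qualifying)
        try:
            ccf = pausing.sd_crosscorr(profiles, sd_tracks)
            ccf.to_csv(outdir / "sd_ccf.tsv", sep="\t", index=False)
            peak_lag = int(ccf.loc[ccf["ccf"].idxmax(), "lag"])
        except ValueError:
            peak_lag = None
        manifest["stages"]["pausing"] = {
            "profiles": len(profiles),
            "qualifying": n_qual,
            "ccf_peak_lag": peak_lag,
        }
    log.info("pausing done in %.1fs", time.time() - t0)

    # ---- outputs -------------------------------------------------------
    ann_records = [c.to_annotation() for c in cds_set]
    write_annotation(ann_records, outdir / "cds.gff3",
                     outdir / "cds_summary.tsv", seqid=genome.id)
    t_records = []
    for t in transcripts:
        t_records.append(AnnotationRecord(
            locus=t.id, start=t.left, end=t.right, strand=t.strand,
            feature="transcript" if t.type == "mRNA" else "ncRNA",
            attrs={"type": t.type, "five_prime_source": t.five_prime_source,
                   "members": [c.locus for c in t.member_cds]},
        ))
    write_annotation(t_records, outdir / "transcripts.gff3", seqid=genome.id)
    op_records = []
    for op in operons:
        op_records.append(AnnotationRecord(
            locus=op.id, start=op.left, end=op.right, strand=op.strand,
            feature="operon",
            attrs={"members": [c.locus for c in op.members],
                   "review": str(op.review).lower()},
        ))
    write_annotation(op_records, outdir / "operons.gff3", seqid=genome.id)
    pd.DataFrame(split_report).to_csv(outdir / "operon_splits.tsv", sep="\t",
                                      index=False)
    pd.DataFrame(alt_starts).to_csv(outdir / "internal_starts.tsv", sep="\t",
                                    index=False)

    # per-stage timing goes to the log only, so manifests stay byte-identical
    log.info("pipeline finished in %.1fs", time.time() - t_start)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
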