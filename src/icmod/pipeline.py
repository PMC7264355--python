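"""End-to-end orchestration: files in, per-stage tables and a summary report out.

Stage order: expression filter -> reference (+decoys) -> site mapping ->
bridge batch correction -> completeness filter -> occupancy (NCP) ratios and
global centering -> rhythm detection (3 levels x 2 genotypes) -> kinase
threshold calibration and ssKSR prediction -> circadian-kinase enrichment ->
signal web.  Any stage failure aborts with a stage-tagged error before
partial output of later stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import enrichment, kinase, normalize, refdb, report, rhythm, web
from .io import (
    read_edges,
    read_fasta,
    read_gene_map,
    read_matrix,
    read_sites,
    write_fasta,
    write_matrix,
    write_results,
    write_sites,
)

log = logging.getLogger("icmod")

DEFAULT_PARAMS = {
    "fpkm_threshold": 1.0,
    "alpha": 0.01,
    "kinase_p": 0.05,
    "fpr_stk": 0.10,
    "fpr_tk": 0.15,
    "background_n": 10_000,
    "period_min": 20.0,
    "period_max": 28.0,
    "power_min": 10.0,
}

REQUIRED_INPUTS = ("samples", "fpkm", "protein", "phospho", "proteome", "gene_map", "sites", "kinases")


class StageError(RuntimeError):
    """Pipeline failure tagged with the stage it occurred in."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


def load_config(path: str | Path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text())
    cfg.setdefault("params", {})
    cfg["params"] = {**DEFAULT_PARAMS, **cfg["params"]}
    cfg.setdefault("genotypes", ["WT", "per0"])
    cfg.setdefault("reference_genotype", cfg["genotypes"][0])
    cfg.setdefault("seed", 0)
    return cfg


def _validate_config(cfg: dict) -> None:
    inputs = cfg.get("inputs", {})
    missing = [k for k in REQUIRED_INPUTS if k not in inputs]
    if missing:
        raise StageError("config", f"missing required inputs: {missing}")
    absent = [k for k in REQUIRED_INPUTS if not Path(inputs[k]).exists()]
    if absent:
        raise StageError("config", f"input files not found: {[inputs[k] for k in absent]}")


def run_pipeline(config: dict | str | Path) -> dict:
    """Run the full flow; returns the report dict (also written to the out dir)."""
    cfg = load_config(config) if not isinstance(config, dict) else _fill(config)
    _validate_config(cfg)
    inputs = cfg["inputs"]
    par = cfg["params"]
    out = Path(cfg.get("out", "results"))
    out.mkdir(parents=True, exist_ok=True)
    rep: dict = {"stages": {}, "params": par, "seed": cfg["seed"]}

    # ---- load ------------------------------------------------------------
    try:
        fpkm = read_matrix(inputs["fpkm"], inputs["samples"], "mrna")
        protein = read_matrix(inputs["protein"], inputs["samples"], "protein")
        phospho = read_matrix(inputs["phospho"], inputs["samples"], "phospho")
        proteome = read_fasta(inputs["proteome"])
        gene_map = read_gene_map(inputs["gene_map"])
        sites = read_sites(inputs["sites"])
        models = kinase.read_kinase_models(inputs["kinases"])
    except Exception as e:  # noqa: BLE001 - stage tagging
        raise StageError("load", str(e)) from e

    # ---- expression filter + reference ------------------------------------
    try:
        batches = sorted({s.batch for s in fpkm.samples if s.sample_id in fpkm.values.columns})
        per_batch = {
            b: refdb.filter_expressed(fpkm, par["fpkm_threshold"], fpkm.sample_ids(batch=b))
            for b in batches
        }
        expressed = set().union(*per_batch.values())
        reference = refdb.build_reference(expressed, proteome, gene_map)
        targets = [p for p in reference if not p.protein_id.startswith(refdb.DECOY_PREFIX)]
        write_fasta(reference, out / "reference.fasta")
        rep["stages"]["reference"] = {
            "expressed_genes": len(expressed),
            "per_batch_reference_size": {b: len(g) for b, g in per_batch.items()},
            "targets": len(targets),
            "decoys": len(reference) - len(targets),
        }
    except StageError:
        raise
    except Exception as e:
        raise StageError("reference", str(e)) from e

    # ---- site mapping -----------------------------------------------------
    try:
        mapped = refdb.map_sites(sites, reference)
        write_sites(mapped, out / "sites_mapped.tsv")
        rep["stages"]["map_sites"] = {"input": len(sites), "mapped": len(mapped)}
    except Exception as e:
        raise StageError("map_sites", str(e)) from e

    # ---- bridge batch correction -------------------------------------------
    try:
        bridge = cfg.get("bridge")
        if bridge:
            protein = normalize.bridge_batch_correct(
                protein, bridge["ref_sample"], bridge["target_sample"], bridge["target_batch"]
            )
            phospho = normalize.bridge_batch_correct(
                phospho, bridge["ref_sample"], bridge["target_sample"], bridge["target_batch"]
            )
            rep["stages"]["bridge"] = dict(bridge)
    except Exception as e:
        raise StageError("bridge", str(e)) from e

    # keep only features of the reference universe
    target_ids = {p.protein_id for p in targets}
    protein = protein.subset(features=target_ids)
    mapped_ids = {s.site_id for s in mapped}
    phospho = phospho.subset(features=mapped_ids)

    # ---- per-genotype normalization + rhythm --------------------------------
    fits: dict[tuple[str, str], pd.DataFrame] = {}
    cycling: dict[tuple[str, str], set[str]] = {}
    analyzed_sites: dict[str, list[str]] = {}
    try:
        for geno in cfg["genotypes"]:
            scope = [c for c in protein.sample_ids(genotype=geno)]
            prot_c = refdb.filter_complete(protein, scope).subset(sample_ids=scope)
            phos_c = refdb.filter_complete(phospho, scope).subset(sample_ids=scope)
            ncp = normalize.compute_ncp_series(phos_c, prot_c)
            write_matrix(ncp, out / f"ncp_{geno}.tsv")
            analyzed_sites[geno] = list(ncp.values.index)

            mrna_scope = fpkm.sample_ids(genotype=geno)
            mrna_expr = fpkm.subset(
                features=refdb.filter_expressed(fpkm, par["fpkm_threshold"], mrna_scope),
                sample_ids=mrna_scope,
            )
            mrna_expr = refdb.filter_complete(mrna_expr, mrna_scope)
            level_mats = {
                "mrna": mrna_expr,
                "protein": normalize.global_center(prot_c),
                "phospho": ncp,
            }
            for level, mat in level_mats.items():
                df = rhythm.fit_matrix(
                    mat,
                    genotype=geno,
                    period_range=(par["period_min"], par["period_max"]),
                    alpha=par["alpha"],
                )
                fits[(level, geno)] = df
                cycling[(level, geno)] = rhythm.classify_cycling(df, par["alpha"])
                write_results(df, out / f"rhythm_{level}_{geno}.tsv")
                rep["stages"][f"rhythm_{level}_{geno}"] = {
                    "features": len(df),
                    "cycling": len(cycling[(level, geno)]),
                    "cycling_pct": report.pct(len(cycling[(level, geno)]), max(len(df), 1)),
                }
    except Exception as e:
        raise StageError("rhythm", str(e)) from e

    ref_geno = cfg["reference_genotype"]
    other = [g for g in cfg["genotypes"] if g != ref_geno]
    if other:
        damping = {}
        for level in ("mrna", "protein", "phospho"):
            d = rhythm.compare_conditions(
                cycling[(level, ref_geno)], cycling[(level, other[0])]
            )
            damping[level] = {
                "abolished_pct": report.pct(len(d.abolished), max(len(cycling[(level, ref_geno)]), 1)),
                "retained": len(d.retained),
            }
        rep["stages"]["damping"] = damping

    # ---- kinase prediction --------------------------------------------------
    try:
        target_seqs = [p.sequence for p in targets]
        ncp_ids = cycling[("phospho", ref_geno)]
        universe = [s for s in mapped if s.site_id in set(analyzed_sites[ref_geno])]
        for m in models:
            residues = "ST" if m.kinase_class == "STK" else "Y"
            fpr = par["fpr_stk"] if m.kinase_class == "STK" else par["fpr_tk"]
            bg = kinase.sample_background(
                target_seqs, residues, n=par["background_n"], seed=cfg["seed"]
            )
            kinase.calibrate_threshold(m, bg, fpr)
        predictions = kinase.predict_sskr(models, universe)
        write_results(kinase.predictions_frame(predictions), out / "predictions.tsv")
        cov = kinase.coverage_by_level(predictions, models, [s.site_id for s in universe])
        rep["stages"]["kinase_prediction"] = {
            "predictions": len(predictions),
            "sites_ge1_pct": report.pct(cov.frac_sites_ge1 * 100, 100),
            "sites_ge2_pct": report.pct(cov.frac_sites_ge2 * 100, 100),
            "group_share": cov.group_share,
        }
    except Exception as e:
        raise StageError("kinase_prediction", str(e)) from e

    # ---- enrichment ---------------------------------------------------------
    try:
        results = enrichment.kinase_enrichment(
            predictions, analyzed_sites[ref_geno], ncp_ids
        )
        circadian_kinases = enrichment.classify_circadian_kinases(results, par["kinase_p"])
        write_results(enrichment.results_frame(results), out / "kinase_enrichment.tsv")
        rep["stages"]["circadian_kinases"] = {
            "tested": len(results),
            "classified": sorted(circadian_kinases),
        }
    except Exception as e:
        raise StageError("enrichment", str(e)) from e

    # ---- signal web ----------------------------------------------------------
    try:
        cyclic_proteins = cycling[("protein", ref_geno)]
        if circadian_kinases:
            swb = web.build_ks_network(predictions, circadian_kinases, ncp_ids)
            if "ppi" in inputs:
                swb = web.expand_with_ppi(swb, read_edges(inputs["ppi"]), cyclic_proteins)
            if "tf_targets" in inputs and "tf_sites" in inputs:
                tf_sites_df = pd.read_csv(inputs["tf_sites"], sep="\t", dtype=str)
                tf_sites = {
                    tf: set(g["site_id"]) for tf, g in tf_sites_df.groupby("tf")
                }
                swb = web.attach_tf_layer(
                    swb,
                    read_edges(inputs["tf_targets"]),
                    tf_sites,
                    predictions,
                    cycling[("mrna", ref_geno)],
                    circadian_kinases,
                )
            swb.write_json(out / "web.json")
            swb.write_sif(out / "web.sif")
            cov_stats = web.coverage_stats(
                swb, ncp_ids, cyclic_proteins, predictions, circadian_kinases
            )
            hubs = web.hub_rank(swb)[:20] if swb.nodes else []
            rep["stages"]["signal_web"] = {
                "nodes": len(swb.nodes),
                "edges": len(swb.edges),
                "ncp_coverage_pct": report.pct(cov_stats.ncp_coverage * 100, 100, 1),
                "protein_direct_pct": report.pct(cov_stats.protein_direct * 100, 100, 1),
                "protein_indirect_pct": report.pct(cov_stats.protein_indirect * 100, 100, 1),
                "protein_union_pct": report.pct(cov_stats.protein_union * 100, 100, 1),
                "top_hubs": hubs[:5],
            }
    except Exception as e:
        raise StageError("signal_web", str(e)) from e

    # ---- report ----------------------------------------------------------
    n_sites_ref = len(analyzed_sites[ref_geno])
    residue_counts: dict[str, int] = {}
    by_id = {s.site_id: s for s in mapped}
    for sid in analyzed_sites[ref_geno]:
        res = by_id[sid].residue
        residue_counts[res] = residue_counts.get(res, 0) + 1
    rep["summary"] = {
        "n_sites": n_sites_ref,
        "n_ncp": len(ncp_ids),
        "ncp_pct": report.ncp_fraction(len(ncp_ids), n_sites_ref),
        "residue_shares_pct": report.residue_shares(residue_counts),
        "n_circadian_kinases": len(circadian_kinases),
    }

    manifest = {
        "inputs": {k: _file_hash(v) for k, v in inputs.items() if Path(str(v)).exists()},
        "params": par,
        "seed": cfg["seed"],
    }
    write_results(manifest, out / "manifest.json")
    write_results(rep, out / "report.json")
    return rep


def _fill(cfg: dict) -> dict:
    cfg = dict(cfg)
    cfg["params"] = {**DEFAULT_PARAMS, **cfg.get("params", {})}
    cfg.setdefault("genotypes", ["WT", "per0"])
    cfg.setdefault("reference_genotype", cfg["genotypes"][0])
    cfg.setdefault("seed", 0)
    return cfg


def _file_hash(path: str | Path) -> str:
    h = hashlib.sha256(Path(path).read_bytes()).hexdigest()
    return f"sha256:{h[:16]}"
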