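"""End-to-end orchestration: simulate -> somatic -> CNA/LOH -> expression ->
enrichment, with a manifest, a machine-readable report, and byte-stable
outputs.

Every stage communicates through serialized TSV/JSON under the output
directory, so stages can be re-run or inspected independently.  All
thresholds (including defaults the protocol leaves unstated) are echoed
verbatim into ``manifest.json``.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel

from . import __version__, cna_loh, enrichment, expression, io, somatic
from .simdata import Cohort, SimConfig, simulate_cohort

logger = logging.getLogger("tnpipe.pipeline")

__all__ = ["RunConfig", "run_pipeline", "classify_driver"]


class RunConfig(BaseModel):
    """One config for the whole run; unset fields use library defaults."""

    sim: SimConfig = SimConfig()
    # somatic selection
    min_depth: int = 8
    p_max: float = 0.05
    frac_min: float = 0.9
    n_perm: int = 10_000
    af_max: float = 0.01
    # LOH / CNA
    het_lo: float = 0.4
    het_hi: float = 0.6
    hom_margin: float = 0.1
    hom_del_cut: float = -2.0
    het_del_cut: float = -0.5
    gain_cut: float = 0.5
    z_threshold: float = 4.0
    min_probes: int = 10
    # expression
    up_p: float = 0.05
    down_p: float = 0.001
    lfc: float = 1.0
    rpkm_floor: float = 0.5
    # enrichment
    q_max: float = 0.05

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()


def _caller_params(cfg: RunConfig) -> somatic.CallerParams:
    return somatic.CallerParams(
        min_depth=cfg.min_depth,
        p_max=cfg.p_max,
        frac_min=cfg.frac_min,
        n_perm=cfg.n_perm,
        seed=cfg.sim.seed,
    )


def _loh_table(sites) -> pd.DataFrame:
    rows = []
    for s in sites:
        if s.normal.depth == 0 or s.tumor.depth == 0:
            continue
        rows.append(
            (
                s.site_id,
                s.pos,
                s.normal.alt_count / s.normal.depth,
                s.tumor.alt_count / s.tumor.depth,
            )
        )
    return pd.DataFrame(rows, columns=["site_id", "pos", "normal_vaf", "tumor_vaf"])


def classify_driver(
    gene: str,
    gene_span: tuple[int, int],
    cna_by_sample: dict,
    loh_status_by_sample: dict,
    filtered_calls_by_sample: dict,
    rel_expr_by_sample: dict,
) -> pd.DataFrame:
    """Per-tumor driver mechanism table (gene inactivation + expression).

    ``cna_by_sample`` maps sample -> GeneCNAResult for the driver gene;
    ``filtered_calls_by_sample`` maps sample -> the sample's filtered
    somatic calls (those inside the gene span count as hits).
    """
    lo, hi = gene_span
    rows = []
    for sample in sorted(cna_by_sample):
        muts = [
            c
            for c in filtered_calls_by_sample.get(sample, [])
            if lo <= c.site.pos <= hi
        ]
        mech = cna_loh.classify_inactivation(
            gene, cna_by_sample[sample], loh_status_by_sample.get(sample, cna_loh.UNINFORMATIVE), muts
        )
        rows.append(
            {
                "sample": sample,
                "gene": gene,
                "copy_log2": cna_by_sample[sample].gene_log2 if cna_by_sample[sample] else np.nan,
                "cna_category": cna_by_sample[sample].category if cna_by_sample[sample] else "NA",
                "loh": loh_status_by_sample.get(sample, cna_loh.UNINFORMATIVE),
                "n_mutations": len(muts),
                "mechanism": mech,
                "biallelic": mech in cna_loh.BIALLELIC,
                "relative_expression": rel_expr_by_sample.get(sample, np.nan),
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(cfg: RunConfig, outdir) -> dict:
    """Run every stage on a simulated cohort and write the output tree.

    Returns the run report (also written to ``report.json``); reruns with
    an identical config produce byte-identical outputs.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"version": __version__, "config_hash": cfg.config_hash(), "stages": {}}

    # ---- simulate -------------------------------------------------------
    logger.info("simulating cohort (seed=%d)", cfg.sim.seed)
    cohort = simulate_cohort(cfg.sim)
    simdir = out / "sim"
    simdir.mkdir(exist_ok=True)
    for t in cohort.tumor_samples:
        io.write_paired_counts(cohort.paired_counts[t], simdir / f"counts_{t}.tsv")
        io.write_tsv(cohort.exon_tables[t], simdir / f"exons_{t}.tsv")
        io.write_tsv(cohort.probe_tables[t], simdir / f"probes_{t}.tsv")
    io.write_count_matrix(cohort.count_matrix, simdir / "rna")
    cohort.gene_sets.to_gmt(simdir / "gene_sets.gmt")
    io.write_gene_list(cohort.cancer_genes, simdir / "cancer_genes.txt")
    io.write_annotations(cohort.annotations, simdir / "annotations.tsv")
    cohort.truth.to_json(simdir / "truth.json")
    io.write_json(
        {
            "signatures": {k: sorted(v) for k, v in cohort.signatures.signatures.items()},
            "reference_gene": cohort.signatures.reference_gene,
        },
        simdir / "signatures.json",
    )
    report["stages"]["sim"] = {
        "n_sites": cfg.sim.n_sites,
        "n_tumors": len(cohort.tumor_samples),
        "n_controls": len(cohort.control_samples),
        "n_genes": cfg.sim.n_genes,
    }

    # ---- somatic --------------------------------------------------------
    params = _caller_params(cfg)
    somdir = out / "somatic"
    somdir.mkdir(exist_ok=True)
    calls_by_sample: dict = {}
    filtered_by_sample: dict = {}
    sens = []
    fprs = []
    for t in cohort.tumor_samples:
        calls = somatic.call_somatic(cohort.paired_counts[t], params)
        calls_by_sample[t] = calls
        io.write_tsv(somatic.calls_to_frame(calls), somdir / f"calls_{t}.tsv")
        io.write_tsv(somatic.volcano_table(calls), somdir / f"volcano_{t}.tsv")
        filtered = somatic.filter_variants(calls, cohort.annotations, af_max=cfg.af_max)
        filtered_by_sample[t] = filtered
        io.write_tsv(somatic.calls_to_frame(filtered), somdir / f"filtered_{t}.tsv")

        # per-tumor truth: shared planted somatic sites + this tumor's driver site
        truth_somatic = set(cohort.truth.somatic_sites)
        shared = truth_somatic - set(filter(None, cohort.driver_mutation_sites.values()))
        own = {cohort.driver_mutation_sites[t]} - {None}
        tumor_truth = shared | own
        called = {c.site.site_id for c in calls if c.verdict == somatic.SOMATIC}
        if tumor_truth:
            sens.append(len(called & tumor_truth) / len(tumor_truth))
        germ = set(cohort.truth.germline_sites)
        if germ:
            fprs.append(len(called & germ) / len(germ))
    report["stages"]["somatic"] = {
        "calls_per_sample": {
            t: int(sum(c.verdict == somatic.SOMATIC for c in calls_by_sample[t]))
            for t in cohort.tumor_samples
        },
        "filtered_per_sample": {t: len(filtered_by_sample[t]) for t in cohort.tumor_samples},
        "sensitivity": float(np.mean(sens)) if sens else None,
        "germline_fpr": float(np.mean(fprs)) if fprs else None,
    }

    # ---- CNA / LOH ------------------------------------------------------
    cuts = cna_loh.CNACutoffs(cfg.hom_del_cut, cfg.het_del_cut, cfg.gain_cut)
    loh_params = cna_loh.LOHParams(cfg.het_lo, cfg.het_hi, cfg.hom_margin)
    cnadir = out / "cna"
    cnadir.mkdir(exist_ok=True)
    driver = cfg.sim.driver_gene
    d_start = int(cohort.model.at[driver, "start"])
    d_end = int(cohort.model.at[driver, "end"])
    w = cfg.sim.window_bp
    tile_lo = ((d_start - 1) // w) * w + 1
    tile_hi = tile_lo + w - 1

    cna_by_sample: dict = {}
    loh_by_sample: dict = {}
    n_flagged = {}
    n_loh = {}
    for t in cohort.tumor_samples:
        genes = cna_loh.gene_level_log2(cohort.exon_tables[t], cuts)
        io.write_tsv(
            pd.DataFrame(
                {
                    "gene": [g.gene for g in genes],
                    "gene_log2": [g.gene_log2 for g in genes],
                    "n_exons": [g.n_exons for g in genes],
                    "category": [g.category for g in genes],
                }
            ),
            cnadir / f"genes_{t}.tsv",
        )
        cna_by_sample[t] = next((g for g in genes if g.gene == driver), None)

        vafs = _loh_table(cohort.paired_counts[t])
        loh_calls = cna_loh.call_loh(vafs[["site_id", "normal_vaf", "tumor_vaf"]], loh_params)
        io.write_tsv(
            pd.DataFrame(
                {
                    "site_id": [c.site_id for c in loh_calls],
                    "normal_vaf": [c.normal_vaf for c in loh_calls],
                    "tumor_vaf": [c.tumor_vaf for c in loh_calls],
                    "status": [c.status for c in loh_calls],
                }
            ),
            cnadir / f"loh_{t}.tsv",
        )
        n_loh[t] = int(sum(c.status == cna_loh.LOH for c in loh_calls))
        pos_by_id = dict(zip(vafs["site_id"], vafs["pos"]))
        region_calls = [
            c for c in loh_calls if tile_lo <= pos_by_id[c.site_id] <= tile_hi
        ]
        loh_by_sample[t] = cna_loh.aggregate_loh(region_calls)

        windows = cna_loh.windowed_z(
            cohort.probe_tables[t],
            window_bp=cfg.sim.window_bp,
            z_threshold=cfg.z_threshold,
            min_probes=cfg.min_probes,
            chrom="chr22",
        )
        io.write_tsv(
            pd.DataFrame(
                {
                    "chrom": [x.chrom for x in windows],
                    "start": [x.start for x in windows],
                    "end": [x.end for x in windows],
                    "n_probes": [x.n_probes for x in windows],
                    "mean_ratio": [x.mean_ratio for x in windows],
                    "z": [x.z for x in windows],
                    "flagged": [x.flagged for x in windows],
                }
            ),
            cnadir / f"windows_{t}.tsv",
        )
        n_flagged[t] = int(sum(x.flagged for x in windows))
    report["stages"]["cna_loh"] = {
        "loh_sites_per_sample": n_loh,
        "flagged_windows_per_sample": n_flagged,
        "driver_loh": loh_by_sample,
    }

    # ---- expression -----------------------------------------------------
    exprdir = out / "expression"
    exprdir.mkdir(exist_ok=True)
    cm = cohort.count_matrix
    rpkm = expression.compute_rpkm(cm)
    io.write_tsv(rpkm.rename_axis("gene"), exprdir / "rpkm.tsv", index=True)
    stats = expression.nb_test(cm)
    thresholds = expression.DEGThresholds(cfg.up_p, cfg.down_p, cfg.lfc, cfg.rpkm_floor)
    degs = expression.select_degs(stats, rpkm, cm.groups, thresholds)
    io.write_tsv(degs.rename_axis("gene"), exprdir / "deg.tsv", index=True)
    up_genes = sorted(degs.index[degs["direction"] == expression.UP])
    down_genes = sorted(degs.index[degs["direction"] == expression.DOWN])
    rel_expr = {
        t: expression.relative_expression(driver, rpkm, t, cohort.control_samples)
        for t in cohort.tumor_samples
    }
    report["stages"]["expression"] = {
        "n_up": len(up_genes),
        "n_down": len(down_genes),
        "up_down_ratio": (len(up_genes) / len(down_genes)) if down_genes else None,
        "driver_relative_expression": rel_expr,
    }

    # ---- enrichment -----------------------------------------------------
    enrdir = out / "enrichment"
    enrdir.mkdir(exist_ok=True)
    query = sorted(set(up_genes) | set(down_genes))
    records = enrichment.hypergeom_enrich(query, cohort.gene_sets, q_max=cfg.q_max)
    io.write_tsv(enrichment.enrichment_to_frame(records), enrdir / "enrichment.tsv")
    mat = enrichment.overlap_matrix(query, records, cohort.gene_sets)
    io.write_tsv(mat.rename_axis("gene"), enrdir / "overlap.tsv", index=True)
    ranked = enrichment.cancer_intersect_rank(mat.index, cohort.cancer_genes, degs)
    io.write_tsv(ranked, enrdir / "ranked.tsv")

    subgroup_calls = {}
    subgroup_rows = []
    for t in cohort.tumor_samples:
        label, scores = enrichment.subgroup_score(rpkm, t, cohort.signatures)
        subgroup_calls[t] = label
        subgroup_rows.append({"sample": t, "label": label, **scores})
    io.write_tsv(pd.DataFrame(subgroup_rows), enrdir / "subgroups.tsv")

    enriched_names = [r.set_name for r in records if r.enriched]
    top_rank = None
    if len(ranked) and cohort.truth.top_gene in set(ranked["gene"]):
        top_rank = int(ranked.loc[ranked["gene"] == cohort.truth.top_gene, "rank"].iloc[0])
    report["stages"]["enrichment"] = {
        "n_enriched_sets": len(enriched_names),
        "enriched_sets": enriched_names,
        "n_candidates": int(len(ranked)),
        "top_gene_rank": top_rank,
        "subgroup_calls": subgroup_calls,
    }

    # ---- driver mechanism table ----------------------------------------
    table = classify_driver(
        driver,
        (d_start, d_end),
        cna_by_sample,
        loh_by_sample,
        filtered_by_sample,
        rel_expr,
    )
    io.write_tsv(table, out / "driver_mechanisms.tsv")
    report["stages"]["driver"] = {
        "mechanisms": dict(zip(table["sample"], table["mechanism"])),
        "n_biallelic": int(table["biallelic"].sum()),
    }

    # ---- truth recovery summary ----------------------------------------
    truth = cohort.truth
    mech_correct = sum(
        report["stages"]["driver"]["mechanisms"].get(s) == m
        for s, m in truth.mechanisms.items()
    )
    subgroup_correct = sum(
        subgroup_calls.get(s) == g for s, g in truth.subgroup_labels.items()
    )
    report["truth_recovery"] = {
        "somatic_sensitivity": report["stages"]["somatic"]["sensitivity"],
        "germline_fpr": report["stages"]["somatic"]["germline_fpr"],
        "mechanisms_correct": int(mech_correct),
        "mechanisms_total": len(truth.mechanisms),
        "enriched_sets_recovered": sorted(
            set(enriched_names) & set(truth.enriched_sets)
        ),
        "top_gene_is_rank1": bool(
            top_rank == 1 if top_rank is not None else False
        ),
        "subgroup_accuracy": (
            subgroup_correct / len(truth.subgroup_labels) if truth.subgroup_labels else None
        ),
    }

    io.write_json(report, out / "report.json")
    manifest = {
        "version": __version__,
        "config": cfg.model_dump(),
        "config_hash": cfg.config_hash(),
    }
    io.write_json(manifest, out / "manifest.json")
    return report
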