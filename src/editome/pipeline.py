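"""End-to-end orchestration: simulate -> call -> diffedit -> cluster ->
psi -> te -> integrate, with one root seed, per-stage logging and a JSON
manifest of outputs."""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import calling, diffedit, integration, patterns, splicing, translation
from .io_formats import (
    RunConfig,
    write_annotation,
    write_genome,
    write_snps,
    write_table,
)
from .synthetic_data import SimulationConfig, SimulatedDataset, simulate_all

logger = logging.getLogger(__name__)

STAGES = ("simulate", "call", "diffedit", "cluster", "psi", "te", "integrate")


def _hash_file(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


@dataclass
class PipelineManifest:
    stages: dict = field(default_factory=dict)

    def record(self, stage: str, seed: int, outputs: dict[str, str],
               runtime: float, warnings: list[str] | None = None,
               failed: bool = False) -> None:
        self.stages[stage] = {
            "seed": seed,
            "outputs": {k: {"path": p, "sha256": _hash_file(p)}
                        for k, p in outputs.items() if os.path.exists(p)},
            "runtime_s": round(runtime, 3),
            "warnings": warnings or [],
            "failed": failed,
        }

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.stages, fh, indent=2)


@dataclass
class PipelineResult:
    """In-memory results of a full run, one attribute per stage output."""

    dataset: SimulatedDataset
    sites: pd.DataFrame
    presence: pd.DataFrame
    attrition: pd.DataFrame
    el_by_tp: pd.DataFrame
    context: pd.DataFrame
    diffedit_results: pd.DataFrame
    clustering: "patterns.FuzzyClustering"
    prevalence: "patterns.PrevalenceGroups"
    psi: pd.DataFrame
    psi_by_tp: pd.DataFrame
    dpsi: pd.DataFrame
    te: pd.DataFrame
    dte: pd.DataFrame
    pairs: pd.DataFrame
    association: "integration.AssociationTable"
    gene_classes: pd.DataFrame
    class_summary: pd.DataFrame
    dte_groups: pd.DataFrame
    adar: pd.DataFrame
    manifest: PipelineManifest


def run_all(config: RunConfig,
            sim_config: SimulationConfig | None = None) -> PipelineResult:
    """Run every stage in dependency order on a fresh synthetic dataset.

    All randomness derives from ``config.seed``; stage seeds are recorded in
    the manifest.  Outputs are written as TSVs under ``config.outdir``.
    """
    config.validate()
    if not config.simulate:
        raise NotImplementedError(
            "running from external files is supported through the library "
            "API; the orchestrated pipeline runs on synthetic data"
        )
    outdir = config.outdir
    os.makedirs(outdir, exist_ok=True)
    manifest = PipelineManifest()

    def path(name: str) -> str:
        return os.path.join(outdir, name)

    # ---- simulate ----------------------------------------------------
    t0 = time.time()
    sim_config = sim_config or SimulationConfig(seed=config.seed)
    sim_config.seed = config.seed
    ds = simulate_all(sim_config)
    write_genome(ds.annotation.genome, path("genome.fa"))
    write_annotation(ds.annotation.model, path("annotation.gtf"))
    write_snps(ds.annotation.snps, path("snps.vcf"))
    write_table(ds.reads, path("reads.tsv"))
    write_table(ds.truth, path("truth_sites.tsv"))
    write_table(ds.events, path("events.tsv"))
    ds.inclusion.to_csv(path("inclusion.tsv"), sep="\t")
    ds.exclusion.to_csv(path("exclusion.tsv"), sep="\t")
    ds.rna_counts.to_csv(path("rna_counts.tsv"), sep="\t")
    ds.ribo_counts.to_csv(path("ribo_counts.tsv"), sep="\t")
    manifest.record(
        "simulate", config.seed,
        {n: path(f) for n, f in [
            ("genome", "genome.fa"), ("annotation", "annotation.gtf"),
            ("snps", "snps.vcf"), ("reads", "reads.tsv"),
            ("truth", "truth_sites.tsv")]},
        time.time() - t0,
    )

    # ---- call --------------------------------------------------------
    t0 = time.time()
    sheet = ds.sample_sheet()
    pileup = ds.pileup()
    candidates = calling.call_candidates(pileup, ds.annotation.genome,
                                         ds.annotation.model)
    thresholds = calling.FilterThresholds(
        min_el=config.min_el, min_coverage=config.min_coverage,
        min_edited=config.min_edited,
        splice_intronic_nt=config.splice_intronic_nt,
    )
    sites, presence, attrition = calling.filter_cascade(
        candidates, sheet, ds.annotation.snps, ds.annotation.model, thresholds
    )
    sites = calling.annotate_sites(sites, ds.annotation.model,
                                   ds.annotation.genome)
    presence = presence.loc[presence.index.isin(sites["site_id"])]
    a2i = sites.loc[sites["etype"] == "AG"]
    el_by_tp = calling.editing_level_by_timepoint(
        candidates, sheet, pileup=pileup,
        min_coverage_defined=config.min_coverage,
    )
    el_by_tp = el_by_tp.loc[el_by_tp.index.isin(a2i["site_id"])]
    context = calling.context_matrix(
        a2i.rename(columns={"pos": "pos"}), ds.annotation.genome, k=1
    )
    write_table(sites, path("sites.tsv"))
    write_table(attrition, path("attrition.tsv"))
    context.to_csv(path("context.tsv"), sep="\t")
    el_by_tp.to_csv(path("el_by_timepoint.tsv"), sep="\t")
    for stage, grp in attrition.groupby("stage", sort=False):
        logger.info("filter stage %-16s: %s sites", stage,
                    grp["n_sites"].sum())
    manifest.record(
        "call", config.seed,
        {"sites": path("sites.tsv"), "attrition": path("attrition.tsv"),
         "el": path("el_by_timepoint.tsv")},
        time.time() - t0,
    )

    # ---- diffedit ------------------------------------------------------
    t0 = time.time()
    tps = list(sim_config.timepoints)
    a2i_keys = set(a2i["site_id"])
    cand_a2i = candidates.loc[
        (candidates["etype"] == "AG")
    ].copy()
    cand_a2i["site_id"] = (
        cand_a2i["chrom"].astype(str) + ":" + cand_a2i["pos"].astype(str)
        + ":" + cand_a2i["strand"] + ":" + cand_a2i["alt"]
    )
    cand_a2i = cand_a2i.loc[cand_a2i["site_id"].isin(a2i_keys)].drop(
        columns=["site_id"]
    )
    de = diffedit.scan_adjacent_timepoints(
        cand_a2i, sheet, tps, presence=presence, alpha=config.diffedit_p
    )
    write_table(de, path("differential_editing.tsv"))
    manifest.record("diffedit", config.seed,
                    {"diffedit": path("differential_editing.tsv")},
                    time.time() - t0)

    # ---- cluster -------------------------------------------------------
    t0 = time.time()
    profiles = patterns.build_profiles(el_by_tp, presence=None, min_defined=2)
    standardized = patterns.standardize_profiles(profiles)
    m = patterns.estimate_fuzzifier(*standardized.shape)
    fc = patterns.fuzzy_cmeans(standardized, c=config.n_clusters, m=m,
                               seed=config.seed)
    fc = patterns.reorder_by_peak(fc, tps)
    prevalence = patterns.group_by_prevalence(presence)
    cluster_df = fc.to_frame()
    cluster_df.index.name = "site_id"
    write_table(cluster_df.reset_index(), path("clusters.tsv"))
    pd.DataFrame(fc.centers, columns=standardized.columns).to_csv(
        path("cluster_centers.tsv"), sep="\t", index=False
    )
    manifest.record("cluster", config.seed,
                    {"clusters": path("clusters.tsv"),
                     "centers": path("cluster_centers.tsv")},
                    time.time() - t0)

    # ---- psi -----------------------------------------------------------
    t0 = time.time()
    events = ds.events.set_index("event_id")
    keep = splicing.coverage_filter(
        events, ds.inclusion, ds.exclusion,
        min_ir=config.psi_min_ir, min_other=config.psi_min_other,
        min_sample_frac=config.psi_min_sample_frac,
        ir_balance=ds.ir_balance,
    )
    events = events.loc[keep]
    psi = splicing.psi_table(events, ds.inclusion.loc[keep],
                             ds.exclusion.loc[keep])
    dpsi = splicing.scan_adjacent_timepoints_psi(
        psi, sheet, tps, min_dpsi=config.min_dpsi, min_range=config.min_range
    )
    # pooled per-time-point PSI for trajectory correlation
    inc_tp = ds.inclusion.loc[keep].T.groupby(
        sheet.set_index("sample")["timepoint"]).sum().T
    exc_tp = ds.exclusion.loc[keep].T.groupby(
        sheet.set_index("sample")["timepoint"]).sum().T
    psi_by_tp = (100.0 * inc_tp / (inc_tp + exc_tp).where(lambda x: x > 0))[tps]
    psi.to_csv(path("psi.tsv"), sep="\t")
    write_table(dpsi, path("differential_splicing.tsv"))
    manifest.record("psi", config.seed,
                    {"psi": path("psi.tsv"),
                     "dpsi": path("differential_splicing.tsv")},
                    time.time() - t0)

    # ---- te ------------------------------------------------------------
    t0 = time.time()
    rna = ds.rna_counts.copy()
    ribo = ds.ribo_counts.copy()
    combined = pd.concat(
        [rna.add_suffix("_RNA"), ribo.add_suffix("_Ribo")], axis=1
    )
    combined = translation.filter_low_counts(combined)
    kept_genes = combined.index
    te_sheet = pd.concat([
        sheet.assign(libtype="RNA", sample=sheet["sample"] + "_RNA"),
        sheet.assign(libtype="Ribo", sample=sheet["sample"] + "_Ribo"),
    ], ignore_index=True)
    sf_rna = translation.size_factors(rna.loc[kept_genes])
    sf_ribo = translation.size_factors(ribo.loc[kept_genes])
    gene_info = ds.annotation.gene_info
    len_kb = gene_info["cds_len"].where(gene_info["cds_len"] > 0,
                                        gene_info["tx_len"])
    rna_norm = translation.normalize_expression(rna.loc[kept_genes], sf_rna,
                                                len_kb)
    ribo_norm = translation.normalize_expression(ribo.loc[kept_genes], sf_ribo,
                                                 len_kb)
    te = translation.translational_efficiency(ribo_norm, rna_norm, sheet)
    dte = translation.scan_adjacent_timepoints_te(
        combined, te_sheet, tps,
        min_log2fc=config.dte_min_log2fc, max_padj=config.dte_max_padj,
    )
    te.to_csv(path("te.tsv"), sep="\t")
    write_table(dte, path("differential_te.tsv"))
    manifest.record("te", config.seed,
                    {"te": path("te.tsv"), "dte": path("differential_te.tsv")},
                    time.time() - t0)

    # ---- integrate -------------------------------------------------------
    t0 = time.time()
    es_genes = set(a2i["gene_id"]) - {""}
    as_genes = set(events["gene_id"])
    flags = pd.DataFrame(
        {
            "es": gene_info.index.isin(es_genes),
            "as_": gene_info.index.isin(as_genes),
        },
        index=gene_info.index,
    )
    assoc = integration.association_fisher(flags)
    site_meta = a2i.drop_duplicates("site_id")[
        ["site_id", "gene_id", "chrom", "pos", "strand"]
    ]
    pairs = integration.pair_sites_to_events(site_meta, events.reset_index())
    pairs = integration.pair_correlation(
        pairs, el_by_tp, psi_by_tp,
        strong_r=config.strong_r, max_p=config.corr_p,
    )
    summaries = integration.pair_summaries(pairs, el_by_tp, psi_by_tp,
                                           seed=config.seed)
    mean_te = te.mean(axis=1)
    gene_classes, class_summary = integration.classify_genes(
        flags, translatable=ds.translatable, te=mean_te
    )
    sig_dte = dte.loc[dte["significant"]]
    dpsi_sig = dpsi.loc[dpsi["significant"], "event_id"]
    dpsi_genes = set(events.loc[events.index.isin(dpsi_sig), "gene_id"])
    del_sites = de.loc[de["significant"], "site_id"]
    del_genes = set(
        a2i.loc[a2i["site_id"].isin(del_sites), "gene_id"]
    ) - {""}
    dte_groups = integration.classify_dte_groups(sig_dte, dpsi_genes, del_genes)

    shared = presence.index[presence.all(axis=1)]
    editing_summary = pd.DataFrame(
        {
            "n_sites": presence.sum(axis=0),
            "shared_mean_el": el_by_tp.loc[
                el_by_tp.index.isin(shared)
            ].mean(axis=0),
        }
    ).loc[tps]
    adar_ids = [g for g in ("Adar", "Adarb1", "Adarb2") if g in te.index]
    adar = integration.adar_correlation(
        editing_summary,
        {
            "RNA": rna_norm.loc[adar_ids].T.groupby(
                sheet.set_index("sample")["timepoint"]).mean().T[tps],
            "Ribo": ribo_norm.loc[adar_ids].T.groupby(
                sheet.set_index("sample")["timepoint"]).mean().T[tps],
        },
    )
    write_table(pairs, path("site_event_pairs.tsv"))
    write_table(gene_classes.reset_index(names="gene_id"),
                path("gene_classes.tsv"))
    write_table(class_summary, path("gene_class_summary.tsv"))
    write_table(dte_groups, path("dte_groups.tsv"))
    write_table(adar, path("adar_correlation.tsv"))
    manifest.record("integrate", config.seed,
                    {"pairs": path("site_event_pairs.tsv"),
                     "adar": path("adar_correlation.tsv")},
                    time.time() - t0)

    manifest.save(path("manifest.json"))
    return PipelineResult(
        dataset=ds, sites=sites, presence=presence, attrition=attrition,
        el_by_tp=el_by_tp, context=context, diffedit_results=de,
        clustering=fc, prevalence=prevalence, psi=psi, psi_by_tp=psi_by_tp,
        dpsi=dpsi, te=te, dte=dte, pairs=pairs, association=assoc,
        gene_classes=gene_classes, class_summary=class_summary,
        dte_groups=dte_groups, adar=adar, manifest=manifest,
    )
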