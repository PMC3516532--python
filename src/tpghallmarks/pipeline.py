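"""Orchestration of all analysis stages over a data bundle.

Stages run in the order expression -> regulation -> domains -> spatial ->
replication timing -> recurrence, each writing TSV outputs plus an entry in
a machine-readable summary.  All randomness flows from the configured
seeds, so a rerun with the same configuration is byte-identical; timing
information goes to the log, never into output files.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import io as tio
from . import rt as trt
from .domains import (
    build_interactor_network,
    cluster_functional_profiles,
    cooccurrence_permutation_test,
    fusion_network_edges,
    fusion_profiles,
    type_dependency_test,
)
from .expression import (
    aggregate_by_tissue,
    fusion_gain_stats,
    paired_partner_difference,
    pol2_peak_frequency,
    signal_metaprofile,
    utr3_features,
)
from .models import CATEGORIES_WITH_N, FormatError
from .recurrence import categorize_by_reports, compare_rare_frequent
from .simulate import Bundle, SimulationConfig, simulate_bundle, write_bundle
from .spatial import (
    bin_centrality,
    lineage_contact_difference,
    locus_centrality,
    pair_contact_frequency,
    partition_contact_clusters,
    tpg_pair_proximity_test,
    CisPairError,
)
from .stats import fold_enrichment_binomial

log = logging.getLogger("tpghallmarks")

ALL_STAGES = ("expression", "domains", "spatial", "rt", "recurrence")


@dataclass
class PipelineConfig:
    bundle_dir: str | Path
    outdir: str | Path
    stages: Sequence[str] = ALL_STAGES
    seed: int = 0
    n_perm_domains: int = 1_000_000   # matches the headline co-occurrence test
    n_perm_spatial: int = 100_000     # matches the headline proximity test
    fdr_q: float = 0.10
    rt_early: float = 0.5
    promoter_flank: int = 3000
    max_clusters: int = 10

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")


_STAGE_INPUTS = {
    "expression": ["genes.tsv", "translocations.tsv", "expression.tsv",
                   "samples.tsv", "h3k4me3.bedgraph", "conserved.bed",
                   "mirna_sites.bed"],
    "domains": ["genes.tsv", "translocations.tsv", "domains.tsv", "categories.tsv"],
    "spatial": ["genes.tsv", "translocations.tsv", "bins.tsv", "contacts_a.tsv",
                "bins_b.tsv", "contacts_b.tsv"],
    "rt": ["genes.tsv", "translocations.tsv", "rt.bedgraph"],
    "recurrence": ["genes.tsv", "translocations.tsv", "report_counts.tsv",
                   "expression.tsv", "samples.tsv", "domains.tsv"],
}


@dataclass
class LoadedBundle:
    catalog: dict
    translocations: list
    annotations: list | None = None
    cmap: object | None = None
    expression: object | None = None
    matrix_a: object | None = None
    matrix_b: object | None = None
    rt_profile: object | None = None
    h3k4me3: object | None = None
    conserved: object | None = None
    mirna: object | None = None
    pol2_tracks: dict = field(default_factory=dict)
    cell_line_groups: dict = field(default_factory=dict)
    report_counts: dict = field(default_factory=dict)


def _preflight(bundle_dir: Path, stages: Sequence[str]) -> None:
    missing = []
    for stage in stages:
        for name in _STAGE_INPUTS[stage]:
            if not (bundle_dir / name).exists():
                missing.append(f"{stage}: {name}")
    if missing:
        raise FormatError("missing input files -> " + "; ".join(missing))


def load_bundle_dir(bundle_dir: str | Path, stages: Sequence[str] = ALL_STAGES,
                    ) -> LoadedBundle:
    d = Path(bundle_dir)
    _preflight(d, stages)
    lb = LoadedBundle(
        catalog=tio.read_gene_models(d / "genes.tsv"),
        translocations=tio.read_translocations(d / "translocations.tsv"),
    )
    if "expression" in stages or "recurrence" in stages:
        lb.expression = tio.read_expression(d / "expression.tsv", d / "samples.tsv")
    if "expression" in stages:
        lb.h3k4me3 = tio.read_bedgraph(d / "h3k4me3.bedgraph")
        lb.conserved = tio.read_bed(d / "conserved.bed")
        lb.mirna = tio.read_bed(d / "mirna_sites.bed")
        for bed in sorted(d.glob("pol2_*.bed")):
            cl = bed.stem.removeprefix("pol2_")
            lb.pol2_tracks[cl] = tio.read_bed(bed)
            lb.cell_line_groups[cl] = ("hematopoietic" if cl.startswith("hem")
                                       else "non_hematopoietic")
    if "domains" in stages or "recurrence" in stages:
        lb.annotations = tio.read_domain_annotations(d / "domains.tsv")
        lb.cmap = tio.read_category_map(d / "categories.tsv")
    if "spatial" in stages or "recurrence" in stages or "rt" in stages:
        lb.matrix_a = tio.read_contact_matrix(d / "bins.tsv", d / "contacts_a.tsv")
    if "spatial" in stages:
        lb.matrix_b = tio.read_contact_matrix(d / "bins_b.tsv", d / "contacts_b.tsv")
    if "rt" in stages:
        lb.rt_profile = tio.read_bedgraph(d / "rt.bedgraph", kind="replication_timing")
    return lb


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the enabled stages and write per-stage TSVs plus summary.json."""
    bundle_dir = Path(config.bundle_dir)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _preflight(bundle_dir, config.stages)
    lb = load_bundle_dir(bundle_dir, config.stages)
    summary: dict = {"seed": config.seed, "stages": {},
                     "n_perm_domains": config.n_perm_domains,
                     "n_perm_spatial": config.n_perm_spatial}
    runners = {
        "expression": _run_expression,
        "domains": _run_domains,
        "spatial": _run_spatial,
        "rt": _run_rt,
        "recurrence": _run_recurrence,
    }
    for stage in config.stages:
        t0 = time.perf_counter()
        summary["stages"][stage] = runners[stage](lb, config, outdir)
        log.info("stage %s finished in %.2f s", stage, time.perf_counter() - t0)
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary


# ---------------------------------------------------------------------------
# stage runners
# ---------------------------------------------------------------------------

def _fusion_profile_inputs(lb: LoadedBundle):
    by_gene: dict[str, list] = {}
    for a in lb.annotations or []:
        by_gene.setdefault(a.gene_id, []).append(a)
    cds = {g: m.cds_start_nt for g, m in lb.catalog.items()}
    return by_gene, cds


def _run_expression(lb: LoadedBundle, config: PipelineConfig, outdir: Path) -> dict:
    tissues, groups = aggregate_by_tissue(lb.expression)
    groups.to_csv(outdir / "expression_group_means.tsv", sep="\t",
                  float_format="%.6g", index_label="gene_id")
    five = [t.five_gene for t in lb.translocations]
    three = [t.three_gene for t in lb.translocations]
    hem = groups["HEM"] if "HEM" in groups.columns else groups.iloc[:, 0]
    paired = paired_partner_difference(
        [hem[g] for g in five], [hem[g] for g in three])
    genes = [lb.catalog[g] for g in sorted(lb.catalog)]
    pol2 = pol2_peak_frequency(genes, lb.pol2_tracks, lb.cell_line_groups,
                               flank=config.promoter_flank)
    pol2.to_csv(outdir / "pol2_frequency.tsv", sep="\t", float_format="%.6g")
    meta = signal_metaprofile(lb.h3k4me3, [lb.catalog[g] for g in set(five)],
                              flank=config.promoter_flank)
    np.savetxt(outdir / "h3k4me3_metaprofile_5p.tsv", meta, fmt="%.6g")
    utr_rows = []
    for g in genes:
        f = utr3_features(g, lb.conserved, lb.mirna)
        if f is not None:
            utr_rows.append([f.gene_id, f.utr_length, f.n_conserved, f.n_mirna_sites])
    pd.DataFrame(utr_rows, columns=["gene_id", "utr_length", "n_conserved",
                                    "n_mirna_sites"]).to_csv(
        outdir / "utr3_features.tsv", sep="\t", index=False)
    utr_len = {r[0]: r[1] for r in utr_rows}
    paired_utr = paired_partner_difference(
        [utr_len.get(g, np.nan) for g in five],
        [utr_len.get(g, np.nan) for g in three])
    return {
        "paired_expression_median_diff": paired.median,
        "paired_expression_p": paired.p_value,
        "paired_utr_length_median_diff": paired_utr.median,
        "paired_utr_length_p": paired_utr.p_value,
        "n_pairs": len(five),
    }


def _run_domains(lb: LoadedBundle, config: PipelineConfig, outdir: Path) -> dict:
    by_gene, cds = _fusion_profile_inputs(lb)
    profiles, retentions = fusion_profiles(lb.translocations, by_gene, cds, lb.cmap)
    prof_by_id = {p.fusion_id: p for p in profiles}
    uniq = tio.deduplicate_translocations(
        lb.translocations, mode="profile",
        profile_key=lambda t: (prof_by_id[t.fusion_id].set5,
                               prof_by_id[t.fusion_id].set3))
    uprofiles = [prof_by_id[t.fusion_id] for t in uniq]
    rng = np.random.default_rng(config.seed)
    cooc = cooccurrence_permutation_test(
        [p.set5 for p in uprofiles], [p.set3 for p in uprofiles],
        n_perm=config.n_perm_domains, q=config.fdr_q, seed=rng)
    rows = []
    for c5 in CATEGORIES_WITH_N:
        for c3 in CATEGORIES_WITH_N:
            r = cooc.cell(c5, c3)
            rows.append([c5, c3, r.observed, r.null_mean, r.fold, r.p_value,
                         r.q_value if r.q_value is not None else "NA",
                         r.direction])
    pd.DataFrame(rows, columns=["cat5", "cat3", "observed", "null_mean", "fold",
                                "p", "q", "direction"]).to_csv(
        outdir / "cooccurrence.tsv", sep="\t", index=False, float_format="%.6g")
    dep = type_dependency_test(uprofiles, n_perm=min(config.n_perm_domains, 100_000),
                               seed=rng)
    clust = cluster_functional_profiles(uprofiles, seed=rng,
                                        max_k=config.max_clusters)
    pd.DataFrame(clust.cluster_probs,
                 columns=[f"{side}_{c}" for side in ("5p", "3p")
                          for c in ("D", "P", "H", "K", "O")]).to_csv(
        outdir / "cluster_probs.tsv", sep="\t", index_label="cluster",
        float_format="%.6g")
    assignments = {p.fusion_id: int(c) for p, c in zip(uprofiles, clust.assignments)}
    edges = fusion_network_edges(uniq, assignments)
    pd.DataFrame(edges, columns=["five_gene", "three_gene", "cluster",
                                 "variant_count"]).to_csv(
        outdir / "fusion_network.tsv", sep="\t", index=False)
    iedges, multiset = build_interactor_network(retentions, side="three_prime")
    pd.DataFrame(iedges, columns=["tpg", "partner", "fusion_id"]).to_csv(
        outdir / "interactor_network.tsv", sep="\t", index=False)
    sig = cooc.reject & cooc.tested
    over = int(np.sum(sig & (cooc.observed >= cooc.null_mean)))
    under = int(np.sum(sig & (cooc.observed < cooc.null_mean)))
    return {
        "n_unique_profiles": len(uprofiles),
        "significant_over": over,
        "significant_under": under,
        "type2_type2_fraction": dep.type2_type2_fraction,
        "type2_type2_fold": dep.type2_type2_fold,
        "type_dependency_fisher_p": dep.fisher_p,
        "selected_k": clust.k,
        "n_interactor_partners": len(multiset),
    }


def _pairs_for(lb: LoadedBundle, translocs) -> list:
    pairs = []
    for t in translocs:
        if t.five_gene in lb.catalog and t.three_gene in lb.catalog:
            pairs.append((lb.catalog[t.five_gene], lb.catalog[t.three_gene]))
    return pairs


def _run_spatial(lb: LoadedBundle, config: PipelineConfig, outdir: Path) -> dict:
    uniq = tio.deduplicate_translocations(lb.translocations, mode="pairs")
    pairs = _pairs_for(lb, uniq)
    result = tpg_pair_proximity_test(pairs, lb.matrix_a,
                                     list(lb.catalog.values()),
                                     n_perm=config.n_perm_spatial,
                                     seed=config.seed)
    pd.DataFrame([
        [s, result.observed_mean, result.null_means[s], result.null_sds[s],
         result.p_values[s]] for s in result.p_values],
        columns=["scheme", "observed_mean", "null_mean", "null_sd", "p"]).to_csv(
        outdir / "proximity_test.tsv", sep="\t", index=False, float_format="%.6g")
    part = partition_contact_clusters(lb.matrix_a, seed=config.seed)
    bed_rows = lb.matrix_a.bins.copy()
    bed_rows["label"] = part.labels
    bed_rows[["chrom", "start", "end", "label"]].to_csv(
        outdir / "compartments.bed", sep="\t", index=False, header=False)
    five_ids = sorted({t.five_gene for t in uniq})
    flags = {}
    for gid, g in lb.catalog.items():
        try:
            flags[gid] = bool(part.central_mask[
                lb.matrix_a.bin_for(g.chrom, g.midpoint)])
        except KeyError:
            continue
    k = sum(flags.get(g, False) for g in five_ids if g in flags)
    n = sum(1 for g in five_ids if g in flags)
    p0 = sum(flags.values()) / len(flags)
    central_enrichment = fold_enrichment_binomial(k, n, p0) if 0 < p0 < 1 else None
    by_lineage: dict[str, list] = {}
    for t in uniq:
        if t.lineage in ("HEM-L", "HEM-M"):
            by_lineage.setdefault(t.lineage, []).append(
                (lb.catalog[t.five_gene], lb.catalog[t.three_gene]))
    contrast = lineage_contact_difference(by_lineage, lb.matrix_a, lb.matrix_b)
    cent_rows = []
    for gid in sorted(lb.catalog):
        try:
            cent_rows.append([gid, locus_centrality(lb.matrix_a, lb.catalog[gid])])
        except (KeyError, ValueError):
            continue
    pd.DataFrame(cent_rows, columns=["gene_id", "centrality"]).to_csv(
        outdir / "centrality.tsv", sep="\t", index=False, float_format="%.6g")
    return {
        "observed_mean_contact": result.observed_mean,
        "n_pairs": result.n_pairs,
        "p_by_scheme": result.p_values,
        "central_enrichment_fold_5p":
            central_enrichment.fold if central_enrichment else None,
        "central_enrichment_p_5p":
            central_enrichment.p_value if central_enrichment else None,
        "lineage_spearman_r": contrast.spearman_r,
        "lineage_between_p": contrast.between_p,
    }


def _run_rt(lb: LoadedBundle, config: PipelineConfig, outdir: Path) -> dict:
    smoothed = trt.loess_smooth(lb.rt_profile)
    genes = list(lb.catalog.values())
    values = trt.gene_rt_values(smoothed, genes)
    pd.DataFrame([[v.gene_id, v.rt, int(v.is_early)] for v in values.values()],
                 columns=["gene_id", "rt", "is_early"]).to_csv(
        outdir / "gene_rt.tsv", sep="\t", index=False, float_format="%.6g")
    uniq = tio.deduplicate_translocations(lb.translocations, mode="pairs")
    tpgs = sorted({t.five_gene for t in uniq} | {t.three_gene for t in uniq})
    enr = trt.early_late_enrichment(tpgs, sorted(lb.catalog), values)
    return {
        "pct_early_tpg": enr.observed,
        "pct_early_background": enr.null_mean,
        "early_enrichment_fold": enr.fold,
        "early_enrichment_p": enr.p_value,
        "direction": enr.direction,
    }


def _run_recurrence(lb: LoadedBundle, config: PipelineConfig, outdir: Path) -> dict:
    uniq = tio.deduplicate_translocations(lb.translocations, mode="pairs")
    counts = {}
    for t in uniq:
        c = lb.report_counts.get(t.gene_pair) if lb.report_counts else None
        counts[t.fusion_id] = max(1, c if c is not None else t.report_count)
    cats = categorize_by_reports(counts)
    _, group_means = aggregate_by_tissue(lb.expression)
    hem = group_means["HEM"] if "HEM" in group_means.columns else group_means.iloc[:, 0]
    features: dict[str, dict[str, float]] = {"five_expression_hem": {}}
    for t in uniq:
        if t.five_gene in hem.index:
            features["five_expression_hem"][t.fusion_id] = float(hem[t.five_gene])
    if lb.matrix_a is not None:
        features["pair_contact"] = {}
        for t in uniq:
            try:
                features["pair_contact"][t.fusion_id] = pair_contact_frequency(
                    lb.matrix_a, lb.catalog[t.five_gene], lb.catalog[t.three_gene])
            except (KeyError, CisPairError):
                continue
    if lb.annotations is not None:
        pii_count: dict[str, int] = {}
        for a in lb.annotations:
            if a.is_pii:
                pii_count[a.gene_id] = pii_count.get(a.gene_id, 0) + 1
        features["three_pii_count"] = {
            t.fusion_id: float(pii_count.get(t.three_gene, 0)) for t in uniq}
    rows, out = [], {}
    for name, vals in features.items():
        cmp_res = compare_rare_frequent(cats, vals, name)
        rows.append([name, cmp_res.n_rare, cmp_res.n_frequent, cmp_res.median_rare,
                     cmp_res.median_frequent,
                     cmp_res.u_statistic if cmp_res.u_statistic is not None else "NA",
                     cmp_res.p_value if cmp_res.p_value is not None else "NA"])
        out[name] = {"p": cmp_res.p_value, "median_rare": cmp_res.median_rare,
                     "median_frequent": cmp_res.median_frequent}
    pd.DataFrame(rows, columns=["feature", "n_rare", "n_frequent", "median_rare",
                                "median_frequent", "U", "p"]).to_csv(
        outdir / "recurrence.tsv", sep="\t", index=False, float_format="%.6g")
    return out


# ---------------------------------------------------------------------------
# convenience entry points
# ---------------------------------------------------------------------------

def simulate_to_dir(config: SimulationConfig, outdir: str | Path) -> Bundle:
    bundle = simulate_bundle(config)
    write_bundle(bundle, outdir)
    return bundle
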