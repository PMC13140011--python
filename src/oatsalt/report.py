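"""Pipeline orchestration, cross-stage joins and summary-table export.

``run_all`` executes simulate -> expression -> homeolog -> network ->
association -> report, writes every intermediate as TSV, and returns a
:class:`SummaryBundle` whose count tables can be re-derived from the
underlying per-gene tables (``reconcile`` checks exactly that).
"""

from __future__ import annotations

import logging
import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import association as assoc_mod
from . import expression as expr_mod
from . import homeolog as homeo_mod
from . import network as net_mod
from . import simulate as sim_mod
from . import io
from .config import CAUSAL_MARKER_ID, PipelineConfig

logger = logging.getLogger(__name__)


@dataclass
class SummaryBundle:
    """All stage outputs: per-gene tables plus the derived count tables."""

    config_hash: str = ""
    # expression
    deg_table: pd.DataFrame | None = None
    deg_counts: pd.DataFrame | None = None
    unions: dict = field(default_factory=dict)
    core_set: set = field(default_factory=set)
    core_regions: pd.DataFrame | None = None
    tf_response: pd.DataFrame | None = None
    # homeolog
    groups: pd.DataFrame | None = None
    category_counts: pd.DataFrame | None = None
    bias_tables: dict = field(default_factory=dict)
    dominance: dict = field(default_factory=dict)
    # network
    soft_threshold: pd.DataFrame | None = None
    module_labels: pd.Series | None = None
    module_census: pd.DataFrame | None = None
    eigengene_adjacency: pd.DataFrame | None = None
    enrichment: pd.DataFrame | None = None
    # association
    qc_report: pd.DataFrame | None = None
    assoc_table: pd.DataFrame | None = None
    ld: pd.DataFrame | None = None
    haplotype: pd.DataFrame | None = None
    candidates: pd.DataFrame | None = None


def candidate_genes(assoc_table: pd.DataFrame, catalog: pd.DataFrame,
                    expr, deg_union: set, groups: pd.DataFrame,
                    homeolog_map: pd.DataFrame,
                    module_labels: pd.Series | None = None,
                    dominant_groups: set | None = None,
                    threshold: float = 1e-4, window_bp: int = 50_000,
                    expressed_floor: float = 0.5) -> pd.DataFrame:
    """Genes within ``window_bp`` of any marker below the threshold.

    Reproduces the candidate-triage logic as successive boolean columns:
    residing in the locus -> expressed (FPKM above floor in >= 1 sample) ->
    subgenome-divergent salt-responsive TF (a TF-family DEG whose homeolog
    group is non-triad or dominance-biased).
    """
    sig = assoc_table[assoc_table["pvalue"] < threshold]
    columns = ["gene_id", "chrom", "start", "nearest_marker", "distance_bp",
               "marker_pvalue", "expressed", "is_deg", "category", "module",
               "tf_family", "divergent_srtf"]
    if sig.empty:
        warnings.warn("no markers below the genome-wide threshold; empty candidate table")
        return pd.DataFrame(columns=columns)

    group_of = homeolog_map.set_index("gene_id")["group_id"]
    category_of = groups.set_index("group_id")["category"]
    max_fpkm = expr.fpkm.max(axis=1)
    dominant_groups = dominant_groups or set()

    rows = []
    for _, gene in catalog.iterrows():
        near = sig[(sig["chrom"] == gene["chromosome"])
                   & ((sig["pos"] - gene["start"]).abs() <= window_bp)]
        if near.empty:
            continue
        best = near.loc[near["pvalue"].idxmin()]
        group = group_of.get(gene["gene_id"], "")
        category = category_of.get(group, "other")
        family = gene["tf_family"] if isinstance(gene["tf_family"], str) else ""
        is_deg = gene["gene_id"] in deg_union
        rows.append({
            "gene_id": gene["gene_id"], "chrom": gene["chromosome"],
            "start": gene["start"], "nearest_marker": best["marker_id"],
            "distance_bp": int(abs(best["pos"] - gene["start"])),
            "marker_pvalue": best["pvalue"],
            "expressed": bool(max_fpkm.get(gene["gene_id"], 0.0) > expressed_floor),
            "is_deg": is_deg,
            "category": category,
            "module": (module_labels.get(gene["gene_id"], "")
                       if module_labels is not None else ""),
            "tf_family": family,
            "divergent_srtf": bool(family) and is_deg
            and (category != "triad" or group in dominant_groups),
        })
    out = pd.DataFrame(rows, columns=columns)
    return out.sort_values(["marker_pvalue", "gene_id"], ignore_index=True)


def reconcile(bundle: SummaryBundle) -> list[str]:
    """Re-derive every count table from its per-gene table; list violations."""
    problems: list[str] = []

    if bundle.deg_table is not None and bundle.deg_counts is not None:
        counts, unions, grand = expr_mod.deg_counts([bundle.deg_table])
        if not counts.sort_values(["tissue", "timepoint_h"], ignore_index=True).equals(
                bundle.deg_counts.sort_values(["tissue", "timepoint_h"],
                                              ignore_index=True)):
            problems.append("deg_counts does not match recount from deg_table")
        if unions != {t: set(u) for t, u in bundle.unions.items()}:
            problems.append("per-tissue DEG unions do not match deg_table")
        if bundle.core_regions is not None:
            core, regions = expr_mod.core_degs(unions)
            if core != bundle.core_set:
                problems.append("core DEG set does not match tissue unions")
            if int(regions["n_genes"].sum()) != len(grand):
                problems.append("core-region counts do not partition the grand union")
            if int(bundle.core_regions["n_genes"].sum()) != len(grand):
                problems.append("stored core-region counts do not sum to the grand union")

    if bundle.groups is not None and bundle.category_counts is not None:
        recount = (bundle.groups.groupby("category").size()
                   .rename("n_groups").reset_index())
        stored = bundle.category_counts.sort_values("category", ignore_index=True)
        if not recount.sort_values("category", ignore_index=True).equals(stored):
            problems.append("category_counts does not match recount from groups")
        triads = bundle.groups[bundle.groups["category"] == "triad"]
        member_genes = int((triads[["n_a", "n_c", "n_d"]].sum(axis=1)).sum())
        if member_genes != 3 * len(triads):
            problems.append("triad identity violated: member genes != 3 x triad groups")

    if bundle.dominance.get("all") is not None and bundle.bias_tables:
        rows = []
        for tissue, table in bundle.bias_tables.items():
            expressed = table[table["label"] != "unexpressed"]
            for label, part in expressed.groupby("label"):
                rows.append({"tissue": tissue, "label": label, "n_triads": len(part)})
        recount = (pd.DataFrame(rows, columns=["tissue", "label", "n_triads"])
                   .sort_values(["tissue", "label"], ignore_index=True))
        stored = bundle.dominance["all"].sort_values(["tissue", "label"],
                                                     ignore_index=True)
        if not recount.equals(stored):
            problems.append("dominance counts do not match bias tables")
        bad = set(stored["label"]) - {"A-dominant", "C-dominant", "D-dominant", "balanced"}
        if bad:
            problems.append(f"dominance labels outside vocabulary: {sorted(bad)}")

    if bundle.module_labels is not None and bundle.module_census is not None:
        recount = (bundle.module_labels.value_counts().rename_axis("module")
                   .rename("n_genes").reset_index()
                   .sort_values("module", ignore_index=True))
        stored = bundle.module_census.sort_values("module", ignore_index=True)
        if not recount.equals(stored):
            problems.append("module census does not match module labels")

    return problems


def run_all(config: PipelineConfig, out_dir: str,
            input_dir: str | None = None) -> tuple[SummaryBundle, pd.DataFrame]:
    """Execute the full pipeline and write all outputs under ``out_dir``.

    Inputs are simulated (the default) or loaded from a fixture bundle.
    Every file is plain TSV (plus one VCF); the run is deterministic for a
    fixed seed and the config hash is recorded in the manifest.
    """
    config.validate()
    config.simulation.seed = config.seed
    os.makedirs(out_dir, exist_ok=True)
    stage = "simulate"
    try:
        if input_dir is None:
            sim = sim_mod.simulate_all(config.simulation)
            sim_mod.write_fixture_bundle(sim, os.path.join(out_dir, "inputs"),
                                         overwrite=True)
        else:
            sim = sim_mod.read_fixture_bundle(input_dir)
        catalog, homeologs, expr, panel, truth = sim
        bundle = SummaryBundle(config_hash=config.config_hash())

        stage = "expression"
        deg_frames = []
        for tissue in expr.design["tissue"].unique():
            for tp in sorted(expr.design["timepoint_h"].unique()):
                if tp == 0:
                    continue
                deg_frames.append(expr_mod.call_degs(
                    expr, tissue, int(tp), fc_min=config.fc_min,
                    fpkm_min=config.deg_fpkm_min, epsilon=config.epsilon,
                    mode=config.deg_mode, alpha=config.alpha))
        bundle.deg_table = pd.concat(deg_frames, ignore_index=True)
        bundle.deg_counts, bundle.unions, grand_union = expr_mod.deg_counts(deg_frames)
        bundle.core_set, bundle.core_regions = expr_mod.core_degs(bundle.unions)
        bundle.tf_response = expr_mod.tf_response_table(catalog, bundle.unions,
                                                        grand_union)

        stage = "homeolog"
        bundle.groups = homeo_mod.classify_groups(homeologs, catalog)
        bundle.category_counts = (bundle.groups.groupby("category").size()
                                  .rename("n_groups").reset_index())
        triads = bundle.groups[bundle.groups["category"] == "triad"]
        for tissue in expr.design["tissue"].unique():
            frac = homeo_mod.ternary_fractions(
                expr, triads, homeologs, catalog, tissue=tissue,
                salt_only=config.bias_context == "salt",
                expression_floor=config.expression_floor)
            bundle.bias_tables[tissue] = homeo_mod.classify_bias_table(
                frac, config.balanced_radius)
        bundle.dominance = homeo_mod.dominance_summary(
            bundle.bias_tables, homeologs, catalog, deg_union=grand_union)

        stage = "network"
        net_in = net_mod.network_input(expr, grand_union, config.network_fpkm_min)
        scan_res, module_set, tom = net_mod.build_network(
            net_in, betas=config.beta_range, r2_target=config.r2_target,
            min_size=config.min_module_size, merge_cut=config.merge_cut,
            cut_height_quantile=config.cut_height_quantile)
        bundle.soft_threshold = scan_res.table if scan_res else None
        bundle.module_labels = module_set.labels
        bundle.module_census = (module_set.labels.value_counts()
                                .rename_axis("module").rename("n_genes")
                                .reset_index().sort_values("module",
                                                           ignore_index=True))
        bundle.eigengene_adjacency = module_set.eigengene_adjacency
        bundle.enrichment = net_mod.module_tissue_enrichment(module_set,
                                                             bundle.unions)

        stage = "association"
        panel_qc, bundle.qc_report = assoc_mod.qc_markers(
            panel, config.maf_min, config.miss_max)
        pcs = assoc_mod.pca_covariates(panel_qc, config.n_pcs)
        bundle.assoc_table = assoc_mod.scan(
            panel_qc, covariates=pcs,
            genome_wide_threshold=config.genome_wide_threshold)
        top = bundle.assoc_table.loc[bundle.assoc_table["pvalue"].idxmin()]
        bundle.ld = assoc_mod.ld_r2(
            panel_qc, region=(top["chrom"], int(top["pos"]) - 500_000,
                              int(top["pos"]) + 500_000))
        if CAUSAL_MARKER_ID in set(panel_qc.markers["marker_id"]):
            bundle.haplotype = assoc_mod.haplotype_compare(
                panel_qc, CAUSAL_MARKER_ID).to_frame()

        stage = "report"
        dominant_groups = {
            g for table in bundle.bias_tables.values()
            for g in table.loc[table["label"].str.endswith("dominant"), "group_id"]}
        bundle.candidates = candidate_genes(
            bundle.assoc_table, catalog, expr, grand_union, bundle.groups,
            homeologs, module_labels=bundle.module_labels,
            dominant_groups=dominant_groups,
            threshold=config.genome_wide_threshold,
            window_bp=config.candidate_window_bp,
            expressed_floor=config.deg_fpkm_min)

        problems = reconcile(bundle)
        if problems:
            raise RuntimeError("reconciliation failed: " + "; ".join(problems))
        manifest = _write_bundle(bundle, config, out_dir)
        return bundle, manifest
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err


def _write_bundle(bundle: SummaryBundle, config: PipelineConfig,
                  out_dir: str) -> pd.DataFrame:
    files = {}

    def put(name, df, index=False):
        io.write_tsv(df, os.path.join(out_dir, name), index=index)
        files[name] = len(df)

    put("deg_records.tsv", bundle.deg_table)
    put("deg_counts.tsv", bundle.deg_counts)
    for tissue in sorted(bundle.unions):
        put(f"deg_union_{tissue}.tsv",
            pd.DataFrame({"gene_id": sorted(bundle.unions[tissue])}))
    put("core_degs.tsv", pd.DataFrame({"gene_id": sorted(bundle.core_set)}))
    put("core_regions.tsv", bundle.core_regions)
    put("tf_response.tsv", bundle.tf_response)
    put("homeolog_categories.tsv", bundle.groups)
    put("category_counts.tsv", bundle.category_counts)
    for tissue, table in sorted(bundle.bias_tables.items()):
        put(f"triad_bias_{tissue}.tsv", table)
    for name, table in sorted(bundle.dominance.items()):
        put(f"dominance_{name}.tsv", table)
    if bundle.soft_threshold is not None:
        put("soft_threshold_scan.tsv", bundle.soft_threshold)
    put("module_assignment.tsv",
        bundle.module_labels.rename("module").rename_axis("gene_id").reset_index())
    put("module_census.tsv", bundle.module_census)
    put("eigengene_adjacency.tsv", bundle.eigengene_adjacency, index=True)
    put("module_tissue_enrichment.tsv", bundle.enrichment)
    put("assoc_qc_report.tsv", bundle.qc_report)
    put("association.tsv", bundle.assoc_table)
    put("ld_r2.tsv", bundle.ld, index=True)
    if bundle.haplotype is not None:
        put("haplotype_comparison.tsv", bundle.haplotype)
    put("candidates.tsv", bundle.candidates)

    with open(os.path.join(out_dir, "config.yaml"), "w", encoding="utf-8") as fh:
        fh.write(f"# config_hash: {bundle.config_hash}\n" + config.to_yaml())
    files["config.yaml"] = 1

    lines = [
        "# Pipeline summary", "",
        f"- config hash: `{bundle.config_hash}`",
        f"- DEGs (grand union): {len(set().union(*bundle.unions.values()))}",
        f"- core DEGs shared by all tissues: {len(bundle.core_set)}",
        f"- homeolog groups: {int(bundle.category_counts['n_groups'].sum())} "
        f"({int(bundle.category_counts.set_index('category')['n_groups'].get('triad', 0))} triads)",
        f"- co-expression modules (non-grey): "
        f"{int((bundle.module_census['module'] != 'grey').sum())}",
        f"- markers passing QC: "
        f"{int(bundle.qc_report.loc[bundle.qc_report['rule'] == 'retained', 'n_dropped'].iloc[0])}",
        f"- candidate genes near significant markers: {len(bundle.candidates)}",
    ]
    with open(os.path.join(out_dir, "summary.md"), "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")
    files["summary.md"] = len(lines)

    manifest = pd.DataFrame(sorted(files.items()), columns=["file", "n_rows"])
    manifest.insert(0, "config_hash", bundle.config_hash)
    io.write_tsv(manifest, os.path.join(out_dir, "manifest.tsv"))
    return manifest
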