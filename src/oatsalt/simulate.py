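"""Ground-truth synthetic data for every pipeline stage.

The generator emulates the structure of an allohexaploid oat salt-stress
study: a gene catalog with A/C/D subgenome assignments organised into
homeolog groups (triads, dyads, singletons), a negative-binomial count
matrix over a 3-tissue x 5-timepoint x 3-replicate design with planted
salt-responsive genes, subgenome-dominance fractions and co-expression
modules, and a genotyped accession panel with a planted causal 3-bp
promoter InDel affecting germination rate.

Everything planted is recorded in :class:`GroundTruth` so downstream stages
have a parameter-recovery oracle.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from . import io
from .association import GenotypePanel
from .config import (CAUSAL_ALT, CAUSAL_CHROM, CAUSAL_MARKER_ID, CAUSAL_POS,
                     CAUSAL_REF, DOMINANCE_LABELS, SUBGENOMES, TF_FAMILIES,
                     SimulationConfig)
from .expression import ExpressionMatrix

_GENE_EFFECT_SD = 0.5      # log2-scale between-gene baseline spread
_TISSUE_INCLUDE_P = 0.6    # chance each tissue joins a DE gene's response set
_BALANCED_MAX_DIST = 0.08  # planted balanced triads stay well inside radius 0.2
_DOMINANT_FRAC = (0.6, 0.85)
_N_REGION_MARKERS = 20     # markers clustered around the causal InDel for LD maps


@dataclass
class GroundTruth:
    """Planted values: per-gene DE status, per-triad dominance, causal marker."""

    genes: pd.DataFrame | None = None        # gene_id, group_id, is_de, de_sign, de_tissues, log2fc, module
    triads: pd.DataFrame | None = None       # group_id, label, f_a, f_c, f_d
    population: pd.DataFrame | None = None   # causal_marker, causal_gene, causal_effect

    def true_log2fc(self, tissue: str) -> pd.Series:
        """Planted log2 fold change (salt vs control) per gene in one tissue."""
        g = self.genes
        responds = g["is_de"] & g["de_tissues"].str.split(";").map(lambda ts: tissue in ts)
        return pd.Series(np.where(responds, g["de_sign"] * g["log2fc"], 0.0),
                         index=g["gene_id"], name="log2fc")

    def merged(self, other: "GroundTruth") -> "GroundTruth":
        return GroundTruth(
            genes=self.genes if self.genes is not None else other.genes,
            triads=self.triads if self.triads is not None else other.triads,
            population=self.population if self.population is not None else other.population,
        )


class SimBundle(NamedTuple):
    catalog: pd.DataFrame
    homeologs: pd.DataFrame
    expression: ExpressionMatrix
    panel: GenotypePanel
    truth: GroundTruth


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    # independent, reproducible streams per generator stage
    return np.random.default_rng([int(config.seed), stream])


# ---------------------------------------------------------------------------
# catalog and homeolog map

def simulate_catalog(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate the gene catalog and homeolog-group map.

    Triads carry one copy per subgenome; dyads one copy in each of two
    subgenomes (patterns AC, AD, CD); singletons a single copy. One dyad_AD
    group is designated causal: its D copy is a WRKY-family gene placed next
    to the causal promoter InDel on chromosome 4D.
    """
    config.validate()
    if config.n_genes() == 0:
        raise ValueError("simulation requests zero genes")
    rng = _rng(config, 0)

    members: list[tuple[str, str]] = []   # (group_id, subgenome)
    gid = 0

    def new_group(subs):
        nonlocal gid
        gid += 1
        group = f"HG{gid:05d}"
        for s in subs:
            members.append((group, s))
        return group

    for _ in range(config.n_triads):
        new_group("ACD")
    causal_group = None
    for pattern in ("AC", "AD", "CD"):
        for i in range(config.n_dyads_per_pattern):
            g = new_group(pattern)
            if pattern == "AD" and i == 0:
                causal_group = g
    for sub in SUBGENOMES:
        for _ in range(config.n_singletons_per_subgenome):
            new_group(sub)

    df = pd.DataFrame(members, columns=["group_id", "subgenome"])
    df["chromosome"] = [f"{c}{s}" for c, s in
                        zip(rng.integers(1, 8, len(df)), df["subgenome"])]
    df["start"] = rng.integers(1, 600_000_000, len(df))
    df["length_bp"] = rng.integers(300, 10_001, len(df))

    # group-level TF family labels: homeologs share their family
    groups = df["group_id"].unique()
    is_tf = rng.random(len(groups)) < config.tf_fraction
    fam = rng.choice(TF_FAMILIES, len(groups))
    family_of = {g: (fam[i] if is_tf[i] else "") for i, g in enumerate(groups)}
    df["tf_family"] = df["group_id"].map(family_of)

    if causal_group is not None:
        mask = (df["group_id"] == causal_group) & (df["subgenome"] == "D")
        df.loc[df["group_id"] == causal_group, "tf_family"] = "WRKY"
        df.loc[mask, ["chromosome", "start"]] = [CAUSAL_CHROM, CAUSAL_POS + 701]

    # gene ids numbered along each chromosome by position
    df = df.sort_values(["chromosome", "start"], kind="stable").reset_index(drop=True)
    serial = df.groupby("chromosome").cumcount() + 1
    df["gene_id"] = ["OT" + c + f"{n:06d}" for c, n in zip(df["chromosome"], serial)]

    catalog = df[["gene_id", "subgenome", "chromosome", "start",
                  "length_bp", "tf_family"]].copy()
    homeologs = df[["group_id", "gene_id"]].sort_values(
        ["group_id", "gene_id"], ignore_index=True)
    if causal_group is not None:
        causal = df[(df["group_id"] == causal_group) & (df["subgenome"] == "D")]
        catalog.attrs["causal_gene"] = causal["gene_id"].iloc[0]
        catalog.attrs["causal_group"] = causal_group
    return catalog, homeologs


# ---------------------------------------------------------------------------
# expression

def simulate_expression(catalog: pd.DataFrame, homeologs: pd.DataFrame,
                        config: SimulationConfig) -> tuple[ExpressionMatrix, GroundTruth]:
    """Draw negative-binomial counts with planted DE, dominance and modules.

    Per-gene/sample mean (log2 scale): baseline + length + subgenome-fraction
    factor (triads) + DE shift (salt timepoints of responsive tissues only)
    + shared module profile scaled by module_snr. With nb_dispersion = 0 the
    counts collapse to rounded means (noise-free mode used by tests).
    """
    config.validate()
    if len(catalog) == 0:
        raise ValueError("catalog is empty")
    if config.nb_dispersion < 0:
        raise ValueError("nb_dispersion must be >= 0")
    rng = _rng(config, 1)

    genes = catalog.merge(homeologs, on="gene_id", how="left")
    n_genes = len(genes)
    tissues = list(config.tissues)

    # sample design
    rows = []
    for t in tissues:
        for tp in config.timepoints_h:
            for r in range(1, config.replicates + 1):
                rows.append({"sample_id": f"{t}_{tp}h_r{r}", "tissue": t,
                             "timepoint_h": tp, "replicate": r})
    design = pd.DataFrame(rows).set_index("sample_id")
    n_samples = len(design)

    # --- group-shared DE assignment ---------------------------------------
    group_ids = genes["group_id"].fillna(genes["gene_id"]).to_numpy()
    uniq_groups, group_idx = np.unique(group_ids, return_inverse=True)
    g_is_de = rng.random(len(uniq_groups)) < config.de_fraction
    g_sign = rng.choice([-1.0, 1.0], len(uniq_groups))
    g_tissues = []
    for _ in uniq_groups:
        sel = rng.random(len(tissues)) < _TISSUE_INCLUDE_P
        if not sel.any():
            sel[rng.integers(len(tissues))] = True
        g_tissues.append(tuple(np.array(tissues)[sel]))

    # the designated causal TF group is always salt-upregulated
    causal_group = catalog.attrs.get("causal_group")
    if causal_group is not None and causal_group in uniq_groups:
        where = int(np.flatnonzero(uniq_groups == causal_group)[0])
        g_is_de[where] = True
        g_sign[where] = 1.0

    is_de = g_is_de[group_idx]
    de_sign = np.where(is_de, g_sign[group_idx], 0.0)
    de_tissues = [";".join(g_tissues[i]) if is_de[k] else ""
                  for k, i in enumerate(group_idx)]

    # --- planted modules (among DE genes; one tissue and sign per module) --
    module = np.array([""] * n_genes, dtype=object)
    module_profiles = {}
    if config.n_modules > 0 and config.module_snr > 0:
        pool = np.flatnonzero(is_de)
        pool = pool[rng.permutation(len(pool))]
        lo, hi = config.module_size_range
        offset = 0
        for m in range(config.n_modules):
            size = int(rng.integers(lo, hi + 1))
            chosen = pool[offset:offset + size]
            if len(chosen) == 0:
                break
            offset += size
            label = f"TM{m + 1}"
            module[chosen] = label
            module_profiles[label] = rng.normal(0.0, 1.0, n_samples)
            m_tissue = tissues[m % len(tissues)]
            m_sign = float(rng.choice([-1.0, 1.0]))
            for g in chosen:
                de_tissues[g] = m_tissue
                de_sign[g] = m_sign

    # --- triad dominance fractions -----------------------------------------
    pattern = (genes.groupby("group_id")["subgenome"]
               .agg(lambda s: tuple(sorted(s))))
    triad_groups = [g for g, p in pattern.items() if p == ("A", "C", "D")]
    labels = rng.choice(len(DOMINANCE_LABELS), len(triad_groups),
                        p=list(config.dominance_mix))
    frac_rows = []
    for g, lab in zip(triad_groups, labels):
        name = DOMINANCE_LABELS[lab]
        if name == "balanced":
            # uniform within a disc of radius _BALANCED_MAX_DIST around the centroid
            theta = rng.uniform(0, 2 * np.pi)
            r = _BALANCED_MAX_DIST * np.sqrt(rng.uniform())
            u = np.array([np.cos(theta), np.sin(theta)])
            basis = np.array([[1, -1, 0], [1, 1, -2]]) / np.array([[np.sqrt(2)], [np.sqrt(6)]])
            f = np.full(3, 1 / 3) + u @ basis * r
        else:
            f_dom = rng.uniform(*_DOMINANT_FRAC)
            f = np.full(3, (1 - f_dom) / 2)
            f[lab] = f_dom
        frac_rows.append({"group_id": g, "label": name,
                          "f_a": f[0], "f_c": f[1], "f_d": f[2]})
    triad_truth = pd.DataFrame(frac_rows)

    frac_factor = np.ones(n_genes)
    if len(triad_truth):
        lut = triad_truth.set_index("group_id")
        in_triad = genes["group_id"].isin(lut.index).to_numpy()
        cols = {"A": "f_a", "C": "f_c", "D": "f_d"}
        fvals = np.array([
            lut.loc[g, cols[s]] if t else 1.0
            for g, s, t in zip(genes["group_id"], genes["subgenome"], in_triad)
        ])
        frac_factor = np.where(in_triad, 3.0 * fvals, 1.0)

    # --- mean model ---------------------------------------------------------
    # baseline spread is drawn per homeolog group (copies share regulatory
    # context) so planted subgenome fractions stay identifiable
    gene_effect = rng.normal(0.0, _GENE_EFFECT_SD, len(uniq_groups))[group_idx]
    base = (config.baseline_log_mean
            + np.log2(genes["length_bp"].to_numpy() / 1e3)
            + np.log2(np.maximum(frac_factor, 1e-12))
            + gene_effect)
    log2mu = np.tile(base[:, None], (1, n_samples))

    salt = (design["timepoint_h"] > 0).to_numpy()
    for t in tissues:
        cols = ((design["tissue"] == t).to_numpy()) & salt
        responds = np.array([t in dt.split(";") if dt else False for dt in de_tissues])
        log2mu[np.ix_(responds, cols)] += (de_sign[responds, None]
                                           * config.de_log2fc_magnitude)
    for label, profile in module_profiles.items():
        rows_m = module == label
        log2mu[rows_m, :] += config.module_snr * profile[None, :]

    mu = np.exp2(log2mu)
    if config.nb_dispersion == 0:
        counts = np.rint(mu).astype(np.int64)
    else:
        n_nb = 1.0 / config.nb_dispersion
        counts = rng.negative_binomial(n_nb, n_nb / (n_nb + mu)).astype(np.int64)

    counts_df = pd.DataFrame(counts, index=genes["gene_id"], columns=design.index)
    lengths = pd.Series(genes["length_bp"].to_numpy(), index=genes["gene_id"],
                        name="length_bp")
    expr = ExpressionMatrix(counts_df, lengths, design)

    truth_genes = pd.DataFrame({
        "gene_id": genes["gene_id"],
        "group_id": genes["group_id"],
        "is_de": is_de,
        "de_sign": de_sign,
        "de_tissues": de_tissues,
        "log2fc": np.where(is_de, config.de_log2fc_magnitude, 0.0),
        "module": module,
    })
    return expr, GroundTruth(genes=truth_genes, triads=triad_truth)


# ---------------------------------------------------------------------------
# population

def simulate_population(config: SimulationConfig,
                        causal_gene: str = "") -> tuple[GenotypePanel, GroundTruth]:
    """Genotype an accession panel and plant a causal promoter InDel.

    Markers are biallelic, Hardy-Weinberg drawn at a uniform MAF; the causal
    record is a 3-bp deletion (REF TCACTC / ALT TCC) whose insertion-carrying
    reference allele (Hap1) raises germination rate by ``causal_effect`` per
    copy. Missing genotypes are masked at ``missing_rate``.
    """
    config.validate()
    if config.n_markers < 1:
        raise ValueError("n_markers must be >= 1")
    rng = _rng(config, 2)
    n_acc, n_mark = config.n_accessions, config.n_markers

    chroms = [f"{c}{s}" for s in SUBGENOMES for c in range(1, 8)]
    n_region = min(_N_REGION_MARKERS, max(n_mark - 1, 0))
    n_bg = n_mark - 1 - n_region

    rows = []
    bg_chroms = rng.choice(chroms, n_bg)
    bg_pos = rng.integers(1, 600_000_000, n_bg)
    for c, p in zip(bg_chroms, bg_pos):
        rows.append({"marker_id": f"SNP_{c}_{p}", "chrom": c, "pos": int(p),
                     "ref": "A", "alt": "T", "type": "SNP"})
    region_pos = rng.integers(CAUSAL_POS - 500_000, CAUSAL_POS + 500_000, n_region)
    for p in region_pos:
        rows.append({"marker_id": f"SNP_{CAUSAL_CHROM}_{p}", "chrom": CAUSAL_CHROM,
                     "pos": int(p), "ref": "G", "alt": "C", "type": "SNP"})
    rows.append({"marker_id": CAUSAL_MARKER_ID, "chrom": CAUSAL_CHROM,
                 "pos": CAUSAL_POS, "ref": CAUSAL_REF, "alt": CAUSAL_ALT,
                 "type": "InDel"})
    markers = pd.DataFrame(rows).drop_duplicates(["chrom", "pos"])
    markers = markers.sort_values(["chrom", "pos"], ignore_index=True)

    maf = rng.uniform(*config.maf_range, len(markers))
    maf[markers["marker_id"] == CAUSAL_MARKER_ID] = config.causal_maf
    dosage = rng.binomial(2, maf[None, :].repeat(n_acc, axis=0)).astype(float)

    accessions = [f"ACC{i:03d}" for i in range(1, n_acc + 1)]
    dosage_df = pd.DataFrame(dosage, index=accessions, columns=markers["marker_id"])

    # phenotype from the true (pre-missingness) causal genotype
    hap1_copies = 2.0 - dosage_df[CAUSAL_MARKER_ID].to_numpy()
    noise = rng.normal(0.0, config.phenotype_sd, n_acc) if config.phenotype_sd > 0 else 0.0
    phenotype = pd.Series(config.phenotype_mean + config.causal_effect * hap1_copies
                          + noise, index=accessions, name="germination_rate")

    if config.missing_rate > 0:
        mask = rng.random(dosage_df.shape) < config.missing_rate
        dosage_df = dosage_df.mask(mask)

    panel = GenotypePanel(markers=markers, dosage=dosage_df, phenotype=phenotype)
    truth = GroundTruth(population=pd.DataFrame([{
        "causal_marker": CAUSAL_MARKER_ID,
        "causal_gene": causal_gene,
        "causal_effect": config.causal_effect,
    }]))
    return panel, truth


def simulate_all(config: SimulationConfig) -> SimBundle:
    """Run all three generators and merge their ground truths."""
    catalog, homeologs = simulate_catalog(config)
    expr, truth_e = simulate_expression(catalog, homeologs, config)
    panel, truth_p = simulate_population(config, catalog.attrs.get("causal_gene", ""))
    return SimBundle(catalog, homeologs, expr, panel, truth_e.merged(truth_p))


# ---------------------------------------------------------------------------
# fixture bundle

_FILES = ("catalog.tsv", "homeologs.tsv", "design.tsv", "counts.tsv",
          "phenotype.tsv", "genotypes.vcf", "truth_genes.tsv",
          "truth_triads.tsv", "truth_population.tsv", "manifest.tsv")


def write_fixture_bundle(bundle: SimBundle, directory: str,
                         overwrite: bool = False) -> pd.DataFrame:
    """Write all fixture tables + a minimal VCF; returns the file manifest."""
    os.makedirs(directory, exist_ok=True)
    paths = {name: os.path.join(directory, name) for name in _FILES}
    io.ensure_fresh(paths.values(), overwrite)

    io.write_tsv(bundle.catalog, paths["catalog.tsv"])
    io.write_tsv(bundle.homeologs, paths["homeologs.tsv"])
    io.write_tsv(bundle.expression.design.reset_index(), paths["design.tsv"])
    io.write_tsv(bundle.expression.counts, paths["counts.tsv"], index=True)
    io.write_tsv(bundle.panel.phenotype.rename_axis("accession").reset_index(),
                 paths["phenotype.tsv"])
    io.write_vcf(bundle.panel.markers, bundle.panel.dosage, paths["genotypes.vcf"])
    io.write_tsv(bundle.truth.genes, paths["truth_genes.tsv"])
    io.write_tsv(bundle.truth.triads, paths["truth_triads.tsv"])
    io.write_tsv(bundle.truth.population, paths["truth_population.tsv"])

    rows = {
        "catalog.tsv": len(bundle.catalog),
        "homeologs.tsv": len(bundle.homeologs),
        "design.tsv": len(bundle.expression.design),
        "counts.tsv": len(bundle.expression.counts),
        "phenotype.tsv": len(bundle.panel.phenotype),
        "genotypes.vcf": len(bundle.panel.markers),
        "truth_genes.tsv": len(bundle.truth.genes),
        "truth_triads.tsv": len(bundle.truth.triads),
        "truth_population.tsv": len(bundle.truth.population),
    }
    manifest = pd.DataFrame(sorted(rows.items()), columns=["file", "n_rows"])
    io.write_tsv(manifest, paths["manifest.tsv"])
    return manifest


def read_fixture_bundle(directory: str) -> SimBundle:
    """Re-read a fixture bundle into the in-memory objects."""
    p = {name: os.path.join(directory, name) for name in _FILES}
    catalog = io.read_tsv(p["catalog.tsv"]).fillna({"tf_family": ""})
    homeologs = io.read_tsv(p["homeologs.tsv"])
    design = io.read_tsv(p["design.tsv"], index_col="sample_id")
    counts = io.read_tsv(p["counts.tsv"], index_col="gene_id")
    counts.columns.name = "sample_id"
    lengths = pd.Series(catalog.set_index("gene_id")["length_bp"]
                        .reindex(counts.index), name="length_bp")
    expr = ExpressionMatrix(counts, lengths, design)
    pheno = io.read_tsv(p["phenotype.tsv"]).set_index("accession")["germination_rate"]
    markers, dosage = io.read_vcf(p["genotypes.vcf"])
    panel = GenotypePanel(markers=markers, dosage=dosage, phenotype=pheno)
    truth = GroundTruth(
        genes=io.read_tsv(p["truth_genes.tsv"]).fillna({"de_tissues": "", "module": ""}),
        triads=io.read_tsv(p["truth_triads.tsv"]),
        population=io.read_tsv(p["truth_population.tsv"]).fillna({"causal_gene": ""}),
    )
    return SimBundle(catalog, homeologs, expr, panel, truth)
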