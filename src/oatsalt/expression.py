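"""FPKM quantification and threshold-based differential-expression calling.

Differential expression is called per tissue and timepoint against the 0-h
control of the same tissue using the study's filter: |log2 fold change| >= 1
(boundary inclusive) with an FPKM > 0.5 expression floor applied to the
larger of the two group means. An optional "test" mode adds a Welch t-test
on log2(FPKM + 1) with Benjamini-Hochberg adjustment across genes within
the contrast.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class ExpressionMatrix:
    """Counts over a tissue/timepoint/replicate design, with lazy FPKM.

    counts : genes x samples, non-negative integers.
    lengths : exonic length in bp per gene (same index as counts).
    design : indexed by sample id with columns tissue, timepoint_h, replicate.
    """

    counts: pd.DataFrame
    lengths: pd.Series
    design: pd.DataFrame

    _fpkm: pd.DataFrame | None = None

    def __post_init__(self):
        if list(self.counts.columns) != list(self.design.index):
            raise ValueError("counts columns must match design sample ids")
        if not self.counts.index.equals(self.lengths.index):
            raise ValueError("counts index must match gene lengths index")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        key = self.design[["tissue", "timepoint_h", "replicate"]]
        if key.duplicated().any():
            raise ValueError("(tissue, timepoint, replicate) must be unique")

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def fpkm(self) -> pd.DataFrame:
        if self._fpkm is None:
            self._fpkm = compute_fpkm(self.counts, self.lengths)
        return self._fpkm

    def samples_for(self, tissue: str, timepoint: int) -> list[str]:
        mask = (self.design["tissue"] == tissue) & (self.design["timepoint_h"] == timepoint)
        return list(self.design.index[mask])


def compute_fpkm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Fragments per kilobase of exon per million mapped fragments.

    fpkm[g, s] = counts[g, s] / (length_kb[g] * libsize[s] / 1e6)
    """
    lengths = lengths.reindex(counts.index)
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    libsize = counts.sum(axis=0)
    zero = libsize[libsize <= 0]
    if len(zero):
        raise ValueError(f"zero library size for sample(s): {list(zero.index)}")
    length_kb = lengths.to_numpy()[:, None] / 1e3
    scale = libsize.to_numpy()[None, :] / 1e6
    return pd.DataFrame(counts.to_numpy() / (length_kb * scale),
                        index=counts.index, columns=counts.columns)


def call_degs(expr: ExpressionMatrix, tissue: str, timepoint: int, *,
              fc_min: float = 1.0, fpkm_min: float = 0.5, epsilon: float = 0.01,
              mode: str = "threshold", alpha: float = 0.05) -> pd.DataFrame:
    """Call DEGs for one tissue/timepoint contrast against the 0-h control.

    Returns one record per gene with log2fc, group means, (optional) p-values
    and the is_deg flag.
    """
    if timepoint == 0:
        raise ValueError("cannot contrast the 0-h control against itself")
    treated = expr.samples_for(tissue, timepoint)
    control = expr.samples_for(tissue, 0)
    if not treated or not control:
        raise ValueError(f"unknown tissue/timepoint: {tissue!r} at {timepoint} h")

    fpkm = expr.fpkm
    mean_t = fpkm[treated].mean(axis=1)
    mean_c = fpkm[control].mean(axis=1)
    log2fc = np.log2((mean_t + epsilon) / (mean_c + epsilon))
    expressed = np.maximum(mean_t, mean_c) > fpkm_min
    is_deg = (log2fc.abs() >= fc_min) & expressed

    pval = np.full(len(fpkm), np.nan)
    padj = np.full(len(fpkm), np.nan)
    if mode == "test":
        lt = np.log2(fpkm[treated].to_numpy() + 1.0)
        lc = np.log2(fpkm[control].to_numpy() + 1.0)
        res = stats.ttest_ind(lt, lc, axis=1, equal_var=False)
        pval = np.where(np.isfinite(res.pvalue), res.pvalue, 1.0)
        padj = stats.false_discovery_control(pval)
        is_deg = is_deg & (padj < alpha)
    elif mode != "threshold":
        raise ValueError(f"unknown mode {mode!r}")

    return pd.DataFrame({
        "gene_id": fpkm.index,
        "tissue": tissue,
        "timepoint_h": timepoint,
        "log2fc": log2fc.to_numpy(),
        "mean_fpkm_treated": mean_t.to_numpy(),
        "mean_fpkm_control": mean_c.to_numpy(),
        "pvalue": pval,
        "padj": padj,
        "is_deg": is_deg.to_numpy(),
    })


def deg_counts(deg_tables: Iterable[pd.DataFrame]):
    """Per-(tissue, timepoint) DEG counts plus per-tissue and grand unions.

    Returns (counts table, per-tissue union dict, grand union set); the
    per-tissue union is the set of genes differential at >= 1 timepoint.
    """
    table = pd.concat(list(deg_tables), ignore_index=True)
    hits = table[table["is_deg"]]
    counts = (hits.groupby(["tissue", "timepoint_h"]).size()
              .rename("n_degs").reset_index())
    unions = {t: set(g["gene_id"]) for t, g in hits.groupby("tissue")}
    for tissue in table["tissue"].unique():
        unions.setdefault(tissue, set())
    grand = set().union(*unions.values()) if unions else set()
    return counts, unions, grand


def core_degs(unions: Mapping[str, set]):
    """Intersection across tissues plus exclusive (UpSet-style) region counts.

    The 2^k - 1 exclusive membership regions partition the grand union; the
    core set is the all-tissue region.
    """
    tissues = list(unions)
    if len(tissues) < 2:
        raise ValueError("core-DEG intersection needs >= 2 tissues")
    core = set.intersection(*(set(unions[t]) for t in tissues))
    rows = []
    for r in range(1, len(tissues) + 1):
        for combo in combinations(tissues, r):
            inside = set.intersection(*(set(unions[t]) for t in combo))
            outside = set().union(*(set(unions[t]) for t in tissues if t not in combo)) \
                if len(combo) < len(tissues) else set()
            exclusive = inside - outside
            rows.append({**{t: t in combo for t in tissues},
                         "n_genes": len(exclusive)})
    regions = pd.DataFrame(rows)
    return core, regions


def responsive_fraction(subset: Iterable[str], deg_union: set) -> float:
    """Fraction of a gene subset that is salt-responsive (in the DEG union)."""
    subset = set(subset)
    if not subset:
        raise ValueError("gene subset must be nonempty")
    return len(subset & set(deg_union)) / len(subset)


def tf_response_table(catalog: pd.DataFrame, unions: Mapping[str, set],
                      grand_union: set) -> pd.DataFrame:
    """Salt-responsive counts/proportions per TF family, overall and per tissue."""
    tf = catalog[catalog["tf_family"].notna() & (catalog["tf_family"] != "")]
    rows = []
    for family, members in tf.groupby("tf_family"):
        genes = set(members["gene_id"])
        row = {"tf_family": family, "n_genes": len(genes),
               "n_responsive": len(genes & grand_union),
               "pct_responsive": 100.0 * responsive_fraction(genes, grand_union)}
        for tissue, union in unions.items():
            row[f"pct_{tissue}"] = 100.0 * responsive_fraction(genes, union)
        rows.append(row)
    return pd.DataFrame(rows).sort_values("tf_family", ignore_index=True)
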