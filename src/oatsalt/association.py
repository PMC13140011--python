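"""Marker QC, PC-covariate association scan, LD r² and haplotype comparison.

The scan regresses the germination-rate phenotype on each marker's allele
dosage with genotype principal components as fixed covariates (a linear
stand-in for a kinship mixed model) and reports a Wald test on the dosage
coefficient. The haplotype comparison groups accessions homozygous for the
insertion-carrying (Hap1) versus deletion (Hap2) allele of a focal InDel
and applies a Student's t-test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class GenotypePanel:
    """Accessions x biallelic markers with a germination-rate phenotype.

    markers : marker_id, chrom, pos (1-based), ref, alt, type (SNP/InDel).
    dosage : alternate-allele copies (0/1/2), NaN = missing genotype.
    phenotype : germination rate per accession (percentage points).
    """

    markers: pd.DataFrame
    dosage: pd.DataFrame
    phenotype: pd.Series | None = None

    def __post_init__(self):
        if list(self.dosage.columns) != list(self.markers["marker_id"]):
            raise ValueError("dosage columns must match markers.marker_id order")
        by_chrom = self.markers.groupby("chrom")["pos"]
        if (by_chrom.diff().dropna() <= 0).any():
            raise ValueError("marker positions must be strictly increasing per chromosome")

    @property
    def accessions(self) -> pd.Index:
        return self.dosage.index

    def maf(self) -> pd.Series:
        freq = self.dosage.mean(axis=0, skipna=True) / 2.0
        return pd.Series(np.minimum(freq, 1.0 - freq), name="maf")

    def missing_rate(self) -> pd.Series:
        return self.dosage.isna().mean(axis=0).rename("missing_rate")

    def subset(self, marker_ids) -> "GenotypePanel":
        keep = self.markers[self.markers["marker_id"].isin(set(marker_ids))]
        return GenotypePanel(markers=keep.reset_index(drop=True),
                             dosage=self.dosage[list(keep["marker_id"])],
                             phenotype=self.phenotype)


def qc_markers(panel: GenotypePanel, maf_min: float = 0.05,
               miss_max: float = 0.1) -> tuple[GenotypePanel, pd.DataFrame]:
    """Retain markers with MAF >= maf_min and missing rate <= miss_max.

    Both boundaries are inclusive. Returns the filtered panel plus a QC
    report with per-rule drop counts.
    """
    if len(panel.markers) == 0:
        raise ValueError("empty genotype panel")
    maf = panel.maf()
    miss = panel.missing_rate()
    low_maf = maf < maf_min
    high_miss = miss > miss_max
    keep = ~(low_maf | high_miss)
    report = pd.DataFrame([
        {"rule": f"maf >= {maf_min}", "n_dropped": int(low_maf.sum())},
        {"rule": f"missing <= {miss_max}", "n_dropped": int(high_miss.sum())},
        {"rule": "retained", "n_dropped": int(keep.sum())},
    ])
    filtered = panel.subset(maf.index[keep])
    if (filtered.maf() <= 0).all():
        raise ValueError("no polymorphic markers remain after QC")
    return filtered, report


def pca_covariates(panel: GenotypePanel, k: int = 3) -> pd.DataFrame:
    """Top-k principal components of the standardized dosage matrix.

    Missing dosages are mean-imputed per marker before standardization;
    monomorphic markers are ignored. Returns accession x k scores.
    """
    n = len(panel.accessions)
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of accessions ({n})")
    X = panel.dosage.to_numpy(dtype=float)
    col_mean = np.nanmean(X, axis=0)
    X = np.where(np.isnan(X), col_mean[None, :], X)
    sd = X.std(axis=0)
    keep = sd > 0
    X = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    u, s, _ = np.linalg.svd(X, full_matrices=False)
    scores = u[:, :k] * s[:k]
    return pd.DataFrame(scores, index=panel.accessions,
                        columns=[f"PC{i + 1}" for i in range(k)])


def scan(panel: GenotypePanel, phenotype: pd.Series | None = None,
         covariates: pd.DataFrame | None = None,
         genome_wide_threshold: float = 1e-4) -> pd.DataFrame:
    """Per-marker least-squares association scan with a Wald test.

    Fits phenotype ~ intercept + covariates + dosage for each marker
    (missing dosages mean-imputed) and tests the dosage coefficient.
    """
    y = panel.phenotype if phenotype is None else phenotype
    if y is None:
        raise ValueError("no phenotype available")
    y = y.reindex(panel.accessions).to_numpy(dtype=float)
    if np.std(y) == 0:
        raise ValueError("phenotype is constant")

    base = [np.ones(len(y))]
    if covariates is not None:
        base.append(covariates.reindex(panel.accessions).to_numpy(dtype=float))
    X0 = np.column_stack(base)

    G = panel.dosage.to_numpy(dtype=float)
    col_mean = np.nanmean(G, axis=0)
    G = np.where(np.isnan(G), col_mean[None, :], G)

    rows = []
    p_cols = X0.shape[1] + 1
    df_resid = len(y) - p_cols
    for j, marker in enumerate(panel.markers.itertuples(index=False)):
        x = G[:, j]
        if np.std(x) == 0:
            continue   # monomorphic after imputation: no test possible
        X = np.column_stack([X0, x])
        XtX_inv = np.linalg.pinv(X.T @ X)
        beta = XtX_inv @ X.T @ y
        resid = y - X @ beta
        sigma2 = resid @ resid / df_resid
        se = np.sqrt(sigma2 * XtX_inv[-1, -1])
        t = beta[-1] / se if se > 0 else 0.0
        p = 2.0 * stats.t.sf(abs(t), df_resid) if se > 0 else 1.0
        rows.append({"marker_id": marker.marker_id, "chrom": marker.chrom,
                     "pos": marker.pos, "beta": beta[-1], "se": se,
                     "pvalue": max(p, np.finfo(float).tiny),
                     "threshold": genome_wide_threshold,
                     "n_covariates": X0.shape[1] - 1})
    return pd.DataFrame(rows)


def ld_r2(panel: GenotypePanel, region: tuple[str, int, int] | None = None,
          marker_ids=None) -> pd.DataFrame:
    """Pairwise composite-LD r²: squared Pearson correlation of dosages.

    ``region`` selects (chrom, start, end); missing genotypes are dropped
    pairwise; monomorphic markers yield NaN rows/columns.
    """
    markers = panel.markers
    if region is not None:
        chrom, start, end = region
        sel = markers[(markers["chrom"] == chrom)
                      & markers["pos"].between(start, end)]["marker_id"]
    elif marker_ids is not None:
        sel = pd.Series(list(marker_ids))
    else:
        sel = markers["marker_id"]
    if len(sel) < 2:
        raise ValueError("LD needs >= 2 markers in the region")
    sub = panel.dosage[list(sel)]
    r2 = sub.corr(method="pearson") ** 2
    return r2


@dataclass
class HaplotypeComparison:
    hap1_label: str
    hap2_label: str
    n1: int
    n2: int
    mean1: float
    mean2: float
    t: float
    pvalue: float
    welch: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "haplotype": self.hap1_label, "n": self.n1, "mean": self.mean1,
            "t": self.t, "pvalue": self.pvalue,
        }, {
            "haplotype": self.hap2_label, "n": self.n2, "mean": self.mean2,
            "t": self.t, "pvalue": self.pvalue,
        }])


def haplotype_compare(panel: GenotypePanel, focal_marker: str,
                      phenotype: pd.Series | None = None,
                      welch: bool = False) -> HaplotypeComparison:
    """Two-group phenotype comparison at a focal InDel.

    Hap1 is the insertion-carrying (longer) allele; accessions homozygous
    for it form group 1, homozygotes for the deletion allele group 2.
    Heterozygous and missing accessions are excluded. Student's (pooled)
    t-test by default, Welch by flag.
    """
    y = panel.phenotype if phenotype is None else phenotype
    rec = panel.markers[panel.markers["marker_id"] == focal_marker]
    if rec.empty:
        raise KeyError(f"marker {focal_marker!r} not in panel")
    ref, alt = rec["ref"].iloc[0], rec["alt"].iloc[0]
    # dosage counts alt copies; the longer allele is insertion-carrying
    hap1_dosage = 0.0 if len(ref) >= len(alt) else 2.0
    dos = panel.dosage[focal_marker]
    g1 = y[dos.index[dos == hap1_dosage]].dropna()
    g2 = y[dos.index[dos == (2.0 - hap1_dosage)]].dropna()
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("each haplotype group needs >= 2 genotyped accessions")
    res = stats.ttest_ind(g1, g2, equal_var=not welch)
    return HaplotypeComparison(
        hap1_label="Hap1", hap2_label="Hap2", n1=len(g1), n2=len(g2),
        mean1=float(g1.mean()), mean2=float(g2.mean()),
        t=float(res.statistic), pvalue=float(res.pvalue), welch=welch)
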