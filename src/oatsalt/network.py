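"""Signed weighted co-expression network: soft threshold, TOM, modules.

The pipeline follows the weighted-network convention of Zhang & Horvath:
signed adjacency a_ij = ((1 + cor_ij)/2)^beta, the soft threshold chosen by
a scale-free topology fit over beta = 1..30, topological overlap
TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij), average-linkage
hierarchical clustering on 1 - TOM with a static quantile tree cut
(a documented, configurable replacement for the dynamic hybrid cut),
module eigengenes as first principal components, and iterative eigengene
merging at dissimilarity 1 - cor below the merge cut.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

GREY = "grey"


@dataclass
class SoftThresholdScan:
    table: pd.DataFrame        # beta, r2 (signed), mean_connectivity
    chosen_beta: int
    r2_target: float


@dataclass
class ModuleSet:
    """Gene -> module labels with eigengenes and merge provenance."""

    labels: pd.Series                      # gene -> label ("grey" = unassigned)
    eigengenes: pd.DataFrame               # module x sample, unit norm
    eigengene_adjacency: pd.DataFrame      # signed: (1 + cor)/2
    eigengene_cor: pd.DataFrame
    merge_history: list = field(default_factory=list)
    params: dict = field(default_factory=dict)

    def sizes(self) -> pd.Series:
        return self.labels.value_counts()

    def members(self, label: str) -> pd.Index:
        return self.labels.index[self.labels == label]


# ---------------------------------------------------------------------------

def network_input(expr, deg_union, fpkm_min: float = 0.2) -> pd.DataFrame:
    """Restrict to salt-responsive genes above the FPKM floor, log-transform.

    Keeps DEG-union genes whose maximum FPKM exceeds ``fpkm_min``, returns
    log2(FPKM + 1) and drops zero-variance genes (count logged via warning).
    """
    fpkm = expr.fpkm
    if fpkm.shape[1] < 3:
        raise ValueError("co-expression needs >= 3 samples")
    genes = [g for g in fpkm.index if g in set(deg_union)]
    sub = fpkm.loc[genes]
    sub = sub[sub.max(axis=1) > fpkm_min]
    mat = np.log2(sub + 1.0)
    variances = mat.var(axis=1)
    n_const = int((variances == 0).sum())
    if n_const:
        warnings.warn(f"dropping {n_const} zero-variance gene(s) from network input")
        mat = mat[variances > 0]
    return mat


def signed_adjacency(expr_matrix: pd.DataFrame, beta: int) -> pd.DataFrame:
    """a_ij = ((1 + cor(x_i, x_j)) / 2)^beta with unit diagonal."""
    if beta < 1:
        raise ValueError("beta must be >= 1")
    X = expr_matrix.to_numpy(dtype=float)
    sd = X.std(axis=1)
    bad = expr_matrix.index[sd == 0]
    if len(bad):
        raise ValueError(f"zero-variance gene(s) give undefined correlations: {list(bad)}")
    cor = np.corrcoef(X)
    a = ((1.0 + np.clip(cor, -1.0, 1.0)) / 2.0) ** beta
    np.fill_diagonal(a, 1.0)
    return pd.DataFrame(a, index=expr_matrix.index, columns=expr_matrix.index)


def scale_free_fit(connectivity: np.ndarray, n_bins: int = 10) -> float:
    """Signed scale-free topology fit index.

    Discretizes connectivity into 10 equal-width bins and regresses
    log10(bin frequency) on log10(mean bin connectivity); the R² is
    sign-flipped negative when the slope is positive (a power law requires
    frequency to fall with connectivity).
    """
    k = np.asarray(connectivity, dtype=float)
    k = k[k > 0]
    if k.size == 0 or np.allclose(k, k[0]):
        raise ValueError("degenerate connectivity: all values identical")
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    edges[-1] += 1e-12
    which = np.digitize(k, edges) - 1
    xs, ys = [], []
    for b in range(n_bins):
        in_bin = which == b
        if in_bin.sum() == 0:
            continue
        xs.append(np.log10(k[in_bin].mean()))
        ys.append(np.log10(in_bin.mean()))
    if len(xs) < 3:
        raise ValueError("degenerate connectivity: too few occupied bins")
    slope, _, r, _, _ = stats.linregress(xs, ys)
    r2 = r ** 2
    return -r2 if slope > 0 else r2


def select_soft_threshold(expr_matrix: pd.DataFrame,
                          betas=tuple(range(1, 31)),
                          r2_target: float = 0.85) -> SoftThresholdScan:
    """Scan candidate powers; choose the smallest with R² >= target.

    Falls back to the argmax R² (with a warning) when no power reaches the
    target.
    """
    if expr_matrix.shape[0] < 50:
        warnings.warn("fewer than 50 genes: scale-free fit is unreliable")
    X = expr_matrix.to_numpy(dtype=float)
    cor = np.corrcoef(X)
    half = (1.0 + np.clip(cor, -1.0, 1.0)) / 2.0
    np.fill_diagonal(half, 0.0)   # exclude self-connectivity
    rows = []
    for beta in betas:
        a = half ** beta
        k = a.sum(axis=1)
        r2 = scale_free_fit(k)
        rows.append({"beta": int(beta), "r2": r2, "mean_connectivity": float(k.mean())})
    table = pd.DataFrame(rows)
    reaching = table[table["r2"] >= r2_target]
    if len(reaching):
        chosen = int(reaching["beta"].iloc[0])
    else:
        chosen = int(table.loc[table["r2"].idxmax(), "beta"])
        warnings.warn(f"no beta reaches scale-free R2 target {r2_target}; "
                      f"using argmax beta={chosen}")
    return SoftThresholdScan(table=table, chosen_beta=chosen, r2_target=r2_target)


def tom_similarity(adjacency: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap: TOM_ij = (l_ij + a_ij) / (min(k_i,k_j) + 1 - a_ij).

    l_ij sums shared-neighbour adjacency excluding i and j themselves;
    k_i is connectivity without the self-edge. TOM_ii = 1.
    """
    A = adjacency.to_numpy(dtype=float)
    if not np.allclose(A, A.T, atol=1e-12):
        raise ValueError("adjacency must be symmetric")
    if A.min() < -1e-12 or A.max() > 1 + 1e-12:
        raise ValueError("adjacency values must lie in [0, 1]")
    A = A.copy()
    np.fill_diagonal(A, 0.0)
    k = A.sum(axis=1)
    # l_ij = sum_u a_iu a_uj over u != i, j; with the diagonal zeroed the
    # matrix product already drops the u = i and u = j terms
    L = A @ A
    denom = np.minimum.outer(k, k) + 1.0 - A
    tom = (L + A) / denom
    np.fill_diagonal(tom, 1.0)
    tom = np.clip(tom, 0.0, 1.0)
    return pd.DataFrame(tom, index=adjacency.index, columns=adjacency.columns)


def detect_modules(diss_tom: pd.DataFrame, min_size: int = 30,
                   cut_height_quantile: float = 0.99) -> pd.Series:
    """Average-linkage clustering on TOM dissimilarity with a quantile cut.

    The tree is cut at the given quantile of merge heights; clusters below
    ``min_size`` are assigned to "grey". Labels "M1", "M2", ... are ordered
    by descending module size.
    """
    if min_size < 2:
        raise ValueError("min_size must be >= 2")
    D = diss_tom.to_numpy(dtype=float)
    condensed = squareform((D + D.T) / 2.0, checks=False)
    Z = linkage(condensed, method="average")
    cut = float(np.quantile(Z[:, 2], cut_height_quantile))
    raw = fcluster(Z, t=cut, criterion="distance")
    labels = pd.Series(raw, index=diss_tom.index, dtype=object)
    sizes = labels.value_counts()
    keep = sizes[sizes >= min_size].index
    ordered = sorted(keep, key=lambda c: (-sizes[c], c))
    rename = {c: f"M{i + 1}" for i, c in enumerate(ordered)}
    return labels.map(lambda c: rename.get(c, GREY))


def module_eigengene(expr_matrix: pd.DataFrame, labels: pd.Series):
    """First-PC eigengene per non-grey module (unit norm over samples).

    Genes are standardized before the SVD; each eigengene is sign-oriented
    to correlate positively with the module's mean expression profile.
    Returns (eigengene DataFrame module x sample, explained-variance Series).
    """
    eigs, expl = {}, {}
    for label in sorted(set(labels) - {GREY}):
        members = labels.index[labels == label]
        X = expr_matrix.loc[members].to_numpy(dtype=float)
        if X.shape[0] == 1:
            warnings.warn(f"module {label} has a single gene; using its profile")
        mu = X.mean(axis=1, keepdims=True)
        sd = X.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        Xs = (X - mu) / sd
        _, s, vt = np.linalg.svd(Xs, full_matrices=False)
        e = vt[0]
        mean_profile = Xs.mean(axis=0)
        if np.dot(e, mean_profile) < 0:
            e = -e
        eigs[label] = e
        expl[label] = float(s[0] ** 2 / (s ** 2).sum()) if s.sum() > 0 else 1.0
    eigengenes = pd.DataFrame(eigs, index=expr_matrix.columns).T
    return eigengenes, pd.Series(expl, name="explained_variance")


def merge_modules(expr_matrix: pd.DataFrame, labels: pd.Series,
                  merge_cut: float = 0.25) -> ModuleSet:
    """Iteratively merge modules whose eigengene dissimilarity is below cut.

    At each step the closest pair (1 - cor < merge_cut) is merged into the
    larger module and eigengenes are recomputed, until no pair qualifies.
    """
    labels = labels.copy()
    history = []
    while True:
        eigengenes, _ = module_eigengene(expr_matrix, labels)
        if len(eigengenes) < 2:
            break
        cor = np.corrcoef(eigengenes.to_numpy())
        diss = 1.0 - cor
        np.fill_diagonal(diss, np.inf)
        i, j = np.unravel_index(np.argmin(diss), diss.shape)
        if diss[i, j] >= merge_cut:
            break
        a, b = eigengenes.index[i], eigengenes.index[j]
        sizes = labels.value_counts()
        keep, gone = (a, b) if sizes[a] >= sizes[b] else (b, a)
        labels[labels == gone] = keep
        history.append({"merged": gone, "into": keep,
                        "dissimilarity": float(diss[i, j])})
    eigengenes, _ = module_eigengene(expr_matrix, labels)
    if len(eigengenes):
        cor = pd.DataFrame(np.corrcoef(eigengenes.to_numpy()) if len(eigengenes) > 1
                           else np.ones((1, 1)),
                           index=eigengenes.index, columns=eigengenes.index)
    else:
        cor = pd.DataFrame()
    return ModuleSet(labels=labels, eigengenes=eigengenes,
                     eigengene_adjacency=(1.0 + cor) / 2.0, eigengene_cor=cor,
                     merge_history=history,
                     params={"merge_cut": merge_cut})


def module_tissue_enrichment(module_set: ModuleSet,
                             tissue_deg_sets: dict,
                             q_threshold: float = 0.05) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of tissue DEGs per module.

    Background is the set of network genes; BH-adjusted q < 0.05 flags a
    module as tissue-dominant.
    """
    genes = set(module_set.labels.index)
    N = len(genes)
    rows = []
    for label in sorted(set(module_set.labels) - {GREY}):
        members = set(module_set.members(label))
        for tissue, degs in tissue_deg_sets.items():
            K = len(set(degs) & genes)
            k = len(members & set(degs))
            p = float(stats.hypergeom.sf(k - 1, N, K, len(members)))
            rows.append({"module": label, "tissue": tissue, "n_module": len(members),
                         "n_tissue_degs": K, "n_overlap": k, "pvalue": p})
    table = pd.DataFrame(rows)
    if len(table):
        table["qvalue"] = stats.false_discovery_control(table["pvalue"])
        table["tissue_dominant"] = table["qvalue"] < q_threshold
    return table


def extract_subnetwork(expr_matrix: pd.DataFrame, module_set: ModuleSet,
                       seed_genes, weight_min: float = 0.5,
                       tom: pd.DataFrame | None = None,
                       tf_families: pd.Series | None = None):
    """Edges between seed genes and their module co-members.

    Keeps pairs with |Pearson cor| >= weight_min; TOM weights are exported
    alongside when a TOM matrix is supplied. Returns (edges, nodes) where
    nodes carry a TF/non-TF annotation.
    """
    seed_genes = list(seed_genes)
    missing = [g for g in seed_genes if g not in module_set.labels.index]
    if missing:
        raise KeyError(f"seed gene(s) outside the network: {missing}")
    seed_modules = set(module_set.labels[seed_genes])
    if len(seed_modules) != 1:
        raise ValueError(f"seed genes span multiple modules: {sorted(seed_modules)}")
    label = seed_modules.pop()
    members = list(module_set.members(label))
    X = expr_matrix.loc[members].to_numpy(dtype=float)
    cor = np.corrcoef(X)
    idx = {g: i for i, g in enumerate(members)}
    seeds = set(seed_genes)
    rows = []
    for i, gi in enumerate(members):
        for j in range(i + 1, len(members)):
            gj = members[j]
            if gi not in seeds and gj not in seeds:
                continue
            r = float(cor[i, j])
            if abs(r) >= weight_min:
                row = {"source": gi, "target": gj, "pearson": r}
                if tom is not None:
                    row["tom"] = float(tom.loc[gi, gj])
                rows.append(row)
    edges = pd.DataFrame(rows, columns=["source", "target", "pearson"]
                         + (["tom"] if tom is not None else []))
    nodes = pd.DataFrame({"gene_id": members, "module": label})
    if tf_families is not None:
        fam = tf_families.reindex(members).fillna("")
        nodes["tf_family"] = fam.to_numpy()
        nodes["is_tf"] = nodes["tf_family"] != ""
    return edges, nodes


def build_network(expr_matrix: pd.DataFrame, *, betas=tuple(range(1, 31)),
                  r2_target: float = 0.85, beta: int | None = None,
                  min_size: int = 30, merge_cut: float = 0.25,
                  cut_height_quantile: float = 0.99):
    """Full pipeline: soft threshold -> signed TOM -> modules -> merge.

    Returns (scan, ModuleSet, TOM). ``beta`` overrides the automatic scan.
    """
    if beta is None:
        scan_res = select_soft_threshold(expr_matrix, betas, r2_target)
        beta = scan_res.chosen_beta
    else:
        scan_res = None
    adj = signed_adjacency(expr_matrix, beta)
    tom = tom_similarity(adj)
    prelim = detect_modules(1.0 - tom, min_size=min_size,
                            cut_height_quantile=cut_height_quantile)
    module_set = merge_modules(expr_matrix, prelim, merge_cut=merge_cut)
    module_set.params.update({"beta": beta, "min_size": min_size,
                              "cut_height_quantile": cut_height_quantile,
                              "tom_type": "signed"})
    return scan_res, module_set, tom
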