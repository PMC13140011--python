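"""Signed adjacency, TOM (vs brute-force oracle), module detection/merging."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from oatsalt import (build_network, detect_modules, extract_subnetwork,
                     merge_modules, module_eigengene, module_tissue_enrichment,
                     network_input, select_soft_threshold, signed_adjacency,
                     tom_similarity)
from oatsalt.network import GREY, scale_free_fit

from conftest import make_expr


def frame(arr, names=None):
    names = names or [f"g{i}" for i in range(len(arr))]
    return pd.DataFrame(np.asarray(arr, dtype=float), index=names, columns=names)


def expr_frame(X, prefix="g"):
    return pd.DataFrame(X, index=[f"{prefix}{i}" for i in range(len(X))],
                        columns=[f"s{j}" for j in range(X.shape[1])])


# --- adjacency -------------------------------------------------------------

def test_signed_adjacency_closed_forms():
    s = np.arange(12.0)
    X = expr_frame(np.vstack([s, s, -s, np.cos(s)]))
    a = signed_adjacency(X, beta=10)
    assert a.iloc[0, 1] == pytest.approx(1.0)        # cor = +1
    assert a.iloc[0, 2] == pytest.approx(0.0)        # cor = -1
    assert float(np.diag(a).min()) == 1.0
    r = np.corrcoef(X.iloc[0], X.iloc[3])[0, 1]
    assert a.iloc[0, 3] == pytest.approx(((1 + r) / 2) ** 10)


def test_uncorrelated_pair_at_beta_10():
    # closed form: cor 0 -> ((1+0)/2)^10
    x = np.array([1.0, -1.0, 1.0, -1.0])
    y = np.array([1.0, 1.0, -1.0, -1.0])
    a = signed_adjacency(expr_frame(np.vstack([x, y])), beta=10)
    assert a.iloc[0, 1] == pytest.approx(0.5 ** 10)


def test_constant_gene_rejected_by_adjacency():
    X = expr_frame(np.vstack([np.arange(5.0), np.ones(5)]))
    with pytest.raises(ValueError, match="g1"):
        signed_adjacency(X, beta=2)


# --- TOM vs brute-force oracle --------------------------------------------

def tom_oracle(A):
    """Triple-loop evaluation of the topological overlap formula."""
    n = len(A)
    A = A.copy()
    np.fill_diagonal(A, 0.0)
    k = A.sum(axis=1)
    T = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l_ij = sum(A[i, u] * A[u, j] for u in range(n) if u not in (i, j))
            T[i, j] = (l_ij + A[i, j]) / (min(k[i], k[j]) + 1 - A[i, j])
    return T


def test_tom_all_ones_triangle():
    a = frame(np.ones((3, 3)))
    tom = tom_similarity(a)
    assert np.allclose(tom, 1.0)  # (1 + 1) / (2 + 1 - 1)


def test_tom_empty_graph():
    tom = tom_similarity(frame(np.eye(4)))
    off = tom.to_numpy()[~np.eye(4, dtype=bool)]
    assert np.allclose(off, 0.0)


@pytest.mark.parametrize("n,seed", [(4, 0), (6, 1), (8, 2), (10, 3)])
def test_tom_matches_brute_force_oracle(n, seed):
    rng = np.random.default_rng(seed)
    raw = rng.uniform(0, 1, (n, n))
    A = (raw + raw.T) / 2
    np.fill_diagonal(A, 1.0)
    tom = tom_similarity(frame(A)).to_numpy()
    assert np.max(np.abs(tom - tom_oracle(A))) < 1e-12


def test_tom_rejects_asymmetric_input():
    A = np.eye(3)
    A[0, 1] = 0.5
    with pytest.raises(ValueError, match="symmetric"):
        tom_similarity(frame(A))


# --- soft threshold --------------------------------------------------------

def block_model(n_modules=20, per_module=50, n_samples=45, snr=3.0, seed=0):
    # hub-skewed membership weights: few strongly connected genes per module
    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(n_modules):
        profile = rng.normal(0, 1, n_samples)
        w = snr * rng.uniform(0, 1, per_module) ** 3
        rows.append(w[:, None] * profile + rng.normal(0, 1, (per_module, n_samples)))
    return expr_frame(np.vstack(rows))


def test_scale_free_fit_reached_on_block_model():
    X = block_model()
    scan = select_soft_threshold(X, betas=range(1, 31), r2_target=0.8)
    assert scan.table["r2"].max() >= 0.8
    assert scan.chosen_beta == int(
        scan.table.loc[scan.table["r2"] >= 0.8, "beta"].iloc[0])


def test_unreachable_target_falls_back_to_argmax():
    X = block_model(n_modules=4, per_module=30)
    with pytest.warns(UserWarning, match="target"):
        scan = select_soft_threshold(X, betas=range(1, 11), r2_target=1.01)
    assert scan.chosen_beta == int(scan.table.loc[scan.table["r2"].idxmax(), "beta"])


def test_scan_invariant_to_gene_order():
    X = block_model(n_modules=4, per_module=30)
    s1 = select_soft_threshold(X, betas=range(1, 11), r2_target=0.8)
    perm = np.random.default_rng(5).permutation(len(X))
    s2 = select_soft_threshold(X.iloc[perm], betas=range(1, 11), r2_target=0.8)
    assert np.allclose(s1.table["r2"], s2.table["r2"])
    assert s1.chosen_beta == s2.chosen_beta


def test_degenerate_connectivity_rejected():
    with pytest.raises(ValueError, match="degenerate"):
        scale_free_fit(np.full(30, 2.0))


# --- module detection ------------------------------------------------------

def two_block_expr():
    p1 = np.tile([1.0, -1.0], 10)
    p2 = np.repeat([1.0, -1.0], 10)           # exactly uncorrelated with p1
    X = np.vstack([p1 * s for s in (1, 2, 3)] + [p2 * s for s in (1, 2, 3)])
    return expr_frame(X)


def test_two_separated_blocks_found_exactly():
    X = two_block_expr()
    adj = signed_adjacency(X, beta=6)
    labels = detect_modules(1.0 - tom_similarity(adj), min_size=2)
    assert set(labels) == {"M1", "M2"}
    assert labels["g0"] == labels["g1"] == labels["g2"]
    assert labels["g3"] == labels["g4"] == labels["g5"]
    assert labels["g0"] != labels["g3"]


def test_min_size_above_all_clusters_gives_all_grey():
    X = two_block_expr()
    adj = signed_adjacency(X, beta=6)
    labels = detect_modules(1.0 - tom_similarity(adj), min_size=10)
    assert set(labels) == {GREY}


def test_min_size_below_two_rejected():
    with pytest.raises(ValueError):
        detect_modules(frame(np.eye(3)), min_size=1)


# --- eigengenes ------------------------------------------------------------

def test_identical_genes_have_their_profile_as_eigengene():
    profile = np.sin(np.arange(20.0))
    X = expr_frame(np.vstack([profile] * 5))
    labels = pd.Series(["M1"] * 5, index=X.index)
    eig, expl = module_eigengene(X, labels)
    z = (profile - profile.mean()) / profile.std()
    e = eig.loc["M1"].to_numpy()
    assert np.allclose(np.abs(np.corrcoef(e, z)[0, 1]), 1.0)
    assert expl["M1"] == pytest.approx(1.0)
    assert np.linalg.norm(e) == pytest.approx(1.0)


def test_orientation_fixed_under_global_sign_flip():
    rng = np.random.default_rng(0)
    X = expr_frame(rng.normal(0, 1, (6, 15)))
    labels = pd.Series(["M1"] * 6, index=X.index)
    e1, _ = module_eigengene(X, labels)
    e2, _ = module_eigengene(-X, labels)
    # flipping all genes flips the mean profile, orientation follows it
    assert np.allclose(e1.loc["M1"], -e2.loc["M1"])


def test_explained_variance_matches_svd_oracle():
    rng = np.random.default_rng(2)
    X = expr_frame(rng.normal(0, 1, (8, 12)))
    labels = pd.Series(["M1"] * 8, index=X.index)
    _, expl = module_eigengene(X, labels)
    Xs = ((X.T - X.mean(axis=1)) / X.std(axis=1)).T.to_numpy()
    s = np.linalg.svd(Xs, compute_uv=False)
    assert expl["M1"] == pytest.approx(s[0] ** 2 / (s ** 2).sum())


# --- merging ---------------------------------------------------------------

def correlated_modules(rho, n=40, per=6, seed=0):
    rng = np.random.default_rng(seed)
    p = rng.normal(0, 1, n)
    q = rho * p + np.sqrt(1 - rho ** 2) * rng.normal(0, 1, n)
    X = np.vstack([p + 0.01 * rng.normal(0, 1, n) for _ in range(per)]
                  + [q + 0.01 * rng.normal(0, 1, n) for _ in range(per)])
    expr = expr_frame(X)
    labels = pd.Series(["M1"] * per + ["M2"] * per, index=expr.index)
    return expr, labels


def test_similar_eigengenes_merge_below_cut():
    expr, labels = correlated_modules(rho=0.9)
    merged = merge_modules(expr, labels, merge_cut=0.25)
    assert merged.labels.nunique() == 1
    assert merged.merge_history


def test_dissimilar_eigengenes_do_not_merge():
    expr, labels = correlated_modules(rho=0.5)
    merged = merge_modules(expr, labels, merge_cut=0.25)
    assert merged.labels.nunique() == 2
    assert not merged.merge_history


def test_merge_cut_zero_is_identity_and_merge_is_monotone():
    expr, labels = correlated_modules(rho=0.9)
    same = merge_modules(expr, labels, merge_cut=0.0)
    assert same.labels.equals(labels)
    once = merge_modules(expr, labels, merge_cut=0.25)
    twice = merge_modules(expr, once.labels, merge_cut=0.25)
    assert once.labels.nunique() <= labels.nunique()
    assert twice.labels.equals(once.labels)


# --- enrichment ------------------------------------------------------------

def hypergeom_enumeration(k, N, K, n):
    """P(X >= k) by direct summation of the hypergeometric pmf."""
    total = 0.0
    for i in range(k, min(K, n) + 1):
        total += math.comb(K, i) * math.comb(N - K, n - i) / math.comb(N, n)
    return total


def test_hypergeometric_p_matches_enumeration_on_toy():
    # 20-gene background, 8 tissue DEGs, module of 6 with 4 overlapping
    p_scipy = float(stats.hypergeom.sf(4 - 1, 20, 8, 6))
    assert p_scipy == pytest.approx(hypergeom_enumeration(4, 20, 8, 6), rel=1e-12)


def test_pure_tissue_module_is_most_enriched():
    genes = [f"g{i}" for i in range(30)]
    labels = pd.Series(["M1"] * 10 + ["M2"] * 20, index=genes)
    from oatsalt.network import ModuleSet
    ms = ModuleSet(labels=labels, eigengenes=pd.DataFrame(),
                   eigengene_adjacency=pd.DataFrame(),
                   eigengene_cor=pd.DataFrame())
    sets = {"Seed": set(genes[:10]), "Leaf": set(genes[10:25])}
    table = module_tissue_enrichment(ms, sets)
    m1 = table[table["module"] == "M1"].set_index("tissue")
    assert m1.loc["Seed", "pvalue"] < m1.loc["Leaf", "pvalue"]
    assert m1.loc["Seed", "pvalue"] == pytest.approx(
        hypergeom_enumeration(10, 30, 10, 10), rel=1e-9)


# --- network input and subnetwork ------------------------------------------

def test_network_input_floor_and_variance_filter(sim):
    expr = sim.expression
    union = set(expr.genes[:50])
    mat = network_input(expr, union, fpkm_min=0.2)
    assert set(mat.index) <= union
    assert (expr.fpkm.loc[mat.index].max(axis=1) > 0.2).all()
    assert (mat.var(axis=1) > 0).all()


def test_subnetwork_weights_match_recomputed_correlations():
    expr, labels = correlated_modules(rho=0.9)
    from oatsalt.network import ModuleSet
    ms = ModuleSet(labels=pd.Series("M1", index=expr.index),
                   eigengenes=pd.DataFrame(), eigengene_adjacency=pd.DataFrame(),
                   eigengene_cor=pd.DataFrame())
    edges, nodes = extract_subnetwork(expr, ms, ["g0"], weight_min=0.0)
    for row in edges.itertuples(index=False):
        r = np.corrcoef(expr.loc[row.source], expr.loc[row.target])[0, 1]
        assert row.pearson == pytest.approx(r)
    assert len(edges) == len(expr) - 1  # complete star around the seed

    strict, _ = extract_subnetwork(expr, ms, ["g0"], weight_min=1.0)
    assert len(strict) == 0 or (strict["pearson"].abs() >= 1.0 - 1e-12).all()

    with pytest.raises(KeyError, match="missing"):
        extract_subnetwork(expr, ms, ["missing"], weight_min=0.5)


def test_pipeline_partition_is_order_invariant():
    from sklearn.metrics import adjusted_rand_score
    X = block_model(n_modules=3, per_module=20, snr=3.0, seed=4)
    _, ms1, _ = build_network(X, beta=6, min_size=5)
    perm = np.random.default_rng(0).permutation(len(X))
    _, ms2, _ = build_network(X.iloc[perm], beta=6, min_size=5)
    joint = ms1.labels.to_frame("a").join(ms2.labels.rename("b"))
    assert adjusted_rand_score(joint["a"], joint["b"]) == 1.0
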