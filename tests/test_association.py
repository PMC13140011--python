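"""Marker QC, PC covariates, association scan (vs OLS oracle), LD, haplotypes."""

import numpy as np
import pandas as pd
import pytest

from oatsalt import (GenotypePanel, haplotype_compare, ld_r2, pca_covariates,
                     qc_markers, scan, simulate_population)
from oatsalt.config import CAUSAL_MARKER_ID
from oatsalt.simulate import SimulationConfig


def panel_from(dosage: pd.DataFrame, phenotype=None, refs=None, alts=None):
    markers = pd.DataFrame({
        "marker_id": dosage.columns,
        "chrom": "1A",
        "pos": range(1, len(dosage.columns) + 1),
        "ref": refs or ["A"] * len(dosage.columns),
        "alt": alts or ["T"] * len(dosage.columns),
        "type": "SNP",
    })
    return GenotypePanel(markers=markers, dosage=dosage, phenotype=phenotype)


def _sim_panel(**kw):
    base = dict(n_markers=120, n_accessions=200, seed=9)
    base.update(kw)
    panel, truth = simulate_population(SimulationConfig(**base))
    return panel, truth


# --- QC --------------------------------------------------------------------

def test_qc_drops_rare_and_gappy_markers():
    n = 100
    rng = np.random.default_rng(0)
    dosage = pd.DataFrame({
        "rare": [1.0] * 4 + [0.0] * (n - 4),            # MAF 0.02
        "gappy": [np.nan] * 15 + [1.0, 0.0] * 42 + [1.0],  # 15% missing
        "boundary": [1.0] * 10 + [0.0] * (n - 10),      # MAF exactly 0.05
        "common": list(rng.integers(0, 3, n).astype(float)),
    }, index=[f"a{i}" for i in range(n)])
    filtered, report = qc_markers(panel_from(dosage), maf_min=0.05, miss_max=0.1)
    kept = set(filtered.markers["marker_id"])
    assert kept == {"boundary", "common"}   # >= and <= are inclusive
    assert report.set_index("rule")["n_dropped"].sum() == 4


def test_qc_is_idempotent():
    panel, _ = _sim_panel()
    once, _ = qc_markers(panel)
    twice, report = qc_markers(once)
    assert list(twice.markers["marker_id"]) == list(once.markers["marker_id"])
    assert report.set_index("rule").loc["retained", "n_dropped"] == len(once.markers)


def test_empty_panel_rejected():
    with pytest.raises(ValueError):
        qc_markers(panel_from(pd.DataFrame(index=["a1"])))


# --- PCA covariates --------------------------------------------------------

def test_identical_accessions_share_pc_rows():
    rng = np.random.default_rng(1)
    row = rng.integers(0, 3, 40).astype(float)
    dosage = pd.DataFrame([row, row] + [rng.integers(0, 3, 40).astype(float)
                                        for _ in range(20)],
                          index=[f"a{i}" for i in range(22)],
                          columns=[f"m{i}" for i in range(40)])
    pcs = pca_covariates(panel_from(dosage), k=3)
    assert np.allclose(pcs.loc["a0"], pcs.loc["a1"])


def test_pc1_separates_planted_clusters():
    rng = np.random.default_rng(2)
    freq = np.array([0.1] * 50 + [0.9] * 50)
    g1 = rng.binomial(2, freq, (30, 100)).astype(float)
    g2 = rng.binomial(2, freq[::-1], (30, 100)).astype(float)
    dosage = pd.DataFrame(np.vstack([g1, g2]),
                          index=[f"a{i}" for i in range(60)],
                          columns=[f"m{i}" for i in range(100)])
    pcs = pca_covariates(panel_from(dosage), k=1)
    member = np.array([0] * 30 + [1] * 30)
    r = np.corrcoef(pcs["PC1"], member)[0, 1]
    assert abs(r) >= 0.9


def test_pcs_are_orthogonal():
    panel, _ = _sim_panel()
    pcs = pca_covariates(panel, k=4)
    gram = pcs.T.to_numpy() @ pcs.to_numpy()
    off = gram - np.diag(np.diag(gram))
    assert np.max(np.abs(off)) < 1e-9 * np.max(np.diag(gram))


def test_k_must_be_below_n():
    panel, _ = _sim_panel(n_accessions=10)
    with pytest.raises(ValueError):
        pca_covariates(panel, k=10)


# --- scan ------------------------------------------------------------------

def test_scan_matches_statsmodels_ols_oracle():
    import statsmodels.api as sm
    rng = np.random.default_rng(3)
    n = 60
    dosage = pd.DataFrame(rng.integers(0, 3, (n, 5)).astype(float),
                          index=[f"a{i}" for i in range(n)],
                          columns=[f"m{i}" for i in range(5)])
    cov = pd.DataFrame(rng.normal(0, 1, (n, 2)), index=dosage.index,
                       columns=["PC1", "PC2"])
    y = pd.Series(rng.normal(50, 5, n) + 2.0 * dosage["m0"], index=dosage.index)
    table = scan(panel_from(dosage, y), covariates=cov).set_index("marker_id")
    for m in dosage.columns:
        X = sm.add_constant(np.column_stack([cov.to_numpy(), dosage[m]]))
        fit = sm.OLS(y.to_numpy(), X).fit()
        assert table.loc[m, "beta"] == pytest.approx(fit.params[-1], rel=1e-9)
        assert table.loc[m, "se"] == pytest.approx(fit.bse[-1], rel=1e-9)
        assert table.loc[m, "pvalue"] == pytest.approx(fit.pvalues[-1], rel=1e-9)


def test_scan_invariant_to_phenotype_rescaling_and_marker_order():
    panel, _ = _sim_panel()
    panel, _ = qc_markers(panel)
    t1 = scan(panel).set_index("marker_id")
    t2 = scan(panel, phenotype=panel.phenotype * 3.0 + 7.0).set_index("marker_id")
    assert np.allclose(t1["pvalue"], t2["pvalue"])

    rng = np.random.default_rng(0)
    perm = rng.permutation(len(panel.markers))
    shuffled = GenotypePanel(
        markers=panel.markers.iloc[perm].reset_index(drop=True)
        .sort_values(["chrom", "pos"], ignore_index=True),
        dosage=panel.dosage,
        phenotype=panel.phenotype)
    shuffled = shuffled.subset(shuffled.markers["marker_id"])
    shuffled.dosage = shuffled.dosage[list(shuffled.markers["marker_id"])]
    t3 = scan(shuffled).set_index("marker_id")
    assert np.allclose(t1.loc[t3.index, "pvalue"], t3["pvalue"])


def test_constant_phenotype_rejected():
    panel, _ = _sim_panel(n_accessions=30)
    with pytest.raises(ValueError, match="constant"):
        scan(panel, phenotype=pd.Series(1.0, index=panel.accessions))


def test_orthogonal_marker_has_null_effect():
    rng = np.random.default_rng(4)
    n = 40
    x = np.tile([0.0, 2.0], n // 2)
    y = pd.Series(np.tile([1.0, 1.0, 5.0, 5.0], n // 4),
                  index=[f"a{i}" for i in range(n)])
    other = rng.integers(0, 3, n).astype(float)
    dosage = pd.DataFrame({"orth": x, "m2": other}, index=y.index)
    assert np.corrcoef(x, y)[0, 1] == pytest.approx(0.0, abs=1e-12)
    table = scan(panel_from(dosage, y)).set_index("marker_id")
    assert table.loc["orth", "beta"] == pytest.approx(0.0, abs=1e-10)
    assert table.loc["orth", "pvalue"] == pytest.approx(1.0)


# --- LD --------------------------------------------------------------------

def test_duplicated_marker_has_r2_one():
    rng = np.random.default_rng(5)
    g = rng.integers(0, 3, 50).astype(float)
    dosage = pd.DataFrame({"m1": g, "m2": g.copy(),
                           "m3": rng.integers(0, 3, 50).astype(float)},
                          index=[f"a{i}" for i in range(50)])
    r2 = ld_r2(panel_from(dosage))
    assert r2.loc["m1", "m2"] == pytest.approx(1.0)
    assert np.allclose(np.diag(r2), 1.0)
    assert np.allclose(r2, r2.T)


def test_independent_markers_have_near_zero_mean_r2():
    rng = np.random.default_rng(6)
    dosage = pd.DataFrame(rng.binomial(2, 0.3, (1000, 40)).astype(float),
                          index=[f"a{i}" for i in range(1000)],
                          columns=[f"m{i}" for i in range(40)])
    r2 = ld_r2(panel_from(dosage)).to_numpy()
    off = r2[~np.eye(40, dtype=bool)]
    assert off.mean() < 0.01


def test_monomorphic_marker_reported_missing():
    dosage = pd.DataFrame({"mono": [1.0] * 20,
                           "poly": [0.0, 2.0] * 10},
                          index=[f"a{i}" for i in range(20)])
    r2 = ld_r2(panel_from(dosage))
    assert np.isnan(r2.loc["mono", "poly"])


# --- haplotype comparison --------------------------------------------------

def test_t_statistic_matches_closed_form_on_six_values():
    g1 = np.array([1.0, 2.0, 3.0])
    g2 = np.array([4.0, 5.0, 7.0])
    dosage = pd.DataFrame({"indel": [0, 0, 0, 2, 2, 2.0]},
                          index=[f"a{i}" for i in range(6)])
    y = pd.Series(np.concatenate([g1, g2]), index=dosage.index)
    res = haplotype_compare(panel_from(dosage, y, refs=["TCACTC"], alts=["TCC"]),
                            "indel")
    sp = np.sqrt(((g1.var(ddof=1) * 2 + g2.var(ddof=1) * 2) / 4) * (2 / 3))
    t_hand = (g1.mean() - g2.mean()) / sp
    assert res.t == pytest.approx(t_hand, rel=1e-12)
    from scipy import stats as ss
    assert res.pvalue == pytest.approx(2 * ss.t.sf(abs(t_hand), 4), rel=1e-12)
    assert (res.n1, res.n2) == (3, 3)


def test_equal_groups_give_t_zero_p_one():
    dosage = pd.DataFrame({"indel": [0, 0, 2, 2.0]}, index=list("abcd"))
    y = pd.Series([1.0, 3.0, 1.0, 3.0], index=dosage.index)
    res = haplotype_compare(panel_from(dosage, y, refs=["TCACTC"], alts=["TCC"]),
                            "indel")
    assert res.t == pytest.approx(0.0)
    assert res.pvalue == pytest.approx(1.0)


def test_planted_haplotype_effect_recovered():
    # effect 5 per Hap1 allele -> homozygote groups differ by 10
    panel, _ = _sim_panel(causal_effect=5.0, phenotype_sd=1.0,
                          n_accessions=400, missing_rate=0.0)
    res = haplotype_compare(panel, CAUSAL_MARKER_ID)
    assert res.mean1 - res.mean2 == pytest.approx(10.0, abs=0.5)
    assert res.pvalue < 1e-10
    assert res.mean1 > res.mean2   # Hap1 (insertion) is the tolerant allele


def test_empty_haplotype_group_rejected():
    dosage = pd.DataFrame({"indel": [0.0, 0.0, 1.0, 1.0]}, index=list("abcd"))
    y = pd.Series([1.0, 2.0, 3.0, 4.0], index=dosage.index)
    with pytest.raises(ValueError, match=">= 2"):
        haplotype_compare(panel_from(dosage, y, refs=["TCACTC"], alts=["TCC"]),
                          "indel")
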