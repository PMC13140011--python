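"""Homeolog-group classification and ternary subgenome expression bias.

Groups are classified by their A:C:D copy pattern — triads (1:1:1), dyads
(n:n:0 with one subgenome lost), subgenome-specific singletons, and "other"
for remaining patterns. For each triad the relative expression fractions
(fA, fC, fD) place it in the ternary simplex; triads within a fixed
Euclidean radius of the balanced centroid (1/3, 1/3, 1/3) are labelled
balanced, all others dominant toward the subgenome of the largest fraction.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .config import SUBGENOMES

logger = logging.getLogger(__name__)

CENTROID = np.full(3, 1.0 / 3.0)
#: largest possible distance to the centroid (at a simplex vertex)
MAX_DISTANCE = float(np.sqrt(2.0 / 3.0))

CATEGORIES = ("triad", "dyad_AC", "dyad_AD", "dyad_CD",
              "singleton_A", "singleton_C", "singleton_D", "other")


def classify_groups(homeolog_map: pd.DataFrame, catalog: pd.DataFrame) -> pd.DataFrame:
    """Assign each homeolog group a copy-pattern category.

    Returns one row per group: copy counts per subgenome and the category.
    Raises if a gene appears in two groups or carries an unknown subgenome.
    """
    dup = homeolog_map["gene_id"][homeolog_map["gene_id"].duplicated()]
    if len(dup):
        raise ValueError(f"gene(s) assigned to multiple groups: {sorted(set(dup))}")
    sub = catalog.set_index("gene_id")["subgenome"]
    unknown = set(sub.unique()) - set(SUBGENOMES)
    if unknown:
        raise ValueError(f"unknown subgenome label(s): {sorted(unknown)}")
    missing = set(homeolog_map["gene_id"]) - set(sub.index)
    if missing:
        raise ValueError(f"group member(s) absent from catalog: {sorted(missing)[:5]}")

    merged = homeolog_map.assign(subgenome=homeolog_map["gene_id"].map(sub))
    counts = (merged.pivot_table(index="group_id", columns="subgenome",
                                 values="gene_id", aggfunc="count", fill_value=0)
              .reindex(columns=list(SUBGENOMES), fill_value=0))
    counts.columns = ["n_a", "n_c", "n_d"]

    def categorize(row) -> str:
        pat = (row["n_a"], row["n_c"], row["n_d"])
        if pat == (1, 1, 1):
            return "triad"
        present = [s for s, n in zip("ACD", pat) if n >= 1]
        if sum(pat) == 1:
            return f"singleton_{present[0]}"
        if len(present) == 2:
            return f"dyad_{present[0]}{present[1]}"
        return "other"

    counts["category"] = counts.apply(categorize, axis=1)
    return counts.reset_index()


def ternary_fractions(expr, groups: pd.DataFrame, homeolog_map: pd.DataFrame,
                      catalog: pd.DataFrame, tissue: str | None = None,
                      salt_only: bool = True,
                      expression_floor: float = 0.5) -> pd.DataFrame:
    """Per-triad relative expression fractions over the selected samples.

    e_X is the mean FPKM of the subgenome-X copy over the selected samples
    (a tissue's salt timepoints by default); fX = e_X / (e_A + e_C + e_D).
    Triads whose summed expression falls below ``expression_floor`` are
    flagged unexpressed (their fractions are NaN).
    """
    non_triad = groups[groups["category"] != "triad"]
    if len(non_triad):
        raise ValueError(
            f"ternary fractions are defined for triads only; got "
            f"{len(non_triad)} non-triad group(s), e.g. {non_triad['group_id'].iloc[0]!r}")

    design = expr.design
    sel = pd.Series(True, index=design.index)
    if tissue is not None:
        sel &= design["tissue"] == tissue
    if salt_only:
        sel &= design["timepoint_h"] > 0
    samples = list(design.index[sel])
    if not samples:
        raise ValueError(f"selector matches no samples (tissue={tissue!r})")

    mean_fpkm = expr.fpkm[samples].mean(axis=1)
    sub = catalog.set_index("gene_id")["subgenome"]
    members = homeolog_map[homeolog_map["group_id"].isin(set(groups["group_id"]))]
    members = members.assign(subgenome=members["gene_id"].map(sub),
                             e=members["gene_id"].map(mean_fpkm).fillna(0.0))

    e_wide = (members.pivot_table(index="group_id", columns="subgenome",
                                  values="e", aggfunc="sum", fill_value=0.0)
              .reindex(columns=list(SUBGENOMES), fill_value=0.0))
    total = e_wide.sum(axis=1)
    unexpressed = total < expression_floor
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = e_wide.div(total, axis=0)
    frac[unexpressed] = np.nan
    return pd.DataFrame({
        "group_id": e_wide.index,
        "tissue": tissue or "all",
        "f_a": frac["A"].to_numpy(), "f_c": frac["C"].to_numpy(),
        "f_d": frac["D"].to_numpy(),
        "total_fpkm": total.to_numpy(),
        "unexpressed": unexpressed.to_numpy(),
    }).reset_index(drop=True)


def distance_to_balanced(fractions: np.ndarray) -> np.ndarray:
    """Euclidean distance from (fA, fC, fD) to the balanced centroid."""
    f = np.asarray(fractions, dtype=float)
    return np.sqrt(((f - CENTROID) ** 2).sum(axis=-1))


def classify_bias(f_a: float, f_c: float, f_d: float,
                  balanced_radius: float = 0.2) -> tuple[str, float]:
    """Label one triad's fractions; returns (label, distance to centroid).

    Within ``balanced_radius`` of the centroid -> balanced; otherwise the
    subgenome with the largest fraction wins, ties broken in A < C < D
    order (and logged).
    """
    f = np.array([f_a, f_c, f_d], dtype=float)
    if (f < 0).any():
        raise ValueError(f"negative fraction in {tuple(f)}")
    if abs(f.sum() - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {f.sum()!r}")
    dist = float(distance_to_balanced(f))
    if dist <= balanced_radius:
        return "balanced", dist
    winners = np.flatnonzero(f == f.max())
    if len(winners) > 1:
        logger.info("tie between subgenomes %s; choosing %s",
                    [SUBGENOMES[i] for i in winners], SUBGENOMES[winners[0]])
    return f"{SUBGENOMES[winners[0]]}-dominant", dist


def classify_bias_table(fractions: pd.DataFrame,
                        balanced_radius: float = 0.2) -> pd.DataFrame:
    """Vectorised bias labels for a ternary_fractions output table."""
    out = fractions.copy()
    labels, dists = [], []
    for row in out.itertuples(index=False):
        if row.unexpressed:
            labels.append("unexpressed")
            dists.append(np.nan)
        else:
            lab, d = classify_bias(row.f_a, row.f_c, row.f_d, balanced_radius)
            labels.append(lab)
            dists.append(d)
    out["distance_to_balanced"] = dists
    out["label"] = labels
    return out


def dominance_summary(bias_tables: dict[str, pd.DataFrame],
                      homeolog_map: pd.DataFrame, catalog: pd.DataFrame,
                      deg_union: set | None = None) -> dict[str, pd.DataFrame]:
    """Count dominance labels per tissue: all triads, DEG- and TF-restricted.

    ``bias_tables`` maps tissue -> classify_bias_table output. A triad is
    DEG-restricted if any member gene is in the DEG union; TF counts use the
    group's family label and are reported per family.
    """
    members = homeolog_map.merge(catalog[["gene_id", "tf_family"]], on="gene_id")
    group_family = members.groupby("group_id")["tf_family"].agg(
        lambda s: next((f for f in s if isinstance(f, str) and f), ""))
    group_has_deg = (members.assign(in_deg=members["gene_id"].isin(deg_union or set()))
                     .groupby("group_id")["in_deg"].any())

    all_rows, deg_rows, tf_rows = [], [], []
    for tissue, table in bias_tables.items():
        expressed = table[table["label"] != "unexpressed"]
        for label, part in expressed.groupby("label"):
            all_rows.append({"tissue": tissue, "label": label, "n_triads": len(part)})
            n_deg = int(part["group_id"].map(group_has_deg).fillna(False).sum())
            deg_rows.append({"tissue": tissue, "label": label, "n_triads": n_deg})
            fams = part["group_id"].map(group_family).fillna("")
            for family, fpart in part[fams != ""].groupby(fams[fams != ""]):
                tf_rows.append({"tissue": tissue, "label": label,
                                "tf_family": family, "n_triads": len(fpart)})
    return {
        "all": pd.DataFrame(all_rows, columns=["tissue", "label", "n_triads"]),
        "deg": pd.DataFrame(deg_rows, columns=["tissue", "label", "n_triads"]),
        "tf": pd.DataFrame(tf_rows, columns=["tissue", "label", "tf_family", "n_triads"]),
    }
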