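"""Plain-text I/O: TSV tables and a minimal VCF v4.2 dialect.

Every table travels as tab-separated UTF-8 with a header row. Genotypes are
written as a minimal GT-only VCF (CHROM POS ID REF ALT QUAL FILTER INFO
FORMAT samples...); reading goes through cyvcf2 so the files stay
interoperable with standard tooling.
"""

from __future__ import annotations

import os
from typing import Iterable

import numpy as np
import pandas as pd

#: fixed float format so repeated runs serialise byte-identically
FLOAT_FORMAT = "%.10g"

_GT_CODES = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def write_tsv(df: pd.DataFrame, path: str, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT)


def read_tsv(path: str, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_vcf(markers: pd.DataFrame, dosage: pd.DataFrame, path: str) -> None:
    """Write biallelic markers as VCF v4.2 with GT-only sample columns.

    Parameters
    ----------
    markers : DataFrame with columns marker_id, chrom, pos, ref, alt.
    dosage : accessions x markers matrix of alternate-allele copies
        (0/1/2, NaN = missing); columns must match ``markers.marker_id``.
    """
    if list(dosage.columns) != list(markers["marker_id"]):
        raise ValueError("dosage columns must match markers.marker_id order")
    accessions = list(dosage.index)
    contigs = list(dict.fromkeys(markers["chrom"]))
    lines = ["##fileformat=VCFv4.2"]
    lines += [f"##contig=<ID={c}>" for c in contigs]
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(accessions))
    values = dosage.to_numpy(dtype=float)
    for j, rec in enumerate(markers.itertuples(index=False)):
        gts = [_GT_CODES.get(v, "./.") if np.isfinite(v) else "./."
               for v in values[:, j]]
        lines.append("\t".join([str(rec.chrom), str(int(rec.pos)), str(rec.marker_id),
                                str(rec.ref), str(rec.alt), ".", "PASS", ".", "GT"]
                               + gts))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


def read_vcf(path: str) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a GT-only VCF into (markers, dosage) via cyvcf2."""
    from cyvcf2 import VCF

    vcf = VCF(path)
    accessions = list(vcf.samples)
    rows, columns = [], []
    marker_rows = []
    for var in vcf:
        vtype = "InDel" if len(var.REF) != len(var.ALT[0]) else "SNP"
        marker_rows.append({
            "marker_id": var.ID, "chrom": var.CHROM, "pos": var.POS,
            "ref": var.REF, "alt": var.ALT[0], "type": vtype,
        })
        gt = var.gt_types.astype(float)  # 0=hom ref, 1=het, 2=unknown, 3=hom alt
        dos = np.where(gt == 0, 0.0,
                       np.where(gt == 1, 1.0,
                                np.where(gt == 3, 2.0, np.nan)))
        columns.append(dos)
        rows.append(var.ID)
    markers = pd.DataFrame(marker_rows)
    dosage = pd.DataFrame(np.column_stack(columns) if columns else np.empty((len(accessions), 0)),
                          index=accessions, columns=rows)
    return markers, dosage


def ensure_fresh(paths: Iterable[str], overwrite: bool) -> None:
    """Refuse to clobber existing files unless overwriting was requested."""
    if overwrite:
        return
    clashes = [p for p in paths if os.path.exists(p)]
    if clashes:
        raise FileExistsError(
            f"refusing to overwrite existing files (pass overwrite=True): {clashes}")
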