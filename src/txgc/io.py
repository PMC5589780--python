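"""Readers and writers for the pipeline's plain-text interchange formats.

Everything is TSV for inspectability.  Genomic interval conventions are
converted at the boundary: BEDPE contact files are 0-based half-open on
disk and 1-based inclusive in memory.  Strand is ignored throughout
(expression-array probes are strandless).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from txgc.grm import GRM, GenotypeMatrix

__all__ = [
    "read_expression",
    "write_expression",
    "read_annotation",
    "write_annotation",
    "read_genotypes_tsv",
    "write_genotypes_tsv",
    "read_grm_tsv",
    "write_grm_tsv",
    "read_eqtl",
    "write_eqtl",
    "read_bedpe",
    "write_bedpe",
    "read_gene_list",
    "write_gene_list",
]

EQTL_COLUMNS = ["snp_id", "chromosome", "position", "probe_id", "beta", "se", "p_value"]
ANNOTATION_COLUMNS = ["probe_id", "gene_id", "chromosome", "position"]


def _require_columns(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")


def _check_numeric(df: pd.DataFrame, cols: list[str], path) -> None:
    for c in cols:
        coerced = pd.to_numeric(df[c], errors="coerce")
        bad = coerced.isna() & df[c].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # +1 header, +1 one-based
            raise ValueError(f"{path}: malformed value in column {c!r} at line {line}")
        df[c] = coerced


def write_expression(expression: pd.DataFrame, path) -> None:
    expression.to_csv(path, sep="\t", index_label="probe_id")


def read_expression(path) -> pd.DataFrame:
    """Probes x individuals matrix; duplicate probe ids are an error."""
    df = pd.read_csv(path, sep="\t", index_col="probe_id")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate probe id {dup!r}")
    return df


def write_annotation(annotation: pd.DataFrame, path) -> None:
    annotation[ANNOTATION_COLUMNS].to_csv(path, sep="\t", index=False)


def read_annotation(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    _require_columns(df, ANNOTATION_COLUMNS, path)
    _check_numeric(df, ["position"], path)
    if df["probe_id"].duplicated().any():
        dup = df["probe_id"][df["probe_id"].duplicated()].iloc[0]
        raise ValueError(f"{path}: duplicate probe id {dup!r}")
    df["position"] = df["position"].astype(int)
    return df


def write_genotypes_tsv(genotypes: GenotypeMatrix, path) -> None:
    """SNPs as rows (id, chromosome, position, then one column per individual)."""
    counts = genotypes.counts.T
    df = pd.DataFrame(counts, columns=genotypes.individual_ids)
    df.insert(0, "snp_id", genotypes.snp_ids)
    df.insert(1, "chromosome", genotypes.snp_chroms)
    df.insert(2, "position", genotypes.snp_positions)
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_genotypes_tsv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str}, na_values=["NA"])
    _require_columns(df, ["snp_id", "chromosome", "position"], path)
    ind_cols = [c for c in df.columns if c not in ("snp_id", "chromosome", "position")]
    counts = df[ind_cols].to_numpy(dtype=float).T
    return GenotypeMatrix(
        counts=counts,
        snp_ids=df["snp_id"].to_numpy(),
        snp_chroms=df["chromosome"].to_numpy(),
        snp_positions=df["position"].to_numpy(dtype=int),
        individual_ids=np.array(ind_cols),
    )


def write_grm_tsv(grm: GRM, path) -> None:
    df = pd.DataFrame(grm.A, index=grm.individual_ids, columns=grm.individual_ids)
    with open(path, "w") as fh:
        fh.write(f"# n_snps_used={grm.n_snps_used}\n")
        df.to_csv(fh, sep="\t", index_label="individual_id")


def read_grm_tsv(path) -> GRM:
    with open(path) as fh:
        header = fh.readline().strip()
        n_snps = int(header.split("=", 1)[1]) if header.startswith("#") else 0
        df = pd.read_csv(fh, sep="\t", index_col="individual_id")
    return GRM(A=df.to_numpy(), individual_ids=df.index.to_numpy(), n_snps_used=n_snps)


def write_eqtl(eqtl: pd.DataFrame, path) -> None:
    eqtl[EQTL_COLUMNS].to_csv(path, sep="\t", index=False)


def read_eqtl(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    _require_columns(df, EQTL_COLUMNS, path)
    _check_numeric(df, ["position", "beta", "se", "p_value"], path)
    df["position"] = df["position"].astype(int)
    return df


def write_bedpe(contacts: pd.DataFrame, path) -> None:
    """Write internal 1-based inclusive anchors as 0-based half-open BEDPE."""
    out = contacts.copy()
    out["start1"] = out["start1"] - 1
    out["start2"] = out["start2"] - 1
    out[["chrom1", "start1", "end1", "chrom2", "start2", "end2"]].to_csv(
        path, sep="\t", index=False, header=False
    )


def read_bedpe(path) -> pd.DataFrame:
    """Read BEDPE (0-based half-open) into 1-based inclusive anchors."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom1", "start1", "end1", "chrom2", "start2", "end2"],
        dtype={"chrom1": str, "chrom2": str},
    )
    _check_numeric(df, ["start1", "end1", "start2", "end2"], path)
    df["start1"] = df["start1"].astype(int) + 1
    df["start2"] = df["start2"].astype(int) + 1
    df["end1"] = df["end1"].astype(int)
    df["end2"] = df["end2"].astype(int)
    bad = (df["start1"] > df["end1"]) | (df["start2"] > df["end2"])
    if bad.any():
        raise ValueError(f"{path}: inverted anchor interval at line {int(bad.idxmax()) + 1}")
    return df


def write_gene_list(genes, path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in genes))


def read_gene_list(path) -> list[str]:
    return [line.strip() for line in Path(path).read_text().splitlines() if line.strip()]
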