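"""Readers and writers for the plain-text interchange formats.

Gene annotation travels as BED (0-based, half-open; converted to 1-based
inclusive on read) or flat GFF3; SNP maps and association results as
tab-delimited PLINK-style tables (SNP, CHR, BP, P [, BETA, SE, T]); LD as
tab-delimited (CHR, POS1, POS2, R2); genotypes as a plain matrix with a
header row of SNP ids; gene sets as GMT and ranked lists as RNK (the two
GSEA interchange formats).  All writers produce byte-stable output at fixed
float precision.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import MISSING, GeneSet, GeneSetCollection, GenotypeMatrix

__all__ = [
    "read_bed",
    "write_bed",
    "read_gff3",
    "write_gff3",
    "read_assoc",
    "write_assoc",
    "read_ld_table",
    "write_ld_table",
    "read_genotypes",
    "write_genotypes",
    "read_gmt",
    "write_gmt",
    "read_rnk",
    "write_rnk",
]


# ---------------------------------------------------------------- annotation
def write_bed(genes: pd.DataFrame, path) -> None:
    """Write 1-based inclusive gene intervals as BED (0-based half-open)."""
    out = pd.DataFrame(
        {
            "chrom": genes["chromosome"],
            "start": genes["start"].astype(int) - 1,
            "end": genes["end"].astype(int),
            "name": genes["gene_id"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def read_bed(path) -> pd.DataFrame:
    bed = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        usecols=[0, 1, 2, 3], names=["chrom", "start", "end", "name"],
    )
    genes = pd.DataFrame(
        {
            "gene_id": bed["name"].astype(str),
            "chromosome": bed["chrom"].astype(str),
            "start": bed["start"].astype(int) + 1,
            "end": bed["end"].astype(int),
        }
    )
    _check_annotation(genes)
    return genes


def write_gff3(genes: pd.DataFrame, path, source: str = "cogsea") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in genes.itertuples(index=False):
            fh.write(
                f"{row.chromosome}\t{source}\tgene\t{int(row.start)}\t{int(row.end)}"
                f"\t.\t+\t.\tID={row.gene_id}\n"
            )


def read_gff3(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != "gene":
                continue
            attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
            gid = attrs.get("ID") or attrs.get("gene_id")
            rows.append((gid, f[0], int(f[3]), int(f[4])))
    genes = pd.DataFrame(rows, columns=["gene_id", "chromosome", "start", "end"])
    _check_annotation(genes)
    return genes


def _check_annotation(genes: pd.DataFrame) -> None:
    if genes["gene_id"].duplicated().any():
        raise ValueError("duplicate gene_ids in annotation")
    if (genes["start"] > genes["end"]).any():
        raise ValueError("annotation has start > end")


# ------------------------------------------------------- association tables
_ASSOC_RENAME = {"SNP": "snp_id", "CHR": "chromosome", "BP": "position", "P": "p_value",
                 "BETA": "beta", "SE": "se", "T": "t"}


def write_assoc(table: pd.DataFrame, path) -> None:
    """PLINK-style association table: SNP CHR BP [BETA SE T] P."""
    cols = {"SNP": table["snp_id"], "CHR": table["chromosome"], "BP": table["position"].astype(int)}
    for src, dst in (("beta", "BETA"), ("se", "SE"), ("t", "T")):
        if src in table.columns:
            cols[dst] = table[src].map(lambda v: f"{v:.6g}" if np.isfinite(v) else "NA")
    cols["P"] = table["p_value"].map(lambda v: f"{v:.6g}" if np.isfinite(v) else "NA")
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


def read_assoc(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    df = df.rename(columns=_ASSOC_RENAME)
    df["snp_id"] = df["snp_id"].astype(str)
    df["chromosome"] = df["chromosome"].astype(str)
    return df


# --------------------------------------------------------------------- LD
def write_ld_table(ld: pd.DataFrame, path) -> None:
    out = pd.DataFrame(
        {
            "CHR": ld["chromosome"],
            "POS1": ld["position_a"].astype(int),
            "POS2": ld["position_b"].astype(int),
            "R2": ld["r_squared"].map(lambda v: f"{v:.6g}"),
        }
    )
    out.to_csv(path, sep="\t", index=False)


def read_ld_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return pd.DataFrame(
        {
            "chromosome": df["CHR"].astype(str),
            "position_a": df["POS1"].astype(int),
            "position_b": df["POS2"].astype(int),
            "r_squared": df["R2"].astype(float),
        }
    )


# -------------------------------------------------------------- genotypes
def write_genotypes(genotypes: GenotypeMatrix, path) -> None:
    """Plain matrix: header row of SNP ids, one row per individual, calls in
    {0,1,2} and NA for missing."""
    calls = genotypes.calls
    header = ("\t".join(genotypes.snp_ids) + "\n").encode()
    if (calls == MISSING).any():
        df = pd.DataFrame(calls, columns=genotypes.snp_ids)
        df = df.astype(object).mask(df == MISSING, "NA")
        df.to_csv(path, sep="\t", index=False)
        return
    # calls are single digits: lay out "digit<TAB>...digit<NL>" rows directly
    n, m = calls.shape
    buf = np.empty((n, 2 * m), dtype=np.uint8)
    buf[:, 0::2] = calls.astype(np.uint8) + ord("0")
    buf[:, 1::2] = ord("\t")
    buf[:, -1] = ord("\n")
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(buf.tobytes())


def read_genotypes(path, snp_map: pd.DataFrame | None = None) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    calls = df.to_numpy(dtype=float)
    calls = np.where(np.isnan(calls), MISSING, calls).astype(np.int8)
    if snp_map is None:
        snp_map = pd.DataFrame(
            {"snp_id": df.columns.astype(str), "chromosome": "NA", "position": 0}
        )
    else:
        snp_map = snp_map[snp_map["snp_id"].isin(df.columns)].reset_index(drop=True)
        if list(snp_map["snp_id"]) != list(df.columns):
            raise ValueError("genotype header does not match the SNP map order")
    return GenotypeMatrix(calls, snp_map)


# ------------------------------------------------------------------- GMT
def write_gmt(collection: GeneSetCollection, path) -> None:
    """GSEA gene-matrix-transposed format: name TAB description TAB genes."""
    with open(path, "w") as fh:
        for s in collection:
            fh.write("\t".join([s.name, s.description or "na", *s.genes]) + "\n")


def read_gmt(path) -> GeneSetCollection:
    coll = GeneSetCollection()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) <= 2:
                raise ValueError(f"{path}:{lineno}: GMT line has <= 2 fields")
            try:
                coll.add(GeneSet(fields[0], tuple(fields[2:]), description=fields[1]))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return coll


# ------------------------------------------------------------------- RNK
def write_rnk(ranked: pd.DataFrame, path) -> None:
    """GSEA RNK: gene_id TAB score, in rank order."""
    with open(path, "w") as fh:
        for row in ranked.itertuples(index=False):
            fh.write(f"{row.gene_id}\t{row.score:.10g}\n")


def read_rnk(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "score"])
    df["gene_id"] = df["gene_id"].astype(str)
    df = df.sort_values("score", ascending=False, kind="stable").reset_index(drop=True)
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    return df
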