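"""Plain-text readers and writers for the pipeline's file formats.

Expression and trait tables are TSV; gene sets are GMT; sparse counts are
MatrixMarket (MTX) with sidecar gene/barcode lists, the 10x-style triplet.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import scipy.io
import scipy.sparse as sp


def read_expression_tsv(path) -> pd.DataFrame:
    """Genes x samples matrix; first column = gene ids, header = sample ids."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][:5].tolist()
        raise ValueError(f"duplicate gene ids: {dup}")
    if df.isna().any().any():
        raise ValueError("missing values in expression matrix")
    return df


def write_expression_tsv(expr: pd.DataFrame, path) -> None:
    expr.to_csv(path, sep="\t", index_label="gene")


def read_trait_tsv(path) -> pd.Series:
    """Two-column TSV (sample, trait) with binary 0/1 trait values."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    s = df.iloc[:, 0].astype(int)
    if not set(s.unique()) <= {0, 1}:
        raise ValueError("trait must be binary 0/1")
    return s


def write_trait_tsv(trait: pd.Series, path) -> None:
    trait.rename("trait").to_csv(path, sep="\t", index_label="sample")


def read_gmt(path) -> dict[str, list[str]]:
    """GMT gene sets: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:80]!r}")
        name, genes = parts[0], [g for g in parts[2:] if g]
        sets[name] = list(dict.fromkeys(genes))
    if not sets:
        raise ValueError(f"no gene sets in {path}")
    return sets


def write_gmt(sets: dict[str, list[str]], path) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, name] + list(genes)) + "\n")


def write_counts_mtx(counts, genes, cells: pd.DataFrame, out_dir) -> None:
    """Write matrix.mtx + genes.tsv + barcodes.tsv + annotations.tsv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(out / "matrix.mtx", sp.coo_matrix(counts))
    pd.Series(genes).to_csv(out / "genes.tsv", sep="\t", index=False,
                            header=False)
    pd.Series(cells.index).to_csv(out / "barcodes.tsv", sep="\t", index=False,
                                  header=False)
    cells.to_csv(out / "annotations.tsv", sep="\t", index_label="barcode")


def read_counts_mtx(in_dir):
    """Read the MTX triplet back: (csr counts, genes, annotations)."""
    in_dir = Path(in_dir)
    counts = sp.csr_matrix(scipy.io.mmread(in_dir / "matrix.mtx"))
    genes = pd.read_csv(in_dir / "genes.tsv", sep="\t",
                        header=None)[0].tolist()
    cells = pd.read_csv(in_dir / "annotations.tsv", sep="\t", index_col=0)
    return counts, genes, cells


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_drug_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"drug_id", "target_symbol", "pchembl"}
    if not required.issubset(df.columns):
        raise ValueError(f"drug table needs columns {sorted(required)}")
    return df
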