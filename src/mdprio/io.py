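"""Readers and writers for the plain-text formats the pipeline exchanges.

Formats
-------
variant table
    Tab-separated, one row per distinct variant. Required columns:
    ``variant_id, gene, variant_type, consequence, allele_count, carriers,
    ref_af``. ``carriers`` is a comma-joined list of sample ids; an empty
    ``ref_af`` marks a novel variant. Columns named ``af_<panel>`` carry
    allele frequencies of additional reference panels; every remaining
    column is interpreted as a deleteriousness-predictor label column.
network edge list
    Whitespace/tab separated ``gene_a gene_b confidence``. Confidences on
    the 0-1000 integer scale are auto-detected (max value > 1) and
    rescaled to fractions.
GMT
    One gene set per line: name, description, then member genes,
    tab-separated.
expression matrix
    Either a dense TSV (genes as rows, cells as columns) or a MatrixMarket
    triplet plus row/column name files, with a separate two-column
    ``cell<TAB>cell_type`` label file.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .filtering import VariantRecord

logger = logging.getLogger(__name__)

_VARIANT_COLUMNS = [
    "variant_id",
    "gene",
    "variant_type",
    "consequence",
    "allele_count",
    "carriers",
    "ref_af",
]


def read_variant_table(path: str | Path) -> list[VariantRecord]:
    """Read the annotated cohort variant table (TSV dialect above)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _VARIANT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"variant table {path} lacks required columns: {missing}")
    panel_cols = [c for c in df.columns if c.startswith("af_")]
    predictor_cols = [
        c for c in df.columns if c not in _VARIANT_COLUMNS and c not in panel_cols
    ]
    records: list[VariantRecord] = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        carriers = frozenset(s for s in d["carriers"].split(",") if s)
        ref_af = float(d["ref_af"]) if d["ref_af"] != "" else None
        panel_afs = {
            c[3:]: float(d[c]) for c in panel_cols if d[c] != ""
        }
        labels = {c: d[c] for c in predictor_cols if d[c] != ""}
        records.append(
            VariantRecord(
                variant_id=d["variant_id"],
                gene=d["gene"],
                variant_type=d["variant_type"],
                consequence=d["consequence"],
                allele_count=int(d["allele_count"]),
                carriers=carriers,
                ref_af=ref_af,
                deleterious_labels=labels,
                panel_afs=panel_afs,
            )
        )
    return records


def write_variant_table(variants: Sequence[VariantRecord], path: str | Path) -> None:
    """Write variants in the same TSV dialect that :func:`read_variant_table` reads."""
    predictor_cols = sorted({k for v in variants for k in v.deleterious_labels})
    panel_cols = sorted({k for v in variants for k in v.panel_afs})
    rows = []
    for v in variants:
        row = {
            "variant_id": v.variant_id,
            "gene": v.gene,
            "variant_type": v.variant_type.value,
            "consequence": v.consequence.value,
            "allele_count": v.allele_count,
            "carriers": ",".join(sorted(v.carriers)),
            "ref_af": "" if v.ref_af is None else repr(float(v.ref_af)),
        }
        for c in panel_cols:
            af = v.panel_afs.get(c)
            row[f"af_{c}"] = "" if af is None else repr(float(af))
        for c in predictor_cols:
            row[c] = v.deleterious_labels.get(c, "")
        rows.append(row)
    cols = (
        _VARIANT_COLUMNS[:6]
        + ["ref_af"]
        + [f"af_{c}" for c in panel_cols]
        + predictor_cols
    )
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def read_edge_list(path: str | Path) -> list[tuple[str, str, float]]:
    """Read a 3-column weighted edge list, rescaling 0-1000 confidences."""
    df = pd.read_csv(
        path,
        sep=r"\s+",
        header=None,
        names=["gene_a", "gene_b", "confidence"],
        dtype={"gene_a": str, "gene_b": str, "confidence": float},
        comment="#",
    )
    conf = df["confidence"].to_numpy(dtype=float)
    if len(conf) and np.nanmax(conf) > 1.0:
        logger.info(
            "edge confidences in %s look like the 0-1000 integer scale "
            "(max %.0f); rescaling to fractions",
            path,
            np.nanmax(conf),
        )
        conf = conf / 1000.0
    return list(zip(df["gene_a"], df["gene_b"], conf))


def write_edge_list(
    edges: Iterable[tuple[str, str, float]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        for a, b, w in edges:
            fh.write(f"{a}\t{b}\t{w:.6g}\n")


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT file into ``{set_name: genes}`` (descriptions dropped)."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line in {path}: {line[:80]!r}")
            sets[parts[0]] = {g for g in parts[2:] if g}
    return sets


def write_gmt(
    sets: Mapping[str, Iterable[str]],
    path: str | Path,
    descriptions: Mapping[str, str] | None = None,
) -> None:
    descriptions = descriptions or {}
    with open(path, "w") as fh:
        for name, genes in sets.items():
            desc = descriptions.get(name, "na")
            fh.write("\t".join([name, desc, *sorted(set(genes))]) + "\n")


def read_gene_list(path: str | Path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")


def read_expression_matrix(
    matrix_path: str | Path,
    genes_path: str | Path | None = None,
    cells_path: str | Path | None = None,
) -> tuple[list[str], list[str], np.ndarray]:
    """Read a genes x cells matrix from dense TSV or MTX triplet files.

    Returns ``(genes, cells, dense ndarray)``. For ``.mtx`` input the row
    (gene) and column (cell) name files are required.
    """
    matrix_path = Path(matrix_path)
    if matrix_path.suffix == ".mtx":
        if genes_path is None or cells_path is None:
            raise ValueError("MTX input requires gene and cell name files")
        mat = spio.mmread(matrix_path)
        if sparse.issparse(mat):
            mat = mat.toarray()
        genes = read_gene_list(genes_path)
        cells = read_gene_list(cells_path)
        mat = np.asarray(mat, dtype=float)
        if mat.shape != (len(genes), len(cells)):
            raise ValueError(
                f"matrix shape {mat.shape} does not match "
                f"{len(genes)} genes x {len(cells)} cells"
            )
        return genes, cells, mat
    df = pd.read_csv(matrix_path, sep="\t", index_col=0)
    return list(df.index.astype(str)), list(df.columns.astype(str)), df.to_numpy(float)


def write_expression_matrix(
    genes: Sequence[str],
    cells: Sequence[str],
    matrix: np.ndarray,
    matrix_path: str | Path,
    genes_path: str | Path,
    cells_path: str | Path,
) -> None:
    """Write a genes x cells matrix as an MTX triplet plus name files."""
    spio.mmwrite(str(matrix_path), sparse.coo_matrix(np.asarray(matrix)))
    write_gene_list(genes, genes_path)
    write_gene_list(cells, cells_path)


def read_cell_labels(path: str | Path) -> dict[str, str]:
    """Read a two-column ``cell<TAB>cell_type`` file."""
    df = pd.read_csv(path, sep="\t", header=None, names=["cell", "cell_type"], dtype=str)
    return dict(zip(df["cell"], df["cell_type"]))


def write_cell_labels(labels: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for cell, ct in labels.items():
            fh.write(f"{cell}\t{ct}\n")
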