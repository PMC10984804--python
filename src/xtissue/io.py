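"""Readers and writers for the plain-text formats the pipeline exchanges.

Counts: TSV (genes x samples, optionally gzipped) or MatrixMarket with gene /
sample sidecar files.  Sample sheets and traits: CSV.  Edges and community
membership: TSV; communities additionally as a GMT-like file.  Ground truth
and reports: JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse


def read_counts(path: str | Path) -> pd.DataFrame:
    """Counts from TSV/TSV.GZ (first column = gene id) or MatrixMarket.

    For an ``.mtx`` file, ``<stem>.genes.txt`` and ``<stem>.samples.txt``
    sidecars (one id per line) must sit next to it.
    """
    path = Path(path)
    if path.suffix == ".mtx":
        mat = spio.mmread(path).toarray().astype(int)
        genes = Path(path.with_suffix("")).with_suffix(".genes.txt").read_text().split()
        samples = Path(path.with_suffix("")).with_suffix(".samples.txt").read_text().split()
        return pd.DataFrame(mat, index=genes, columns=samples)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates or df.columns.has_duplicates:
        raise ValueError("duplicate gene or sample ids in count matrix")
    return df.astype(int)


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    if path.suffix == ".mtx":
        spio.mmwrite(path, sparse.csr_matrix(counts.to_numpy()))
        Path(path.with_suffix("")).with_suffix(".genes.txt").write_text(
            "\n".join(counts.index) + "\n"
        )
        Path(path.with_suffix("")).with_suffix(".samples.txt").write_text(
            "\n".join(counts.columns) + "\n"
        )
    else:
        counts.to_csv(path, sep="\t")


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"sample_id", "subject_id", "tissue", "timepoint"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    return df


def read_traits(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "subject_id" not in df.columns:
        raise ValueError("trait table must have a subject_id column")
    return df


def read_gene_list(path: str | Path) -> set[str]:
    """Plain-text gene list, one id per line (e.g. protein-evidence genes)."""
    return {
        line.strip() for line in Path(path).read_text().splitlines() if line.strip()
    }


def write_edges(edges: pd.DataFrame, path: str | Path) -> None:
    edges.to_csv(path, sep="\t", index=False)


def write_membership(membership: pd.Series, path: str | Path) -> None:
    membership.rename("community").to_csv(path, sep="\t")


def write_gmt(communities: dict[int, list[str]], path: str | Path) -> None:
    """GMT-like file: community id, description, tab-separated gene list."""
    with open(path, "w") as fh:
        for cid in sorted(communities):
            name = f"community_{cid}" if cid != 0 else "unassigned"
            genes = "\t".join(communities[cid])
            fh.write(f"{name}\t{len(communities[cid])} genes\t{genes}\n")


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, pd.DataFrame):
        return {"index": list(map(str, obj.index)),
                "columns": list(map(str, obj.columns)),
                "values": obj.to_numpy().tolist()}
    if isinstance(obj, pd.Series):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(_jsonify(obj), indent=2, sort_keys=True) + "\n")


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
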