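"""Readers and writers for the pipeline's plain-text formats.

Counts: TSV with genes in rows and a header of sample IDs. Design:
two-column TSV (sample, stage). Networks: two-column TSV or SIF
("node relation node"). Labels: one gene ID per line. Ground truth and
manifests: JSON.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import List, Set, Tuple

import networkx as nx
import pandas as pd


class FormatError(ValueError):
    pass


def read_counts(path) -> pd.DataFrame:
    """Read a gene-by-sample integer count matrix from TSV."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"{path}: duplicate gene IDs: {dupes[:5]}")
    for col in df.columns:
        series = df[col]
        bad = series[~series.apply(lambda v: float(v).is_integer())]
        if len(bad):
            raise FormatError(
                f"{path}: non-integer count at gene {bad.index[0]!r}, sample {col!r}"
            )
    df = df.astype(int)
    if (df.to_numpy() < 0).any():
        raise FormatError(f"{path}: negative counts")
    return df


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t")


def read_design(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise FormatError(f"{path}: design needs (sample, stage) columns")
    df = df.iloc[:, :2]
    df.columns = ["sample", "stage"]
    if df["sample"].duplicated().any():
        raise FormatError(f"{path}: duplicate sample IDs")
    df["stage"] = pd.Categorical(df["stage"])
    return df


def write_design(design: pd.DataFrame, path) -> None:
    design.to_csv(path, sep="\t", index=False)


def read_edges(path) -> nx.Graph:
    """Read an edge list from two-column TSV or SIF; symmetrise, drop self-loops."""
    graph = nx.Graph()
    n_self, n_dup = 0, 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) == 3:
                a, _, b = fields  # SIF: source relation target
            elif len(fields) == 2:
                a, b = fields
            else:
                raise FormatError(
                    f"{path}:{lineno}: expected 2 (TSV) or 3 (SIF) fields, got {len(fields)}"
                )
            if a == b:
                n_self += 1
                continue
            if graph.has_edge(a, b):
                n_dup += 1
                continue
            graph.add_edge(a, b)
    if n_self or n_dup:
        warnings.warn(
            f"{path}: dropped {n_self} self-loop(s) and {n_dup} duplicate edge(s)",
            stacklevel=2,
        )
    return graph


def write_edges(edges: List[Tuple[str, str]], path, sif: bool = False) -> None:
    with open(path, "w") as fh:
        for a, b in edges:
            if sif:
                fh.write(f"{a}\tpp\t{b}\n")
            else:
                fh.write(f"{a}\t{b}\n")


def read_labels(path) -> Set[str]:
    labels = set()
    with open(path) as fh:
        for line in fh:
            gene = line.strip()
            if gene:
                labels.add(gene)
    return labels


def write_labels(labels, path) -> None:
    with open(path, "w") as fh:
        for gene in sorted(labels):
            fh.write(f"{gene}\n")


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())
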