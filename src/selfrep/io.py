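"""TSV readers and writers for the pair-list and similarity contracts.

Pair lists are headered TSV with columns ``gene_a``, ``gene_b`` (extras
ignored).  Similarity comes either as a square matrix whose first row and
column carry gene identifiers, or in long form (``gene_a``, ``gene_b``,
``similarity``); the dialect is auto-detected from the header.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .data import GeneIndex, InteractionMatrix, SimilarityGraph, build_similarity_graph
from .model import TrainingTrace
from .ranking import PredictionRanking

__all__ = [
    "read_pairs",
    "write_pairs",
    "read_similarity",
    "write_similarity",
    "write_ranking",
    "write_trace",
    "write_cv_report",
]

_LONG_FORM_COLUMNS = {"gene_a", "gene_b", "similarity"}


def read_pairs(path: str | Path) -> list[tuple[str, str]]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("gene_a", "gene_b"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    return list(zip(df["gene_a"], df["gene_b"]))


def write_pairs(pairs, path: str | Path) -> None:
    df = pd.DataFrame(sorted(pairs), columns=["gene_a", "gene_b"])
    df.to_csv(path, sep="\t", index=False)


def read_similarity(path: str | Path, index: GeneIndex) -> SimilarityGraph:
    """Load a similarity matrix onto an existing gene index.

    Genes present in ``index`` but absent from the file receive all-zero
    similarity rows/columns (their graph penalty is neutral); file genes
    outside the index are dropped.
    """
    header = pd.read_csv(path, sep="\t", nrows=0)
    if set(header.columns) == _LONG_FORM_COLUMNS:
        df = pd.read_csv(path, sep="\t", dtype={"gene_a": str, "gene_b": str})
        S = np.zeros((index.n, index.n))
        for a, b, value in zip(df["gene_a"], df["gene_b"], df["similarity"].astype(float)):
            if a in index and b in index:
                i, j = index.position(a), index.position(b)
                S[i, j] = S[j, i] = value
    else:
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        S = np.zeros((index.n, index.n))
        shared = [g for g in index.genes if g in df.index and g in df.columns]
        if shared:
            pos = [index.position(g) for g in shared]
            block = df.loc[shared, shared].to_numpy(dtype=float)
            S[np.ix_(pos, pos)] = block
    return build_similarity_graph(S, index)


def write_similarity(graph: SimilarityGraph, path: str | Path) -> None:
    genes = list(graph.index.genes)
    pd.DataFrame(graph.S, index=genes, columns=genes).to_csv(path, sep="\t")


def write_ranking(ranking: PredictionRanking, path: str | Path) -> None:
    rows = [
        {"rank": i + 1, "gene_a": a, "gene_b": b, "score": f"{s:.4f}"}
        for i, (a, b, s) in enumerate(ranking)
    ]
    pd.DataFrame(rows, columns=["rank", "gene_a", "gene_b", "score"]).to_csv(
        path, sep="\t", index=False
    )


def write_trace(trace: TrainingTrace, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "iteration": np.arange(len(trace.objective_values)),
            "objective": trace.objective_values,
        }
    )
    df.to_csv(path, sep="\t", index=False)


def write_cv_report(report, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("fold\tauc\n")
        for i, auc in enumerate(report.per_fold_auc):
            fh.write(f"{i}\t{auc:.6f}\n")
        fh.write(
            f"# mean_auc={report.mean_auc:.6f}\tsd={report.sd_auc:.6f}"
            f"\tci_halfwidth={report.ci_halfwidth:.6f}\n"
        )
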