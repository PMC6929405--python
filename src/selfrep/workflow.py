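"""End-to-end fit/predict workflow with reproducibility manifest."""

from __future__ import annotations

import hashlib
import json
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import pandas as pd

from . import io as sio
from .data import Hyperparameters, build_interaction_matrix
from .model import fit, predict
from .ranking import rank_candidates

__all__ = ["run_fit_predict"]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _package_version() -> str:
    try:
        return version("selfrep")
    except PackageNotFoundError:
        return "unknown"


def run_fit_predict(
    pairs_path: str | Path,
    similarity_path: str | Path | None,
    out_dir: str | Path,
    hp: Hyperparameters,
    top_k: int | None = None,
) -> dict[str, str]:
    """Fit on all known pairs, rank unknown pairs, write artifacts.

    Writes ``ranking.tsv``, ``trace.tsv``, ``U.tsv`` and ``manifest.json``
    under ``out_dir``.  Inputs are validated before any computation; on
    failure any partially written outputs are removed.
    """
    pairs_path = Path(pairs_path)
    if not pairs_path.is_file():
        raise FileNotFoundError(f"pair list not found: {pairs_path}")
    if similarity_path is not None:
        similarity_path = Path(similarity_path)
        if not similarity_path.is_file():
            raise FileNotFoundError(f"similarity matrix not found: {similarity_path}")

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs = {
        "ranking": out_dir / "ranking.tsv",
        "trace": out_dir / "trace.tsv",
        "U": out_dir / "U.tsv",
        "manifest": out_dir / "manifest.json",
    }
    try:
        X = build_interaction_matrix(sio.read_pairs(pairs_path))
        graph = sio.read_similarity(similarity_path, X.index) if similarity_path else None
        state, trace = fit(X, graph, hp)
        scores = predict(X, state.U)
        ranking = rank_candidates(X, scores, top_k=top_k)

        sio.write_ranking(ranking, outputs["ranking"])
        sio.write_trace(trace, outputs["trace"])
        genes = list(X.index.genes)
        pd.DataFrame(state.U, index=genes, columns=genes).to_csv(outputs["U"], sep="\t")

        manifest = {
            "package_version": _package_version(),
            "inputs": {
                "pairs": {"path": str(pairs_path), "sha256": _sha256(pairs_path)},
                "similarity": (
                    {"path": str(similarity_path), "sha256": _sha256(similarity_path)}
                    if similarity_path
                    else None
                ),
            },
            "hyperparameters": {
                "lambda_l2": hp.lambda_l2,
                "beta_graph": hp.beta_graph,
                "tol": hp.tol,
                "max_iter": hp.max_iter,
                "eps_div": hp.eps_div,
                "init_mode": hp.init_mode,
                "seed": hp.seed,
                "renormalize_columns": hp.renormalize_columns,
            },
            "top_k": top_k,
            "n_genes": X.n,
            "n_known_pairs": X.n_positives(),
            "n_iterations": trace.n_iter,
            "converged": trace.converged,
            "final_objective": float(trace.objective_values[-1]),
        }
        with open(outputs["manifest"], "w") as fh:
            json.dump(manifest, fh, indent=2)
    except Exception:
        for path in outputs.values():
            path.unlink(missing_ok=True)
        raise
    return {name: str(path) for name, path in outputs.items()}
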