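"""Readers, writers, PCA preprocessing and the end-to-end pipeline.

This is the plumbing layer: CSV/TSV input (subjects in rows), optional
PCA reduction, the selected sampler (TIP, EPA, or CRP), consensus and
graph summaries, and deterministic text outputs keyed by subject
identifier.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .consensus import (
    ConsensusResult,
    PosteriorSimilarityMatrix,
    posterior_similarity_from_draws,
    select_consensus,
)
from .epa_baseline import EPAParams, run_crp_sampler, run_epa_sampler
from .gibbs_sampler import ChainRecord, SamplerConfig, run_sampler
from .graph_summary import one_cluster_graph, write_edge_list
from .similarity import DistanceMatrix

__all__ = [
    "RunConfig",
    "PipelineResult",
    "read_matrix",
    "read_distance_matrix",
    "pca_reduce",
    "run_pipeline",
]


def read_matrix(path, label_column: str | None = None):
    """Read a subjects-by-features CSV/TSV.

    The first column is treated as subject identifiers when it is
    non-numeric; otherwise row numbers are used.  Returns
    ``(X, subject_ids, labels)`` with ``labels`` None unless
    ``label_column`` names a column to split off.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep)
    first = df.columns[0]
    if not pd.api.types.is_numeric_dtype(df[first]):
        df = df.set_index(first)
    labels = None
    if label_column is not None:
        if label_column not in df.columns:
            raise ValueError(f"label column {label_column!r} not found")
        labels = df[label_column].to_numpy()
        df = df.drop(columns=[label_column])
    X = df.to_numpy(dtype=float)
    return X, [str(i) for i in df.index], labels


def read_distance_matrix(path) -> DistanceMatrix:
    """Read a square distance matrix CSV/TSV with matching row/column ids."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    if list(df.index.astype(str)) != list(df.columns.astype(str)):
        raise ValueError("distance matrix row and column identifiers disagree")
    return DistanceMatrix(df.to_numpy(dtype=float), subject_ids=[str(i) for i in df.index])


def pca_reduce(X: np.ndarray, q: int, scale: bool = False):
    """Project onto the top ``q`` principal components via centered SVD.

    The sign of each component is fixed so its largest-magnitude loading
    is positive, making the projection deterministic.  Returns the
    (n, q) scores and the cumulative explained-variance fractions.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if not 1 <= q <= min(n, p):
        raise ValueError(f"q must lie in [1, {min(n, p)}]")
    Xc = X - X.mean(axis=0)
    if scale:
        sd = Xc.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        Xc = Xc / sd
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    # deterministic sign: largest-|loading| entry of each component positive
    for j in range(Vt.shape[0]):
        pivot = np.argmax(np.abs(Vt[j]))
        if Vt[j, pivot] < 0:
            Vt[j] *= -1
            U[:, j] *= -1
    var = s**2
    explained = np.cumsum(var) / var.sum() if var.sum() > 0 else np.ones_like(var)
    scores = U[:, :q] * s[:q]
    return scores, explained[:q]


@dataclass(frozen=True)
class RunConfig:
    """Everything needed for one end-to-end clustering run."""

    input_path: str | None = None
    distance_path: str | None = None
    prior: str = "tip"  # tip | epa | crp
    pca_components: int | None = None
    scale: bool = False
    label_column: str | None = None
    sampler: SamplerConfig = field(default_factory=SamplerConfig)
    epa: EPAParams = field(default_factory=EPAParams)
    output_dir: str | None = None


@dataclass
class PipelineResult:
    record: ChainRecord
    Bbar: PosteriorSimilarityMatrix
    consensus: ConsensusResult
    subject_ids: list[str]
    report: dict


def _run_selected(prior: str, X, D, sampler: SamplerConfig, epa: EPAParams) -> ChainRecord:
    if prior == "tip":
        return run_sampler(X=X, D=D, config=sampler)
    if prior == "epa":
        return run_epa_sampler(X=X, D=D, config=sampler, params=epa)
    if prior == "crp":
        return run_crp_sampler(X=X, D=D, config=sampler, params=epa)
    raise ValueError(f"unknown prior {prior!r}; choose tip, epa or crp")


def run_pipeline(
    config: RunConfig,
    X: np.ndarray | None = None,
    D: DistanceMatrix | None = None,
    subject_ids: list[str] | None = None,
) -> PipelineResult:
    """Read input, reduce, sample, summarize, and (optionally) write.

    Inputs may be passed in memory (``X`` and/or ``D``) or read from the
    paths in ``config``.  When ``config.output_dir`` is set, consensus
    assignments, the posterior similarity matrix, the one-cluster edge
    list, the K trace and a JSON run report are written there.
    """
    if X is None and config.input_path is not None:
        X, subject_ids, _ = read_matrix(config.input_path, config.label_column)
    if D is None and config.distance_path is not None:
        D = read_distance_matrix(config.distance_path)
        subject_ids = subject_ids or D.subject_ids
    if X is None and D is None:
        raise ValueError("no input: supply X/D or input_path/distance_path")
    if X is not None:
        X = np.asarray(X, dtype=float)
        if config.pca_components is not None:
            X, _ = pca_reduce(X, config.pca_components, scale=config.scale)
    n = X.shape[0] if X is not None else D.n
    if subject_ids is None:
        subject_ids = [str(i) for i in range(n)]

    record = _run_selected(config.prior, X, D, config.sampler, config.epa)
    Bbar = posterior_similarity_from_draws(record.draws)
    consensus = select_consensus(record.draws, Bbar)
    graph = one_cluster_graph(Bbar)
    report = {
        "prior": config.prior,
        "seed": config.sampler.seed,
        "burn_in": config.sampler.burn_in,
        "samples": config.sampler.samples,
        "n": n,
        "consensus_K": int(consensus.assignment.max()),
        "pear": consensus.pear_value,
        "graph_components": graph.components,
    }
    result = PipelineResult(record, Bbar, consensus, list(subject_ids), report)

    if config.output_dir is not None:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(
            {"subject_id": subject_ids, "cluster": consensus.assignment}
        ).to_csv(out / "consensus.csv", index=False)
        pd.DataFrame(Bbar.values, index=subject_ids, columns=subject_ids).to_csv(
            out / "posterior_similarity.csv"
        )
        pd.DataFrame(
            {"iteration": np.arange(record.K_trace.size), "K": record.K_trace}
        ).to_csv(out / "k_trace.csv", index=False)
        pd.DataFrame(
            {"draw": np.arange(consensus.pear_trace.size), "pear": consensus.pear_trace}
        ).to_csv(out / "pear_trace.csv", index=False)
        write_edge_list(graph, out / "one_cluster_edges.tsv")
        with open(out / "run_report.json", "w", encoding="utf-8") as fh:
            json.dump(report, fh, indent=2)
    return result
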