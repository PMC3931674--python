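"""Dissimilarity (prototype-based) patient representation.

Each patient x is mapped to the vector of its dissimilarities from a fixed
prototype set P = {y_1 ... y_n}: phi(x, P) = (D(x, y_1), ..., D(x, y_n)).
Prototypes are the lowest-stage (stage II) patients; distances are computed
over the combined-signature genes' expression.  Classifiers then operate in
this dissimilarity space R^n instead of gene space.

Supported dissimilarities D:

* ``euclidean`` – L2 norm of the difference;
* ``manhattan`` – L1 norm;
* ``kendall_tau`` – (1 - tau_b) / 2, the tie-corrected Kendall rank
  correlation rescaled to [0, 1] (0 = identical ordering);
* ``kl`` – Jeffreys-symmetrized Kullback-Leibler divergence between the
  profiles mapped back to the linear scale, shifted by a pseudocount of
  1e-6 and normalized to the probability simplex.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.stats import kendalltau

from .signature import CombinedSignature
from .simulate import ExpressionCohort

METRICS: tuple[str, ...] = ("euclidean", "manhattan", "kendall_tau", "kl")

_PSEUDOCOUNT = 1e-6


def _to_probabilities(v: np.ndarray) -> np.ndarray:
    """Map a log2 expression profile to the probability simplex."""
    linear = np.exp2(v) + _PSEUDOCOUNT
    return linear / linear.sum()


def _jeffreys_kl(p: np.ndarray, q: np.ndarray) -> float:
    # 0.5 * (KL(p||q) + KL(q||p)) = 0.5 * sum (p - q) * (log p - log q)
    logp, logq = np.log(p), np.log(q)
    return float(0.5 * np.sum((p - q) * (logp - logq)))


def _kendall_distance(x: np.ndarray, y: np.ndarray) -> float:
    if x.size < 2:
        raise ValueError("kendall_tau needs vectors of length >= 2")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("kendall_tau is undefined for constant vectors")
    tau = kendalltau(x, y).statistic
    return float((1.0 - tau) / 2.0)


def pairwise_distance(x, y, metric: str) -> float:
    """Dissimilarity between two equal-length expression profiles.

    Symmetric for every supported metric (KL is Jeffreys-symmetrized).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"vectors must be 1-D and equal length, got {x.shape} vs {y.shape}")
    if metric == "euclidean":
        return float(np.linalg.norm(x - y))
    if metric == "manhattan":
        return float(np.abs(x - y).sum())
    if metric == "kendall_tau":
        return _kendall_distance(x, y)
    if metric == "kl":
        return _jeffreys_kl(_to_probabilities(x), _to_probabilities(y))
    raise ValueError(f"unknown metric {metric!r}; choose one of {METRICS}")


#: above this many (gene pair) x (vector) sign entries the tau matrix falls
#: back to per-pair scipy calls to bound memory
_KENDALL_VECTOR_LIMIT = 20_000_000


def _kendall_matrix(X: np.ndarray, P: np.ndarray) -> np.ndarray:
    """All patient-by-prototype tau-b distances.

    tau_b = (P - Q) / sqrt((n0 - t_x)(n0 - t_y)) where P - Q is the sum over
    gene pairs of the product of difference signs; vectorized as a sign-matrix
    product, falling back to per-pair evaluation for very long profiles.
    """
    m = X.shape[1]
    if m < 2:
        raise ValueError("kendall_tau needs vectors of length >= 2")
    n_pairs = m * (m - 1) // 2
    if n_pairs * max(X.shape[0], P.shape[0]) > _KENDALL_VECTOR_LIMIT:
        d = np.empty((X.shape[0], P.shape[0]))
        for j in range(P.shape[0]):
            for i in range(X.shape[0]):
                d[i, j] = _kendall_distance(X[i], P[j])
        return d
    iu, ju = np.triu_indices(m, k=1)
    sx = np.sign(X[:, iu] - X[:, ju])
    sp = np.sign(P[:, iu] - P[:, ju])
    nx = n_pairs - np.count_nonzero(sx == 0, axis=1)  # untied pairs in x
    np_ = n_pairs - np.count_nonzero(sp == 0, axis=1)
    if np.any(nx == 0) or np.any(np_ == 0):
        raise ValueError("kendall_tau is undefined for constant vectors")
    tau = (sx @ sp.T) / np.sqrt(nx[:, None] * np_[None, :])
    return (1.0 - tau) / 2.0


@dataclass
class PrototypeSet:
    """Ordered prototype patients with their signature-gene profiles.

    ``vectors`` is genes x prototypes, rows in the source cohort's gene order.
    """

    ids: tuple[str, ...]
    vectors: pd.DataFrame
    stage: str

    def __post_init__(self) -> None:
        if len(self.ids) < 1:
            raise ValueError("prototype set must contain at least one patient")

    def __len__(self) -> int:
        return len(self.ids)


def signature_gene_index(values: pd.DataFrame, signature: CombinedSignature) -> pd.Index:
    """Signature genes in the matrix's stable row order; errors if any are absent."""
    genes = signature.genes
    if not genes:
        raise ValueError("combined signature is empty")
    missing = genes - set(values.index)
    if missing:
        raise ValueError(f"{len(missing)} signature genes absent from matrix: "
                         f"{sorted(missing)[:5]}...")
    return values.index[values.index.isin(genes)]


def select_prototypes(
    cohort: ExpressionCohort, stage: str, signature: CombinedSignature
) -> PrototypeSet:
    """All patients of the (lowest available) ``stage``, restricted to the
    signature genes, in stable cohort order."""
    samples = cohort.samples_of_stage(stage)
    if not samples:
        raise ValueError(f"cohort {cohort.name} has no stage-{stage} samples")
    genes = signature_gene_index(cohort.values, signature)
    return PrototypeSet(
        ids=tuple(samples),
        vectors=cohort.values.loc[genes, samples],
        stage=stage,
    )


@dataclass
class DissimilarityMatrix:
    """N x n matrix of patient-to-prototype dissimilarities."""

    values: pd.DataFrame  # patients (rows) x prototypes (columns)
    metric: str

    def write(self, path) -> None:
        """TSV with prototype IDs as column headers."""
        self.values.to_csv(path, sep="\t", index_label="patient_id")


def build_dissimilarity_matrix(
    patients: pd.DataFrame, prototypes: PrototypeSet, metric: str
) -> DissimilarityMatrix:
    """phi(x, P) for every patient column of ``patients``.

    ``patients`` is genes x patients over exactly the prototype gene order;
    a gene-order mismatch is an error rather than silently realigned.
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose one of {METRICS}")
    if not patients.index.equals(prototypes.vectors.index):
        raise ValueError("gene order of patients does not match the prototype set")
    X = patients.to_numpy(dtype=float).T  # patients x genes
    P = prototypes.vectors.to_numpy(dtype=float).T  # prototypes x genes
    if metric == "euclidean":
        d = cdist(X, P, metric="euclidean")
    elif metric == "manhattan":
        d = cdist(X, P, metric="cityblock")
    elif metric == "kendall_tau":
        d = _kendall_matrix(X, P)
    else:  # kl, vectorized Jeffreys divergence
        A = np.apply_along_axis(_to_probabilities, 1, X)
        B = np.apply_along_axis(_to_probabilities, 1, P)
        logA, logB = np.log(A), np.log(B)
        d = 0.5 * (
            (A * logA).sum(axis=1)[:, None]
            + (B * logB).sum(axis=1)[None, :]
            - A @ logB.T
            - logA @ B.T
        )
        d = np.maximum(d, 0.0)  # guard tiny negative round-off
    values = pd.DataFrame(d, index=patients.columns, columns=list(prototypes.ids))
    return DissimilarityMatrix(values=values, metric=metric)
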