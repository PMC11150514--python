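"""Similarity computation and fusion.

Two disease semantic similarities are computed over MeSH-style ancestor
DAGs — a geometric-decay contribution scheme and an information-content
scheme — and averaged.  Gaussian interaction-profile kernel (GIPK)
similarities are computed from the binary association matrix for both the
miRNA and disease sides.  The fused miRNA similarity MM takes the
functional similarity entry where it is non-zero and the GIPK entry
otherwise; the fused disease similarity DD does the same with the semantic
similarity.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .io import (
    AssociationMatrix,
    DiseaseDAG,
    LabelError,
    LabeledMatrix,
    Role,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SemanticScores",
    "GipkBandwidths",
    "semantic_contribution_w1",
    "semantic_similarity_ds1",
    "semantic_contribution_w2",
    "semantic_similarity_ds2",
    "ds1_matrix",
    "ds2_matrix",
    "integrate_disease_semantic",
    "gipk_bandwidths",
    "gipk_similarity",
    "fuse_similarity",
    "build_fused_similarities",
]


@dataclass
class SemanticScores:
    """Per-term semantic contributions and per-disease totals for one scheme."""

    contributions: dict[tuple[str, str], float]  # (disease, term) -> W
    totals: dict[str, float]                     # disease -> S
    scheme: str                                  # "scheme1" | "scheme2"


# ---------------------------------------------------------------------------
# scheme 1: geometric decay up the ancestor DAG


def semantic_contribution_w1(dag: DiseaseDAG, disease_id: str) -> dict[str, float]:
    """Contribution of every term in T(d) to disease d.

    The disease's own term contributes 1; an ancestor t contributes
    ``phi`` times the largest contribution among its DAG children inside
    T(d), i.e. the contribution decays geometrically along the best path
    back to d.
    """
    tset = dag.term_set(disease_id)
    root = dag.disease_roots[disease_id]
    w: dict[str, float] = {}

    def contribution(term: str) -> float:
        if term in w:
            return w[term]
        if term == root:
            w[term] = 1.0
            return 1.0
        children = dag.children_in(term, tset)
        # every non-root term of T(d) has a child on a path from d
        w[term] = dag.phi * max(contribution(c) for c in children)
        return w[term]

    for t in tset:
        contribution(t)
    return w


def _s1(w: Mapping[str, float]) -> float:
    return float(sum(w.values()))


def semantic_similarity_ds1(dag: DiseaseDAG, d_i: str, d_j: str) -> float:
    """Scheme-1 semantic similarity: shared-term contributions over totals."""
    wi = semantic_contribution_w1(dag, d_i)
    wj = semantic_contribution_w1(dag, d_j)
    shared = set(wi) & set(wj)
    denom = _s1(wi) + _s1(wj)
    assert denom > 0, "scheme-1 totals are >= 1 by construction"
    return sum(wi[t] + wj[t] for t in shared) / denom


def ds1_matrix(dag: DiseaseDAG, disease_ids: Sequence[str] | None = None) -> LabeledMatrix:
    """Scheme-1 similarity matrix over the disease universe."""
    ids = list(disease_ids) if disease_ids is not None else dag.diseases
    w = {d: semantic_contribution_w1(dag, d) for d in ids}
    s = {d: _s1(w[d]) for d in ids}
    n = len(ids)
    values = np.eye(n)
    for a in range(n):
        for b in range(a + 1, n):
            wa, wb = w[ids[a]], w[ids[b]]
            shared = set(wa) & set(wb)
            values[a, b] = values[b, a] = sum(wa[t] + wb[t] for t in shared) / (
                s[ids[a]] + s[ids[b]]
            )
    return LabeledMatrix(ids, ids, values, Role.DS1).validate()


# ---------------------------------------------------------------------------
# scheme 2: information content over DAG membership


def semantic_contribution_w2(
    dag: DiseaseDAG, disease_universe: Sequence[str] | None = None
) -> dict[str, float]:
    """Disease-independent term contribution -log(n_DAGs(t) / n_diseases).

    A term appearing in every disease's ancestor DAG carries no information
    (contribution 0); rarer terms carry more.  Natural logarithm.  Terms in
    no DAG are absent from the mapping.
    """
    ids = list(disease_universe) if disease_universe is not None else dag.diseases
    if not ids:
        raise ValueError("disease universe must be non-empty")
    counts: dict[str, int] = {}
    for d in ids:
        for t in dag.term_set(d):
            counts[t] = counts.get(t, 0) + 1
    n = len(ids)
    return {t: -math.log(c / n) for t, c in counts.items()}


def semantic_similarity_ds2(
    dag: DiseaseDAG,
    d_i: str,
    d_j: str,
    w2: Mapping[str, float] | None = None,
    disease_universe: Sequence[str] | None = None,
) -> float:
    """Scheme-2 semantic similarity; 0/0 (all shared terms ubiquitous) -> 0."""
    if w2 is None:
        w2 = semantic_contribution_w2(dag, disease_universe)
    ti, tj = dag.term_set(d_i), dag.term_set(d_j)
    si = sum(w2.get(t, 0.0) for t in ti)
    sj = sum(w2.get(t, 0.0) for t in tj)
    denom = si + sj
    if denom == 0.0:
        return 0.0
    num = sum(2.0 * w2.get(t, 0.0) for t in ti & tj)
    return num / denom


def ds2_matrix(dag: DiseaseDAG, disease_ids: Sequence[str] | None = None) -> LabeledMatrix:
    """Scheme-2 similarity matrix over the disease universe.

    The diagonal is forced to 1 (self-similarity convention) even for the
    degenerate disease whose every term is ubiquitous.
    """
    ids = list(disease_ids) if disease_ids is not None else dag.diseases
    w2 = semantic_contribution_w2(dag, ids)
    n = len(ids)
    values = np.eye(n)
    for a in range(n):
        for b in range(a + 1, n):
            values[a, b] = values[b, a] = semantic_similarity_ds2(dag, ids[a], ids[b], w2)
    return LabeledMatrix(ids, ids, values, Role.DS2).validate()


def integrate_disease_semantic(ds1: LabeledMatrix, ds2: LabeledMatrix) -> LabeledMatrix:
    """Elementwise average of the two semantic similarities."""
    if ds1.row_ids != ds2.row_ids or ds1.col_ids != ds2.col_ids:
        raise LabelError("DS1 and DS2 must share labels")
    out = LabeledMatrix(list(ds1.row_ids), list(ds1.col_ids), (ds1.values + ds2.values) / 2.0, Role.DS)
    return out.validate()


# ---------------------------------------------------------------------------
# Gaussian interaction-profile kernels


@dataclass(frozen=True)
class GipkBandwidths:
    """Kernel bandwidths, the reciprocal mean squared profile norms."""

    lambda_m: float
    lambda_d: float

    def __post_init__(self) -> None:
        for name, v in (("lambda_m", self.lambda_m), ("lambda_d", self.lambda_d)):
            if not (v > 0 and math.isfinite(v)):
                raise ValueError(f"{name} must be positive and finite, got {v}")


def gipk_bandwidths(assoc: AssociationMatrix) -> GipkBandwidths:
    """Bandwidths lambda = 1 / mean squared interaction-profile norm."""
    a = assoc.values
    nm, nd = a.shape
    row_ms = float((a ** 2).sum()) / nm
    col_ms = float((a ** 2).sum()) / nd
    if row_ms == 0.0 or col_ms == 0.0:
        raise ZeroDivisionError(
            "association matrix has no known associations; GIPK bandwidths are undefined"
        )
    return GipkBandwidths(lambda_m=1.0 / row_ms, lambda_d=1.0 / col_ms)


def gipk_similarity(
    assoc: AssociationMatrix, axis: str, bw: GipkBandwidths
) -> LabeledMatrix:
    """RBF kernel over interaction profiles (rows for miRNAs, columns for diseases)."""
    if axis == "mirna":
        profiles, lam, ids, role = assoc.values, bw.lambda_m, assoc.mirna_ids, Role.MGKS
    elif axis == "disease":
        profiles, lam, ids, role = assoc.values.T, bw.lambda_d, assoc.disease_ids, Role.DGKS
    else:
        raise ValueError(f"axis must be 'mirna' or 'disease', got {axis!r}")
    d2 = squareform(pdist(profiles, metric="sqeuclidean"))
    values = np.exp(-lam * d2)
    np.fill_diagonal(values, 1.0)
    return LabeledMatrix(list(ids), list(ids), values, role).validate()


# ---------------------------------------------------------------------------
# fusion


def fuse_similarity(primary: LabeledMatrix, gipk: LabeledMatrix) -> LabeledMatrix:
    """Fuse a primary similarity with a GIPK fallback.

    Where the primary entry is non-zero it is kept; elsewhere the GIPK entry
    fills in.  The result is symmetrized and its diagonal forced to 1.
    """
    if primary.row_ids != gipk.row_ids or primary.col_ids != gipk.col_ids:
        raise LabelError("primary and GIPK matrices must share labels")
    values = np.where(primary.values != 0.0, primary.values, gipk.values)
    values = (values + values.T) / 2.0
    np.fill_diagonal(values, 1.0)
    role = Role.MM if gipk.role == Role.MGKS else Role.DD
    return LabeledMatrix(list(primary.row_ids), list(primary.col_ids), values, role).validate()


def build_fused_similarities(
    assoc: AssociationMatrix,
    mf: LabeledMatrix | None = None,
    ds: LabeledMatrix | None = None,
) -> tuple[LabeledMatrix, LabeledMatrix]:
    """Full similarity pipeline: GIPK from the association matrix, then fusion.

    ``mf``/``ds`` are the primary miRNA-functional and disease-semantic
    similarities; when absent an all-zero placeholder is used so the fused
    matrix falls back to pure GIPK.
    """
    bw = gipk_bandwidths(assoc)
    mgks = gipk_similarity(assoc, "mirna", bw)
    dgks = gipk_similarity(assoc, "disease", bw)
    if mf is None:
        mf = LabeledMatrix(list(assoc.mirna_ids), list(assoc.mirna_ids),
                           np.zeros((len(assoc.mirna_ids),) * 2), Role.MF)
    if ds is None:
        ds = LabeledMatrix(list(assoc.disease_ids), list(assoc.disease_ids),
                           np.zeros((len(assoc.disease_ids),) * 2), Role.DS)
    mm = fuse_similarity(mf, mgks)
    dd = fuse_similarity(ds, dgks)
    return mm, dd
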