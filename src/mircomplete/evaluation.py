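"""Cross-validation protocols, ranking metrics and sensitivity experiments.

Global leave-one-out CV treats each known association in turn as the test
pair, re-solves the completion on the remaining associations and ranks the
held-out pair against every unknown candidate pair.  k-fold CV partitions
the known associations into folds and scores each fold's pairs against the
unknown pairs.  Unless disabled, the GIPK similarities (and hence the
fused similarity blocks) are recomputed from the training matrix of each
fold so held-out pairs never leak into training artifacts.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import average_precision_score

from .completion import SolverConfig, build_target_matrix, solve
from .io import AssociationMatrix, LabeledMatrix
from .similarity import build_fused_similarities

logger = logging.getLogger(__name__)

__all__ = [
    "CVConfig",
    "CVResult",
    "auc_from_scores",
    "aupr_from_scores",
    "training_matrix",
    "global_loocv",
    "kfold_cv",
    "threshold_metrics",
    "sparsity_experiment",
]


@dataclass
class CVConfig:
    """Cross-validation settings.

    recompute_gipk
        Recompute GIPK similarity from the training matrix of each fold
        (prevents information leakage from held-out pairs).
    negative_ratio
        Negatives-to-positives ratio for the sampled confusion-metric table.
    loocv_cap
        Number of associations above which leave-one-out emits a runtime
        warning (a faithful LOOCV re-solves once per association).
    """

    scheme: str = "kfold"  # "kfold" | "global_loocv"
    k: int = 5
    seed: int = 0
    recompute_gipk: bool = True
    negative_ratio: float = 1.0
    loocv_cap: int = 200

    def validate(self) -> "CVConfig":
        if self.scheme not in ("kfold", "global_loocv"):
            raise ValueError(f"unknown CV scheme {self.scheme!r}")
        if self.scheme == "kfold" and self.k < 2:
            raise ValueError("kfold requires k >= 2")
        return self


@dataclass
class CVResult:
    """Aggregate CV outcome."""

    auc: float
    aupr: float
    per_fold: list[float]
    score_table: pd.DataFrame  # columns: mirna, disease, score, is_positive
    thresholds: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# ranking metrics


def auc_from_scores(positives: Sequence[float], negatives: Sequence[float]) -> float:
    """Rank-based AUC (Mann-Whitney U / (n+ * n-)); ties count one half."""
    pos = np.asarray(positives, dtype=float)
    neg = np.asarray(negatives, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score lists must be non-empty")
    ranks = rankdata(np.concatenate([pos, neg]))
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def aupr_from_scores(positives: Sequence[float], negatives: Sequence[float]) -> float:
    """Area under the precision-recall curve (step interpolation, tie groups)."""
    pos = np.asarray(positives, dtype=float)
    neg = np.asarray(negatives, dtype=float)
    if pos.size == 0:
        raise ValueError("positives must be non-empty")
    y = np.concatenate([np.ones(pos.size), np.zeros(neg.size)])
    return float(average_precision_score(y, np.concatenate([pos, neg])))


# ---------------------------------------------------------------------------
# shared fold machinery


def training_matrix(
    assoc: AssociationMatrix, test_idx: np.ndarray
) -> AssociationMatrix:
    """Training copy of the association matrix with test entries zeroed.

    ``test_idx`` is an (n, 2) array of (row, col) indices.  Only these
    positions are read from/written to, so any sentinel values planted in
    held-out cells never reach a training artifact.
    """
    values = assoc.values.copy()
    if len(test_idx):
        values[test_idx[:, 0], test_idx[:, 1]] = 0.0
    return AssociationMatrix(list(assoc.mirna_ids), list(assoc.disease_ids), values)


def _fold_scores(
    train: AssociationMatrix,
    mf: LabeledMatrix | None,
    ds: LabeledMatrix | None,
    mm_full: LabeledMatrix | None,
    dd_full: LabeledMatrix | None,
    cfg: CVConfig,
    solver_cfg: SolverConfig,
) -> np.ndarray:
    """Solve the completion for one training matrix; return the score block."""
    if cfg.recompute_gipk or mm_full is None:
        mm, dd = build_fused_similarities(train, mf, ds)
    else:
        mm, dd = mm_full, dd_full
    system = build_target_matrix(mm, train, dd)
    result = solve(system, solver_cfg)
    return result.A_star.values


def _positive_indices(assoc: AssociationMatrix) -> np.ndarray:
    return np.argwhere(assoc.values == 1.0)


# ---------------------------------------------------------------------------
# protocols


def global_loocv(
    assoc: AssociationMatrix,
    mf: LabeledMatrix | None = None,
    ds: LabeledMatrix | None = None,
    cfg: CVConfig | None = None,
    solver_cfg: SolverConfig | None = None,
    fast: bool = False,
) -> CVResult:
    """Leave-one-out over known associations, pooled against all candidates.

    Each known pair is removed, the model re-solved on the remainder and the
    held-out pair compared with every unknown pair; comparisons are pooled
    into one Mann-Whitney AUC.  Deterministic: no sampling is involved.

    ``fast=True`` performs a single solve with every association observed
    and ranks each positive from that one model.  This is an optimistic
    shortcut (each test pair influenced its own training) suitable only for
    quick sanity checks, never for reported results.
    """
    cfg = (cfg or CVConfig(scheme="global_loocv")).validate()
    solver_cfg = solver_cfg or SolverConfig()
    pos_idx = _positive_indices(assoc)
    if len(pos_idx) < 2:
        raise ValueError("global LOOCV needs at least 2 known associations")
    if fast:
        logger.warning("fast LOOCV scores all pairs from a single leaky solve")
    if len(pos_idx) > cfg.loocv_cap:
        logger.warning(
            "global LOOCV over %d associations re-solves the model %d times; "
            "consider kfold or raising loocv_cap deliberately",
            len(pos_idx), len(pos_idx),
        )
    unknown = assoc.values == 0.0
    unknown_idx = np.argwhere(unknown)
    neg_rng = np.random.default_rng(cfg.seed)
    wins = 0.0
    total = 0
    per_fold: list[float] = []
    pooled_pos: list[float] = []
    pooled_neg: list[np.ndarray] = []
    rows = []
    full_scores = (
        _fold_scores(assoc, mf, ds, None, None, cfg, solver_cfg) if fast else None
    )
    for i, j in pos_idx:
        if fast:
            scores = full_scores
        else:
            train = training_matrix(assoc, np.array([[i, j]]))
            scores = _fold_scores(train, mf, ds, None, None, cfg, solver_cfg)
        test_score = scores[i, j]
        cand = scores[unknown]
        wins += float((cand < test_score).sum()) + 0.5 * float((cand == test_score).sum())
        total += cand.size
        per_fold.append(auc_from_scores([test_score], cand))
        pooled_pos.append(test_score)
        pooled_neg.append(cand)
        rows.append((assoc.mirna_ids[i], assoc.disease_ids[j], float(test_score), True))
        n_neg = max(1, int(round(cfg.negative_ratio)))
        for ui, uj in unknown_idx[neg_rng.choice(len(unknown_idx), size=n_neg, replace=False)]:
            rows.append((assoc.mirna_ids[ui], assoc.disease_ids[uj], float(scores[ui, uj]), False))
    auc = wins / total
    aupr = aupr_from_scores(pooled_pos, np.concatenate(pooled_neg))
    table = pd.DataFrame(rows, columns=["mirna", "disease", "score", "is_positive"])
    return CVResult(auc=auc, aupr=aupr, per_fold=per_fold, score_table=table)


def kfold_cv(
    assoc: AssociationMatrix,
    mf: LabeledMatrix | None = None,
    ds: LabeledMatrix | None = None,
    cfg: CVConfig | None = None,
    solver_cfg: SolverConfig | None = None,
) -> CVResult:
    """Seeded k-fold CV over known associations.

    Positives are shuffled and split into k near-equal folds; each fold's
    entries are zeroed in the training matrix, the completion re-solved and
    the fold scored against all unknown pairs.  The score table pools the
    held-out positive scores with a per-fold seeded 1:1 (``negative_ratio``)
    sample of unknown-pair scores for threshold metrics.
    """
    cfg = (cfg or CVConfig()).validate()
    solver_cfg = solver_cfg or SolverConfig()
    pos_idx = _positive_indices(assoc)
    if cfg.k > len(pos_idx):
        raise ValueError(f"k={cfg.k} exceeds the {len(pos_idx)} known associations")
    rng = np.random.default_rng(cfg.seed)
    order = rng.permutation(len(pos_idx))
    folds = np.array_split(order, cfg.k)
    unknown_idx = np.argwhere(assoc.values == 0.0)
    per_fold_auc: list[float] = []
    per_fold_aupr: list[float] = []
    rows = []
    for f, fold in enumerate(folds):
        if len(fold) == 0:
            raise ValueError(f"fold {f} is empty; reduce k")
        test_idx = pos_idx[fold]
        train = training_matrix(assoc, test_idx)
        scores = _fold_scores(train, mf, ds, None, None, cfg, solver_cfg)
        pos_scores = scores[test_idx[:, 0], test_idx[:, 1]]
        neg_scores = scores[unknown_idx[:, 0], unknown_idx[:, 1]]
        per_fold_auc.append(auc_from_scores(pos_scores, neg_scores))
        per_fold_aupr.append(aupr_from_scores(pos_scores, neg_scores))
        for (i, j), s in zip(test_idx, pos_scores):
            rows.append((assoc.mirna_ids[i], assoc.disease_ids[j], float(s), True))
        n_neg = int(round(cfg.negative_ratio * len(test_idx)))
        pick = rng.choice(len(unknown_idx), size=min(n_neg, len(unknown_idx)), replace=False)
        for i, j in unknown_idx[pick]:
            rows.append((assoc.mirna_ids[i], assoc.disease_ids[j], float(scores[i, j]), False))
    table = pd.DataFrame(rows, columns=["mirna", "disease", "score", "is_positive"])
    return CVResult(
        auc=float(np.mean(per_fold_auc)),
        aupr=float(np.mean(per_fold_aupr)),
        per_fold=per_fold_auc,
        score_table=table,
    )


# ---------------------------------------------------------------------------
# thresholded confusion metrics


def _confusion_metrics(scores: np.ndarray, labels: np.ndarray, tau: float) -> dict[str, float]:
    pred = scores >= tau
    tp = float(np.sum(pred & labels))
    fp = float(np.sum(pred & ~labels))
    fn = float(np.sum(~pred & labels))
    tn = float(np.sum(~pred & ~labels))
    acc = (tp + tn) / (tp + tn + fp + fn)
    prec = tp / (tp + fp) if tp + fp > 0 else 0.0
    rec = tp / (tp + fn) if tp + fn > 0 else 0.0
    f1 = 2 * prec * rec / (prec + rec) if prec + rec > 0 else 0.0
    denom = np.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = (tp * tn - fp * fn) / denom if denom > 0 else 0.0
    return {
        "threshold": tau,
        "accuracy": acc,
        "precision": prec,
        "recall": rec,
        "f1": f1,
        "mcc": float(mcc),
    }


def threshold_metrics(
    score_table: pd.DataFrame, thresholds: dict[str, float] | None = None
) -> pd.DataFrame:
    """Confusion metrics at thresholds T1/T2/T3 maximizing accuracy, F1, MCC.

    Without explicit thresholds each criterion is maximized exhaustively
    over the midpoints of consecutive sorted unique scores (plus sentinels
    below the minimum and above the maximum).
    """
    scores = score_table["score"].to_numpy(dtype=float)
    labels = score_table["is_positive"].to_numpy(dtype=bool)
    if labels.all() or (~labels).all():
        raise ValueError("score table must contain both classes")
    if thresholds is None:
        uniq = np.unique(scores)
        candidates = np.concatenate(
            [[uniq[0] - 1.0], (uniq[1:] + uniq[:-1]) / 2.0, [uniq[-1] + 1.0]]
        )
        best = {"T1": (-np.inf, None), "T2": (-np.inf, None), "T3": (-np.inf, None)}
        for tau in candidates:
            m = _confusion_metrics(scores, labels, tau)
            for key, crit in (("T1", "accuracy"), ("T2", "f1"), ("T3", "mcc")):
                if m[crit] > best[key][0]:
                    best[key] = (m[crit], tau)
        thresholds = {key: tau for key, (_, tau) in best.items()}
    out = pd.DataFrame(
        [_confusion_metrics(scores, labels, tau) for tau in thresholds.values()],
        index=list(thresholds.keys()),
    )
    return out


# ---------------------------------------------------------------------------
# sparsity sensitivity


def sparsity_experiment(
    assoc: AssociationMatrix,
    fractions: Sequence[float],
    mf: LabeledMatrix | None = None,
    ds: LabeledMatrix | None = None,
    cfg: CVConfig | None = None,
    solver_cfg: SolverConfig | None = None,
) -> pd.DataFrame:
    """CV performance as the known-association set is subsampled.

    For each fraction, that share of the known 1-entries is kept (seeded,
    without replacement) and the configured CV scheme re-run.  Fraction 1.0
    keeps every association and reproduces the plain CV result exactly.
    """
    cfg = (cfg or CVConfig()).validate()
    solver_cfg = solver_cfg or SolverConfig()
    for f in fractions:
        if not 0.0 < f <= 1.0:
            raise ValueError(f"fractions must lie in (0, 1], got {f}")
    pos_idx = _positive_indices(assoc)
    records = []
    for fi, f in enumerate(fractions):
        keep = int(round(f * len(pos_idx)))
        if keep < max(cfg.k, 2):
            raise ValueError(f"fraction {f} leaves only {keep} associations")
        sub_rng = np.random.default_rng([cfg.seed, fi])
        chosen = (
            np.arange(len(pos_idx))
            if keep == len(pos_idx)
            else sub_rng.choice(len(pos_idx), size=keep, replace=False)
        )
        sub = assoc.copy()
        sub.values[:] = 0.0
        kept = pos_idx[chosen]
        sub.values[kept[:, 0], kept[:, 1]] = 1.0
        if cfg.scheme == "kfold":
            res = kfold_cv(sub, mf, ds, cfg, solver_cfg)
        else:
            res = global_loocv(sub, mf, ds, cfg, solver_cfg)
        records.append((f, keep, res.auc, res.aupr))
    return pd.DataFrame(records, columns=["fraction", "n_associations", "auc", "aupr"])
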