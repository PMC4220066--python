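"""Principal component regression (PCR) for genomic prediction.

The regression ``y = 1*mu + T g + e`` treats the coefficients on PC scores
as *fixed* effects (ordinary least squares) — a deliberate contrast with
mixed-model prediction, which shrinks marker effects as random.  PCs enter
in a specified order, either by decreasing eigenvalue (genotype variance)
or by decreasing contribution to the regression sum of squares in the
reference set, and prediction accuracy can be scanned over the number of
included components.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_triangular

from .pca import PCDecomposition

logger = logging.getLogger(__name__)


@dataclass
class PCRanking:
    """An inclusion order over PCs.

    ``order`` is a permutation of ``0..k-1`` (0-based PC indices);
    ``ss_contributions`` holds the per-PC regression sum-of-squares
    contribution when ``criterion == "ss"``.
    """

    criterion: str
    order: np.ndarray
    ss_contributions: np.ndarray | None = None


def rank_eigen(decomposition: PCDecomposition) -> PCRanking:
    """Rank PCs by decreasing eigenvalue (SVD order; ties keep lower index)."""
    s = decomposition.singular_values
    order = np.lexsort((np.arange(len(s)), -s))
    return PCRanking(criterion="eigen", order=order)


def rank_ss(reference_scores: np.ndarray, phenotypes: np.ndarray) -> PCRanking:
    """Rank PCs by their contribution to the regression sum of squares.

    For mean-centred score column ``t_j`` and mean-centred phenotype ``y``,
    the contribution is ``(t_j'y)^2 / (t_j't_j)`` — the Type-I sum of
    squares of PC j regardless of entry order when score columns are
    mutually orthogonal (exactly true on the defining set of the
    decomposition).  Zero-variance columns contribute 0.
    """
    T = np.asarray(reference_scores, dtype=float)
    y = np.asarray(phenotypes, dtype=float)
    if T.shape[0] != y.shape[0]:
        raise ValueError("scores and phenotypes are not aligned")
    if T.shape[0] < 2:
        raise ValueError("need at least two animals")
    Tc = T - T.mean(axis=0, keepdims=True)
    yc = y - y.mean()
    tt = np.einsum("ij,ij->j", Tc, Tc)
    ty = Tc.T @ yc
    with np.errstate(divide="ignore", invalid="ignore"):
        contrib = np.where(tt > 0, ty**2 / np.where(tt > 0, tt, 1.0), 0.0)
    order = np.lexsort((np.arange(T.shape[1]), -contrib))
    return PCRanking(criterion="ss", order=order, ss_contributions=contrib)


@dataclass
class PCRModel:
    """Fixed-effect PCR fit: intercept plus coefficients on ranked PCs."""

    intercept: float
    coefficients: np.ndarray
    included_pc_indices: np.ndarray

    @property
    def k(self) -> int:
        return len(self.coefficients)


def fit_pcr(
    reference_scores: np.ndarray,
    phenotypes: np.ndarray,
    ranking: PCRanking,
    k: int,
) -> PCRModel:
    """OLS of y on intercept + the first k ranked score columns.

    ``k = 0`` is the null model (intercept = mean of y).  ``k = n - 1``
    (an interpolating fit, reached when the score matrix has full row rank)
    is allowed; ``k > n - 1`` is rank-deficient and rejected.
    """
    T = np.asarray(reference_scores, dtype=float)
    y = np.asarray(phenotypes, dtype=float)
    n = len(y)
    if not 0 <= k <= T.shape[1]:
        raise ValueError(f"k={k} outside 0..{T.shape[1]}")
    if k > n - 1:
        raise ValueError(f"k={k} exceeds the degrees of freedom (n={n})")
    idx = ranking.order[:k]
    if k == 0:
        return PCRModel(float(np.mean(y)), np.zeros(0), idx)
    M = np.column_stack([np.ones(n), T[:, idx]])
    beta, *_ = np.linalg.lstsq(M, y, rcond=None)
    return PCRModel(float(beta[0]), beta[1:], idx)


def predict_pcr(model: PCRModel, test_scores: np.ndarray) -> np.ndarray:
    """GEBV for test animals: ``mu + T_t[:, included] g``."""
    T = np.asarray(test_scores, dtype=float)
    if model.k == 0:
        return np.full(T.shape[0], model.intercept)
    if T.shape[1] <= model.included_pc_indices.max():
        raise ValueError("test scores have fewer PCs than the model uses")
    return model.intercept + T[:, model.included_pc_indices] @ model.coefficients


def prefix_predictions(
    reference_scores: np.ndarray,
    y_r: np.ndarray,
    test_scores: np.ndarray,
    order: np.ndarray,
    k_max: int,
) -> np.ndarray:
    """Test-set predictions of every prefix model k = 0..k_max, in one pass.

    Equivalent to refitting :func:`fit_pcr` at each k (QR of the ordered
    design; the span of the first k+1 Q columns equals the span of the
    intercept plus first k ranked PCs).  Returns an ``(n_test, k_max + 1)``
    array whose column k is the prediction with k PCs.
    """
    T_r = np.asarray(reference_scores, dtype=float)
    y = np.asarray(y_r, dtype=float)
    T_t = np.asarray(test_scores, dtype=float)
    idx = np.asarray(order[:k_max], dtype=int)
    M_r = np.column_stack([np.ones(T_r.shape[0]), T_r[:, idx]])
    M_t = np.column_stack([np.ones(T_t.shape[0]), T_t[:, idx]])
    Q, R = np.linalg.qr(M_r)
    c = Q.T @ y
    # coordinates of the test design in the Q basis: M_t R^{-1}
    Mq = solve_triangular(R, M_t.T, trans="T", lower=False).T
    return np.cumsum(Mq * c[None, :], axis=1)


def pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation; NaN when either vector has zero variance."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) != len(b):
        raise ValueError("length mismatch")
    if len(a) < 2 or np.std(a) == 0 or np.std(b) == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


@dataclass
class AccuracyTrajectory:
    """Per-k test-set accuracies for k = 0..k_max and their maximum."""

    accuracies: np.ndarray  # length k_max + 1; NaN where undefined
    best_k: int | None
    best_accuracy: float
    criterion: str
    test_label: str = ""

    @property
    def k_max(self) -> int:
        return len(self.accuracies) - 1


def accuracy_trajectory(
    reference_scores: np.ndarray,
    y_r: np.ndarray,
    test_scores: np.ndarray,
    y_t: np.ndarray,
    ranking: PCRanking,
    k_max: int | None = None,
    test_label: str = "",
) -> AccuracyTrajectory:
    """Scan Pearson accuracy in the test set over the number of included PCs.

    ``k = 0`` (constant prediction) is always recorded as missing.  The
    best k is the argmax over defined entries, smallest k on ties.
    """
    T_r = np.asarray(reference_scores, dtype=float)
    y_r = np.asarray(y_r, dtype=float)
    y_t = np.asarray(y_t, dtype=float)
    n_r = T_r.shape[0]
    limit = min(T_r.shape[1], n_r - 2)
    k_max = limit if k_max is None else min(int(k_max), limit)
    preds = prefix_predictions(T_r, y_r, test_scores, ranking.order, k_max)
    acc = np.array([pearson(preds[:, k], y_t) for k in range(k_max + 1)])
    if np.isnan(acc).all():
        best_k, best = None, float("nan")
    else:
        best_k = int(np.nanargmax(acc))
        best = float(acc[best_k])
    return AccuracyTrajectory(acc, best_k, best, ranking.criterion, test_label)
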