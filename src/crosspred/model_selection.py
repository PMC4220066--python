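"""Cross-validation selection of the number of PCs in PCR.

Within the reference set, PCs are added one by one and the number retained
is the one minimising the pooled mean squared prediction error over
held-out folds.  Two schemes are supported: a seeded random 5-fold split
and a stratified split with one fold per population.  For the plain PCR
mode the decomposition (and ranking) is recomputed from each training fold
and held-out animals are only projected — exactly mirroring, at CV level,
what reference-to-test prediction does.  For the semi-supervised mode the
held-out fold's *genotypes* join the decomposition while its phenotypes
remain unseen.

The fold decompositions depend only on genotypes, so they are computed
once (:func:`decompose_folds`) and reused across traits and ranking
criteria (:func:`cv_mse_curve_from_folds`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold

from . import pca, pcr
from .qc import GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class CVScheme:
    """Fold-making recipe: ``random_kfold`` (default 5 folds) or ``stratified``."""

    kind: str = "random_kfold"
    n_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("random_kfold", "stratified"):
            raise ValueError(f"unknown CV scheme {self.kind!r}")
        if self.n_folds < 2:
            raise ValueError("need at least two folds")


def make_folds(reference_ids, scheme: CVScheme, labels=None) -> pd.Series:
    """Deterministic fold assignment, one fold id per reference animal.

    Random folds partition the set with sizes differing by at most one;
    stratified folds are the distinct population labels.
    """
    ids = [str(i) for i in reference_ids]
    if scheme.kind == "random_kfold":
        if len(ids) < scheme.n_folds:
            raise ValueError("fewer animals than folds")
        assignment = pd.Series(index=ids, dtype=object)
        kf = KFold(n_splits=scheme.n_folds, shuffle=True, random_state=scheme.seed)
        for fold, (_, held) in enumerate(kf.split(np.zeros(len(ids)))):
            assignment.iloc[held] = f"fold{fold}"
        return assignment
    if labels is None:
        raise ValueError("stratified CV needs population labels")
    labels = [str(x) for x in labels]
    if len(labels) != len(ids):
        raise ValueError("labels must cover the reference set")
    if len(set(labels)) < 2:
        raise ValueError("stratified CV needs at least two distinct labels")
    return pd.Series(labels, index=ids)


@dataclass
class FoldScores:
    """Genotype-only part of one CV fold: scores for train and held-out sets."""

    name: str
    train_ids: list[str]
    held_ids: list[str]
    T_train: np.ndarray
    T_held: np.ndarray
    k_limit: int  # min(rank, n_train - 2)


def decompose_folds(
    genotypes: GenotypeMatrix,
    folds: pd.Series,
    mode: str = "pcr",
    scale: bool = False,
) -> list[FoldScores]:
    """Per-fold PC scores under the given mode.

    ``pcr``: decomposition from the training fold only, held-out animals
    projected (no leakage).  ``sspcr``: joint decomposition over training
    plus held-out genotypes.
    """
    if mode not in ("pcr", "sspcr"):
        raise ValueError(f"unknown mode {mode!r}")
    ref_ids = [str(i) for i in folds.index]
    out = []
    for fold in pd.unique(folds.to_numpy()):
        held = [i for i in ref_ids if folds[i] == fold]
        train = [i for i in ref_ids if folds[i] != fold]
        sub = genotypes.subset(sample_ids=train + held)
        if mode == "pcr":
            decomp, T_train, T_held = pca.reference_decomposition(
                sub, train, held, scale=scale
            )
        else:
            decomp, T_train, T_held = pca.semi_supervised_decompose(
                sub, train, held, scale=scale
            )
        out.append(
            FoldScores(
                name=str(fold), train_ids=train, held_ids=held,
                T_train=T_train, T_held=T_held,
                k_limit=min(decomp.k, len(train) - 2),
            )
        )
    return out


@dataclass
class CVResult:
    """Pooled MSE per k, the selected k, and per-fold predictions."""

    mse_curve: np.ndarray
    selected_k: int
    scheme: CVScheme
    criterion: str
    mode: str
    fold_predictions: dict[str, pd.DataFrame] = field(default_factory=dict)
    accuracy_curve: np.ndarray | None = None


def select_k(cv_result: CVResult, target: str = "mse") -> int:
    """Argmin of the MSE curve (default) or argmax of the accuracy curve.

    Ties are resolved toward the smallest k.  ``target="accuracy"`` is an
    optional alternative objective; minimum MSE is the standard one.
    """
    if target == "mse":
        return int(np.argmin(cv_result.mse_curve))
    if target == "accuracy":
        acc = cv_result.accuracy_curve
        if acc is None or np.isnan(acc).all():
            return 0
        return int(np.nanargmax(acc))
    raise ValueError(f"unknown selection target {target!r}")


def cv_mse_curve_from_folds(
    fold_scores: list[FoldScores],
    y_r: pd.Series,
    criterion: str,
    mode: str,
    k_max: int | None = None,
    scheme: CVScheme | None = None,
) -> CVResult:
    """MSE over held-out folds for prefix models k = 0..k_max.

    Per fold: rank the training-fold PCs (``eigen``: decreasing eigenvalue,
    i.e. natural SVD order; ``ss``: decreasing regression sum-of-squares
    contribution against the training phenotypes), fit every prefix model
    on the training fold and predict the held-out animals.  Squared errors
    are pooled over all held-out predictions (micro-average); the curve is
    truncated to the largest k feasible in every fold.  k = 0 (the null,
    intercept-only model) is always included.
    """
    if criterion not in ("eigen", "ss"):
        raise ValueError(f"unknown ranking criterion {criterion!r}")
    y_r = y_r.astype(float)
    k_common = min(fs.k_limit for fs in fold_scores)
    if k_max is not None:
        k_common = min(k_common, int(k_max))
    per_fold: dict[str, pd.DataFrame] = {}
    preds_list, y_list = [], []
    for fs in fold_scores:
        y_train = y_r.loc[fs.train_ids].to_numpy()
        if criterion == "eigen":
            ranking = pcr.PCRanking("eigen", np.arange(fs.T_train.shape[1]))
        else:
            if np.std(y_train) == 0:
                raise ValueError(
                    f"constant phenotype in training fold {fs.name!r}: "
                    "ss ranking undefined"
                )
            ranking = pcr.rank_ss(fs.T_train, y_train)
        preds = pcr.prefix_predictions(
            fs.T_train, y_train, fs.T_held, ranking.order, k_common
        )
        per_fold[fs.name] = pd.DataFrame(
            preds, index=fs.held_ids,
            columns=[f"k{k}" for k in range(k_common + 1)],
        )
        preds_list.append(preds)
        y_list.append(y_r.loc[fs.held_ids].to_numpy())
    all_preds = np.vstack(preds_list)
    all_y = np.concatenate(y_list)
    mse = ((all_preds - all_y[:, None]) ** 2).mean(axis=0)
    acc = np.array(
        [pcr.pearson(all_preds[:, k], all_y) for k in range(k_common + 1)]
    )
    result = CVResult(
        mse_curve=mse,
        selected_k=0,
        scheme=scheme if scheme is not None else CVScheme(),
        criterion=criterion,
        mode=mode,
        fold_predictions=per_fold,
        accuracy_curve=acc,
    )
    result.selected_k = select_k(result)
    return result


def cv_mse_curve(
    genotypes: GenotypeMatrix,
    reference_ids,
    y_r: pd.Series,
    criterion: str,
    folds: pd.Series,
    mode: str = "pcr",
    k_max: int | None = None,
    scale: bool = False,
    scheme: CVScheme | None = None,
) -> CVResult:
    """Convenience wrapper: decompose folds then compute the MSE curve."""
    ref_ids = [str(i) for i in reference_ids]
    fold_scores = decompose_folds(
        genotypes.subset(sample_ids=ref_ids), folds, mode=mode, scale=scale
    )
    return cv_mse_curve_from_folds(
        fold_scores, y_r, criterion, mode, k_max=k_max, scheme=scheme
    )
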