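"""Centering/scaling and SVD-based principal component analysis of genotypes.

Two flavours are used in across-population prediction:

* reference-only PCA — loadings V come from the reference animals alone and
  test animals are projected onto them (``T_t = X_t V``);
* semi-supervised PCA — a single decomposition over reference AND test
  genotypes, whose score matrix is split by membership afterwards.  Only
  genotypes of the test animals enter; their phenotypes never do.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .qc import GenotypeMatrix

logger = logging.getLogger(__name__)

#: singular values below RANK_RTOL * largest are treated as numerically zero
RANK_RTOL = 1e-10


@dataclass
class CenteredGenotypes:
    """Real-valued genotype matrix after centering (and optional scaling).

    ``column_centers``/``column_scales`` are defined over ``defining_ids``
    (the animal set whose statistics were used), which need not coincide
    with the rows present in ``matrix``.
    """

    matrix: np.ndarray
    sample_ids: list[str]
    snp_ids: list[str]
    column_centers: np.ndarray
    column_scales: np.ndarray | None
    defining_ids: list[str]

    def rows(self, ids) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        return self.matrix[[lookup[str(i)] for i in ids]]


def center_scale(
    genotypes: GenotypeMatrix,
    defining_ids=None,
    scale: bool = False,
) -> CenteredGenotypes:
    """Center (and optionally scale) all rows using defining-set statistics.

    Centers are the column means over ``defining_ids`` (default: all
    samples).  With ``scale=True`` columns are divided by the defining-set
    SD; zero-SD columns are dropped with a warning.  Missing values must be
    imputed beforehand.
    """
    X = genotypes.values
    if np.isnan(X).any():
        raise ValueError("missing genotypes: impute before PCA")
    if defining_ids is None:
        defining_ids = list(genotypes.sample_ids)
    rows = genotypes.sample_index(defining_ids)
    if len(rows) == 0:
        raise ValueError("defining set is empty")
    centers = X[rows].mean(axis=0)
    out = X - centers[None, :]
    snp_ids = list(genotypes.snp_ids)
    scales = None
    if scale:
        sd = X[rows].std(axis=0)
        keep = sd > 0
        if not keep.all():
            logger.warning("dropping %d constant columns under scaling",
                           int((~keep).sum()))
        out = out[:, keep] / sd[None, keep]
        centers = centers[keep]
        scales = sd[keep]
        snp_ids = [s for s, k in zip(snp_ids, keep) if k]
    return CenteredGenotypes(
        matrix=out,
        sample_ids=list(genotypes.sample_ids),
        snp_ids=snp_ids,
        column_centers=centers,
        column_scales=scales,
        defining_ids=[str(i) for i in defining_ids],
    )


@dataclass
class PCDecomposition:
    """Thin SVD of a centered genotype matrix: X = U diag(s) V'.

    ``scores = U diag(s) = X V`` are the PC scores of the animals the
    decomposition was computed on; ``variance_proportions`` are
    ``s_j^2 / sum(s^2)``.  Columns of V carry a deterministic sign
    convention: the entry of largest magnitude in each loading is positive.
    """

    loadings: np.ndarray       # p x k
    singular_values: np.ndarray
    scores: np.ndarray         # n x k
    variance_proportions: np.ndarray
    sample_ids: list[str]
    snp_ids: list[str]
    rank: int
    provenance: dict = field(default_factory=dict)

    @property
    def k(self) -> int:
        return len(self.singular_values)

    def scores_frame(self) -> pd.DataFrame:
        cols = [f"PC{j + 1}" for j in range(self.k)]
        return pd.DataFrame(self.scores, index=self.sample_ids, columns=cols)


def _fix_signs(U: np.ndarray, V: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # sign convention: largest-magnitude loading entry positive per column
    if V.shape[1] == 0:
        return U, V
    anchor = np.abs(V).argmax(axis=0)
    signs = np.sign(V[anchor, np.arange(V.shape[1])])
    signs[signs == 0] = 1.0
    return U * signs[None, :], V * signs[None, :]


def svd_decompose(centered: CenteredGenotypes, provenance: str = "reference") -> PCDecomposition:
    """Thin SVD with numerical-rank truncation and fixed sign convention."""
    X = centered.matrix
    if X.shape[0] < 2:
        raise ValueError("need at least two animals for PCA")
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    if s.size and s[0] > 0:
        keep = s > RANK_RTOL * s[0]
    else:
        keep = np.zeros(s.shape, dtype=bool)
    U, s, V = U[:, keep], s[keep], Vt[keep].T
    U, V = _fix_signs(U, V)
    total = float(np.sum(s**2))
    props = s**2 / total if total > 0 else np.zeros_like(s)
    return PCDecomposition(
        loadings=V,
        singular_values=s,
        scores=U * s[None, :],
        variance_proportions=props,
        sample_ids=list(centered.sample_ids),
        snp_ids=list(centered.snp_ids),
        rank=int(keep.sum()),
        provenance={
            "mode": provenance,
            "defining_ids_n": len(centered.defining_ids),
            "scaled": centered.column_scales is not None,
        },
    )


def project(decomposition: PCDecomposition, centered_other: np.ndarray) -> np.ndarray:
    """Project rows (centered with the DEFINING set's centers) onto V."""
    other = np.asarray(centered_other, dtype=float)
    if other.ndim != 2 or other.shape[1] != decomposition.loadings.shape[0]:
        raise ValueError(
            f"expected {decomposition.loadings.shape[0]} columns, "
            f"got {other.shape}"
        )
    return other @ decomposition.loadings


def reference_decomposition(
    genotypes: GenotypeMatrix,
    reference_ids,
    test_ids,
    scale: bool = False,
) -> tuple[PCDecomposition, np.ndarray, np.ndarray]:
    """Reference-only PCA plus projected test scores (T_r, T_t)."""
    centered = center_scale(genotypes, defining_ids=reference_ids, scale=scale)
    ref_rows = centered.rows(reference_ids)
    ref_centered = CenteredGenotypes(
        matrix=ref_rows,
        sample_ids=[str(i) for i in reference_ids],
        snp_ids=centered.snp_ids,
        column_centers=centered.column_centers,
        column_scales=centered.column_scales,
        defining_ids=centered.defining_ids,
    )
    decomp = svd_decompose(ref_centered, provenance="reference")
    T_t = project(decomp, centered.rows(test_ids))
    return decomp, decomp.scores, T_t


def semi_supervised_decompose(
    genotypes: GenotypeMatrix,
    reference_ids,
    test_ids,
    scale: bool = False,
) -> tuple[PCDecomposition, np.ndarray, np.ndarray]:
    """Joint PCA over reference and test animals; scores split by membership.

    Centering uses ALL animals.  Returns ``(decomposition, T_r, T_t)`` with
    score rows ordered as in ``reference_ids`` / ``test_ids``.
    """
    ref = [str(i) for i in reference_ids]
    tst = [str(i) for i in test_ids]
    if set(ref) & set(tst):
        raise ValueError("reference and test sets overlap")
    if set(ref) | set(tst) != set(genotypes.sample_ids):
        raise ValueError("reference + test must cover all animals")
    centered = center_scale(genotypes, defining_ids=None, scale=scale)
    decomp = svd_decompose(centered, provenance="semi-supervised")
    frame = decomp.scores_frame()
    T_r = frame.loc[ref].to_numpy()
    T_t = frame.loc[tst].to_numpy()
    decomp.provenance.update({"reference_n": len(ref), "test_n": len(tst)})
    return decomp, T_r, T_t


def cumulative_variance(decomposition: PCDecomposition, checkpoints=None) -> pd.DataFrame:
    """Cumulative proportion of genotype variance captured by leading PCs."""
    cum = np.cumsum(decomposition.variance_proportions)
    if checkpoints is None:
        checkpoints = range(1, decomposition.k + 1)
    rows = []
    for c in checkpoints:
        c = int(c)
        if c < 1:
            raise ValueError("checkpoints must be >= 1")
        idx = min(c, decomposition.k) - 1
        rows.append({"n_pcs": c, "cumulative_proportion": float(cum[idx]) if decomposition.k else 0.0})
    return pd.DataFrame(rows)


def save_decomposition(decomposition: PCDecomposition, out_dir) -> None:
    """Persist a decomposition as CSV matrices plus JSON metadata."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cols = [f"PC{j + 1}" for j in range(decomposition.k)]
    pd.DataFrame(decomposition.loadings, index=decomposition.snp_ids,
                 columns=cols).to_csv(out / "loadings.csv")
    decomposition.scores_frame().to_csv(out / "scores.csv")
    pd.DataFrame({"singular_value": decomposition.singular_values,
                  "variance_proportion": decomposition.variance_proportions},
                 index=cols).to_csv(out / "singular_values.csv")
    meta = dict(decomposition.provenance)
    meta.update({"rank": decomposition.rank, "rank_rtol": RANK_RTOL,
                 "sign_convention": "largest-magnitude loading entry positive"})
    (out / "metadata.json").write_text(json.dumps(meta, indent=2))
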