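"""Pedigree and genomic relationship matrices.

Builds the numerator relationship matrix A by the tabular recursion, the
VanRaden genomic relationship matrix G_VR = ZZ'/(2*sum p_i(1-p_i)) with Z
the allele-frequency-centred genotype matrix, and the blended matrix
G = b*G_VR + (1-b)*A that regresses marker-derived relationships back
towards their pedigree expectation to attenuate marker-sampling noise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .qc import GenotypeMatrix, allele_frequency

logger = logging.getLogger(__name__)


class PedigreeError(ValueError):
    """Cyclic pedigree or reference to an unknown parent."""


UNKNOWN = {None, "", "0", "NA", "nan", "None"}


@dataclass
class PedigreeTable:
    """Records of (animal_id, sire_id, dam_id), topologically orderable.

    Unknown parents are stored as ``None``.  Extra columns (population,
    generation) are preserved in :attr:`frame`.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame.copy()
        for col in ("animal_id", "sire_id", "dam_id"):
            if col not in df.columns:
                raise PedigreeError(f"pedigree table missing column {col!r}")
            df[col] = df[col].astype(object).where(df[col].notna(), None)
            df[col] = [None if str(v) in UNKNOWN or v is None else str(v)
                       for v in df[col]]
        if df["animal_id"].duplicated().any():
            raise PedigreeError("duplicate animal ids in pedigree")
        self.frame = df.reset_index(drop=True)
        self._validate_and_sort()

    def _validate_and_sort(self) -> None:
        ids = set(self.frame["animal_id"])
        for col in ("sire_id", "dam_id"):
            for v in self.frame[col]:
                if v is not None and v not in ids:
                    raise PedigreeError(f"unknown parent id {v!r}")
        # Kahn topological sort; detects cycles.
        children: dict[str, list[str]] = {a: [] for a in ids}
        indeg = {a: 0 for a in ids}
        for _, row in self.frame.iterrows():
            for par in (row["sire_id"], row["dam_id"]):
                if par is not None:
                    children[par].append(row["animal_id"])
                    indeg[row["animal_id"]] += 1
        order, queue = [], [a for a in self.frame["animal_id"] if indeg[a] == 0]
        while queue:
            a = queue.pop(0)
            order.append(a)
            for c in children[a]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    queue.append(c)
        if len(order) != len(ids):
            raise PedigreeError("cycle detected in pedigree")
        rank = {a: i for i, a in enumerate(order)}
        self.frame = (
            self.frame.assign(_rank=[rank[a] for a in self.frame["animal_id"]])
            .sort_values("_rank", kind="stable")
            .drop(columns="_rank")
            .reset_index(drop=True)
        )

    @property
    def animal_ids(self) -> list[str]:
        return list(self.frame["animal_id"])

    @classmethod
    def from_csv(cls, path) -> "PedigreeTable":
        return cls(pd.read_csv(path, dtype=str))

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False, na_rep="")


def compute_A(pedigree: PedigreeTable, subset=None) -> pd.DataFrame:
    """Numerator relationship matrix by the tabular recursion.

    ``A[i,i] = 1 + 0.5*A[sire, dam]``; ``A[i,j]`` is the mean of ``A`` between
    j and i's known parents, unknown parents contributing 0.  Optionally
    restricted to ``subset`` ids (rows/columns) after the full recursion.
    """
    ids = pedigree.animal_ids
    idx = {a: i for i, a in enumerate(ids)}
    n = len(ids)
    A = np.zeros((n, n))
    sires = [idx.get(s) if s is not None else None for s in pedigree.frame["sire_id"]]
    dams = [idx.get(d) if d is not None else None for d in pedigree.frame["dam_id"]]
    for i in range(n):
        s, d = sires[i], dams[i]
        # relationship with all previously processed animals
        if s is not None and d is not None:
            rel = 0.5 * (A[s, :i] + A[d, :i])
            diag = 1.0 + 0.5 * A[s, d]
        elif s is not None:
            rel = 0.5 * A[s, :i]
            diag = 1.0
        elif d is not None:
            rel = 0.5 * A[d, :i]
            diag = 1.0
        else:
            rel = np.zeros(i)
            diag = 1.0
        A[i, :i] = rel
        A[:i, i] = rel
        A[i, i] = diag
    out = pd.DataFrame(A, index=ids, columns=ids)
    if subset is not None:
        subset = [str(s) for s in subset]
        out = out.loc[subset, subset]
    return out


def compute_G_vr(genotypes: GenotypeMatrix) -> tuple[pd.DataFrame, pd.Series]:
    """VanRaden (method 1) genomic relationship matrix.

    Allele frequencies ``p_i`` are taken across all genotyped animals in the
    input; ``Z = X - 2 p_i`` columnwise and ``G = ZZ' / (2 sum p_i(1-p_i))``.
    Requires a complete (imputed) matrix with at least one polymorphic SNP.
    """
    X = genotypes.values
    if np.isnan(X).any():
        raise ValueError("missing genotypes: impute before building G")
    p = allele_frequency(X)
    denom = 2.0 * np.sum(p * (1.0 - p))
    if denom <= 0:
        raise ValueError("all SNPs monomorphic: VanRaden denominator is zero")
    Z = X - 2.0 * p[None, :]
    G = (Z @ Z.T) / denom
    ids = genotypes.sample_ids
    return (
        pd.DataFrame(G, index=ids, columns=ids),
        pd.Series(p, index=genotypes.snp_ids, name="allele_freq"),
    )


@dataclass
class BlendEstimate:
    """Per-bin attenuation coefficients and their pooled scalar summary."""

    per_bin: pd.DataFrame  # columns: a_low, a_high, n_pairs, b
    scalar: float


def estimate_blend_b(G_vr: pd.DataFrame, A: pd.DataFrame, n_bins: int = 5) -> BlendEstimate:
    """Estimate the blending coefficient b per bin of pedigree relationships.

    Off-diagonal (i<j) pairs are binned on their A value; within each bin the
    attenuation ``b = 1 - var(G - A) / var(G)`` estimates the fraction of the
    variation in G that is signal rather than marker-sampling noise.  Bins
    with fewer than two pairs are merged with their neighbour.  Values are
    clipped to [0, 1]; the scalar summary pools bins weighted by pair count.
    """
    if G_vr.shape != A.shape:
        raise ValueError("G and A dimensions differ")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    A = A.loc[G_vr.index, G_vr.columns]
    iu = np.triu_indices(len(G_vr), k=1)
    a = A.to_numpy()[iu]
    g = G_vr.to_numpy()[iu]
    edges = np.unique(np.quantile(a, np.linspace(0, 1, n_bins + 1)))
    if len(edges) < 2:
        edges = np.array([a.min() - 1e-12, a.max() + 1e-12])
    groups = np.clip(np.searchsorted(edges, a, side="right") - 1, 0, len(edges) - 2)
    bins: list[np.ndarray] = [np.flatnonzero(groups == k) for k in range(len(edges) - 1)]
    lows, highs = list(edges[:-1]), list(edges[1:])
    # merge undersized bins with their left (or right) neighbour
    k = 0
    while k < len(bins):
        if len(bins[k]) < 2 and len(bins) > 1:
            j = k - 1 if k > 0 else k + 1
            logger.warning("merging relationship bin %d (<2 pairs) into neighbour", k)
            bins[j] = np.concatenate([bins[j], bins[k]])
            lows[j] = min(lows[j], lows[k])
            highs[j] = max(highs[j], highs[k])
            del bins[k], lows[k], highs[k]
        else:
            k += 1
    rows = []
    for lo, hi, members in zip(lows, highs, bins):
        gg, aa = g[members], a[members]
        var_g = float(np.var(gg))
        var_noise = float(np.var(gg - aa))
        if var_g < 1e-30:
            b = 1.0 if var_noise < 1e-30 else 0.0
        else:
            b = 1.0 - var_noise / var_g
        rows.append(
            {"a_low": lo, "a_high": hi, "n_pairs": len(members),
             "b": float(np.clip(b, 0.0, 1.0))}
        )
    per_bin = pd.DataFrame(rows)
    weights = per_bin["n_pairs"].to_numpy(dtype=float)
    scalar = float(np.average(per_bin["b"], weights=weights))
    return BlendEstimate(per_bin=per_bin, scalar=scalar)


def blend_G(G_vr: pd.DataFrame, A: pd.DataFrame, b: float) -> pd.DataFrame:
    """Affine blend ``G = b*G_VR + (1-b)*A`` with b in [0, 1]."""
    if not 0.0 <= b <= 1.0:
        raise ValueError("blend coefficient must be in [0, 1]")
    if G_vr.shape != A.shape:
        raise ValueError("G and A dimensions differ")
    A = A.loc[G_vr.index, G_vr.columns]
    return b * G_vr + (1.0 - b) * A


@dataclass
class RelationshipSet:
    """A, G_VR and the blended G, with the blend estimate and allele freqs."""

    A: pd.DataFrame
    G_vr: pd.DataFrame
    G: pd.DataFrame
    blend: BlendEstimate | None
    allele_freqs: pd.Series


def build_relationships(
    genotypes: GenotypeMatrix,
    pedigree: PedigreeTable | None,
    n_bins: int = 5,
    fixed_b: float | None = None,
) -> RelationshipSet:
    """Convenience wrapper: G_VR, A (identity if no pedigree), blended G.

    ``fixed_b`` overrides the estimated scalar; ``fixed_b=1`` disables
    blending entirely.
    """
    G_vr, freqs = compute_G_vr(genotypes)
    if pedigree is not None:
        A = compute_A(pedigree, subset=genotypes.sample_ids)
    else:
        A = pd.DataFrame(
            np.eye(genotypes.n_samples),
            index=genotypes.sample_ids,
            columns=genotypes.sample_ids,
        )
    blend = None
    if fixed_b is None:
        blend = estimate_blend_b(G_vr, A, n_bins=n_bins)
        b = blend.scalar
    else:
        b = fixed_b
    return RelationshipSet(A=A, G_vr=G_vr, G=blend_G(G_vr, A, b), blend=blend,
                           allele_freqs=freqs)


def relationship_summary(matrix: pd.DataFrame, population_labels) -> pd.DataFrame:
    """Within/between-population averages and SDs of off-diagonal relationships.

    "Within" pools pairs with both animals in the population; "between" pools
    pairs linking the population to any other.  A population of size 1 has no
    within pairs and is reported as ``NaN`` there.
    """
    labels = np.asarray([str(x) for x in population_labels])
    if len(labels) != len(matrix):
        raise ValueError("labels must cover all animals")
    M = matrix.to_numpy()
    rows = []
    for pop in pd.unique(labels):
        inside = np.flatnonzero(labels == pop)
        outside = np.flatnonzero(labels != pop)
        if len(inside) > 1:
            iu = np.triu_indices(len(inside), k=1)
            within = M[np.ix_(inside, inside)][iu]
            w_av, w_sd = float(np.mean(within)), float(np.std(within))
        else:
            w_av = w_sd = np.nan
        if len(outside):
            between = M[np.ix_(inside, outside)].ravel()
            b_av, b_sd = float(np.mean(between)), float(np.std(between))
        else:
            b_av = b_sd = np.nan
        rows.append({"population": pop, "scope": "within", "mean": w_av, "sd": w_sd})
        rows.append({"population": pop, "scope": "between", "mean": b_av, "sd": b_sd})
    return pd.DataFrame(rows)
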