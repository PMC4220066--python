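"""Genotype containers, file IO and SNP quality control.

Genotypes are additively coded: 0 and 2 for the two homozygotes, 1 for the
heterozygote, ``NaN`` for a missing call.  The QC filters mirror a standard
50k-chip editing pipeline for multi-population cattle data: per-SNP call
rate, per-population minor allele frequency, and a (deliberately permissive)
Hardy-Weinberg chi-square cut-off applied to the pooled data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: QC thresholds used throughout: call rate > 0.95, per-population MAF > 0.01,
#: pooled HWE chi-square < 600.
DEFAULT_CALL_RATE = 0.95
DEFAULT_MAF = 0.01
DEFAULT_HWE_CHISQ = 600.0


class ParseError(ValueError):
    """Malformed genotype file (message carries the offending line number)."""


class QCError(ValueError):
    """Raised when a QC step cannot produce a usable result."""


# ---------------------------------------------------------------------------
# Genotype container
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """n x p additive genotype matrix with sample/SNP metadata.

    Parameters
    ----------
    values
        Float array of shape ``(n_samples, n_snps)`` with entries in
        ``{0, 1, 2, NaN}``.
    sample_ids, snp_ids
        Unique identifiers for rows and columns.
    population_labels
        One population (country / selection line) label per sample.
    imputed
        True once missing calls have been replaced by per-SNP means, after
        which entries are real-valued rather than 0/1/2 codes.
    """

    values: np.ndarray
    sample_ids: list[str]
    snp_ids: list[str]
    population_labels: list[str]
    imputed: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.snp_ids = [str(s) for s in self.snp_ids]
        self.population_labels = [str(s) for s in self.population_labels]
        n, p = self.values.shape
        if len(self.sample_ids) != n:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {n} rows")
        if len(self.snp_ids) != p:
            raise ValueError(f"{len(self.snp_ids)} SNP ids for {p} columns")
        if len(self.population_labels) != n:
            raise ValueError("one population label required per sample")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample ids")
        if len(set(self.snp_ids)) != p:
            raise ValueError("duplicate SNP ids")
        if not self.imputed:
            obs = self.values[~np.isnan(self.values)]
            if obs.size and not np.isin(obs, (0.0, 1.0, 2.0)).all():
                bad = obs[~np.isin(obs, (0.0, 1.0, 2.0))][0]
                raise ValueError(f"genotype codes must be 0/1/2/NaN, found {bad!r}")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_snps(self) -> int:
        return self.values.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    def sample_index(self, ids) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            return np.array([lookup[str(i)] for i in ids], dtype=int)
        except KeyError as exc:  # pragma: no cover - defensive
            raise KeyError(f"unknown sample id {exc.args[0]!r}") from None

    def subset(self, sample_ids=None, snp_ids=None) -> "GenotypeMatrix":
        """Return a copy restricted to the given samples and/or SNPs."""
        rows = (
            self.sample_index(sample_ids)
            if sample_ids is not None
            else np.arange(self.n_samples)
        )
        if snp_ids is not None:
            col_lookup = {s: j for j, s in enumerate(self.snp_ids)}
            cols = np.array([col_lookup[str(s)] for s in snp_ids], dtype=int)
        else:
            cols = np.arange(self.n_snps)
        return GenotypeMatrix(
            self.values[np.ix_(rows, cols)].copy(),
            [self.sample_ids[i] for i in rows],
            [self.snp_ids[j] for j in cols],
            [self.population_labels[i] for i in rows],
            imputed=self.imputed,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.sample_ids, columns=self.snp_ids
        )


# ---------------------------------------------------------------------------
# File formats: additive matrix text and PLINK .ped/.map
# ---------------------------------------------------------------------------

_ALLELE_PAIRS = {0.0: ("A", "A"), 1.0: ("A", "B"), 2.0: ("B", "B")}


def write_genotypes(genotypes: GenotypeMatrix, path, fmt: str = "matrix") -> None:
    """Write genotypes as additive matrix text (``matrix``) or PLINK ``ped``.

    For ``ped`` the path is a prefix: ``<prefix>.ped`` and ``<prefix>.map``
    are produced, with the population label stored as the family id.
    """
    path = Path(path)
    if fmt == "matrix":
        df = genotypes.to_frame()
        df.insert(0, "population", genotypes.population_labels)
        df.index.name = "animal_id"
        df.to_csv(path, sep="\t", na_rep="NA", float_format="%.0f")
    elif fmt == "ped":
        with open(path.with_suffix(".ped"), "w") as fh:
            for i, sid in enumerate(genotypes.sample_ids):
                fields = [genotypes.population_labels[i], sid, "0", "0", "0", "-9"]
                for g in genotypes.values[i]:
                    a, b = ("0", "0") if np.isnan(g) else _ALLELE_PAIRS[g]
                    fields += [a, b]
                fh.write(" ".join(fields) + "\n")
        with open(path.with_suffix(".map"), "w") as fh:
            for j, snp in enumerate(genotypes.snp_ids):
                fh.write(f"1 {snp} 0 {j + 1}\n")
    else:
        raise ValueError(f"unknown genotype format {fmt!r}")


def _parse_matrix(path: Path) -> GenotypeMatrix:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 3 or header[1] != "population":
            raise ParseError(f"{path}:1: expected 'animal_id<TAB>population<TAB>snp...' header")
        snp_ids = header[2:]
        samples, pops, rows = [], [], []
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(header):
                raise ParseError(
                    f"{path}:{lineno}: expected {len(header)} columns, found {len(parts)}"
                )
            samples.append(parts[0])
            pops.append(parts[1])
            row = np.empty(len(snp_ids))
            for j, tok in enumerate(parts[2:]):
                if tok in ("NA", "nan", ""):
                    row[j] = np.nan
                elif tok in ("0", "1", "2"):
                    row[j] = float(tok)
                else:
                    raise ParseError(
                        f"{path}:{lineno}: invalid genotype code {tok!r}"
                    )
            rows.append(row)
    return GenotypeMatrix(np.array(rows), samples, snp_ids, pops)


def _parse_ped(prefix: Path) -> GenotypeMatrix:
    map_path = prefix.with_suffix(".map")
    snp_ids = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if len(parts) != 4:
                raise ParseError(f"{map_path}:{lineno}: expected 4 columns")
            snp_ids.append(parts[1])
    pair_to_code = {("A", "A"): 0.0, ("A", "B"): 1.0, ("B", "A"): 1.0,
                    ("B", "B"): 2.0, ("0", "0"): np.nan}
    samples, pops, rows = [], [], []
    ped_path = prefix.with_suffix(".ped")
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if len(parts) != 6 + 2 * len(snp_ids):
                raise ParseError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * len(snp_ids)} fields, "
                    f"found {len(parts)}"
                )
            pops.append(parts[0])
            samples.append(parts[1])
            alleles = parts[6:]
            row = np.empty(len(snp_ids))
            for j in range(len(snp_ids)):
                pair = (alleles[2 * j], alleles[2 * j + 1])
                if pair not in pair_to_code:
                    raise ParseError(
                        f"{ped_path}:{lineno}: unknown allele pair {pair!r} at SNP {j + 1}"
                    )
                row[j] = pair_to_code[pair]
            rows.append(row)
    return GenotypeMatrix(np.array(rows), samples, snp_ids, pops)


def read_genotypes(path, fmt: str = "matrix") -> GenotypeMatrix:
    """Read genotypes from ``matrix`` text or a PLINK ``ped``/``map`` prefix."""
    path = Path(path)
    if fmt == "matrix":
        return _parse_matrix(path)
    if fmt == "ped":
        return _parse_ped(path)
    raise ValueError(f"unknown genotype format {fmt!r}")


# ---------------------------------------------------------------------------
# Per-SNP statistics
# ---------------------------------------------------------------------------

def call_rate(genotypes: GenotypeMatrix) -> np.ndarray:
    """Fraction of non-missing calls per SNP, in [0, 1]."""
    return 1.0 - np.isnan(genotypes.values).mean(axis=0)


def allele_frequency(values: np.ndarray) -> np.ndarray:
    """Frequency of the allele coded 2, per column, from non-missing calls."""
    with np.errstate(invalid="ignore"):
        return np.nanmean(values, axis=0) / 2.0


def maf_per_population(genotypes: GenotypeMatrix) -> pd.DataFrame:
    """Minor allele frequency per SNP within each population.

    Computed on non-missing calls only; a population with no call at a SNP
    yields ``NaN`` there (treated as failing by :func:`apply_qc`).
    """
    labels = np.asarray(genotypes.population_labels)
    out = {}
    for pop in pd.unique(labels):
        freq = allele_frequency(genotypes.values[labels == pop])
        out[pop] = np.minimum(freq, 1.0 - freq)
    return pd.DataFrame(out, index=genotypes.snp_ids)


def hwe_chisq(genotypes: GenotypeMatrix) -> np.ndarray:
    """Pearson chi-square for Hardy-Weinberg proportions, pooled over samples.

    Three genotype classes against expected counts ``n*(q^2, 2pq, p^2)``
    where ``p`` is the pooled frequency of the allele coded 2.  Monomorphic
    SNPs return 0 by convention.
    """
    v = genotypes.values
    n0 = np.nansum(v == 0, axis=0).astype(float)
    n1 = np.nansum(v == 1, axis=0).astype(float)
    n2 = np.nansum(v == 2, axis=0).astype(float)
    n = n0 + n1 + n2
    with np.errstate(divide="ignore", invalid="ignore"):
        p = (2 * n2 + n1) / (2 * n)
        q = 1.0 - p
        exp = np.stack([n * q**2, 2 * n * p * q, n * p**2])
        obs = np.stack([n0, n1, n2])
        terms = np.where(exp > 0, (obs - exp) ** 2 / np.where(exp > 0, exp, 1.0), 0.0)
        chisq = terms.sum(axis=0)
    chisq[(n == 0) | (p <= 0) | (p >= 1)] = 0.0
    return chisq


# ---------------------------------------------------------------------------
# QC driver
# ---------------------------------------------------------------------------

@dataclass
class QCReport:
    """Outcome of :func:`apply_qc`: per-SNP statistics and removal audit."""

    snp_stats: pd.DataFrame
    removed: dict[str, list[str]] = field(default_factory=dict)
    n_before: int = 0
    n_after: int = 0

    def reconciles(self) -> bool:
        return self.n_before == self.n_after + sum(len(v) for v in self.removed.values())

    def summary(self) -> str:
        lines = [f"SNPs in: {self.n_before}"]
        for name, snps in self.removed.items():
            lines.append(f"  removed by {name}: {len(snps)}")
        lines.append(f"SNPs out: {self.n_after}")
        return "\n".join(lines)


def apply_qc(
    genotypes: GenotypeMatrix,
    call_rate_min: float = DEFAULT_CALL_RATE,
    maf_min: float = DEFAULT_MAF,
    hwe_chisq_max: float = DEFAULT_HWE_CHISQ,
) -> tuple[GenotypeMatrix, QCReport]:
    """Apply the SNP filters in fixed order: call rate, per-population MAF, HWE.

    A SNP is attributed to the first filter it fails; surviving SNPs keep
    their original order.  Raises :class:`QCError` if nothing survives.
    """
    if min(call_rate_min, maf_min, hwe_chisq_max) < 0:
        raise ValueError("thresholds must be nonnegative")
    cr = call_rate(genotypes)
    maf = maf_per_population(genotypes)
    chisq = hwe_chisq(genotypes)
    snp_ids = np.asarray(genotypes.snp_ids)

    fail_cr = cr <= call_rate_min
    maf_ok = (maf.to_numpy() > maf_min) & ~np.isnan(maf.to_numpy())
    fail_maf = ~fail_cr & ~maf_ok.all(axis=1)
    fail_hwe = ~fail_cr & ~fail_maf & (chisq >= hwe_chisq_max)
    keep = ~(fail_cr | fail_maf | fail_hwe)

    stats = pd.DataFrame(
        {"call_rate": cr, "hwe_chisq": chisq, "min_maf": maf.min(axis=1).to_numpy()},
        index=genotypes.snp_ids,
    )
    stats = pd.concat([stats, maf.add_prefix("maf_")], axis=1)
    report = QCReport(
        snp_stats=stats,
        removed={
            "call_rate": list(snp_ids[fail_cr]),
            "maf": list(snp_ids[fail_maf]),
            "hwe": list(snp_ids[fail_hwe]),
        },
        n_before=genotypes.n_snps,
        n_after=int(keep.sum()),
    )
    if not keep.any():
        raise QCError("all SNPs removed by QC")
    logger.info("QC: %d -> %d SNPs", report.n_before, report.n_after)
    return genotypes.subset(snp_ids=snp_ids[keep]), report


def impute_missing(genotypes: GenotypeMatrix) -> GenotypeMatrix:
    """Replace missing calls by the per-SNP mean genotype (a real number).

    Mean imputation leaves column means unchanged, so downstream centering is
    unaffected.  A SNP with no observed call at all raises :class:`QCError`.
    """
    v = genotypes.values
    if not np.isnan(v).any():
        return genotypes
    n_obs = (~np.isnan(v)).sum(axis=0)
    if (n_obs == 0).any():
        bad = np.asarray(genotypes.snp_ids)[n_obs == 0][0]
        raise QCError(f"SNP {bad} has no observed genotype to impute from")
    col_means = np.nanmean(v, axis=0)
    filled = np.where(np.isnan(v), col_means[None, :], v)
    return GenotypeMatrix(
        filled,
        list(genotypes.sample_ids),
        list(genotypes.snp_ids),
        list(genotypes.population_labels),
        imputed=True,
    )
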