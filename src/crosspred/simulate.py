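"""Synthetic multi-population cattle data for across-population prediction.

Emulates a pooled dataset of five weakly related Holstein-like populations:
allele frequencies drift apart under a Balding-Nichols model (population
frequency ~ Beta with mean p and variance F*p*(1-p) around the ancestral
frequency p), genotypes descend through a random-mating pedigree by gene
dropping, and additive polygenic traits arise from normally distributed
effects at a random subset of QTL.  Defaults reproduce the study
conditions the pipeline targets: final-generation population sizes
206/210/181/394/618 (1609 animals in total) and heritabilities inside the
0.13-0.59 band reported for pre-adjusted milk-yield phenotypes.

SNPs segregate independently (no linkage map); the pedigree still induces
LD-like covariance between relatives, which is all the downstream methods
require.  Missing genotypes, when requested, are missing completely at
random — they exist to give the QC call-rate filter a target.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .qc import GenotypeMatrix
from .relationships import PedigreeTable

logger = logging.getLogger(__name__)

DEFAULT_POPULATIONS = ("UK_1", "UK_2", "SWE", "IRL", "NLD")
DEFAULT_POPULATION_SIZES = (206, 210, 181, 394, 618)
#: UK_1 drifts furthest (it separates on PC1 of the pooled data); the other
#: populations share a milder differentiation.
DEFAULT_FST = (0.10, 0.04, 0.04, 0.04, 0.04)
DEFAULT_HERITABILITIES = {"milk": 0.30, "fat": 0.35, "protein": 0.25}


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class SimulationConfig:
    """Stated world of the generator; defaults mirror the target study."""

    population_sizes: tuple[int, ...] = DEFAULT_POPULATION_SIZES
    population_names: tuple[str, ...] = DEFAULT_POPULATIONS
    n_snps: int = 5000
    n_qtl: int = 500
    fst: tuple[float, ...] = DEFAULT_FST
    heritability: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_HERITABILITIES)
    )
    n_generations: int = 3
    base_maf_range: tuple[float, float] = (0.05, 0.5)
    seed: int = 0
    missing_rate: float = 0.0
    migration_rate: float = 0.0

    def __post_init__(self) -> None:
        if not self.population_sizes or any(n <= 0 for n in self.population_sizes):
            raise ConfigurationError("population sizes must be positive")
        if len(self.population_names) != len(self.population_sizes):
            raise ConfigurationError("need one name per population")
        if not 0 < self.n_qtl <= self.n_snps:
            raise ConfigurationError("need 0 < n_qtl <= n_snps")
        if len(self.fst) != len(self.population_sizes):
            raise ConfigurationError("need one Fst per population")
        if any(not 0.0 < f < 1.0 for f in self.fst):
            raise ConfigurationError("every Fst must lie strictly in (0, 1)")
        for trait, h2 in self.heritability.items():
            if not 0.0 < h2 < 1.0:
                raise ConfigurationError(f"heritability of {trait!r} outside (0, 1)")
        if self.n_generations < 1:
            raise ConfigurationError("pedigree depth must be >= 1")
        lo, hi = self.base_maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigurationError("base MAF range must lie within (0, 0.5]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigurationError("missing rate must be in [0, 1)")
        if not 0.0 <= self.migration_rate < 1.0:
            raise ConfigurationError("migration rate must be in [0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("population_sizes", "population_names", "fst", "base_maf_range"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


@dataclass
class SimulatedStudy:
    """Everything downstream stages need, plus the simulation truth."""

    config: SimulationConfig
    pedigree: PedigreeTable
    genotypes: GenotypeMatrix            # final generation only
    true_breeding_values: pd.DataFrame   # animal x trait
    phenotypes: pd.DataFrame             # animal x trait
    qtl_ids: list[str]
    qtl_effects: pd.DataFrame            # qtl x trait


# ---------------------------------------------------------------------------
# Founder allele frequencies (Balding-Nichols drift)
# ---------------------------------------------------------------------------

def draw_founder_frequencies(
    n_snps: int,
    fst_per_population,
    base_maf_range=(0.05, 0.5),
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Ancestral and per-population allele frequencies.

    Ancestral minor-allele frequencies are uniform on ``base_maf_range``
    and mirrored to either allele with equal probability.  Each population
    then draws SNP-wise from ``Beta(p(1-F)/F, (1-p)(1-F)/F)``, whose mean
    is p and whose variance is ``F*p*(1-p)``.

    Returns ``(ancestral, per_population)`` with shapes ``(n_snps,)`` and
    ``(n_pops, n_snps)``.
    """
    fst = np.asarray(list(fst_per_population), dtype=float)
    if fst.size == 0 or np.any((fst <= 0) | (fst >= 1)):
        raise ConfigurationError("every Fst must lie strictly in (0, 1)")
    lo, hi = base_maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ConfigurationError("base MAF range must lie within (0, 0.5]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    maf = rng.uniform(lo, hi, size=n_snps)
    mirror = rng.random(n_snps) < 0.5
    ancestral = np.where(mirror, 1.0 - maf, maf)
    eps = 1e-9
    per_pop = np.empty((fst.size, n_snps))
    for k, F in enumerate(fst):
        a = ancestral * (1.0 - F) / F
        b = (1.0 - ancestral) * (1.0 - F) / F
        per_pop[k] = np.clip(rng.beta(a, b), eps, 1.0 - eps)
    return ancestral, per_pop


# ---------------------------------------------------------------------------
# Pedigree and gene dropping
# ---------------------------------------------------------------------------

def random_pedigree(
    population_sizes,
    population_names,
    n_generations: int,
    rng: np.random.Generator,
    migration_rate: float = 0.0,
) -> PedigreeTable:
    """Random-mating pedigree: founders unrelated, mating within population.

    Every generation of a population has the population's final size.  With
    probability ``migration_rate`` a parent is drawn from another
    population's previous generation (default 0: populations stay
    pedigree-unrelated).
    """
    records = []
    prev: dict[str, list[str]] = {}
    for g in range(n_generations + 1):
        current: dict[str, list[str]] = {}
        for pop, size in zip(population_names, population_sizes):
            ids = [f"{pop}_G{g}_{i + 1:04d}" for i in range(size)]
            current[pop] = ids
            for animal in ids:
                if g == 0:
                    records.append((animal, None, None, pop, g))
                else:
                    parents = []
                    for _ in range(2):
                        source = pop
                        if migration_rate > 0 and len(population_names) > 1 \
                                and rng.random() < migration_rate:
                            others = [q for q in population_names if q != pop]
                            source = others[rng.integers(len(others))]
                        parents.append(source)
                    pool_s = prev[parents[0]]
                    sire = pool_s[rng.integers(len(pool_s))]
                    pool_d = prev[parents[1]]
                    dam = sire
                    while dam == sire:
                        dam = pool_d[rng.integers(len(pool_d))]
                    records.append((animal, sire, dam, pop, g))
        prev = current
    frame = pd.DataFrame(
        records, columns=["animal_id", "sire_id", "dam_id", "population", "generation"]
    )
    return PedigreeTable(frame)


def gene_drop(
    pedigree: PedigreeTable,
    founder_frequencies: np.ndarray,
    seed: int | np.random.Generator = 0,
    missing_rate: float = 0.0,
    snp_ids=None,
) -> GenotypeMatrix:
    """Drop alleles through the pedigree; returns genotypes of all animals.

    Founders draw two alleles per SNP from their population's frequency;
    each non-founder inherits one uniformly chosen allele from each parent,
    independently across SNPs.  ``founder_frequencies`` is indexed by the
    order of populations as they appear in the pedigree's ``population``
    column (``pd.unique``).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    df = pedigree.frame
    if "population" not in df.columns:
        raise ValueError("pedigree needs a 'population' column for founders")
    pops = list(pd.unique(df["population"]))
    freqs = np.asarray(founder_frequencies, dtype=float)
    if freqs.shape[0] != len(pops):
        raise ValueError("one frequency row required per population")
    n, p = len(df), freqs.shape[1]
    idx = {a: i for i, a in enumerate(df["animal_id"])}
    pop_row = {pop: k for k, pop in enumerate(pops)}
    maternal = np.empty((n, p), dtype=np.uint8)
    paternal = np.empty((n, p), dtype=np.uint8)
    sires = df["sire_id"].to_numpy()
    dams = df["dam_id"].to_numpy()
    populations = df["population"].to_numpy()
    for i in range(n):
        if sires[i] is None and dams[i] is None:
            f = freqs[pop_row[populations[i]]]
            paternal[i] = rng.random(p) < f
            maternal[i] = rng.random(p) < f
        elif sires[i] is None or dams[i] is None:
            raise ValueError(f"animal {df['animal_id'][i]!r} has exactly one known parent")
        else:
            s, d = idx[sires[i]], idx[dams[i]]
            pick_s = rng.random(p) < 0.5
            paternal[i] = np.where(pick_s, paternal[s], maternal[s])
            pick_d = rng.random(p) < 0.5
            maternal[i] = np.where(pick_d, paternal[d], maternal[d])
    values = (maternal + paternal).astype(float)
    if missing_rate > 0:
        values[rng.random(values.shape) < missing_rate] = np.nan
    if snp_ids is None:
        snp_ids = [f"SNP{j + 1:06d}" for j in range(p)]
    return GenotypeMatrix(
        values, list(df["animal_id"]), list(snp_ids), list(populations)
    )


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

def assign_phenotypes(
    genotypes: GenotypeMatrix,
    n_qtl: int,
    heritability: dict[str, float] | float,
    seed: int | np.random.Generator = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Additive polygenic traits from a random QTL subset.

    QTL are sampled without replacement; per-trait effects are iid standard
    normal; the breeding value is centred-QTL-genotypes x effects, and the
    residual SD is set from the realised breeding-value variance so that
    var(bv)/var(phenotype) equals the heritability in expectation.

    Returns ``(true_breeding_values, phenotypes, qtl_effects)``; QTL ids
    are the index of ``qtl_effects``.
    """
    if isinstance(heritability, float):
        heritability = {"trait": heritability}
    for trait, h2 in heritability.items():
        if not 0.0 < h2 < 1.0:
            raise ConfigurationError(f"heritability of {trait!r} outside (0, 1)")
    if not 0 < n_qtl <= genotypes.n_snps:
        raise ConfigurationError("need 0 < n_qtl <= n_snps")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    X = genotypes.values
    if np.isnan(X).any():
        raise ValueError("assign phenotypes before masking genotypes as missing")
    qtl_pos = np.sort(rng.choice(genotypes.n_snps, size=n_qtl, replace=False))
    qtl_ids = [genotypes.snp_ids[j] for j in qtl_pos]
    Q = X[:, qtl_pos]
    Qc = Q - Q.mean(axis=0, keepdims=True)
    bv, phe, eff = {}, {}, {}
    for trait, h2 in heritability.items():
        effects = rng.standard_normal(n_qtl)
        u = Qc @ effects
        var_u = float(np.var(u))
        resid_sd = np.sqrt(var_u * (1.0 - h2) / h2) if var_u > 0 else 1.0
        e = rng.standard_normal(len(u)) * resid_sd
        bv[trait] = u
        phe[trait] = u + e
        eff[trait] = effects
    index = genotypes.sample_ids
    return (
        pd.DataFrame(bv, index=index),
        pd.DataFrame(phe, index=index),
        pd.DataFrame(eff, index=qtl_ids),
    )


# ---------------------------------------------------------------------------
# Composition
# ---------------------------------------------------------------------------

def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    """Pedigree -> gene drop -> phenotypes, deterministically from the seed."""
    rng = np.random.default_rng(config.seed)
    _, per_pop = draw_founder_frequencies(
        config.n_snps, config.fst, config.base_maf_range, rng
    )
    pedigree = random_pedigree(
        config.population_sizes, config.population_names,
        config.n_generations, rng, config.migration_rate,
    )
    all_geno = gene_drop(pedigree, per_pop, rng, missing_rate=0.0)
    final = pedigree.frame.loc[
        pedigree.frame["generation"] == config.n_generations, "animal_id"
    ]
    genotypes = all_geno.subset(sample_ids=list(final))
    bv, phe, effects = assign_phenotypes(
        genotypes, config.n_qtl, config.heritability, rng
    )
    if config.missing_rate > 0:
        vals = genotypes.values
        vals[rng.random(vals.shape) < config.missing_rate] = np.nan
    logger.info(
        "simulated %d animals in %d populations, %d SNPs (%d QTL), traits: %s",
        genotypes.n_samples, len(config.population_sizes), config.n_snps,
        config.n_qtl, ", ".join(config.heritability),
    )
    return SimulatedStudy(
        config=config,
        pedigree=pedigree,
        genotypes=genotypes,
        true_breeding_values=bv,
        phenotypes=phe,
        qtl_ids=list(effects.index),
        qtl_effects=effects,
    )


def write_study(study: SimulatedStudy, out_dir) -> None:
    """Persist a study as plain-text files (matrix + ped/map + CSV tables)."""
    from pathlib import Path

    from .qc import write_genotypes

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_genotypes(study.genotypes, out / "genotypes.tsv", fmt="matrix")
    write_genotypes(study.genotypes, out / "genotypes", fmt="ped")
    study.pedigree.to_csv(out / "pedigree.csv")
    phe = study.phenotypes.copy()
    phe.insert(0, "population", study.genotypes.population_labels)
    phe.index.name = "animal_id"
    phe.to_csv(out / "phenotypes.csv")
    bv = study.true_breeding_values.copy()
    bv.index.name = "animal_id"
    bv.to_csv(out / "true_breeding_values.csv")
    study.qtl_effects.rename_axis("qtl_id").to_csv(out / "qtl_effects.csv")
    study.config.to_yaml(out / "config.yaml")
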