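"""Leave-one-population-out evaluation of GREML, PCR and SSPCR.

The study design follows across-population genomic prediction: the pooled
data are split so that each test set is exactly one population (or
selection line) and the reference set is everything else — every animal
has its breeding value predicted exactly once per trait and method.
Prediction accuracy is the Pearson correlation between predicted breeding
values and the (pre-adjusted) phenotypes within the test set; on simulated
data the correlation with the true breeding values is reported alongside.

For each split and trait the report contains:

* GREML accuracy (REML variance components on the reference block of the
  blended genomic relationship matrix, GBLUP prediction of the test set);
* PCR and SSPCR accuracies at the cross-validation-selected number of PCs,
  for eigenvalue and sum-of-squares rankings under both a random 5-fold
  and a population-stratified CV scheme;
* "best case" accuracies: the maximum of the test-set accuracy trajectory
  over all numbers of PCs — an upper bound that uses test phenotypes and
  is therefore unattainable in practice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import greml as greml_mod
from . import model_selection as ms
from . import pca, pcr
from .qc import GenotypeMatrix, apply_qc, impute_missing
from .relationships import PedigreeTable, build_relationships, relationship_summary

logger = logging.getLogger(__name__)


def pearson_accuracy(gebv, y_test) -> float:
    """Pearson correlation of predictions with test phenotypes; NaN if either
    vector is constant (e.g. a null model giving every animal the same
    prediction)."""
    return pcr.pearson(np.asarray(gebv, dtype=float), np.asarray(y_test, dtype=float))


def heritability_rescale(accuracy: float, heritability: float) -> float:
    """Convert a phenotype correlation to an accuracy of GEBV: r / sqrt(h2).

    The result may exceed 1 for noisy estimates and is reported as-is.
    """
    if not 0.0 < heritability <= 1.0:
        raise ValueError("heritability must be in (0, 1]")
    out = accuracy / np.sqrt(heritability)
    if np.isfinite(out) and abs(out) > 1:
        logger.warning("rescaled accuracy %.3f exceeds 1 in magnitude", out)
    return out


@dataclass
class StudyDesign:
    """What to run: traits, methods, CV schemes, seeds, scan depth."""

    traits: list[str] | None = None          # None: all phenotype columns
    run_greml: bool = True
    run_pcr: bool = True
    run_sspcr: bool = True
    rankings: tuple[str, ...] = ("eigen", "ss")
    cv_schemes: tuple[str, ...] = ("random5", "stratified")
    seed: int = 0
    k_max: int | None = None                 # None: full feasible rank
    fixed_blend_b: float | None = None       # None: estimate b from the data
    n_bins: int = 5
    scale: bool = False


@dataclass
class StudyResult:
    """Tidy accuracy report plus the per-cell accuracy trajectories."""

    report: pd.DataFrame
    trajectories: dict[tuple[str, str, str, str], pcr.AccuracyTrajectory]
    relationship_summaries: pd.DataFrame
    design: StudyDesign
    extras: dict = field(default_factory=dict)

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.report.to_csv(out / "report.csv", index=False, float_format="%.10g")
        summarize(self.report).to_csv(out / "summary.csv", index=False,
                                      float_format="%.10g")
        self.relationship_summaries.to_csv(
            out / "relationship_summary.csv", index=False, float_format="%.10g"
        )
        traj_dir = out / "trajectories"
        traj_dir.mkdir(exist_ok=True)
        for (pop, trait, mode, crit), traj in self.trajectories.items():
            frame = pd.DataFrame(
                {"k": np.arange(len(traj.accuracies)), "accuracy": traj.accuracies}
            )
            frame.to_csv(traj_dir / f"{pop}_{trait}_{mode}_{crit}.csv",
                         index=False, float_format="%.10g")


def _scheme_for(name: str, seed: int) -> ms.CVScheme:
    if name == "random5":
        return ms.CVScheme(kind="random_kfold", n_folds=5, seed=seed)
    if name == "stratified":
        return ms.CVScheme(kind="stratified", seed=seed)
    raise ValueError(f"unknown CV scheme {name!r}")


def run_study(
    design: StudyDesign,
    genotypes: GenotypeMatrix,
    phenotypes: pd.DataFrame,
    pedigree: PedigreeTable | None = None,
    true_breeding_values: pd.DataFrame | None = None,
) -> StudyResult:
    """Run the full leave-one-population-out comparison.

    ``genotypes`` must already have passed QC; missing calls are imputed
    here.  ``phenotypes`` is indexed by animal id with one column per
    trait.  Any cell that fails (non-convergence, degenerate fold) is
    recorded with status ``failed`` and the run continues.
    """
    genotypes = impute_missing(genotypes)
    traits = design.traits or list(phenotypes.columns)
    labels = pd.Series(genotypes.population_labels, index=genotypes.sample_ids)
    populations = list(pd.unique(labels.to_numpy()))
    if len(populations) < 2:
        raise ValueError("need at least two populations for the split design")
    phenotypes = phenotypes.loc[genotypes.sample_ids, traits].astype(float)

    # relationship matrices are split-independent: allele frequencies and the
    # blend are taken across all genotyped animals
    relset = build_relationships(
        genotypes, pedigree, n_bins=design.n_bins, fixed_b=design.fixed_blend_b
    )
    rel_summaries = []
    for name, mat in (("pedigree", relset.A), ("genomic", relset.G)):
        s = relationship_summary(mat, labels.to_list())
        s.insert(0, "matrix", name)
        rel_summaries.append(s)

    rows: list[dict] = []
    trajectories: dict[tuple[str, str, str, str], pcr.AccuracyTrajectory] = {}

    modes = [m for m, on in (("pcr", design.run_pcr), ("sspcr", design.run_sspcr)) if on]
    for split_idx, test_pop in enumerate(populations):
        test_ids = list(labels.index[labels == test_pop])
        ref_ids = list(labels.index[labels != test_pop])
        assert not set(test_ids) & set(ref_ids)
        scores: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        if design.run_pcr:
            _, T_r, T_t = pca.reference_decomposition(
                genotypes, ref_ids, test_ids, scale=design.scale
            )
            scores["pcr"] = (T_r, T_t)
        if design.run_sspcr:
            _, T_r, T_t = pca.semi_supervised_decompose(
                genotypes, ref_ids, test_ids, scale=design.scale
            )
            scores["sspcr"] = (T_r, T_t)
        # fold decompositions depend only on genotypes: compute once per
        # (scheme, mode) and reuse across traits and ranking criteria
        ref_geno = genotypes.subset(sample_ids=ref_ids)
        fold_scores: dict[tuple[str, str], list[ms.FoldScores]] = {}
        for scheme_name in design.cv_schemes:
            scheme = _scheme_for(scheme_name, design.seed + split_idx)
            assignment = ms.make_folds(
                ref_ids, scheme, labels=labels.loc[ref_ids].to_list()
            )
            for mode in modes:
                fold_scores[(scheme_name, mode)] = ms.decompose_folds(
                    ref_geno, assignment, mode=mode, scale=design.scale
                )
        for trait in traits:
            y = phenotypes[trait]
            y_r = y.loc[ref_ids].to_numpy()
            y_t = y.loc[test_ids].to_numpy()

            if design.run_greml:
                try:
                    vc = greml_mod.reml_fit(
                        y_r, relset.G.loc[ref_ids, ref_ids].to_numpy()
                    )
                    gebv = greml_mod.predict_gebv(
                        vc, relset.G, ref_ids, test_ids, y_r
                    )
                    rows.append(
                        _row(test_pop, trait, "greml", None, None, None,
                             pearson_accuracy(gebv.gebv, y_t),
                             _tbv_acc(gebv.gebv, true_breeding_values, test_ids, trait),
                             extra={"sigma_u2": vc.sigma_u2,
                                    "sigma_e2": vc.sigma_e2,
                                    "converged": vc.converged})
                    )
                except Exception as exc:  # noqa: BLE001 - cell-level isolation
                    logger.exception("GREML failed for %s/%s", test_pop, trait)
                    rows.append(_failed(test_pop, trait, "greml", None, None, exc))

            for mode in modes:
                T_r, T_t = scores[mode]
                for crit in design.rankings:
                    # best-case scan on the outer decomposition
                    try:
                        ranking = _ranking(crit, T_r, y_r)
                        traj = pcr.accuracy_trajectory(
                            T_r, y_r, T_t, y_t, ranking,
                            k_max=design.k_max, test_label=test_pop,
                        )
                        trajectories[(test_pop, trait, mode, crit)] = traj
                        rows.append(
                            _row(test_pop, trait, mode, crit, "best_case",
                                 traj.best_k, traj.best_accuracy, np.nan)
                        )
                    except Exception as exc:  # noqa: BLE001
                        logger.exception("scan failed for %s/%s/%s/%s",
                                         test_pop, trait, mode, crit)
                        rows.append(_failed(test_pop, trait, mode, crit,
                                            "best_case", exc))
                    for scheme_name in design.cv_schemes:
                        try:
                            cv = ms.cv_mse_curve_from_folds(
                                fold_scores[(scheme_name, mode)],
                                y.loc[ref_ids], crit, mode,
                                k_max=design.k_max,
                                scheme=_scheme_for(scheme_name,
                                                   design.seed + split_idx),
                            )
                            k_sel = cv.selected_k
                            ranking = _ranking(crit, T_r, y_r)
                            model = pcr.fit_pcr(T_r, y_r, ranking, k_sel)
                            pred = pcr.predict_pcr(model, T_t)
                            # read the accuracy off the scan where possible so
                            # that best-case dominance is exact by construction
                            traj = trajectories.get((test_pop, trait, mode, crit))
                            if traj is not None and k_sel <= traj.k_max:
                                acc_sel = float(traj.accuracies[k_sel])
                            else:
                                acc_sel = pearson_accuracy(pred, y_t)
                            rows.append(
                                _row(test_pop, trait, mode, crit, scheme_name,
                                     k_sel, acc_sel,
                                     _tbv_acc(pred, true_breeding_values,
                                              test_ids, trait),
                                     mse=float(cv.mse_curve[k_sel]))
                            )
                        except Exception as exc:  # noqa: BLE001
                            logger.exception("CV cell failed for %s/%s/%s/%s/%s",
                                             test_pop, trait, mode, crit,
                                             scheme_name)
                            rows.append(_failed(test_pop, trait, mode, crit,
                                                scheme_name, exc))

    report = pd.DataFrame(rows)
    return StudyResult(
        report=report,
        trajectories=trajectories,
        relationship_summaries=pd.concat(rel_summaries, ignore_index=True),
        design=design,
        extras={"blend": relset.blend, "n_animals": genotypes.n_samples},
    )


def _ranking(criterion: str, T_r: np.ndarray, y_r: np.ndarray) -> pcr.PCRanking:
    # eigen order is the natural SVD column order; ss ranks on reference fit
    if criterion == "eigen":
        return pcr.PCRanking("eigen", np.arange(T_r.shape[1]))
    return pcr.rank_ss(T_r, y_r)


def _tbv_acc(pred, tbv: pd.DataFrame | None, test_ids, trait) -> float:
    if tbv is None or trait not in tbv.columns:
        return float("nan")
    return pearson_accuracy(pred, tbv.loc[[str(i) for i in test_ids], trait].to_numpy())


def _row(pop, trait, method, ranking, scheme, k, accuracy, accuracy_tbv,
         mse=np.nan, extra=None) -> dict:
    row = {
        "test_population": pop, "trait": trait, "method": method,
        "ranking": ranking, "scheme": scheme, "k": k,
        "accuracy": accuracy, "accuracy_tbv": accuracy_tbv, "mse": mse,
        "status": "ok",
    }
    if extra:
        row.update(extra)
    return row


def _failed(pop, trait, method, ranking, scheme, exc) -> dict:
    return {
        "test_population": pop, "trait": trait, "method": method,
        "ranking": ranking, "scheme": scheme, "k": np.nan,
        "accuracy": np.nan, "accuracy_tbv": np.nan, "mse": np.nan,
        "status": f"failed: {exc}",
    }


def summarize(report: pd.DataFrame) -> pd.DataFrame:
    """Mean and SD of accuracy per trait and method over test populations.

    Missing cells (NA accuracies) are excluded from the average and counted.
    """
    if report.empty:
        raise ValueError("empty report")
    grouped = report.groupby(
        ["trait", "method", "ranking", "scheme"], dropna=False
    )["accuracy"]
    out = grouped.agg(
        mean_accuracy="mean", sd_accuracy="std",
        n_cells="size", n_missing=lambda s: int(s.isna().sum()),
    ).reset_index()
    return out


# ---------------------------------------------------------------------------
# End-to-end demo: simulate -> QC -> study
# ---------------------------------------------------------------------------

def full_demo(
    seed: int = 0,
    out_dir=None,
    config=None,
    design: StudyDesign | None = None,
):
    """Simulate the default five-population study, run QC and the comparison.

    Returns ``(study, qc_report, result)``; writes report/summary/trajectory
    CSVs (and the simulated inputs) under ``out_dir`` when given.  Fully
    deterministic given the seed.
    """
    from .simulate import SimulationConfig, simulate_study, write_study

    if config is None:
        config = SimulationConfig(seed=seed)
    study = simulate_study(config)
    cleaned, qc_report = apply_qc(study.genotypes)
    if design is None:
        design = StudyDesign(seed=seed)
    result = run_study(
        design, cleaned, study.phenotypes,
        pedigree=study.pedigree,
        true_breeding_values=study.true_breeding_values,
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_study(study, out / "inputs")
        qc_report.snp_stats.rename_axis("snp_id").to_csv(out / "qc_stats.csv",
                                                         float_format="%.10g")
        (out / "qc_log.txt").write_text(qc_report.summary() + "\n")
        result.write(out)
    return study, qc_report, result


# ---------------------------------------------------------------------------
# Optional plots (matplotlib, behind explicit calls / CLI flag)
# ---------------------------------------------------------------------------

def plot_trajectory(trajectory: pcr.AccuracyTrajectory, path) -> None:
    """Accuracy versus number of included PCs for one cell."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(np.arange(len(trajectory.accuracies)), trajectory.accuracies, lw=0.8)
    if trajectory.best_k is not None:
        ax.axvline(trajectory.best_k, color="red", ls="--", lw=0.8)
    ax.set_xlabel("number of PCs")
    ax.set_ylabel("accuracy (Pearson r)")
    ax.set_title(trajectory.test_label or "accuracy trajectory")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_pc_scatter(decomposition: pca.PCDecomposition, population_labels, path) -> None:
    """PC1 vs PC2 scatter coloured by population."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = np.asarray([str(x) for x in population_labels])
    fig, ax = plt.subplots(figsize=(6, 5))
    for pop in pd.unique(labels):
        mask = labels == pop
        ax.scatter(decomposition.scores[mask, 0], decomposition.scores[mask, 1],
                   s=8, label=pop, alpha=0.7)
    var = decomposition.variance_proportions
    ax.set_xlabel(f"PC1 ({100 * var[0]:.1f}%)")
    ax.set_ylabel(f"PC2 ({100 * var[1]:.1f}%)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
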