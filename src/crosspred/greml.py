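"""Genomic REML (GREML) and GBLUP prediction with a single random effect.

The animal model is ``y = 1*mu + u + e`` with ``u ~ N(0, G sigma_u^2)`` and
``e ~ N(0, I sigma_e^2)`` (one record per animal, so the incidence matrix
is the identity after alignment).  Variance components are estimated by
restricted maximum likelihood.  Because there is a single random effect,
the restricted likelihood can be profiled exactly: after rotating y into
the eigenbasis of G, both the intercept and the residual variance maximise
in closed form, leaving a one-dimensional search over the signal fraction
``h = sigma_u^2 / (sigma_u^2 + sigma_e^2)``.

``snp_blup_oracle`` provides the ridge-regression (SNP-BLUP) formulation
that is mathematically equivalent to GBLUP with ``G = ZZ'/c`` and penalty
``lambda = c * sigma_e^2 / sigma_u^2``; it is used to cross-validate the
matrix route.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

logger = logging.getLogger(__name__)

_LOG2PI = np.log(2.0 * np.pi)


class MatrixError(ValueError):
    """Relationship matrix not usable (non-PSD beyond jitter, singular)."""


@dataclass
class VarianceComponents:
    """REML estimates for the single-random-effect animal model."""

    sigma_u2: float
    sigma_e2: float
    mu_hat: float
    restricted_log_likelihood: float
    converged: bool
    n_iterations: int
    boundary: bool = False


@dataclass
class GEBVSet:
    """Predicted breeding values for a set of animals."""

    animal_ids: list[str]
    gebv: np.ndarray
    model_tag: str
    provenance: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"animal_id": self.animal_ids, "gebv": self.gebv,
             "model_tag": self.model_tag}
        )


def _prepare_eigen(G: np.ndarray, jitter: float = 1e-8) -> tuple[np.ndarray, np.ndarray]:
    lam, Q = np.linalg.eigh(G)
    if lam.min() < -1e-6:
        raise MatrixError(f"G has eigenvalue {lam.min():.3g}; not PSD beyond jitter")
    if lam.min() < 0:
        logger.info("clipping %d slightly negative eigenvalues (jitter %g)",
                    int((lam < 0).sum()), jitter)
    lam = np.clip(lam, 0.0, None) + jitter
    return lam, Q


def _profile_parts(h: float, lam: np.ndarray, z: np.ndarray, x: np.ndarray):
    """Profiled quantities at signal fraction h = s_u^2/(s_u^2+s_e^2).

    With gamma = h/(1-h), V = sigma_e^2 * diag(gamma*lam + 1) in the
    rotated basis.  Returns (gamma, weights, mu_hat, sigma_e2_hat).
    """
    gamma = h / (1.0 - h)
    w = 1.0 / (gamma * lam + 1.0)
    sxx = float(np.sum(w * x * x))
    sxy = float(np.sum(w * x * z))
    mu = sxy / sxx
    r = z - mu * x
    n = len(z)
    se2 = float(np.sum(w * r * r)) / (n - 1)
    return gamma, w, mu, se2


def _reml_loglik_profiled(h: float, lam: np.ndarray, z: np.ndarray, x: np.ndarray) -> float:
    gamma, w, mu, se2 = _profile_parts(h, lam, z, x)
    n = len(z)
    sxx = float(np.sum(w * x * x))
    if se2 <= 0:
        return -np.inf
    return -0.5 * (
        (n - 1) * _LOG2PI
        + (n - 1) * np.log(se2)
        - float(np.sum(np.log(w)))
        + np.log(sxx)
        + (n - 1)
    )


def restricted_loglik(
    y: np.ndarray,
    G: np.ndarray,
    sigma_u2: float,
    sigma_e2: float,
    method: str = "eigen",
    jitter: float = 1e-8,
) -> float:
    """Restricted log-likelihood of (sigma_u2, sigma_e2) for y = 1*mu + u + e.

    ``method="eigen"`` evaluates via the eigendecomposition of G;
    ``method="dense"`` builds V = sigma_u2*G + sigma_e2*I explicitly and
    evaluates ``-0.5[(n-1)log 2pi + log|V| + log|X'V^-1 X| + y'Py]``.
    The two agree to numerical precision and serve as mutual checks.
    """
    y = np.asarray(y, dtype=float)
    G = np.asarray(G, dtype=float)
    n = len(y)
    ones = np.ones(n)
    if method == "dense":
        V = sigma_u2 * (G + jitter * np.eye(n)) + sigma_e2 * np.eye(n)
        sign, logdet_v = np.linalg.slogdet(V)
        if sign <= 0:
            raise MatrixError("V not positive definite")
        Vi_y = np.linalg.solve(V, y)
        Vi_1 = np.linalg.solve(V, ones)
        sxx = float(ones @ Vi_1)
        mu = float(ones @ Vi_y) / sxx
        r = y - mu * ones
        ypy = float(r @ np.linalg.solve(V, r))
        return -0.5 * ((n - 1) * _LOG2PI + logdet_v + np.log(sxx) + ypy)
    if method != "eigen":
        raise ValueError(f"unknown method {method!r}")
    lam, Q = _prepare_eigen(G, jitter=jitter)
    z = Q.T @ y
    x = Q.T @ ones
    d = sigma_u2 * lam + sigma_e2
    w = 1.0 / d
    sxx = float(np.sum(w * x * x))
    mu = float(np.sum(w * x * z)) / sxx
    r = z - mu * x
    ypy = float(np.sum(w * r * r))
    return -0.5 * ((n - 1) * _LOG2PI + float(np.sum(np.log(d))) + np.log(sxx) + ypy)


def reml_fit(
    y_r: np.ndarray,
    G_rr: np.ndarray,
    jitter: float = 1e-8,
    tol: float = 1e-10,
) -> VarianceComponents:
    """Maximise the restricted likelihood over (sigma_u2, sigma_e2).

    One eigendecomposition of the reference block of G, then a bounded
    Brent search on the signal fraction h in [0, 1).  Estimates within
    1e-10 of the h = 0 boundary are reported as sigma_u2 = 0 with a
    boundary flag.
    """
    y = np.asarray(y_r, dtype=float)
    G = np.asarray(G_rr, dtype=float)
    if G.shape != (len(y), len(y)):
        raise ValueError("G block does not match phenotype vector")
    lam, Q = _prepare_eigen(G, jitter=jitter)
    z = Q.T @ y
    x = Q.T @ np.ones(len(y))

    neg = lambda h: -_reml_loglik_profiled(h, lam, z, x)
    res = minimize_scalar(neg, bounds=(0.0, 1.0 - 1e-9), method="bounded",
                          options={"xatol": tol})
    h_hat = float(res.x)
    # the bounded optimizer cannot land exactly on 0; test the boundary too
    if neg(0.0) <= res.fun:
        h_hat = 0.0
    gamma, w, mu, se2 = _profile_parts(h_hat, lam, z, x)
    su2 = gamma * se2
    boundary = su2 < 1e-10
    if boundary:
        su2 = 0.0
    ll = _reml_loglik_profiled(h_hat, lam, z, x)
    return VarianceComponents(
        sigma_u2=float(su2),
        sigma_e2=float(se2),
        mu_hat=float(mu),
        restricted_log_likelihood=float(ll),
        converged=bool(res.success),
        n_iterations=int(res.nfev),
        boundary=boundary,
    )


def predict_gebv(
    components: VarianceComponents,
    G_full: pd.DataFrame,
    reference_ids,
    test_ids,
    y_r: np.ndarray,
    jitter: float = 1e-8,
    model_tag: str = "greml",
) -> GEBVSet:
    """BLUP of breeding values for test animals under the fitted model.

    ``u_hat = sigma_u^2 * G[:, ref] V_rr^{-1} (y_r - 1*mu_hat)`` with
    ``V_rr = G_rr sigma_u^2 + I sigma_e^2``.  Reference animals' entries
    solve the same equations and are available via ``provenance``.
    """
    ref = [str(i) for i in reference_ids]
    tst = [str(i) for i in test_ids]
    y = np.asarray(y_r, dtype=float)
    if len(y) != len(ref):
        raise ValueError("phenotypes do not match reference ids")
    G_rr = G_full.loc[ref, ref].to_numpy()
    G_tr = G_full.loc[tst, ref].to_numpy()
    n_r = len(ref)
    V_rr = components.sigma_u2 * G_rr + (components.sigma_e2 + jitter) * np.eye(n_r)
    resid = y - components.mu_hat
    alpha = np.linalg.solve(V_rr, resid)
    u_test = components.sigma_u2 * (G_tr @ alpha)
    u_ref = components.sigma_u2 * (G_rr @ alpha)
    return GEBVSet(
        animal_ids=tst,
        gebv=u_test,
        model_tag=model_tag,
        provenance={
            "reference_n": n_r,
            "mu_hat": components.mu_hat,
            "u_ref": u_ref,
        },
    )


def snp_blup_oracle(
    centered_train: np.ndarray,
    y_r: np.ndarray,
    lam: float,
    centered_test: np.ndarray,
) -> np.ndarray:
    """Ridge regression on SNP effects with an unpenalised intercept.

    Solves ``min ||y - 1*mu - Z b||^2 + lam ||b||^2`` and predicts the test
    rows.  Equivalent to GBLUP with ``G = ZZ'/c`` when
    ``lam = c * sigma_e^2 / sigma_u^2``.
    """
    if lam <= 0:
        raise ValueError("penalty must be positive")
    Z = np.asarray(centered_train, dtype=float)
    y = np.asarray(y_r, dtype=float)
    n, p = Z.shape
    M = np.empty((p + 1, p + 1))
    M[0, 0] = n
    M[0, 1:] = Z.sum(axis=0)
    M[1:, 0] = M[0, 1:]
    M[1:, 1:] = Z.T @ Z + lam * np.eye(p)
    rhs = np.concatenate([[y.sum()], Z.T @ y])
    sol = np.linalg.solve(M, rhs)
    mu, b = sol[0], sol[1:]
    return mu + np.asarray(centered_test, dtype=float) @ b
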