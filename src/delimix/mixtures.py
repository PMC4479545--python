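"""Gaussian mixture EM over a six-family covariance lattice with BIC selection.

This is the clustering engine applied identically to every dataset. The
covariance lattice follows the model-based-clustering nomenclature
(volume/shape/orientation): EII and VII are spherical with equal or
varying volume, EEI and VVI diagonal, EEE and VVV full covariance —
spanning clusters of different volumes, orientations, and shapes while
keeping parameter-count formulas auditable.

BIC here is 2*loglik - n_params*ln(n): larger is better, and model
selection maximizes it over the K x family grid with seeded k-means++
restarts. Classification uncertainty for a specimen is one minus its
maximum posterior membership probability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from sklearn.cluster import kmeans_plusplus

from .errors import SelectionError, SingularFitError

FAMILIES = ("EII", "VII", "EEI", "VVI", "EEE", "VVV")

#: Eigenvalue floor applied to every covariance estimate; prevents
#: singular fits on duplicated specimens.
COV_FLOOR = 1e-8

LOG2PI = np.log(2.0 * np.pi)


def cov_param_count(family: str, K: int, d: int) -> int:
    """Free covariance parameters for a family at K components in d dims."""
    full = d * (d + 1) // 2
    return {
        "EII": 1,
        "VII": K,
        "EEI": d,
        "VVI": K * d,
        "EEE": full,
        "VVV": K * full,
    }[family]


@dataclass
class MixtureFit:
    """A fitted Gaussian mixture for one (family, K) cell."""

    family: str
    K: int
    weights: np.ndarray            # (K,)
    means: np.ndarray              # (K, d)
    covariances: np.ndarray        # (K, d, d), expanded regardless of family
    loglik: float
    n_iter: int
    converged: bool
    n: int                         # training sample size
    bic: float = np.nan
    singular: bool = False         # a component collapsed onto the covariance floor
    loglik_path: list = None       # per-iteration log-likelihoods (monotone)

    @property
    def d(self) -> int:
        return self.means.shape[1]

    @property
    def n_params(self) -> int:
        return (self.K - 1) + self.K * self.d + cov_param_count(self.family, self.K, self.d)


@dataclass
class Partition:
    """Hard labels (1..K, renumbered by descending cluster size) + posteriors."""

    labels: np.ndarray             # (n,), int, 1-based
    posterior: np.ndarray          # (n, K)
    uncertainty: np.ndarray        # (n,), 1 - max posterior

    @property
    def K(self) -> int:
        return self.posterior.shape[1]


def _log_prob_matrix(
    X: np.ndarray, weights: np.ndarray, means: np.ndarray, covs: np.ndarray
) -> np.ndarray:
    """(n, K) matrix of log w_k + log N(x | mu_k, Sigma_k), batched over K."""
    d = X.shape[1]
    try:
        chol = np.linalg.cholesky(covs)
    except np.linalg.LinAlgError:
        floored = []
        for cov in covs:
            vals, vecs = np.linalg.eigh(cov)
            floored.append((vecs * np.maximum(vals, COV_FLOOR)) @ vecs.T)
        chol = np.linalg.cholesky(np.stack(floored))
    diff = X[None, :, :] - means[:, None, :]           # (K, n, d)
    sol = np.linalg.solve(chol, diff.transpose(0, 2, 1))
    maha = np.sum(sol**2, axis=1)                      # (K, n)
    logdet = 2.0 * np.sum(np.log(np.diagonal(chol, axis1=1, axis2=2)), axis=1)
    log_pdf = -0.5 * (d * LOG2PI + logdet[:, None] + maha)
    return (np.log(weights + 1e-300)[:, None] + log_pdf).T


def _mstep_covariances(
    X: np.ndarray, resp: np.ndarray, means: np.ndarray, family: str
) -> np.ndarray:
    """Family-constrained covariance M-step; returns expanded (K, d, d)."""
    n, d = X.shape
    K = means.shape[0]
    Nk = resp.sum(axis=0)
    diff = X[None, :, :] - means[:, None, :]
    scatter = np.einsum("nk,knd,kne->kde", resp, diff, diff)
    eye = np.eye(d)
    floor_eye = COV_FLOOR * eye
    if family == "VVV":
        covs = scatter / Nk[:, None, None] + floor_eye
    elif family == "EEE":
        covs = np.repeat(scatter.sum(axis=0)[None] / n + floor_eye, K, axis=0)
    elif family == "VVI":
        diags = np.maximum(np.einsum("kii->ki", scatter) / Nk[:, None], COV_FLOOR)
        covs = diags[:, :, None] * eye
    elif family == "EEI":
        diag = np.maximum(np.einsum("kii->i", scatter) / n, COV_FLOOR)
        covs = np.repeat((diag[:, None] * eye)[None], K, axis=0)
    elif family == "VII":
        lam = np.maximum(np.einsum("kii->k", scatter) / (Nk * d), COV_FLOOR)
        covs = lam[:, None, None] * eye
    elif family == "EII":
        lam = max(np.einsum("kii->", scatter) / (n * d), COV_FLOOR)
        covs = np.repeat((lam * eye)[None], K, axis=0)
    else:
        raise ValueError(f"unknown family {family!r}")
    return covs


def em_fit(
    scores: np.ndarray,
    K: int,
    family: str,
    seed: int,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> MixtureFit:
    """Fit one Gaussian mixture by EM from a seeded k-means++ start.

    The log-likelihood is non-decreasing across iterations; convergence
    is declared when its increase falls below ``tol``. Deterministic
    given ``seed``. Raises :class:`SingularFitError` if a component
    collapses despite the covariance floor (model selection reports
    such cells instead of propagating the exception).
    """
    X = np.atleast_2d(np.asarray(scores, dtype=float))
    if X.ndim == 2 and X.shape[1] > X.shape[0] and X.shape[0] == 1:
        X = X.T
    n, d = X.shape
    if K > n:
        raise ValueError(f"K={K} exceeds sample size n={n}")
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    if K == 1:
        centers = X.mean(axis=0, keepdims=True)
        resp = np.ones((n, 1))
    else:
        centers, _ = kmeans_plusplus(X, n_clusters=K, random_state=int(seed) % (2**31))
        assign = np.argmin(((X[:, None, :] - centers[None]) ** 2).sum(axis=2), axis=1)
        resp = np.zeros((n, K))
        resp[np.arange(n), assign] = 1.0
        # guard: empty initial components get their seeding center's nearest point
        for k in np.flatnonzero(resp.sum(axis=0) == 0):
            j = np.argmin(((X - centers[k]) ** 2).sum(axis=1))
            resp[j] = 0.0
            resp[j, k] = 1.0

    loglik = -np.inf
    converged = False
    weights = means = covs = None
    loglik_path: list[float] = []
    for it in range(1, max_iter + 1):
        # M-step
        Nk = resp.sum(axis=0)
        if np.any(Nk < 1e-10) or not np.all(np.isfinite(resp)):
            raise SingularFitError(f"component collapsed (family={family}, K={K})")
        weights = Nk / n
        means = (resp.T @ X) / Nk[:, None]
        covs = _mstep_covariances(X, resp, means, family)
        # E-step (inline log-sum-exp; this loop dominates runtime)
        log_prob = _log_prob_matrix(X, weights, means, covs)
        mx = log_prob.max(axis=1)
        log_norm = mx + np.log(np.exp(log_prob - mx[:, None]).sum(axis=1))
        new_loglik = float(log_norm.sum())
        if not np.isfinite(new_loglik):
            raise SingularFitError(f"non-finite log-likelihood (family={family}, K={K})")
        resp = np.exp(log_prob - log_norm[:, None])
        loglik_path.append(new_loglik)
        if new_loglik - loglik < tol and it > 1:
            loglik = max(loglik, new_loglik)
            converged = True
            break
        loglik = new_loglik
    eigmins = np.array([np.linalg.eigvalsh(c)[0] for c in covs])
    # spurious-solution guard: a component collapsed onto the covariance
    # floor, or has too few effective members to support its own mean and
    # covariance (the classic unbounded-likelihood pathology)
    singular = bool(
        np.any(eigmins <= 2.0 * COV_FLOOR) or (K > 1 and resp.sum(axis=0).min() < d + 2)
    )
    fit = MixtureFit(
        family=family, K=K, weights=weights, means=means, covariances=covs,
        loglik=loglik, n_iter=it, converged=converged, n=n, singular=singular,
        loglik_path=loglik_path,
    )
    fit.bic = bic(fit, n)
    return fit


def bic(fit: MixtureFit, n: int) -> float:
    """BIC = 2*loglik - n_params*ln(n); larger is better."""
    return 2.0 * fit.loglik - fit.n_params * np.log(n) if n > 1 else 2.0 * fit.loglik


def model_select(
    scores: np.ndarray,
    K_max: int = 12,
    families: tuple[str, ...] = FAMILIES,
    restarts: int = 10,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> tuple[MixtureFit, pd.DataFrame]:
    """Search the K x family grid, best-of-restarts per cell, argmax BIC.

    Ties (BIC equal within 1e-9) are broken toward smaller K, then fewer
    parameters. Returns the winning fit and the full BIC table so any
    sensitivity to the lattice is explicit.
    """
    X = np.atleast_2d(np.asarray(scores, dtype=float))
    if X.shape[0] == 1 and X.shape[1] > 1:
        X = X.T
    n = X.shape[0]
    if K_max < 1:
        raise ValueError("K_max must be >= 1")
    ss = np.random.SeedSequence(int(seed) % (2**31))
    rows = []
    fits: list[MixtureFit] = []
    cell_seeds = ss.generate_state(len(families) * min(K_max, n) * restarts)
    s_idx = 0
    for K in range(1, min(K_max, n) + 1):
        for family in families:
            best = None
            for _ in range(restarts):
                sub_seed = int(cell_seeds[s_idx] % (2**31))
                s_idx += 1
                try:
                    fit = em_fit(X, K, family, seed=sub_seed, tol=tol, max_iter=max_iter)
                except SingularFitError:
                    continue
                if fit.singular:
                    continue  # collapsed component: reported below, never selected
                if best is None or fit.loglik > best.loglik:
                    best = fit
                if K == 1:
                    break  # K=1 fit is deterministic; restarts identical
            if best is None:
                rows.append((K, family, np.nan, False))
                continue
            rows.append((K, family, best.bic, best.converged))
            fits.append(best)
    table = pd.DataFrame(rows, columns=["K", "family", "bic", "converged"])
    if not fits:
        raise SelectionError("every candidate fit was singular")
    return select_best(fits), table


def select_best(fits: list[MixtureFit]) -> MixtureFit:
    """Argmax-BIC choice with deterministic tie-breaking.

    BIC values within 1e-9 are treated as tied; ties go to the smaller
    K, then the fewer-parameter family.
    """
    best_bic = max(f.bic for f in fits)
    tied = [f for f in fits if best_bic - f.bic <= 1e-9]
    tied.sort(key=lambda f: (f.K, f.n_params))
    return tied[0]


def classify(fit: MixtureFit, scores: np.ndarray) -> Partition:
    """Posterior classification of specimens under a fitted mixture.

    Labels are argmax-posterior components renumbered 1..K by descending
    cluster size; uncertainty is 1 minus the maximum posterior.
    """
    X = np.atleast_2d(np.asarray(scores, dtype=float))
    if X.shape[1] != fit.d:
        raise ValueError(f"scores have {X.shape[1]} dims, fit expects {fit.d}")
    log_prob = _log_prob_matrix(X, fit.weights, fit.means, fit.covariances)
    log_norm = logsumexp(log_prob, axis=1)
    posterior = np.exp(log_prob - log_norm[:, None])
    raw = np.argmax(posterior, axis=1)
    sizes = np.bincount(raw, minlength=fit.K)
    order = np.argsort(-sizes, kind="stable")      # descending size, stable ties
    rank = np.empty(fit.K, dtype=int)
    rank[order] = np.arange(1, fit.K + 1)
    labels = rank[raw]
    posterior = posterior[:, order]
    uncertainty = 1.0 - posterior.max(axis=1)
    return Partition(labels=labels, posterior=posterior, uncertainty=uncertainty)
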