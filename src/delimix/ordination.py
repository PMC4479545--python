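"""Correlation-matrix PCA with axis retention and missingness screening.

The same ordination is applied to every dataset: variables are
standardized (mean 0, sd 1), the correlation matrix is
eigendecomposed, and all axes explaining more than 5% of total variance
are retained for clustering. For molecular datasets an additional
screen drops retained axes whose scores track per-specimen missing-data
fraction, which otherwise masquerades as population structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .encoding import FeatureMatrix
from .errors import DegenerateInputError


@dataclass
class ScoreSet:
    """PCA eigensystem and specimen scores.

    scores: specimens x axes (all axes, descending eigenvalue order)
    eigenvalues: descending, from the correlation matrix
    variance_fractions: eigenvalue / sum(eigenvalues)
    loadings: variables x axes eigenvectors
    retained: ordered indices (0-based) of axes kept for clustering
    """

    specimen_ids: list[str]
    feature_ids: list[str]
    scores: np.ndarray
    eigenvalues: np.ndarray
    variance_fractions: np.ndarray
    loadings: np.ndarray
    retained: list[int] = field(default_factory=list)

    def retained_scores(self) -> np.ndarray:
        return self.scores[:, self.retained]

    def to_frame(self) -> pd.DataFrame:
        cols = {f"pc{k + 1}": self.scores[:, k] for k in range(self.scores.shape[1])}
        return pd.DataFrame({"specimen_id": self.specimen_ids, **cols})


def pca_correlation(fm: FeatureMatrix) -> ScoreSet:
    """PCA on the correlation matrix of a feature matrix.

    Sign convention: within each axis the loading of largest magnitude
    is made positive, so runs are reproducible across platforms.
    """
    X = np.asarray(fm.values, dtype=float)
    n, p = X.shape
    if n < 2 or p < 2:
        raise DegenerateInputError("PCA needs >= 2 specimens and >= 2 variables")
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = [fm.feature_ids[j] for j in np.flatnonzero(sd == 0)]
        raise DegenerateInputError(f"constant columns reached PCA: {bad}")
    Z = (X - X.mean(axis=0)) / sd
    corr = (Z.T @ Z) / (n - 1)
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    # fix eigenvector signs: largest-magnitude loading per axis positive
    for k in range(eigvecs.shape[1]):
        j = np.argmax(np.abs(eigvecs[:, k]))
        if eigvecs[j, k] < 0:
            eigvecs[:, k] = -eigvecs[:, k]
    scores = Z @ eigvecs
    fractions = eigvals / eigvals.sum()
    ss = ScoreSet(
        specimen_ids=list(fm.specimen_ids),
        feature_ids=list(fm.feature_ids),
        scores=scores,
        eigenvalues=eigvals,
        variance_fractions=fractions,
        loadings=eigvecs,
    )
    ss.retained = retain_axes(ss)
    return ss


def retain_axes(score_set: ScoreSet, threshold: float = 0.05) -> list[int]:
    """Indices of axes explaining strictly more than ``threshold`` of variance.

    Never empty: axis 1 is always retained, so downstream clustering has
    at least one dimension even in degenerate cases.
    """
    kept = [k for k, f in enumerate(score_set.variance_fractions) if f > threshold]
    if not kept:
        kept = [0]
    return kept


def screen_missingness_axes(
    score_set: ScoreSet,
    missing_fraction: np.ndarray,
    r_threshold: float = 0.7,
) -> list[int]:
    """Flag retained axes whose scores correlate with missing-data fraction.

    Returns the flagged axis indices and removes them from
    ``score_set.retained`` (axis 1 may be dropped; the guard that axis 1
    is never empty applies to retention, not to this screen — if the
    screen empties the retained set the first unflagged axis is kept).
    """
    missing_fraction = np.asarray(missing_fraction, dtype=float)
    if missing_fraction.shape[0] != score_set.scores.shape[0]:
        raise DegenerateInputError("missing_fraction length mismatch with scores")
    if np.ptp(missing_fraction) == 0:
        return []
    dropped = []
    for k in score_set.retained:
        r = np.corrcoef(score_set.scores[:, k], missing_fraction)[0, 1]
        if np.abs(r) >= r_threshold:
            dropped.append(k)
    score_set.retained = [k for k in score_set.retained if k not in dropped]
    if not score_set.retained:
        flagged = set(dropped)
        for k in range(score_set.scores.shape[1]):
            if k not in flagged:
                score_set.retained = [k]
                break
    return dropped


def write_scores(score_set: ScoreSet, path, retained_only: bool = True) -> None:
    """Export scores as TSV (specimen_id + pc columns)."""
    axes = score_set.retained if retained_only else range(score_set.scores.shape[1])
    out = pd.DataFrame({"specimen_id": score_set.specimen_ids})
    for k in axes:
        out[f"pc{k + 1}"] = score_set.scores[:, k]
    out.to_csv(path, sep="\t", index=False)
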