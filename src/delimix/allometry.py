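"""ANCOVA homogeneity-of-slopes test for allometric trajectories.

Tests whether delimited species differ in the allometric slope of one
body part on another (e.g., head size on rattle size). Both variables
are log10-transformed by default, a full model with per-group slopes
and intercepts is compared against a reduced common-slope model, and

    F = ((RSS_reduced - RSS_full)/df1) / (RSS_full/df2),
    df1 = g - 1,  df2 = n - 2g,

is referred to the F distribution. A small p indicates distinct
developmental trajectories among groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats as sps

from .errors import DegenerateInputError, DomainError


@dataclass
class SlopeTest:
    """Result of the homogeneity-of-slopes ANCOVA."""

    n: int
    groups: list
    slopes: dict
    intercepts: dict
    F: float
    df1: int
    df2: int
    p: float
    rss_full: float
    rss_reduced: float


def slope_heterogeneity(x, y, group, log10: bool = True) -> SlopeTest:
    """Compare per-group allometric slopes of y on x.

    ``x`` and ``y`` must be positive when ``log10`` is requested;
    every group needs at least 3 points and nonzero x-variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    group = np.asarray(group)
    if x.shape != y.shape or x.shape != group.shape:
        raise DomainError("x, y and group must have equal length")
    if log10:
        if np.any(x <= 0) or np.any(y <= 0):
            raise DomainError("x and y must be positive for log10 transform")
        x = np.log10(x)
        y = np.log10(y)
    labels, counts = np.unique(group, return_counts=True)
    g = len(labels)
    if g < 2:
        raise DegenerateInputError("need at least 2 groups")
    if np.any(counts < 3):
        small = labels[counts < 3].tolist()
        raise DegenerateInputError(f"groups with fewer than 3 points: {small}")
    for lab in labels:
        if np.ptp(x[group == lab]) == 0:
            raise DegenerateInputError(f"group {lab!r} has zero x-variance")
    n = x.size
    df = pd.DataFrame({"x": x, "y": y, "g": group.astype(str)})
    full = smf.ols("y ~ C(g) + x + C(g):x", data=df).fit()
    reduced = smf.ols("y ~ C(g) + x", data=df).fit()
    rss_f = float(full.ssr)
    rss_r = float(reduced.ssr)
    df1 = g - 1
    df2 = n - 2 * g
    F = ((rss_r - rss_f) / df1) / (rss_f / df2)
    p = float(sps.f.sf(F, df1, df2))
    slopes, intercepts = {}, {}
    for lab in labels:
        sel = group == lab
        fit = sps.linregress(x[sel], y[sel])
        slopes[lab] = float(fit.slope)
        intercepts[lab] = float(fit.intercept)
    return SlopeTest(
        n=n, groups=labels.tolist(), slopes=slopes, intercepts=intercepts,
        F=float(F), df1=df1, df2=df2, p=p, rss_full=rss_f, rss_reduced=rss_r,
    )
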