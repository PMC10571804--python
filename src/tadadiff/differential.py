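"""Differential Pol II binding: orthogonal regression and residual z-scores.

Each bound gene contributes one point ``(x, y)`` — its mean occupancy in the
control and in the inactivated (*shi*) condition. Because both axes carry
the same kind of measurement error, the trend is fitted by orthogonal (total
least squares) regression: the line through the centroid along the first
principal component of the 2x2 covariance of the scatter. A gene's residual
is its signed perpendicular distance to that line (positive above the line,
i.e. higher occupancy in the inactive condition); dividing by the residual
standard deviation gives a z-score, and ``|z| > 1.96`` marks the two-tailed
~95% band. A significant call additionally requires a small per-sample
occupancy FDR and more than one GATC site inside the gene.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .genes import filter_bound_genes

log = logging.getLogger(__name__)

Z_CUT = 1.96          # two-tailed ~95% confidence band
FDR_CUT = 0.01
GATC_CUT = 1          # strict: genes need > 1 GATC site


class DegenerateGeometryError(ValueError):
    """Isotropic or collinear scatter; no meaningful principal axis."""


class SchemaError(KeyError):
    pass


class OrthogonalRegression(BaseEstimator):
    """Total-least-squares line fit with signed orthogonal residuals.

    scikit-learn-style estimator over an ``(n, 2)`` array of points.

    Attributes (after ``fit``)
    --------------------------
    center_ : ndarray (2,)
        Centroid of the points; the fitted line passes through it.
    direction_ : ndarray (2,)
        Unit vector along the line (first principal eigenvector),
        oriented with a positive x-component.
    slope_, intercept_ : float
        The same line in y = slope * x + intercept form (slope may be
        infinite only for a vertical line, rejected as degenerate here).
    residual_sd_ : float
        Sample standard deviation (ddof=1) of the training residuals.

    Notes
    -----
    Residuals are signed perpendicular distances; a point with larger y
    than the line predicts has a positive residual. The residual mean is 0
    by construction (the line passes through the centroid).
    """

    def __init__(self, min_eigengap: float = 1e-12):
        self.min_eigengap = min_eigengap

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must be an (n, 2) array of (x, y) points")
        if X.shape[0] < 3:
            raise ValueError("need at least 3 points for a meaningful fit")
        self.center_ = X.mean(axis=0)
        cov = np.cov(X, rowvar=False)
        evals, evecs = np.linalg.eigh(cov)  # ascending
        if evals[1] - evals[0] <= self.min_eigengap * max(evals[1], 1.0):
            raise DegenerateGeometryError(
                "principal axes are indistinguishable (isotropic scatter); "
                "inspect the x/y scatter before fitting"
            )
        d = evecs[:, 1]
        if d[0] < 0:
            d = -d
        if abs(d[0]) < 1e-12:
            raise DegenerateGeometryError("vertical principal axis")
        self.direction_ = d
        self.slope_ = d[1] / d[0]
        self.intercept_ = self.center_[1] - self.slope_ * self.center_[0]
        res = self.transform(X)
        self.residual_sd_ = float(res.std(ddof=1))
        return self

    def transform(self, X) -> np.ndarray:
        """Signed orthogonal distance of each point to the fitted line."""
        X = np.asarray(X, dtype=float)
        d = self.direction_
        normal = np.array([-d[1], d[0]])  # points "up": +y side is positive
        return (X - self.center_) @ normal

    def z_scores(self, X) -> np.ndarray:
        """Residuals standardized by the training residual SD."""
        if self.residual_sd_ < 1e-12:
            raise DegenerateGeometryError(
                "all points are collinear; residual SD is zero"
            )
        return self.transform(X) / self.residual_sd_


def pca_regression(points: np.ndarray) -> OrthogonalRegression:
    """Fit the orthogonal-regression line to (x, y) points."""
    return OrthogonalRegression().fit(np.asarray(points))


def residual_zscores(points: np.ndarray, line: OrthogonalRegression) -> np.ndarray:
    """z-score of each point's signed orthogonal residual around ``line``."""
    return line.z_scores(np.asarray(points))


def call_differential(gene_table: pd.DataFrame,
                      fdr_cut: float = FDR_CUT,
                      z_cut: float = Z_CUT,
                      gatc_cut: int = GATC_CUT,
                      bound_alpha: float = 0.05,
                      fdr_mode: str = "occupancy") -> pd.DataFrame:
    """Call genes with significantly altered Pol II binding.

    Pipeline: restrict to bound genes (occupancy FDR < ``bound_alpha`` in
    every replicate of at least one condition), fit the orthogonal
    regression of shi-vs-control mean occupancy, z-score the residuals, and
    gate conjunctively on ``min_fdr < fdr_cut``, ``|z| > z_cut`` and
    ``n_gatc_sites > gatc_cut``. Positive z means increased binding in the
    inactive (shi) muscles.

    ``fdr_mode`` selects what "FDR" gates the call: ``"occupancy"``
    (default) reuses the smallest per-sample occupancy FDR; ``"zscore"``
    BH-adjusts two-sided normal p-values of the z-scores instead.
    """
    needed = {"mean_control", "mean_shi", "n_gatc_sites", "biotype"}
    missing = needed - set(gene_table.columns)
    if missing:
        raise SchemaError(f"gene table lacks columns: {sorted(missing)}")
    if fdr_mode not in ("occupancy", "zscore"):
        raise ValueError(f"unknown fdr_mode {fdr_mode!r}")

    bound = filter_bound_genes(gene_table, alpha=bound_alpha)
    bound = bound.dropna(subset=["mean_control", "mean_shi"])
    pts = bound[["mean_control", "mean_shi"]].to_numpy()
    line = pca_regression(pts)
    res = line.transform(pts)
    z = line.z_scores(pts)

    fdr_cols = [c for c in bound.columns if c.startswith("fdr_")]
    min_fdr = bound[fdr_cols].min(axis=1)
    if fdr_mode == "occupancy":
        gate_fdr = min_fdr < fdr_cut
    else:
        p = 2.0 * norm.sf(np.abs(z))
        gate_fdr = pd.Series(multipletests(p, method="fdr_bh")[1] < fdr_cut,
                             index=bound.index)
    significant = gate_fdr & (np.abs(z) > z_cut) & (bound["n_gatc_sites"] > gatc_cut)

    table = pd.DataFrame(
        {
            "biotype": bound["biotype"],
            "x": pts[:, 0],
            "y": pts[:, 1],
            "residual": res,
            "z": z,
            "n_gatc_sites": bound["n_gatc_sites"],
            "min_fdr": min_fdr,
            "significant": significant,
            "direction": np.where(z > 0, "up", "down"),
        },
        index=bound.index,
    )
    n_sig = int(significant.sum())
    log.info("differential call: %d analyzed -> %d bound -> %d significant "
             "(%d up, %d down)", len(gene_table), len(bound), n_sig,
             int((significant & (z > 0)).sum()), int((significant & (z < 0)).sum()))
    return table
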