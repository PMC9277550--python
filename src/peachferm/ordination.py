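"""PCA ordination for community snapshots and volatile profiles.

A thin, deterministic SVD-based PCA: optional centering and unit-variance
scaling, variance-explained fractions over *all* components, and a fixed
sign convention (the largest-magnitude entry of each loading vector is
positive) so downstream comparisons are reproducible.

Community ordination conventionally runs on genus-level relative abundances
(centered only); volatile ordination on z-scored concentrations, because
concentrations span several orders of magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["PCAResult", "pca"]


@dataclass
class PCAResult:
    scores: pd.DataFrame        # samples x components
    loadings: pd.DataFrame      # variables x components
    var_explained: np.ndarray   # fraction per component, sums to 1
    centered: bool
    unit_variance: bool
    mean_: np.ndarray
    scale_: np.ndarray

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]

    def reconstruct(self) -> pd.DataFrame:
        """Reconstruct the processed (centered/scaled) matrix from all
        components; exact up to numerical precision."""
        rec = self.scores.to_numpy() @ self.loadings.to_numpy().T
        return pd.DataFrame(rec, index=self.scores.index, columns=self.loadings.index)


def pca(X, center: bool = True, unit_variance: bool = False) -> PCAResult:
    """Exact PCA of a samples x variables matrix via SVD.

    Zero-variance variables are an error when ``unit_variance`` is set (they
    cannot be scaled); an entirely constant matrix is always an error.
    Missing entries must be handled by the caller (the volatile pipeline
    fills not-detected with 0 beforehand).
    """
    df = pd.DataFrame(X)
    if df.shape[0] < 2:
        raise ValueError("PCA needs at least 2 samples")
    M = df.to_numpy(dtype=float)
    if np.isnan(M).any():
        raise ValueError("PCA input contains missing values; impute first")
    mean = M.mean(axis=0) if center else np.zeros(M.shape[1])
    Z = M - mean
    if not np.any(Z.std(axis=0) > 0):
        raise ValueError("matrix is constant; no variance to decompose")
    if unit_variance:
        scale = Z.std(axis=0, ddof=1)
        if (scale == 0).any():
            bad = df.columns[np.where(scale == 0)[0][0]]
            raise ValueError(f"zero-variance variable {bad!r} cannot be autoscaled")
    else:
        scale = np.ones(M.shape[1])
    Z = Z / scale

    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    # sign convention: largest-|.| entry of each loading vector is positive
    for a in range(Vt.shape[0]):
        j = np.argmax(np.abs(Vt[a]))
        if Vt[a, j] < 0:
            Vt[a] *= -1.0
            U[:, a] *= -1.0
    var = s**2
    total = var.sum()
    comp_names = [f"PC{a + 1}" for a in range(len(s))]
    scores = pd.DataFrame(U * s, index=df.index, columns=comp_names)
    loadings = pd.DataFrame(Vt.T, index=df.columns, columns=comp_names)
    return PCAResult(
        scores=scores,
        loadings=loadings,
        var_explained=var / total,
        centered=center,
        unit_variance=unit_variance,
        mean_=mean,
        scale_=scale,
    )
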