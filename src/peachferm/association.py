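"""Correlation analysis: co-occurrence networks and taxon-volatile blocks.

Correlations are plain Pearson (default) or Spearman; two-sided p-values
come from the t transform t = r sqrt((n-2)/(1-r^2)) with n-2 degrees of
freedom.  Network construction keeps edges with |r| strictly above the
magnitude threshold and p strictly below the significance threshold
(conventionally |r| > 0.7 or 0.9 with p < 0.01 for within-community
networks, |r| > 0.6 for taxon-volatile screening).  Positive r marks
co-occurrence, negative r co-exclusion.

No multiple-testing correction is applied by default; Benjamini-Hochberg
is available via ``adjust="bh"`` on the network builder.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .tables import AbundanceTable, VolatileTable, to_relative

__all__ = [
    "CorrelationEdge",
    "correlation_matrix",
    "correlation_pvalues",
    "cooccurrence_network",
    "taxa_volatile_correlations",
]


@dataclass
class CorrelationEdge:
    node_a: str
    node_b: str
    type_a: str
    type_b: str
    r: float
    p: float
    sign: str  # "+" co-occurrence / "-" co-exclusion
    n: int = 0

    def get(self, key, default=None):  # mapping-style access for exporters
        return getattr(self, key, default)


def _rank(X: np.ndarray) -> np.ndarray:
    return np.apply_along_axis(stats.rankdata, 0, X)


def correlation_pvalues(R: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p from the t transform of r with n-2 df (NaN-safe)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.clip(R, -1.0, 1.0)
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, 1e-300))
        p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    return np.where(np.isnan(R), np.nan, p)


def correlation_matrix(X, method: str = "pearson") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Symmetric correlation matrix R and its p-value matrix P.

    Requires at least 4 samples (fewer leave the t test meaningless).
    Zero-variance variables get NaN correlations and a warning; network
    builders skip NaN edges.
    """
    df = pd.DataFrame(X)
    n = df.shape[0]
    if n < 4:
        raise ValueError("correlation needs at least 4 samples")
    M = df.to_numpy(dtype=float)
    if method == "spearman":
        M = _rank(M)
    elif method != "pearson":
        raise ValueError(f"unknown method {method!r}")
    sd = M.std(axis=0)
    if (sd == 0).any():
        bad = list(df.columns[sd == 0])
        warnings.warn(f"zero-variance variables excluded from correlations: {bad}")
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.corrcoef(M, rowvar=False)
    R[sd == 0, :] = np.nan
    R[:, sd == 0] = np.nan
    np.fill_diagonal(R, np.where(sd == 0, np.nan, 1.0))
    P = correlation_pvalues(R, n)
    np.fill_diagonal(P, np.nan)
    Rdf = pd.DataFrame(R, index=df.columns, columns=df.columns)
    Pdf = pd.DataFrame(P, index=df.columns, columns=df.columns)
    return Rdf, Pdf


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    flat = p[np.isfinite(p)]
    if flat.size == 0:
        return p
    order = np.argsort(flat)
    ranked = flat[order]
    m = flat.size
    adj = ranked * m / (np.arange(m) + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.full_like(flat, np.nan)
    out[order] = np.clip(adj, 0, 1)
    res = p.copy()
    res[np.isfinite(p)] = out
    return res


def cooccurrence_network(
    R: pd.DataFrame,
    P: pd.DataFrame,
    r_threshold: float = 0.7,
    p_threshold: float = 0.01,
    node_types: dict[str, str] | str = "taxon",
    adjust: str | None = None,
) -> list[CorrelationEdge]:
    """Edges with |r| > r_threshold and p < p_threshold (strict).

    ``node_types`` maps node id -> type tag (or one tag for all nodes).
    Square R gives within-set (upper-triangle) edges; a rectangular R gives
    the cross-block bipartite edges.
    """
    if not (0 < r_threshold < 1) or not (0 < p_threshold < 1):
        raise ValueError("thresholds must lie in (0, 1)")
    type_of = (lambda v: node_types) if isinstance(node_types, str) else (
        lambda v: node_types.get(v, "node"))
    Pm = P.to_numpy(dtype=float)
    if adjust == "bh":
        square = R.shape[0] == R.shape[1] and list(R.index) == list(R.columns)
        if square:
            iu = np.triu_indices(Pm.shape[0], k=1)
            flat = Pm[iu]
            adj = _bh_adjust(flat)
            Pm = Pm.copy()
            Pm[iu] = adj
            Pm[(iu[1], iu[0])] = adj
        else:
            Pm = _bh_adjust(Pm)
    square = R.shape[0] == R.shape[1] and list(R.index) == list(R.columns)
    edges = []
    rows = list(R.index)
    cols = list(R.columns)
    for i, a in enumerate(rows):
        for j, b in enumerate(cols):
            if square and j <= i:
                continue
            if a == b:
                continue
            r = R.iat[i, j]
            p = Pm[i, j]
            if not (np.isfinite(r) and np.isfinite(p)):
                continue
            if abs(r) > r_threshold and p < p_threshold:
                na, nb = (a, b) if str(a) <= str(b) else (b, a)
                ta, tb = (type_of(na), type_of(nb))
                edges.append(CorrelationEdge(na, nb, ta, tb, float(r), float(p),
                                             "+" if r > 0 else "-", n=0))
    return edges


def taxa_volatile_correlations(
    abund: AbundanceTable,
    v: VolatileTable,
    method: str = "pearson",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cross-correlation block between taxa and compounds.

    Samples are aligned replicate-to-replicate when the volatile table
    carries per-sample rows matching the abundance table's (stage,
    replicate) design; otherwise both sides are collapsed to stage means.
    Taxon abundances are used as relative abundances; not-detected
    concentrations count as 0 (below detection).
    """
    rel = to_relative(abund) if abund.mode == "counts" else abund
    X = rel.data
    if v.stage is not None:
        pairs_a = list(zip(rel.stage, rel.replicate))
        pairs_v = list(zip(v.stage, v.replicate))
        if set(pairs_a) == set(pairs_v):
            Y = v.filled(0.0).set_axis(pd.MultiIndex.from_tuples(pairs_v), axis=0)
            X = X.set_axis(pd.MultiIndex.from_tuples(pairs_a), axis=0)
            Y = Y.loc[X.index]
        else:
            raise ValueError("replicate designs of the two tables do not match")
    else:
        common = [s for s in rel.stage_means().index if s in v.stage_means().index]
        if not common:
            raise ValueError("no common stages between tables")
        X = rel.stage_means().loc[common]
        Y = v.stage_means().fillna(0.0).loc[common]
    n = X.shape[0]
    if n < 4:
        raise ValueError("need at least 4 aligned samples")
    joint = pd.concat([X.reset_index(drop=True), Y.reset_index(drop=True)], axis=1)
    R, P = correlation_matrix(joint, method=method)
    taxa = list(X.columns)
    compounds = list(Y.columns)
    return R.loc[taxa, compounds], P.loc[taxa, compounds]
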