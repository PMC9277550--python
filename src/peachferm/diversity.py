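"""Alpha-diversity estimators and stage-wise OTU set algebra.

Estimators operate on a single sample's count vector (integer counts are
required where the estimator is defined on singleton/doubleton structure).
``alpha_diversity`` applies all five to every sample of an
:class:`~peachferm.tables.AbundanceTable`; ``stage_otu_sets`` pools
replicates within a stage and reports shared/unique OTU counts across
stages.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .tables import AbundanceTable

__all__ = [
    "observed_richness",
    "chao1",
    "shannon",
    "simpson",
    "goods_coverage",
    "alpha_diversity",
    "rarefy",
    "stage_otu_sets",
]


def _as_counts(counts) -> np.ndarray:
    x = np.asarray(counts)
    if x.size == 0:
        raise ValueError("empty count vector")
    if not np.all(np.isfinite(np.asarray(x, dtype=float))):
        raise ValueError("counts must be finite")
    xi = np.asarray(np.rint(np.asarray(x, dtype=float)), dtype=np.int64)
    if not np.allclose(np.asarray(x, dtype=float), xi):
        raise ValueError("richness estimators require integer counts")
    if (xi < 0).any():
        raise ValueError("counts must be nonnegative")
    return xi


def _as_proportions(values) -> np.ndarray:
    x = np.asarray(values, dtype=float)
    if x.size == 0 or (x < 0).any():
        raise ValueError("need a nonnegative, nonempty vector")
    total = x.sum()
    if total <= 0:
        raise ValueError("all entries are zero")
    p = x / total
    return p[p > 0]


def observed_richness(counts) -> int:
    """Number of taxa with nonzero count."""
    return int((_as_counts(counts) > 0).sum())


def chao1(counts) -> float:
    """Bias-corrected Chao1 richness: S_obs + F1(F1-1) / (2(F2+1)).

    F1/F2 are singleton/doubleton counts; without singletons the estimate
    collapses to the observed richness.
    """
    x = _as_counts(counts)
    if x.sum() == 0:
        raise ValueError("all counts are zero")
    s_obs = int((x > 0).sum())
    f1 = int((x == 1).sum())
    f2 = int((x == 2).sum())
    return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))


def shannon(values, base: float = np.e) -> float:
    """Shannon entropy H = -sum p_i log p_i (natural log by default)."""
    p = _as_proportions(values)
    return float(-(p * np.log(p)).sum() / np.log(base))


def simpson(values, dominance: bool = False) -> float:
    """Gini-Simpson diversity 1 - sum p_i^2 (rises with evenness).

    ``dominance=True`` returns the complement sum p_i^2 instead.
    """
    p = _as_proportions(values)
    d = float((p**2).sum())
    return d if dominance else 1.0 - d


def goods_coverage(counts) -> float:
    """Good's coverage 1 - F1/N (fraction of reads from seen-again taxa)."""
    x = _as_counts(counts)
    n = int(x.sum())
    if n == 0:
        raise ValueError("zero total count")
    return 1.0 - int((x == 1).sum()) / n


def rarefy(counts, depth: int, seed: int = 0) -> np.ndarray:
    """Subsample a count vector to ``depth`` reads without replacement."""
    x = _as_counts(counts)
    n = int(x.sum())
    if depth > n:
        raise ValueError(f"depth {depth} exceeds sample total {n}")
    rng = np.random.default_rng(seed)
    reads = np.repeat(np.arange(x.size), x)
    picked = rng.choice(reads, size=depth, replace=False)
    return np.bincount(picked, minlength=x.size)


def alpha_diversity(t: AbundanceTable, base: float = np.e,
                    rarefy_depth: int | None = None, seed: int = 0) -> pd.DataFrame:
    """All five estimators per sample; optional seeded rarefaction first."""
    if t.mode != "counts":
        raise ValueError("alpha diversity requires a counts table")
    rows = {}
    for i, sample in enumerate(t.data.index):
        x = t.data.iloc[i].to_numpy()
        if rarefy_depth is not None:
            x = rarefy(x, rarefy_depth, seed=seed + i)
        rows[sample] = {
            "observed_species": observed_richness(x),
            "chao1": chao1(x),
            "shannon": shannon(x, base=base),
            "simpson": simpson(x),
            "goods_coverage": goods_coverage(x),
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.insert(0, "stage", t.stage.to_numpy())
    out.insert(1, "replicate", t.replicate.to_numpy())
    return out


def stage_otu_sets(t: AbundanceTable) -> dict:
    """Per-stage presence sets (pooled over replicates) and their algebra.

    Returns per-stage OTU counts, the size of the all-stage intersection and
    per-stage unique counts (OTUs seen in exactly one stage).
    """
    if t.mode != "counts":
        raise ValueError("presence/absence requires a counts table")
    stages = list(dict.fromkeys(t.stage))
    sets: dict[str, set] = {}
    for stage in stages:
        mask = (t.stage == stage).to_numpy()
        pooled = t.data.loc[mask].sum(axis=0)
        sets[stage] = set(pooled.index[pooled > 0])
    common = set.intersection(*sets.values()) if sets else set()
    uniques = {}
    for stage in stages:
        others = set().union(*(sets[s] for s in stages if s != stage)) if len(stages) > 1 else set()
        uniques[stage] = len(sets[stage] - others)
    return {
        "per_stage_sets": sets,
        "per_stage_counts": {s: len(sets[s]) for s in stages},
        "n_common": len(common),
        "common": common,
        "per_stage_unique": uniques,
    }
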