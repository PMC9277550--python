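"""Three-criteria screen for core functional microbiota and core volatiles.

A taxon (restricted to the ``top_n`` most abundant) is *core* when it

  (i)   is present sufficiently steadily across fermentation stages
        (prevalence in at least half the stages by default, optionally a
        coefficient-of-variation cap on its nonzero stage values);
  (ii)  has PLS2 variable importance VIP > 1.0 for predicting the volatile
        block from the taxon block; and
  (iii) has |Pearson r| > 0.6 with at least one volatile.

Core volatiles pass the same three gates with the blocks swapped: stability
of the concentration series, VIP from a second PLS fit with volatiles as
predictors of taxa, and max |r| over taxa.  All threshold comparisons are
strict.  The bipartite network connects each core taxon to each core
volatile whose |r| clears the correlation threshold.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .association import CorrelationEdge, correlation_pvalues, taxa_volatile_correlations
from .pls import PLSModel, fit_pls2
from .tables import AbundanceTable, VolatileTable, to_relative

__all__ = ["ScreenConfig", "CoreScreenResult", "stability_filter", "screen_core", "bipartite_network"]


@dataclass
class ScreenConfig:
    vip_threshold: float = 1.0
    r_threshold: float = 0.6
    min_stage_prevalence: float = 0.5
    max_cv: float | None = None
    top_n: int = 40

    def __post_init__(self) -> None:
        if self.vip_threshold <= 0 or self.r_threshold <= 0:
            raise ValueError("thresholds must be positive")
        if not (0 < self.min_stage_prevalence <= 1):
            raise ValueError("prevalence must lie in (0, 1]")


@dataclass
class CoreScreenResult:
    taxa: pd.DataFrame        # index taxon: passed_stability, vip, max_abs_r, passed
    volatiles: pd.DataFrame   # same structure per compound
    R: pd.DataFrame           # taxa x compounds correlations
    P: pd.DataFrame
    config: ScreenConfig
    taxon_types: dict = field(default_factory=dict)
    compound_classes: dict = field(default_factory=dict)

    @property
    def core_taxa(self) -> list[str]:
        return list(self.taxa.index[self.taxa["passed"]])

    @property
    def core_volatiles(self) -> list[str]:
        return list(self.volatiles.index[self.volatiles["passed"]])


def stability_filter(series, cfg: ScreenConfig) -> tuple[bool, dict]:
    """Criterion (i): steady presence across the per-stage series.

    Passes when the value is nonzero in at least
    ceil(prevalence x n_stages) stages, and — when ``max_cv`` is set — the
    coefficient of variation of the nonzero stage values does not exceed
    it.  Returns the flag plus raw diagnostics for auditing.
    """
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        raise ValueError("empty stage series")
    x = np.nan_to_num(x, nan=0.0)
    n_stages = x.size
    nz = x[x > 0]
    required = math.ceil(cfg.min_stage_prevalence * n_stages)
    ok = nz.size >= required
    cv = float(nz.std(ddof=0) / nz.mean()) if nz.size and nz.mean() > 0 else float("nan")
    if ok and cfg.max_cv is not None:
        ok = np.isfinite(cv) and cv <= cfg.max_cv
    return bool(ok), {"n_stages": n_stages, "n_nonzero": int(nz.size),
                      "required": required, "cv": cv}


def _flags(names, stage_profile: pd.DataFrame, vip: pd.Series,
           max_abs_r: pd.Series, cfg: ScreenConfig) -> pd.DataFrame:
    rows = {}
    for name in names:
        stab, diag = stability_filter(stage_profile[name].to_numpy(), cfg)
        v = float(vip.get(name, 0.0))
        r = float(max_abs_r.get(name, np.nan))
        r_ok = np.isfinite(r) and r > cfg.r_threshold
        rows[name] = {
            "passed_stability": stab,
            "vip": v,
            "max_abs_r": r,
            "passed_vip": v > cfg.vip_threshold,
            "passed_r": bool(r_ok),
            "cv": diag["cv"],
            "passed": bool(stab and v > cfg.vip_threshold and r_ok),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def screen_core(
    abund: AbundanceTable,
    v: VolatileTable,
    model: PLSModel,
    R: pd.DataFrame,
    cfg: ScreenConfig | None = None,
    P: pd.DataFrame | None = None,
    volatile_model: PLSModel | None = None,
) -> CoreScreenResult:
    """Apply the three criteria to both blocks.

    ``model`` must be the PLS2 fit of the volatile block on the (top_n)
    taxon block, and ``R`` the matching taxa x compounds correlation block.
    When no swapped-block model is supplied, one is fitted here with the
    same number of components (volatiles as predictors of taxa) to provide
    volatile-side VIPs.
    """
    cfg = cfg or ScreenConfig()
    taxa = list(R.index)
    compounds = list(R.columns)
    missing = set(taxa) - set(abund.taxa)
    if missing or set(compounds) - set(v.compounds):
        raise ValueError("R is not aligned with the abundance/volatile tables")

    rel = to_relative(abund) if abund.mode == "counts" else abund
    taxa_profile = rel.stage_means()[taxa]
    vol_profile = v.stage_means().fillna(0.0)[compounds]

    taxa_vip = model.vip.reindex(taxa).fillna(0.0)
    if volatile_model is None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            X_vol = _aligned_block(v, compounds)
            Y_tax = _aligned_taxa(rel, taxa, X_vol.index)
            A = min(model.A, max(1, min(X_vol.shape[0] - 1, X_vol.shape[1])))
            volatile_model = fit_pls2(X_vol, Y_tax, A)
    vol_vip = volatile_model.vip.reindex(compounds).fillna(0.0)

    absR = R.abs()
    taxa_df = _flags(taxa, taxa_profile, taxa_vip, absR.max(axis=1), cfg)
    vol_df = _flags(compounds, vol_profile, vol_vip, absR.max(axis=0), cfg)

    if P is None:
        P = pd.DataFrame(correlation_pvalues(R.to_numpy(), max(4, len(taxa_profile))),
                         index=R.index, columns=R.columns)
    taxon_types = {t: f"taxon-{abund.kingdom}" for t in taxa}
    classes = {c: str(v.compound_class.get(c, "volatile")) for c in compounds}
    return CoreScreenResult(taxa_df, vol_df, R, P, cfg,
                            taxon_types=taxon_types, compound_classes=classes)


def _aligned_block(v: VolatileTable, compounds) -> pd.DataFrame:
    if v.stage is not None:
        return v.filled(0.0)[compounds]
    return v.stage_means().fillna(0.0)[compounds]


def _aligned_taxa(rel: AbundanceTable, taxa, index) -> pd.DataFrame:
    if list(index) == list(rel.data.index):
        return rel.data[taxa]
    return rel.stage_means().loc[index, taxa]


def bipartite_network(res: CoreScreenResult) -> list[CorrelationEdge]:
    """Core-taxon x core-volatile edges with |r| above the screen threshold.

    Edge sign encodes the direction of association (positive: the taxon's
    abundance rises with the compound's concentration).
    """
    edges = []
    for taxon in res.core_taxa:
        for compound in res.core_volatiles:
            r = res.R.at[taxon, compound]
            if not np.isfinite(r) or abs(r) <= res.config.r_threshold:
                continue
            p = res.P.at[taxon, compound]
            edges.append(
                CorrelationEdge(
                    taxon, compound,
                    res.taxon_types.get(taxon, "taxon"),
                    f"volatile-{res.compound_classes.get(compound, 'unknown')}",
                    float(r), float(p), "+" if r > 0 else "-",
                )
            )
    return edges


def run_screen(
    abund: AbundanceTable,
    v: VolatileTable,
    cfg: ScreenConfig | None = None,
    A: int | None = None,
    A_max: int = 5,
) -> tuple[CoreScreenResult, PLSModel]:
    """Convenience end-to-end screen: top-n selection, correlations, PLS fit
    (components by LOO cross-validation unless ``A`` is given), and the
    three-criteria screen."""
    from .pls import select_components_cv
    from .tables import top_n_taxa

    cfg = cfg or ScreenConfig()
    rel = to_relative(abund) if abund.mode == "counts" else abund
    top = top_n_taxa(rel, cfg.top_n)
    R, P = taxa_volatile_correlations(top, v)
    X = _aligned_block_taxa(top, v)
    Y = _aligned_block(v, list(v.compounds))
    if set(Y.index) == set(X.index):
        Y = Y.loc[X.index]
    else:
        raise ValueError("abundance and volatile tables index different samples")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if A is None:
            A = select_components_cv(X.to_numpy(), Y.to_numpy(), A_max=A_max).chosen_A
        model = fit_pls2(X, Y, A)
    res = screen_core(top, v, model, R, cfg, P=P)
    return res, model


def _aligned_block_taxa(rel: AbundanceTable, v: VolatileTable) -> pd.DataFrame:
    if v.stage is not None:
        return rel.data
    return rel.stage_means()
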