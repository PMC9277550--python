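"""Tabular containers and I/O for fermentation microbiome / volatile data.

Three containers back every stage of the pipeline:

* :class:`AbundanceTable` — samples x taxa abundances (counts or relative)
  with per-sample fermentation ``stage`` and ``replicate`` metadata;
* :class:`VolatileTable` — samples-or-stages x compounds concentrations in
  ug/L, with a compound-class label per compound; not-detected entries are
  NaN, distinct from a measured zero;
* :class:`OdorThresholds` — per-compound odor threshold in ug/L, stored as a
  [low, high] interval (equal when the source gives a single value, NaN when
  no threshold is known).

A packaged fixture carries the full 53-compound volatile table of a
six-stage spontaneous flat-peach-wine fermentation (stages A-F = fermentation
days 0, 3, 6, 9, 13 and 16; means and standard deviations of three parallel
fermentations) together with its odor thresholds and printed OAV bands.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AbundanceTable",
    "VolatileTable",
    "OdorThresholds",
    "ValidationError",
    "read_abundance_table",
    "write_abundance_table",
    "to_relative",
    "aggregate_taxa",
    "top_n_taxa",
    "load_table1_fixture",
    "write_edge_list",
    "read_edge_list",
    "STAGE_DAYS",
]

#: Stage label -> fermentation day (methods text; one figure caption prints
#: day 12 for stage E, the methods day 13 is kept).
STAGE_DAYS = {"A": 0, "B": 3, "C": 6, "D": 9, "E": 13, "F": 16}

_REL_TOL = 1e-6  # row-sum tolerance for auto-detecting relative mode

EDGE_COLUMNS = ["node_a", "node_b", "type_a", "type_b", "r", "p", "sign"]


class ValidationError(ValueError):
    """Raised when a table violates its structural invariants."""


@dataclass
class AbundanceTable:
    """Samples x taxa abundance matrix with stage/replicate metadata.

    ``data`` is a DataFrame indexed by sample id with one numeric column per
    taxon; ``stage`` and ``replicate`` are Series aligned to the same index.
    ``mode`` is ``"counts"`` or ``"relative"``.
    """

    data: pd.DataFrame
    stage: pd.Series
    replicate: pd.Series
    kingdom: str = "fungal"
    rank: str = "genus"
    mode: str = "counts"
    #: True for a column subset of a relative table (rows then sum to < 1)
    subcomposition: bool = False

    def __post_init__(self) -> None:
        if self.data.shape[0] == 0 or self.data.shape[1] == 0:
            raise ValidationError("abundance table is empty")
        if self.mode not in ("counts", "relative"):
            raise ValidationError(f"unknown mode {self.mode!r}")
        vals = self.data.to_numpy(dtype=float)
        if np.isnan(vals).any():
            raise ValidationError("abundance table contains missing values")
        if (vals < 0).any():
            i, j = np.argwhere(vals < 0)[0]
            raise ValidationError(
                f"negative abundance at sample {self.data.index[i]!r}, "
                f"taxon {self.data.columns[j]!r}"
            )
        if self.data.columns.duplicated().any():
            dup = self.data.columns[self.data.columns.duplicated()][0]
            raise ValidationError(f"duplicate taxon name {dup!r}")
        pairs = list(zip(self.stage, self.replicate))
        if len(pairs) != len(set(pairs)):
            raise ValidationError("duplicate (stage, replicate) pair")
        if self.mode == "relative" and not self.subcomposition:
            sums = vals.sum(axis=1)
            if not np.allclose(sums, 1.0, atol=1e-9):
                raise ValidationError("relative-mode rows must sum to 1")

    @property
    def taxa(self) -> list[str]:
        return list(self.data.columns)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def stage_means(self) -> pd.DataFrame:
        """Per-stage mean abundance (stages in first-appearance order)."""
        order = list(dict.fromkeys(self.stage))
        grouped = self.data.groupby(self.stage.to_numpy()).mean()
        return grouped.loc[order]


@dataclass
class VolatileTable:
    """Concentration matrix (ug/L); rows are stages or replicate samples.

    Not-detected entries are NaN.  ``compound_class`` maps each compound to
    one of {ester, alcohol, aldehyde, ketone, terpene, phenol, acid}.  When
    rows are replicate samples, ``stage``/``replicate`` are aligned Series;
    for a per-stage table they are None and the index holds stage labels.
    """

    concentrations: pd.DataFrame
    compound_class: pd.Series
    sd: pd.DataFrame | None = None
    retention_index: pd.Series | None = None
    stage: pd.Series | None = None
    replicate: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.concentrations.columns.duplicated().any():
            raise ValidationError("duplicate compound name")
        vals = self.concentrations.to_numpy(dtype=float)
        if np.nanmin(vals, initial=0.0) < 0:
            raise ValidationError("negative concentration")
        missing = set(self.concentrations.columns) - set(self.compound_class.index)
        if missing:
            raise ValidationError(f"compounds without class label: {sorted(missing)}")

    @property
    def compounds(self) -> list[str]:
        return list(self.concentrations.columns)

    @property
    def stages(self) -> list[str]:
        if self.stage is not None:
            return list(dict.fromkeys(self.stage))
        return list(self.concentrations.index)

    def stage_means(self) -> pd.DataFrame:
        if self.stage is None:
            return self.concentrations
        order = list(dict.fromkeys(self.stage))
        return self.concentrations.groupby(self.stage.to_numpy()).mean().loc[order]

    def filled(self, value: float = 0.0) -> pd.DataFrame:
        """Concentrations with not-detected entries replaced by ``value``."""
        return self.concentrations.fillna(value)


@dataclass
class OdorThresholds:
    """Per-compound odor thresholds (ug/L), as [low, high] intervals."""

    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        for col in ("threshold_low", "threshold_high"):
            if col not in self.table.columns:
                raise ValidationError(f"threshold table missing column {col!r}")
        low = self.table["threshold_low"]
        high = self.table["threshold_high"]
        if (low.dropna() <= 0).any() or (high.dropna() <= 0).any():
            raise ValidationError("odor thresholds must be strictly positive")
        both = low.notna() & high.notna()
        if (high[both] < low[both]).any():
            raise ValidationError("threshold_high < threshold_low")

    def value(self, compound: str, policy: str = "low") -> float:
        """Threshold under a policy in {low, high, midpoint}; NaN if unknown."""
        if compound not in self.table.index:
            return float("nan")
        low = self.table.at[compound, "threshold_low"]
        high = self.table.at[compound, "threshold_high"]
        if policy == "low":
            return float(low)
        if policy == "high":
            return float(high)
        if policy == "midpoint":
            return float((low + high) / 2.0)
        raise ValueError(f"unknown threshold policy {policy!r}")


# ---------------------------------------------------------------------------
# abundance-table I/O and transforms
# ---------------------------------------------------------------------------

def read_abundance_table(path, kingdom: str = "fungal", rank: str = "genus") -> AbundanceTable:
    """Read a TSV abundance table (rows = samples, columns = taxa).

    The file must have a ``stage`` and a ``replicate`` column; every other
    column is a taxon.  Mode is auto-detected: if every row sums to 1 within
    1e-6 the table is taken as relative abundances, otherwise as counts.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    for col in ("stage", "replicate"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing required column {col!r}")
    stage = df["stage"].astype(str)
    replicate = df["replicate"].astype(int)
    values = df.drop(columns=["stage", "replicate"]).astype(float)
    sums = values.to_numpy().sum(axis=1)
    mode = "relative" if np.allclose(sums, 1.0, atol=_REL_TOL) else "counts"
    if mode == "relative":
        # renormalise away round-trip noise below the detection tolerance
        values = values.div(values.sum(axis=1), axis=0)
    return AbundanceTable(values, stage, replicate, kingdom=kingdom, rank=rank, mode=mode)


def write_abundance_table(t: AbundanceTable, path) -> None:
    out = t.data.copy()
    out.insert(0, "replicate", t.replicate.to_numpy())
    out.insert(0, "stage", t.stage.to_numpy())
    out.to_csv(path, sep="\t", index_label="sample")


def to_relative(t: AbundanceTable) -> AbundanceTable:
    """Normalise a counts table to per-sample relative abundances."""
    if t.mode == "relative":
        return t
    totals = t.data.sum(axis=1)
    zero = totals[totals == 0]
    if len(zero):
        raise ValidationError(f"sample {zero.index[0]!r} has zero total abundance")
    rel = t.data.div(totals, axis=0)
    return AbundanceTable(rel, t.stage, t.replicate, kingdom=t.kingdom,
                          rank=t.rank, mode="relative")


def aggregate_taxa(t: AbundanceTable, mapping: dict[str, str],
                   other: str = "Other", rank: str = "genus") -> AbundanceTable:
    """Sum taxa into groups given a taxon -> group mapping.

    Taxa absent from the mapping are pooled into ``other``.  Per-sample
    totals are conserved exactly (the operation is a column regrouping).
    """
    if not mapping:
        raise ValidationError("empty taxonomy mapping")
    groups = [mapping.get(taxon, other) for taxon in t.data.columns]
    agg = t.data.T.groupby(pd.Index(groups, name="group")).sum().T
    # keep first-appearance order of groups rather than alphabetical
    order = list(dict.fromkeys(groups))
    agg = agg[order]
    agg.columns.name = None
    return AbundanceTable(agg, t.stage, t.replicate, kingdom=t.kingdom,
                          rank=rank, mode=t.mode)


def top_n_taxa(t: AbundanceTable, n: int) -> AbundanceTable:
    """Keep the ``n`` taxa of highest mean relative abundance.

    Ties are broken lexicographically by taxon name (smaller name ranks
    first).  ``n`` larger than the table keeps everything.
    """
    if n <= 0:
        raise ValidationError("n must be positive")
    if t.mode != "relative":
        raise ValidationError("top_n_taxa requires a relative-abundance table")
    means = t.data.mean(axis=0)
    ranking = sorted(means.index, key=lambda name: (-means[name], name))
    keep = ranking[:n]
    return AbundanceTable(t.data[keep], t.stage, t.replicate, kingdom=t.kingdom,
                          rank=t.rank, mode=t.mode,
                          subcomposition=len(keep) < t.data.shape[1] or t.subcomposition)


# ---------------------------------------------------------------------------
# packaged volatile fixture
# ---------------------------------------------------------------------------

def _parse_threshold(text: str) -> tuple[float, float]:
    text = text.strip()
    if text in ("", "/"):
        return (float("nan"), float("nan"))
    if "-" in text:
        low, high = text.split("-")
        return (float(low), float(high))
    return (float(text), float(text))


def load_table1_fixture() -> tuple[VolatileTable, OdorThresholds]:
    """Load the packaged 53-compound volatile table of flat-peach-wine
    fermentation (stages A-F, means of three parallel runs, ug/L).

    Returns the concentration table (stage x compound means, with the
    per-stage standard deviations on ``sd`` and the source's printed OAV
    band on ``printed_band``) and the odor-threshold table.  "Nd" cells are
    NaN; threshold ranges such as "20-50" become [low, high]; "/" means no
    threshold is known.
    """
    ref = importlib.resources.files("peachferm.data") / "table1_volatiles.csv"
    with importlib.resources.as_file(ref) as p:
        raw = pd.read_csv(p, dtype=str, keep_default_na=False)
    stages = list(STAGE_DAYS)
    conc = pd.DataFrame(index=stages, dtype=float)
    sd = pd.DataFrame(index=stages, dtype=float)
    for _, row in raw.iterrows():
        name = row["compound"]
        conc[name] = [float(row[f"mean_{s}"]) if row[f"mean_{s}"] != "Nd" else np.nan
                      for s in stages]
        sd[name] = [float(row[f"sd_{s}"]) if row[f"sd_{s}"] not in ("", "Nd") else np.nan
                    for s in stages]
    classes = pd.Series(raw["compound_class"].to_numpy(), index=raw["compound"])
    ri = pd.Series(
        [float(x) if x not in ("", "/") else np.nan for x in raw["retention_index"]],
        index=raw["compound"], name="retention_index",
    )
    vt = VolatileTable(conc, classes, sd=sd, retention_index=ri)
    vt.printed_band = pd.Series(
        [b if b else None for b in raw["oav_band"]], index=raw["compound"]
    )
    th = pd.DataFrame(
        [_parse_threshold(x) for x in raw["threshold"]],
        index=raw["compound"], columns=["threshold_low", "threshold_high"],
    )
    return vt, OdorThresholds(th)


# ---------------------------------------------------------------------------
# edge-list export (Cytoscape-style TSV)
# ---------------------------------------------------------------------------

def write_edge_list(edges, path) -> None:
    """Write correlation edges as a TSV importable by network viewers.

    ``edges`` is an iterable of objects (or mappings) with fields
    ``node_a, node_b, type_a, type_b, r, p, sign``; node types distinguish
    taxon-fungal / taxon-bacterial / volatile nodes.
    """
    rows = []
    for e in edges:
        get = e.get if isinstance(e, dict) else lambda k, _e=e: getattr(_e, k)
        rows.append({c: get(c) for c in EDGE_COLUMNS})
    pd.DataFrame(rows, columns=EDGE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_edge_list(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(EDGE_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: edge list missing columns {sorted(missing)}")
    return df
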