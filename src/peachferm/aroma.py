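"""Odor-activity-value (OAV) scoring and volatile-profile clustering.

OAV is a compound's concentration divided by its odor threshold; OAV > 1
marks a likely perceptible contributor to aroma.  Bands follow the
convention printed in semi-quantitative aroma tables: "<0.1", "0.1-1"
(both endpoints inclusive) and ">1".  Where a threshold is a range, the
default policy uses the low end (the aroma-conservative choice).

``oav_band_agreement`` compares computed bands against a table's printed
bands and reports mismatches rather than asserting agreement — published
tables are known to carry band/stage inconsistencies (for the packaged
fixture, the ethanol row).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .tables import OdorThresholds, VolatileTable

__all__ = [
    "OAVRecord",
    "band_of",
    "quantify_internal_standard",
    "compute_oav",
    "oav_table",
    "oav_band_agreement",
    "cluster_volatile_profiles",
]

BANDS = ("<0.1", "0.1-1", ">1")


@dataclass
class OAVRecord:
    compound: str
    stage: str
    concentration: float  # ug/L; NaN when not detected
    threshold: float      # ug/L; NaN when unknown
    oav: float            # NaN when undefined
    band: str | None      # None when OAV undefined


def band_of(oav: float) -> str | None:
    """Monotone step banding; [0.1, 1] is the middle band, inclusive."""
    if oav is None or np.isnan(oav):
        return None
    if oav < 0.1:
        return "<0.1"
    if oav <= 1.0:
        return "0.1-1"
    return ">1"


def quantify_internal_standard(areas, is_area: float, is_conc: float) -> np.ndarray:
    """Internal-standard semi-quantification: conc_i = area_i/IS_area x IS_conc.

    For a spike of ``v_spike`` mL at ``c_stock`` ug/mL into ``v_sample`` mL,
    the effective IS concentration is v_spike x c_stock / v_sample (e.g.
    2 uL of 30 mg/mL into 10 mL gives 6000 ug/L).
    """
    if is_area <= 0 or is_conc <= 0:
        raise ValueError("internal-standard area and concentration must be positive")
    return np.asarray(areas, dtype=float) / is_area * is_conc


def compute_oav(
    v: VolatileTable,
    th: OdorThresholds,
    stage: str,
    threshold_policy: str = "low",
) -> list[OAVRecord]:
    """One OAV record per compound at the given stage.

    Compounds not detected at the stage, or lacking a threshold, yield a
    record with ``oav`` NaN and no band (they are reported, not dropped).
    """
    means = v.stage_means()
    if stage not in means.index:
        raise ValueError(f"unknown stage {stage!r}")
    records = []
    for compound in v.compounds:
        conc = float(means.at[stage, compound])
        thr = th.value(compound, policy=threshold_policy)
        oav = conc / thr if np.isfinite(conc) and np.isfinite(thr) else float("nan")
        records.append(
            OAVRecord(compound, stage, conc, thr, oav, band_of(oav))
        )
    return records


def oav_table(v: VolatileTable, th: OdorThresholds,
              threshold_policy: str = "low") -> pd.DataFrame:
    """Per-stage OAV matrix (stages x compounds; NaN where undefined)."""
    means = v.stage_means()
    out = pd.DataFrame(index=means.index, columns=v.compounds, dtype=float)
    for compound in v.compounds:
        thr = th.value(compound, policy=threshold_policy)
        out[compound] = means[compound] / thr if np.isfinite(thr) else np.nan
    return out


def oav_band_agreement(
    v: VolatileTable,
    th: OdorThresholds,
    stage: str = "F",
    threshold_policy: str = "low",
) -> pd.DataFrame:
    """Computed vs printed OAV bands, with a per-compound status.

    Status is one of ``match``, ``mismatch`` (both bands defined, unequal),
    ``undetected_at_stage`` (printed band but no concentration at the
    stage), ``no_threshold``, and ``not_printed``.  Requires the table to
    carry a ``printed_band`` attribute (the packaged fixture does).
    """
    printed = getattr(v, "printed_band", None)
    if printed is None:
        printed = pd.Series(None, index=v.compounds, dtype=object)
    rows = []
    for rec in compute_oav(v, th, stage, threshold_policy):
        want = printed.get(rec.compound)
        if want is not None and (not isinstance(want, str) or not want):
            want = None  # NaN / empty markers mean no printed band
        if rec.band is not None and want:
            status = "match" if rec.band == want else "mismatch"
        elif want and not np.isfinite(rec.concentration):
            status = "undetected_at_stage"
        elif want and np.isnan(rec.threshold):
            status = "no_threshold"
        else:
            status = "not_printed" if not want else "mismatch"
        rows.append(
            {
                "compound": rec.compound,
                "stage": rec.stage,
                "oav": rec.oav,
                "computed_band": rec.band,
                "printed_band": want,
                "status": status,
            }
        )
    return pd.DataFrame(rows)


def cluster_volatile_profiles(
    v: VolatileTable,
    k: int = 2,
    metric: str = "euclidean",
    method: str = "average",
) -> pd.Series:
    """Agglomerative clustering of per-compound stage profiles.

    Profiles are z-scored across stages (not-detected filled with 0 first,
    i.e. below detection); compounds with a constant profile get z = 0.
    Returns a cluster label (1..k) per compound; labels are deterministic
    and invariant to compound ordering (scipy's linkage on a fixed distance
    matrix).
    """
    if k < 2 or k > len(v.compounds):
        raise ValueError("k must be in [2, number of compounds]")
    profiles = v.stage_means().fillna(0.0).T  # compounds x stages
    mu = profiles.mean(axis=1)
    sd = profiles.std(axis=1, ddof=0)
    z = profiles.sub(mu, axis=0).div(sd.replace(0.0, 1.0), axis=0)
    order = np.argsort(z.index)  # canonical order for determinism
    zs = z.iloc[order]
    labels = fcluster(linkage(pdist(zs.to_numpy(), metric=metric), method=method),
                      t=k, criterion="maxclust")
    out = pd.Series(labels, index=zs.index, name="cluster")
    return out.loc[z.index]
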