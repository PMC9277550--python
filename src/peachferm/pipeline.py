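"""Config-driven orchestration of the full analysis.

A :class:`RunConfig` names either real input tables (abundance TSVs plus a
volatile/threshold CSV pair) or a ``synthetic`` block; :func:`run_pipeline`
then executes diversity -> ordination -> aroma -> association -> PLS/VIP ->
core screen in order, writes every artifact under the output directory and
returns a machine-readable report.  All stage thresholds default to the
conventional values (network |r| > 0.7 / 0.9 with p < 0.01; VIP > 1.0;
screen |r| > 0.6; top 40 taxa), and a single seed drives every random
step, so identical config + seed gives identical reports.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .aroma import cluster_volatile_profiles, oav_band_agreement, oav_table
from .association import cooccurrence_network, correlation_matrix, taxa_volatile_correlations
from .diversity import alpha_diversity, stage_otu_sets
from .ordination import pca
from .screen import ScreenConfig, bipartite_network, run_screen
from .synth import make_screening_dataset, truth_report
from .tables import (
    load_table1_fixture,
    read_abundance_table,
    to_relative,
    top_n_taxa,
    write_abundance_table,
    write_edge_list,
)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    outdir: str = "peachferm_out"
    seed: int = 0
    abundance_path: str | None = None   # TSV; real-data mode
    volatile_path: str | None = None    # CSV; None = packaged fixture
    synthetic: dict | None = None       # kwargs of make_screening_dataset
    network_r: float = 0.7
    network_p: float = 0.01
    oav_stage: str = "F"
    screen: ScreenConfig = field(default_factory=ScreenConfig)
    n_clusters: int = 2

    def __post_init__(self) -> None:
        if self.abundance_path is None and self.synthetic is None:
            raise ValueError("config needs either real input paths or a synthetic block")
        if self.abundance_path is not None and self.synthetic is not None:
            raise ValueError("exactly one of real paths / synthetic block, not both")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        screen = ScreenConfig(**raw.pop("screen", {}))
        return cls(screen=screen, **raw)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all stages; returns (and writes) the run report."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"version": __version__, "seed": cfg.seed, "stages": {},
                    "config": _config_echo(cfg)}
    try:
        # ------------------------------------------------------------ inputs
        truth = None
        if cfg.synthetic is not None:
            kwargs = dict(cfg.synthetic)
            kwargs.setdefault("seed", cfg.seed)
            abund, volatiles, truth = make_screening_dataset(**kwargs)
            write_abundance_table(abund, out / "abundance.tsv")
            volatiles.concentrations.to_csv(out / "volatiles.csv")
            (out / "truth.json").write_text(json.dumps({
                "core_taxa": sorted(truth.core_taxa),
                "core_compounds": sorted(truth.core_compounds),
                "noise_sd": truth.noise_sd,
                "seed": kwargs["seed"],
            }, indent=2))
            thresholds = None
        else:
            abund = read_abundance_table(cfg.abundance_path)
            if cfg.volatile_path is None:
                volatiles, thresholds = load_table1_fixture()
            else:
                raise NotImplementedError("external volatile CSVs: use the library API")
        report["stages"]["inputs"] = {
            "n_samples": len(abund.sample_ids), "n_taxa": len(abund.taxa),
            "n_compounds": len(volatiles.compounds), "status": "ok",
        }

        # --------------------------------------------------------- diversity
        alpha = alpha_diversity(abund)
        alpha.to_csv(out / "alpha_diversity.csv")
        otus = stage_otu_sets(abund)
        report["stages"]["diversity"] = {
            "status": "ok",
            "n_common_otus": otus["n_common"],
            "per_stage_counts": otus["per_stage_counts"],
        }

        # -------------------------------------------------------- ordination
        rel = to_relative(abund)
        community = pca(rel.stage_means(), center=True, unit_variance=False)
        vol_means = volatiles.stage_means().fillna(0.0)
        vol_pca = pca(vol_means, center=True, unit_variance=True)
        community.scores.to_csv(out / "pca_community_scores.csv")
        vol_pca.scores.to_csv(out / "pca_volatile_scores.csv")
        report["stages"]["ordination"] = {
            "status": "ok",
            "community_var_explained": [round(float(x), 4) for x in community.var_explained[:2]],
            "volatile_var_explained": [round(float(x), 4) for x in vol_pca.var_explained[:2]],
        }

        # ------------------------------------------------------------- aroma
        aroma_report: dict = {"status": "ok"}
        if cfg.synthetic is None:
            fixture_v, fixture_th = (volatiles, thresholds)
            oav = oav_table(fixture_v, fixture_th)
            oav.to_csv(out / "oav_per_stage.csv")
            agreement = oav_band_agreement(fixture_v, fixture_th, stage=cfg.oav_stage)
            agreement.to_csv(out / "oav_band_agreement.csv", index=False)
            aroma_report["n_band_mismatches"] = int((agreement["status"] == "mismatch").sum())
        clusters = cluster_volatile_profiles(volatiles, k=cfg.n_clusters)
        clusters.to_csv(out / "volatile_clusters.csv")
        aroma_report["cluster_sizes"] = clusters.value_counts().sort_index().tolist()
        report["stages"]["aroma"] = aroma_report

        # ------------------------------------------------------- association
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            R, P = correlation_matrix(rel.data)
            edges = cooccurrence_network(R, P, cfg.network_r, cfg.network_p,
                                         node_types=f"taxon-{abund.kingdom}")
        write_edge_list(edges, out / "cooccurrence_edges.tsv")
        report["stages"]["association"] = {"status": "ok", "n_edges": len(edges)}

        # --------------------------------------------------- pls + screening
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res, model = run_screen(abund, volatiles, cfg.screen)
        res.taxa.to_csv(out / "screen_taxa.csv")
        res.volatiles.to_csv(out / "screen_volatiles.csv")
        model.vip.to_csv(out / "vip_taxa.csv")
        bip = bipartite_network(res)
        write_edge_list(bip, out / "bipartite_edges.tsv")
        screen_report = {
            "status": "ok",
            "n_components": model.A,
            "n_core_taxa": len(res.core_taxa),
            "n_core_volatiles": len(res.core_volatiles),
            "n_bipartite_edges": len(bip),
            "core_taxa": res.core_taxa,
        }
        if truth is not None:
            planted, _ = truth_report(truth)
            recovered = set(res.core_taxa)
            union = planted | recovered
            screen_report["jaccard_vs_truth"] = (
                round(len(planted & recovered) / len(union), 4) if union else 1.0
            )
        report["stages"]["screen"] = screen_report
    except Exception as exc:  # partial outputs retained with a FAILED marker
        report["status"] = "FAILED"
        report["error"] = f"{type(exc).__name__}: {exc}"
        (out / "FAILED").write_text(report["error"])
        (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        raise
    report["status"] = "ok"
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report


def _config_echo(cfg: RunConfig) -> dict:
    d = dataclasses.asdict(cfg)
    return json.loads(json.dumps(d, default=str))
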