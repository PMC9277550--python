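"""Synthetic fermentation data with known microbe -> volatile associations.

The generator emulates the statistical structure of a staged spontaneous
fermentation experiment:

* **succession** — each taxon follows a latent trajectory across stages
  (rising, falling, transient or stable, parameterised by a logistic
  midpoint and rate on the log-intensity scale);
* **compositionality** — per-sample counts are drawn Dirichlet-multinomial
  around the stage's latent composition, so replicates are overdispersed
  and rows sum to the sequencing depth;
* **planted associations** — volatile concentrations are noisy log-linear
  functions of selected taxa's relative abundances, with the full effect
  matrix ``B`` retained as ground truth for recovery benchmarks.

All randomness flows from explicit integer seeds via ``numpy``'s PCG64
generator, so identical parameters give byte-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tables import AbundanceTable, VolatileTable, to_relative

__all__ = [
    "TaxonProfile",
    "SuccessionParams",
    "AssociationTruth",
    "generate_succession",
    "generate_volatiles",
    "truth_report",
    "make_screening_dataset",
]

PROFILE_KINDS = ("rising", "falling", "transient", "stable")


@dataclass
class TaxonProfile:
    """Latent trajectory of one taxon across stages.

    log-intensity(s) = log(base) + amplitude * g(s), where g is a logistic
    ramp (rising/falling, midpoint/rate in stage units), a Gaussian bump
    (transient) or identically zero (stable).
    """

    name: str
    kind: str = "stable"
    midpoint: float = 2.5
    rate: float = 1.0
    amplitude: float = 2.0
    base: float = 1.0

    def log_intensity(self, stage_idx: np.ndarray) -> np.ndarray:
        s = np.asarray(stage_idx, dtype=float)
        if self.kind == "rising":
            g = 1.0 / (1.0 + np.exp(-(s - self.midpoint) / self.rate))
        elif self.kind == "falling":
            g = 1.0 - 1.0 / (1.0 + np.exp(-(s - self.midpoint) / self.rate))
        elif self.kind == "transient":
            g = np.exp(-((s - self.midpoint) ** 2) / (2.0 * self.rate**2))
        elif self.kind == "stable":
            g = np.zeros_like(s)
        else:
            raise ValueError(f"unknown trajectory kind {self.kind!r}")
        return np.log(self.base) + self.amplitude * g


@dataclass
class SuccessionParams:
    """Design of a synthetic succession experiment."""

    n_taxa: int = 40
    n_stages: int = 6
    n_replicates: int = 3
    profiles: list[TaxonProfile] | None = None
    sequencing_depth: int = 50_000
    concentration: float = 300.0  # Dirichlet overdispersion; inf = noiseless
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 2:
            raise ValueError("need at least 2 taxa")
        if self.sequencing_depth <= 0 or self.concentration <= 0:
            raise ValueError("depth and concentration must be positive")


@dataclass
class AssociationTruth:
    """Ground-truth log-linear effects of taxa on volatile concentrations.

    log C_ik = baseline_k + sum_j B_jk * relabund_ij + eps,  eps ~ N(0, sd^2)
    """

    B: pd.DataFrame  # taxa x compounds
    baseline: pd.Series  # per compound, log ug/L
    noise_sd: float = 0.05
    compound_class: pd.Series | None = None

    @property
    def core_taxa(self) -> set[str]:
        nz = (self.B != 0).any(axis=1)
        return set(self.B.index[nz])

    @property
    def core_compounds(self) -> set[str]:
        nz = (self.B != 0).any(axis=0)
        return set(self.B.columns[nz])


def truth_report(truth: AssociationTruth) -> tuple[set[str], set[str]]:
    """Ground-truth core sets: taxa with a nonzero row of B, compounds with
    a nonzero column."""
    return truth.core_taxa, truth.core_compounds


def _default_profiles(p: SuccessionParams, rng: np.random.Generator) -> list[TaxonProfile]:
    profiles = []
    for j in range(p.n_taxa):
        kind = PROFILE_KINDS[rng.integers(len(PROFILE_KINDS))]
        profiles.append(
            TaxonProfile(
                name=f"taxon_{j:02d}",
                kind=kind,
                midpoint=float(rng.uniform(1.0, p.n_stages - 2.0)),
                rate=float(rng.uniform(0.6, 1.5)),
                amplitude=float(rng.uniform(1.5, 3.0)),
                base=float(rng.lognormal(0.0, 1.0)),
            )
        )
    return profiles


def generate_succession(p: SuccessionParams) -> AbundanceTable:
    """Draw a counts-mode abundance table under the succession model.

    Stage compositions are the normalised latent intensities; each replicate
    draws a Dirichlet(concentration x composition) realisation and then a
    multinomial at the sequencing depth, so per-sample totals equal the
    depth exactly.  ``concentration=inf`` removes both noise sources and
    returns rounded expected counts (the noiseless limit).
    """
    rng = np.random.default_rng(p.seed)
    profiles = p.profiles if p.profiles is not None else _default_profiles(p, rng)
    if len(profiles) != p.n_taxa:
        raise ValueError("profiles length must equal n_taxa")
    stage_idx = np.arange(p.n_stages)
    log_int = np.stack([pr.log_intensity(stage_idx) for pr in profiles])  # taxa x stages
    comp = np.exp(log_int)
    comp /= comp.sum(axis=0, keepdims=True)

    return _sample_counts(comp, [pr.name for pr in profiles], p, rng)


def _sample_counts(comp: np.ndarray, names: list[str], p: SuccessionParams,
                   rng: np.random.Generator) -> AbundanceTable:
    """Dirichlet-multinomial replicate counts around stage compositions
    (``comp`` is taxa x stages, columns summing to 1)."""
    stages = [chr(ord("A") + s) for s in range(p.n_stages)]
    rows, stage_col, rep_col, ids = [], [], [], []
    for s, stage in enumerate(stages):
        for r in range(1, p.n_replicates + 1):
            if np.isinf(p.concentration):
                counts = np.rint(comp[:, s] * p.sequencing_depth).astype(int)
            else:
                q = rng.dirichlet(np.maximum(p.concentration * comp[:, s], 1e-9))
                counts = rng.multinomial(p.sequencing_depth, q)
            rows.append(counts)
            stage_col.append(stage)
            rep_col.append(r)
            ids.append(f"{stage}{r}")
    data = pd.DataFrame(rows, index=ids, columns=names)
    return AbundanceTable(
        data,
        pd.Series(stage_col, index=ids),
        pd.Series(rep_col, index=ids),
        kingdom="fungal",
        rank="genus",
        mode="counts",
    )


def generate_volatiles(
    abund: AbundanceTable,
    truth: AssociationTruth,
    seed: int = 0,
    log_scale_response: bool = True,
) -> VolatileTable:
    """Generate per-sample volatile concentrations from the planted model.

    With ``log_scale_response`` (default) the linear predictor acts on the
    log scale and concentrations are its exponential (positive by
    construction); the linear-scale switch emits the predictor directly,
    clipped at zero, as a worst case for correlation-based screens.
    """
    rel = to_relative(abund) if abund.mode == "counts" else abund
    if list(truth.B.index) != list(rel.data.columns):
        raise ValueError("truth.B rows must match the abundance table's taxa")
    rng = np.random.default_rng(seed)
    eta = (
        rel.data.to_numpy() @ truth.B.to_numpy()
        + truth.baseline.to_numpy()[None, :]
    )
    eps = rng.normal(0.0, truth.noise_sd, size=eta.shape) if truth.noise_sd > 0 else 0.0
    conc = np.exp(eta + eps) if log_scale_response else np.maximum(eta + eps, 0.0)
    df = pd.DataFrame(conc, index=rel.data.index, columns=truth.B.columns)
    classes = (
        truth.compound_class
        if truth.compound_class is not None
        else pd.Series("ester", index=truth.B.columns)
    )
    return VolatileTable(df, classes, stage=rel.stage, replicate=rel.replicate)


def make_screening_dataset(
    seed: int = 1,
    n_taxa: int = 40,
    n_core: int = 5,
    n_compounds: int = 12,
    compounds_per_core: int = 2,
    effect: float = 3.0,
    noise_sd: float = 0.05,
    n_stages: int = 6,
    n_replicates: int = 3,
    sequencing_depth: int = 50_000,
    concentration: float = 300.0,
    null_effects: bool = False,
) -> tuple[AbundanceTable, VolatileTable, AssociationTruth]:
    """Benchmark dataset for the core-microbiota screen.

    The planted core taxa (5 by default) redistribute a fixed fraction of
    the community among themselves along well-separated trajectories — the
    classic succession picture, where late fermenters replace the initial
    flora — and each drives ``compounds_per_core`` volatiles with
    log-scale effect ``effect``.  Background taxa hold fixed shares of the
    remaining mass, so their expected relative abundances are stage-stable:
    a background taxon co-varying with a core taxon (whether through shared
    dynamics or compositional closure) would be observationally confounded
    with it, and no correlation-based screen could separate the two, so the
    benchmark excludes that degeneracy by construction.  Replicates keep
    the full Dirichlet-multinomial noise.  ``null_effects=True`` zeroes B
    for false-positive control runs while keeping everything else
    identical.
    """
    if n_core * compounds_per_core > n_compounds:
        raise ValueError("not enough compounds for the requested core effects")
    rng = np.random.default_rng(seed)
    names = [f"taxon_{j:02d}" for j in range(n_taxa)]
    # distinct dynamic shapes for the planted cores, cycled if n_core > 5
    core_shapes = [
        TaxonProfile("", "rising", midpoint=1.5, rate=0.8, amplitude=2.5),
        TaxonProfile("", "falling", midpoint=1.5, rate=0.8, amplitude=2.5),
        TaxonProfile("", "rising", midpoint=n_stages - 2.5, rate=0.8, amplitude=2.5),
        TaxonProfile("", "falling", midpoint=n_stages - 2.5, rate=0.8, amplitude=2.5),
        TaxonProfile("", "transient", midpoint=(n_stages - 1) / 2.0, rate=0.8,
                     amplitude=2.5),
    ]
    stage_idx = np.arange(n_stages)
    core_int = np.stack([
        np.exp(core_shapes[j % len(core_shapes)].log_intensity(stage_idx))
        for j in range(n_core)
    ])  # n_core x n_stages
    core_mass = 0.5  # community fraction the succession redistributes
    core_comp = core_mass * core_int / core_int.sum(axis=0, keepdims=True)
    bg_shares = rng.lognormal(0.0, 1.0, size=n_taxa - n_core)
    bg_shares /= bg_shares.sum()
    bg_comp = np.repeat(((1.0 - core_mass) * bg_shares)[:, None], n_stages, axis=1)
    comp = np.vstack([core_comp, bg_comp])
    params = SuccessionParams(
        n_taxa=n_taxa,
        n_stages=n_stages,
        n_replicates=n_replicates,
        sequencing_depth=sequencing_depth,
        concentration=concentration,
        seed=seed,
    )
    abund = _sample_counts(comp, names, params, rng)

    compounds = [f"compound_{k:02d}" for k in range(n_compounds)]
    B = pd.DataFrame(0.0, index=names, columns=compounds)
    if not null_effects:
        k = 0
        for j in range(n_core):
            for _ in range(compounds_per_core):
                sign = -1.0 if (j == n_core - 1 and k % 2 == 1) else 1.0
                B.iloc[j, k] = sign * effect
                k += 1
    baseline = pd.Series(rng.normal(np.log(100.0), 1.0, size=n_compounds),
                         index=compounds)
    truth = AssociationTruth(B, baseline, noise_sd=noise_sd)
    volatiles = generate_volatiles(abund, truth, seed=seed + 10_007)
    return abund, volatiles, truth
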