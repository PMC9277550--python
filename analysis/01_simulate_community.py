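#!/usr/bin/env python
"""Generate the synthetic fermentation dataset used by the later analyses.

Emits a 6-stage x 3-replicate community (40 genera: 5 dynamic core taxa
redistributing half the community, 35 stage-stable background genera), the
matching 12-compound volatile table, and the planted ground-truth effect
matrix.  Everything downstream (diversity, ordination, networks, screen)
runs on these tables; the ground truth makes the screen auditable.
"""

import json
from pathlib import Path

from peachferm import make_screening_dataset, to_relative, truth_report
from peachferm.tables import write_abundance_table

OUT = Path(__file__).resolve().parents[1] / "results" / "synthetic"
SEED = 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    abund, volatiles, truth = make_screening_dataset(seed=SEED)
    write_abundance_table(abund, OUT / "abundance_counts.tsv")
    write_abundance_table(to_relative(abund), OUT / "abundance_relative.tsv")
    volatiles.concentrations.to_csv(OUT / "volatiles_ugL.csv")
    core_taxa, core_compounds = truth_report(truth)
    (OUT / "truth.json").write_text(json.dumps({
        "seed": SEED,
        "core_taxa": sorted(core_taxa),
        "core_compounds": sorted(core_compounds),
        "noise_sd": truth.noise_sd,
    }, indent=2))
    rel = to_relative(abund).stage_means()
    print(f"wrote {abund.data.shape[0]} samples x {abund.data.shape[1]} taxa to {OUT}")
    print("planted core taxa:", sorted(core_taxa))
    print("core relative-abundance ranges across stages:")
    for t in sorted(core_taxa):
        print(f"  {t}: {rel[t].min():.3f} -> {rel[t].max():.3f}")


if __name__ == "__main__":
    main()
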