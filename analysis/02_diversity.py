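#!/usr/bin/env python
"""Alpha diversity and stage-wise OTU sharing on the synthetic community.

Computes observed richness, Chao1, Shannon, Simpson and Good's coverage for
every sample, plus the per-stage presence sets and their intersection — the
standard sequencing-quality summary of a staged fermentation experiment.
"""

import json
from pathlib import Path

from peachferm import alpha_diversity, read_abundance_table, stage_otu_sets

BASE = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    abund = read_abundance_table(BASE / "synthetic" / "abundance_counts.tsv")
    alpha = alpha_diversity(abund)
    alpha.to_csv(BASE / "alpha_diversity.csv")
    otus = stage_otu_sets(abund)
    summary = {
        "per_stage_taxon_counts": otus["per_stage_counts"],
        "n_common_all_stages": otus["n_common"],
        "per_stage_unique": otus["per_stage_unique"],
    }
    (BASE / "otu_sharing.json").write_text(json.dumps(summary, indent=2))
    print(alpha.round(3).to_string())
    print(f"\ntaxa present in all stages: {otus['n_common']}")
    print("coverage is ~1 throughout: at depth 50,000 almost no taxon is a singleton")


if __name__ == "__main__":
    main()
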