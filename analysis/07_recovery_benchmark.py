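#!/usr/bin/env python
"""Recovery and false-positive benchmark of the screen over 20 seeds.

Repeats the full generate -> correlate -> PLS -> screen pipeline on seeds
1..20 with planted effects (|B| = 3, sigma = 0.05) and with all effects
zeroed, reporting mean Jaccard recovery of the planted core taxa and the
mean number of false-positive core calls under the null.
"""

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from peachferm import make_screening_dataset, run_screen

BASE = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for seed in range(1, 21):
            ab, vo, tr = make_screening_dataset(seed=seed)
            res, model = run_screen(ab, vo)
            planted, rec = tr.core_taxa, set(res.core_taxa)
            ab0, vo0, _ = make_screening_dataset(seed=seed, null_effects=True)
            res0, _ = run_screen(ab0, vo0)
            rows.append({
                "seed": seed,
                "A": model.A,
                "recall": len(planted & rec) / len(planted),
                "jaccard": len(planted & rec) / len(planted | rec),
                "null_false_positives": len(res0.core_taxa),
            })
    df = pd.DataFrame(rows).set_index("seed")
    df.to_csv(BASE / "recovery_benchmark.csv")
    print(df.to_string())
    print(f"\nmean Jaccard: {df['jaccard'].mean():.3f}  "
          f"mean recall: {df['recall'].mean():.3f}  "
          f"mean null FP: {df['null_false_positives'].mean():.2f}")
    print("false positives trace to chance |r| > 0.6 at n = 18 (about 0.1 "
          "probability per background taxon across a 12-compound panel); "
          "the PLS weights are built from those same correlations, so the "
          "VIP gate cannot fully remove them — see docs/methods.md.")


if __name__ == "__main__":
    main()
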