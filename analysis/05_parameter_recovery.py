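"""Replicate-level parameter recovery at study scale.

Simulates several independent datasets at the study conditions, fits each
with the short chain preset, and reports how often the model-averaged 95%
credible intervals cover the generating values and how strongly the
generating effects (grassland for the prey; the two road-density terms in
the predator's prey-absent block) are selected.
"""

from pathlib import Path
import sys

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "tests"))
from test_acceptance import run_recovery  # reuse the replicate driver

OUT = Path(__file__).resolve().parents[1] / "results"
N_REPLICATES = 10
SEED0 = 5000


def main() -> None:
    covered, checks, majorities = run_recovery(N_REPLICATES, seed0=SEED0)
    table = pd.DataFrame(
        {
            "quantity": [
                "CI coverage (6 parameters x replicates)",
                "road (cell) selected > 0.5",
                "road (neighborhood) selected > 0.5",
                "grassland selected > 0.5",
            ],
            "value": [
                f"{covered}/{checks}",
                f"{majorities[5]}/{N_REPLICATES}",
                f"{majorities[7]}/{N_REPLICATES}",
                f"{majorities[15]}/{N_REPLICATES}",
            ],
        }
    )
    OUT.mkdir(exist_ok=True)
    table.to_csv(OUT / "recovery_summary.csv", index=False)
    print(table.to_string(index=False))
    print("\nNominal coverage is 0.95; the binomial band at this replicate count "
          "is wide, so values a few checks below nominal are expected noise.")
    print("Per-replicate inclusion of the road terms is bimodal (near 0 or near 1):"
          "\nwith ~6% predator occupancy a |slope| of about 1 sits close to the"
          "\ndetection threshold under the very wide slope prior, so whether it is"
          "\nselected depends on the landscape realization.")


if __name__ == "__main__":
    main()
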