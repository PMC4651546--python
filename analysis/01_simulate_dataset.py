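"""Generate the study-condition synthetic dataset.

Draws an 8x8 grid of 2.5-km cells with a one-cell buffer, spatially
smoothed landscape covariates, and an 11-week detection history with up to
7 daily replicates per cell-week, using the selected-model estimates as
generating values.  Writes detections.csv / covariates.csv / truth tables
under results/.
"""

import json
from pathlib import Path

import numpy as np

from cooccupancy import TrueParams, generate_landscape, scale_covariates, simulate_dataset
from cooccupancy.io import write_covariates, write_detection_history
from cooccupancy.model import params_to_dict

SEED = 1
OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    grid, raw = generate_landscape(8, 8, seed=SEED, spatial_smoothness=0.3)
    cov = scale_covariates(raw, grid)
    params = TrueParams()
    history, latent, detection = simulate_dataset(cov, params, n_weeks=11, seed=SEED + 1)

    write_detection_history(history, OUT / "detections.csv", seed=SEED)
    write_covariates(cov, OUT / "covariates.csv", seed=SEED)
    truth = params_to_dict(params.hare, params.bobcat)
    truth["seed"] = SEED
    (OUT / "truth.json").write_text(json.dumps(truth, indent=2))
    np.savetxt(OUT / "truth_z_hare.csv", latent.z_hare, fmt="%d", delimiter=",")
    np.savetxt(OUT / "truth_z_bobcat.csv", latent.z_bobcat, fmt="%d", delimiter=",")

    print(f"{history.n_cells} cells x {history.n_weeks} weeks, K max {history.k.max()}")
    print(f"true hare occupancy  {latent.z_hare.mean():.3f}  (weeks with detection "
          f"{(history.y_hare > 0).mean():.3f})")
    print(f"true bobcat occupancy {latent.z_bobcat.mean():.3f}  (weeks with detection "
          f"{(history.y_bobcat > 0).mean():.3f})")
    print(f"mean daily detection: hare {detection.p_hare.mean():.2f}, "
          f"bobcat {detection.p_bobcat.mean():.2f}")


if __name__ == "__main__":
    main()
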