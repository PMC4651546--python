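"""Posterior-predictive goodness-of-fit via Bayesian p-values.

For each posterior draw the observed weekly detection totals are compared,
through a discrepancy statistic, with totals replicated from the fitted
detection model (Y_rep ~ Binomial(K, p*Z) at that draw's p and Z).  The
Bayesian p-value is the fraction of draws in which the replicated
discrepancy reaches the observed one; values near 0 or 1 flag misfit.

The default discrepancy is the Pearson chi-square on weekly totals with an
epsilon-floored expectation; the Freeman-Tukey statistic (sqrt(Y) - sqrt(E))^2
is available as an alternative.  In power checks on sparse predator counts
the Pearson form detected unmodeled detection heterogeneity that
Freeman-Tukey missed, while both are well calibrated under the generating
model.

The detection-structure ladder fits three nested observation models —
detection constant everywhere, predator detection per cell with prey
detection per cell-week, and both per cell-week — and tabulates both
species' p-values for each, supporting the standard select-then-infer
workflow for the observation process.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .landscape import CovariateTable
from .mcmc import MCMCConfig, PosteriorSamples, run_mcmc
from .model import DetectionHistory, PriorConfig

DISCREPANCIES = ("pearson_chisq", "freeman_tukey")
_PEARSON_FLOOR = 1e-6

#: The three nested detection structures, coarsest first:
#: (name, predator structure, prey structure).
LADDER = (
    ("constant", "constant", "constant"),
    ("cell", "cell", "cell_week"),
    ("cell_week", "cell_week", "cell_week"),
)


@dataclass
class GofResult:
    """Per-draw observed and replicated discrepancies and their tail probability."""

    species: str
    discrepancy: str
    t_obs: np.ndarray
    t_rep: np.ndarray
    bayesian_p: float


def _discrepancy(y: np.ndarray, e: np.ndarray, kind: str) -> np.ndarray:
    """Sum the cell-week discrepancy over the last two axes."""
    if kind == "freeman_tukey":
        d = (np.sqrt(y) - np.sqrt(e)) ** 2
    elif kind == "pearson_chisq":
        d = (y - e) ** 2 / np.maximum(e, _PEARSON_FLOOR)
    else:
        raise ValueError(f"unknown discrepancy {kind!r}")
    return d.sum(axis=(-2, -1))


def bayesian_p_value(
    history: DetectionHistory,
    samples: PosteriorSamples,
    species: str,
    discrepancy: str = "pearson_chisq",
    seed: int | np.random.Generator | None = None,
) -> GofResult:
    """Posterior-predictive p-value for one species' weekly detection totals.

    Ties (replicated discrepancy equal to observed) count toward the
    p-value, which estimates Pr(T_rep >= T_obs | data).
    """
    if species == "hare":
        y = history.y_hare
        p_full = samples.p_hare_full()
        z = samples.z_hare_flat()
    elif species == "bobcat":
        y = history.y_bobcat
        p_full = samples.p_bobcat_full()
        z = samples.z_bobcat_flat()
    else:
        raise ValueError(f"species must be 'hare' or 'bobcat', got {species!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    rate = p_full * z  # (draws, n, T) success probability per camera day
    e = history.k * rate
    t_obs = _discrepancy(y[None, :, :], e, discrepancy)
    y_rep = rng.binomial(np.broadcast_to(history.k, rate.shape), rate)
    t_rep = _discrepancy(y_rep, e, discrepancy)
    return GofResult(
        species=species,
        discrepancy=discrepancy,
        t_obs=t_obs,
        t_rep=t_rep,
        bayesian_p=float(np.mean(t_rep >= t_obs)),
    )


def detection_structure_ladder(
    history: DetectionHistory,
    covariates: CovariateTable,
    config: MCMCConfig | None = None,
    priors: PriorConfig | None = None,
    discrepancy: str = "pearson_chisq",
    seed: int | None = None,
) -> pd.DataFrame:
    """Fit the three nested detection structures and tabulate their p-values.

    Returns one row per structure with both species' Bayesian p-values.  The
    occupancy (ecological) submodel is identical across rows; only the
    pooling of detection probabilities changes.
    """
    config = config or MCMCConfig()
    rows = []
    for i, (name, bob, hare) in enumerate(LADDER):
        cfg = replace(config, bobcat_detection=bob, hare_detection=hare)
        samples = run_mcmc(history, covariates, cfg, priors)
        rep_seed = (seed if seed is not None else cfg.seed) * 7919 + i
        res = {
            sp: bayesian_p_value(history, samples, sp, discrepancy, seed=rep_seed + 101 * j)
            for j, sp in enumerate(("hare", "bobcat"))
        }
        rows.append(
            {
                "model": name,
                "bobcat_detection": bob,
                "hare_detection": hare,
                "p_hare": res["hare"].bayesian_p,
                "p_bobcat": res["bobcat"].bayesian_p,
            }
        )
    return pd.DataFrame(rows)
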