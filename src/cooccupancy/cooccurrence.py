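"""Posterior co-occurrence summaries and beta-binomial proportion contrasts.

Each posterior draw of the two latent occupancy fields yields a 2x2
contingency table over cell-week units: both species present, predator
only, prey only, neither.  Conditional proportions from the posterior-mean
table summarize observed co-occurrence; the conjugate-beta contrast turns a
draw's counts into a probability that one conditional occupancy proportion
exceeds the other:

    theta_1 | y1, n1 ~ Beta(y1 + 1, n1 - y1 + 1)   (uniform prior)
    theta_2 | y2, n2 ~ Beta(y2 + 1, n2 - y2 + 1)
    Pr(theta_1 > theta_2) ~= mean over M joint draws of 1{theta_1 > theta_2}

Applying the contrast to every contingency draw gives a posterior
distribution of that probability, reported as mean and central 95%
interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mcmc import PosteriorSamples

TABLE_CELLS = ("both", "bobcat_only", "hare_only", "neither")


@dataclass
class ContingencyPosterior:
    """Per-draw 2x2 cell-week co-occurrence counts and their summaries."""

    counts: pd.DataFrame  # one row per draw, columns TABLE_CELLS
    total: int  # cell-weeks per draw

    def margins(self) -> pd.DataFrame:
        c = self.counts
        return pd.DataFrame(
            {
                "hare_present": c["both"] + c["hare_only"],
                "hare_absent": c["bobcat_only"] + c["neither"],
                "bobcat_present": c["both"] + c["bobcat_only"],
                "bobcat_absent": c["hare_only"] + c["neither"],
            }
        )

    def summary(self) -> pd.DataFrame:
        """Posterior mean and central 95% interval per table cell and margin."""
        full = pd.concat([self.counts, self.margins()], axis=1)
        return pd.DataFrame(
            {
                "mean": full.mean(),
                "lo95": full.quantile(0.025),
                "hi95": full.quantile(0.975),
            }
        )


def contingency_posterior(samples: PosteriorSamples) -> ContingencyPosterior:
    """Tally the four co-occurrence counts for every stored posterior draw."""
    zh = samples.z_hare_flat().astype(bool)
    zb = samples.z_bobcat_flat().astype(bool)
    both = (zh & zb).sum(axis=(1, 2))
    bob_only = (~zh & zb).sum(axis=(1, 2))
    hare_only = (zh & ~zb).sum(axis=(1, 2))
    total = zh.shape[1] * zh.shape[2]
    counts = pd.DataFrame(
        {
            "both": both,
            "bobcat_only": bob_only,
            "hare_only": hare_only,
            "neither": total - both - bob_only - hare_only,
        }
    )
    return ContingencyPosterior(counts=counts, total=total)


def conditional_proportions(both, bobcat_only, hare_only, neither) -> dict[str, float]:
    """Conditional co-occurrence proportions from one 2x2 table.

    Accepts posterior-mean (fractional) counts; returns proportions on the
    0-1 scale, e.g. ``bobcat_given_hare_present`` = both / all hare-present
    cell-weeks.
    """
    hare_present = both + hare_only
    hare_absent = bobcat_only + neither
    bob_present = both + bobcat_only
    bob_absent = hare_only + neither
    return {
        "bobcat_given_hare_present": both / hare_present,
        "bobcat_given_hare_absent": bobcat_only / hare_absent,
        "hare_given_bobcat_present": both / bob_present,
        "hare_given_bobcat_absent": hare_only / bob_absent,
    }


@dataclass
class ContrastResult:
    """Beta-binomial contrast of two conditional occupancy proportions."""

    direction: str
    prob_greater: float  # Pr(theta_1 > theta_2), MC estimate (or their mean)
    delta: np.ndarray  # sample of theta_1 - theta_2
    per_draw: np.ndarray | None = None  # per-contingency-draw probabilities
    lo95: float | None = None
    hi95: float | None = None


def beta_contrast(
    y1: int,
    n1: int,
    y2: int,
    n2: int,
    m: int = 10_000,
    seed: int | np.random.Generator | None = None,
) -> ContrastResult:
    """Monte-Carlo Pr(theta_1 > theta_2) under independent conjugate betas.

    ``y``/``n`` are successes and trials for the two binomial proportions;
    both get uniform Beta(1,1) priors.  Returns the indicator mean over
    ``m`` joint draws together with the sampled difference delta.
    """
    for y, n in ((y1, n1), (y2, n2)):
        if not 0 <= y <= n:
            raise ValueError("need 0 <= y <= n")
    if m < 1:
        raise ValueError("m must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t1 = rng.beta(y1 + 1, n1 - y1 + 1, size=m)
    t2 = rng.beta(y2 + 1, n2 - y2 + 1, size=m)
    delta = t1 - t2
    return ContrastResult(
        direction="theta1_vs_theta2",
        prob_greater=float(np.mean(t1 > t2)),
        delta=delta,
    )


def contrast_over_posterior(
    contingency: ContingencyPosterior,
    direction: str = "bobcat_given_hare",
    m_per_draw: int = 10_000,
    seed: int | np.random.Generator | None = None,
) -> ContrastResult:
    """Apply the beta contrast to every posterior contingency draw.

    ``direction='bobcat_given_hare'`` contrasts the proportion of
    prey-present cell-weeks occupied by the predator (theta_1) against the
    proportion of prey-absent ones (theta_2); ``'hare_given_bobcat'`` is the
    reverse conditioning.  The per-draw probabilities are summarized by
    their mean and central 95% interval.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    c = contingency.counts
    if direction == "bobcat_given_hare":
        y1, n1 = c["both"], c["both"] + c["hare_only"]
        y2, n2 = c["bobcat_only"], c["bobcat_only"] + c["neither"]
    elif direction == "hare_given_bobcat":
        y1, n1 = c["both"], c["both"] + c["bobcat_only"]
        y2, n2 = c["hare_only"], c["hare_only"] + c["neither"]
    else:
        raise ValueError(f"unknown direction {direction!r}")

    y1 = y1.to_numpy()[:, None]
    n1 = n1.to_numpy()[:, None]
    y2 = y2.to_numpy()[:, None]
    n2 = n2.to_numpy()[:, None]
    t1 = rng.beta(y1 + 1, n1 - y1 + 1, size=(y1.shape[0], m_per_draw))
    t2 = rng.beta(y2 + 1, n2 - y2 + 1, size=(y2.shape[0], m_per_draw))
    per_draw = (t1 > t2).mean(axis=1)
    delta = (t1 - t2)[:, 0]  # one delta draw per contingency draw
    return ContrastResult(
        direction=direction,
        prob_greater=float(per_draw.mean()),
        delta=delta,
        per_draw=per_draw,
        lo95=float(np.quantile(per_draw, 0.025)),
        hi95=float(np.quantile(per_draw, 0.975)),
    )
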