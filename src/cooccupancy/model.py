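"""Probability layer of the two-species co-occurrence occupancy model.

The hierarchy, for cell i and week t:

  prey (hare) occupancy      Z^H_{i,t} ~ Bernoulli(mu^H_{i,t})
      logit mu^H = b_H + sum_k w_k beta_k x_k(i) + eps^H_{i,t}

  predator (bobcat) occupancy  Z^B_{i,t} ~ Bernoulli(mu^B_{i,t})
      mu^B = Z^H mu1 + (1 - Z^H) mu0          (conditional mixture on prey)
      logit mu1 = b1 + sum_k w_k theta1_k u_k(i) + eps^B_{i,t}
      logit mu0 = b0 + sum_k w_k theta0_k u_k(i) + eps^B_{i,t}

  detection                  Y ~ Binomial(K, p * Z)

where x are the nine scaled landcover proportions, u the five scaled
road/water covariates (cell scale, neighborhood scale, distance to water),
w binary inclusion indicators with Bernoulli(1/2) priors, and eps iid
Normal(0, sigma^2) cell-week random effects.  Detection is imperfect: Y
counts detection days out of K operating days, and Y is forced to 0 when
the species is absent.

Everything here is a pure function of explicit state so the simulator and
the MCMC sampler share one set of probability computations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats

from .landscape import LANDCOVER_CLASSES, PREDATOR_COVARIATES

#: Order of the 19 inclusion indicators: the five predator slopes with prey
#: present, the five with prey absent, then the nine prey landcover slopes.
INDICATOR_NAMES = (
    tuple(f"present_{c}" for c in PREDATOR_COVARIATES)
    + tuple(f"absent_{c}" for c in PREDATOR_COVARIATES)
    + tuple(f"hare_{c}" for c in LANDCOVER_CLASSES)
)

N_INDICATORS = 19
_ETA_CLIP = 35.0  # linear predictors clipped here before exponentiation


def inv_logit(eta):
    """Numerically safe inverse logit; clips the predictor at +-35."""
    eta = np.clip(eta, -_ETA_CLIP, _ETA_CLIP)
    return 1.0 / (1.0 + np.exp(-eta))


def log1pexp(eta):
    """log(1 + exp(eta)), stable for large |eta|."""
    return np.logaddexp(0.0, eta)


def bernoulli_loglik(z, eta):
    """Sum log Bernoulli(z | inv_logit(eta)) over the array."""
    z = np.asarray(z, dtype=float)
    eta = np.asarray(eta, dtype=float)
    return float(np.sum(z * eta - log1pexp(eta)))


@dataclass
class HareParams:
    """Prey occupancy parameters: intercept, nine landcover slopes, RE variance."""

    intercept: float = 0.0
    slopes: np.ndarray = field(default_factory=lambda: np.zeros(9))
    sigma2: float = 1.0

    def __post_init__(self) -> None:
        self.slopes = np.asarray(self.slopes, dtype=float)
        if self.slopes.shape != (9,):
            raise ValueError("hare slopes must have length 9 (landcover classes)")
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")


@dataclass
class BobcatParams:
    """Predator occupancy parameters, one block per prey state.

    ``slopes_present``/``slopes_absent`` follow PREDATOR_COVARIATES order:
    road/water density at cell scale, at neighborhood scale, distance to
    water.
    """

    intercept_present: float = 0.0
    intercept_absent: float = 0.0
    slopes_present: np.ndarray = field(default_factory=lambda: np.zeros(5))
    slopes_absent: np.ndarray = field(default_factory=lambda: np.zeros(5))
    sigma2: float = 1.0

    def __post_init__(self) -> None:
        self.slopes_present = np.asarray(self.slopes_present, dtype=float)
        self.slopes_absent = np.asarray(self.slopes_absent, dtype=float)
        if self.slopes_present.shape != (5,) or self.slopes_absent.shape != (5,):
            raise ValueError("bobcat slope blocks must have length 5")
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")


@dataclass
class DetectionParams:
    """Daily detection probabilities.

    ``p_bobcat`` is per cell (shape (n,) or broadcastable), ``p_hare`` per
    cell-week (shape (n, T) or broadcastable); both in [0, 1].
    """

    p_bobcat: np.ndarray
    p_hare: np.ndarray

    def __post_init__(self) -> None:
        self.p_bobcat = np.asarray(self.p_bobcat, dtype=float)
        self.p_hare = np.asarray(self.p_hare, dtype=float)
        for p in (self.p_bobcat, self.p_hare):
            if np.any(p < 0) or np.any(p > 1):
                raise ValueError("detection probabilities must lie in [0, 1]")


@dataclass
class Indicators:
    """The 19 binary inclusion indicators, in INDICATOR_NAMES order."""

    w: np.ndarray = field(default_factory=lambda: np.ones(N_INDICATORS, dtype=np.int64))

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=np.int64)
        if self.w.shape != (N_INDICATORS,):
            raise ValueError(f"need {N_INDICATORS} indicators")
        if not np.isin(self.w, (0, 1)).all():
            raise ValueError("indicators must be binary")

    @property
    def present(self) -> np.ndarray:
        return self.w[0:5]

    @property
    def absent(self) -> np.ndarray:
        return self.w[5:10]

    @property
    def hare(self) -> np.ndarray:
        return self.w[10:19]


@dataclass
class PriorConfig:
    """Prior hyperparameters.

    Slope priors are mean-zero normals with the *variances* given (prey
    landcover slopes variance 100, predator road/water slopes variance
    10000); intercepts get a proper but effectively flat Normal(0, 1000^2).
    Detection probabilities are Beta(a, b) (uniform by default), random-effect
    variances Inverse-Gamma(shape, rate), and each inclusion indicator is
    Bernoulli(w_prob) a priori.

    The variance prior defaults to a weakly-informative IG(2.5, 0.75)
    (prior mean 0.5, sd on the logit scale mostly between 0.3 and 1.3)
    rather than the traditional vague IG(0.1, 0.1): with one Bernoulli
    observation per random effect the variance is only weakly identified,
    and a vague inverse-gamma lets it and the intercepts drift together
    along a logit-scale ridge.
    """

    hare_slope_sd: float = 10.0
    bobcat_slope_sd: float = 100.0
    intercept_sd: float = 1000.0
    detection_a: float = 1.0
    detection_b: float = 1.0
    sigma2_shape: float = 2.5
    sigma2_rate: float = 0.75
    w_prob: float = 0.5

    def slope_sds(self) -> np.ndarray:
        """Prior sd of each of the 19 candidate slopes, indicator order."""
        return np.concatenate(
            [np.full(10, self.bobcat_slope_sd), np.full(9, self.hare_slope_sd)]
        )


@dataclass
class LatentState:
    """Latent occupancy matrices and random effects (cells x weeks)."""

    z_hare: np.ndarray
    z_bobcat: np.ndarray
    eps_hare: np.ndarray
    eps_bobcat: np.ndarray
    eps_bobcat_absent: np.ndarray | None = None  # only when effects not shared

    def __post_init__(self) -> None:
        self.z_hare = np.asarray(self.z_hare)
        self.z_bobcat = np.asarray(self.z_bobcat)
        for z in (self.z_hare, self.z_bobcat):
            if not np.isin(z, (0, 1)).all():
                raise ValueError("occupancy states must be binary")


@dataclass
class DetectionHistory:
    """Weekly detection-day counts Y and operating-day counts K (cells x weeks)."""

    y_bobcat: np.ndarray
    y_hare: np.ndarray
    k: np.ndarray
    cell_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.y_bobcat = np.asarray(self.y_bobcat, dtype=np.int64)
        self.y_hare = np.asarray(self.y_hare, dtype=np.int64)
        self.k = np.asarray(self.k, dtype=np.int64)
        if not (self.y_bobcat.shape == self.y_hare.shape == self.k.shape):
            raise ValueError("Y and K matrices must share one (cells, weeks) shape")
        if self.y_bobcat.ndim != 2:
            raise ValueError("detection history must be 2-D (cells x weeks)")
        if np.any(self.k < 0) or np.any(self.y_bobcat < 0) or np.any(self.y_hare < 0):
            raise ValueError("counts must be nonnegative")
        if np.any(self.y_bobcat > self.k) or np.any(self.y_hare > self.k):
            raise ValueError("detection days Y cannot exceed operating days K")
        if self.cell_ids is None:
            self.cell_ids = np.arange(self.k.shape[0])

    @property
    def n_cells(self) -> int:
        return self.k.shape[0]

    @property
    def n_weeks(self) -> int:
        return self.k.shape[1]


# ---------------------------------------------------------------------------
# occupancy probabilities


def hare_occupancy_prob(covariate_row, params: HareParams, indicators: Indicators, eps=0.0):
    """Prey occupancy probability mu^H for one cell (or an array of cells).

    ``covariate_row``: the nine scaled landcover values in LANDCOVER_CLASSES
    order (shape (9,) or (n, 9)).
    """
    x = np.asarray(covariate_row, dtype=float)
    if x.shape[-1] != 9:
        raise ValueError("expected 9 landcover covariates")
    if np.any(np.isnan(x)):
        raise ValueError("missing covariate value")
    eta = params.intercept + x @ (indicators.hare * params.slopes) + eps
    return inv_logit(eta)


def bobcat_occupancy_prob(
    z_hare, covariate_row, params: BobcatParams, indicators: Indicators, eps=0.0
):
    """Predator occupancy probability, conditional on the prey state.

    Returns mu1 (prey present) where ``z_hare`` is 1 and mu0 where it is 0;
    each branch uses its own intercept, slopes, and indicator block.
    """
    u = np.asarray(covariate_row, dtype=float)
    if u.shape[-1] != 5:
        raise ValueError("expected 5 road/water covariates")
    if np.any(np.isnan(u)):
        raise ValueError("missing covariate value")
    z = np.asarray(z_hare)
    if not np.isin(z, (0, 1)).all():
        raise ValueError("z_hare must be binary")
    eta1 = params.intercept_present + u @ (indicators.present * params.slopes_present) + eps
    eta0 = params.intercept_absent + u @ (indicators.absent * params.slopes_absent) + eps
    return np.where(z == 1, inv_logit(eta1), inv_logit(eta0))


def detection_loglik(y, k, p, z):
    """Binomial(K, p*z) log-pmf of Y, summed over the array.

    With z = 0 the success probability is 0: log-density 0 for Y = 0 and
    -inf for any positive count.
    """
    y = np.asarray(y, dtype=np.int64)
    k = np.asarray(k, dtype=np.int64)
    p = np.asarray(p, dtype=float)
    z = np.asarray(z)
    if np.any(y > k) or np.any(y < 0):
        raise ValueError("need 0 <= Y <= K")
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("p must lie in [0, 1]")
    if np.any((z == 0) & (y > 0)):
        return -np.inf
    effective = np.where(np.asarray(z) == 1, p, 0.0)
    return float(np.sum(stats.binom.logpmf(y, k, effective)))


def log_joint(
    history: DetectionHistory,
    latent: LatentState,
    hare: HareParams,
    bobcat: BobcatParams,
    detection: DetectionParams,
    indicators: Indicators,
    priors: PriorConfig | None = None,
    prey_design: np.ndarray | None = None,
    predator_design: np.ndarray | None = None,
) -> float:
    """Log joint density of data, latent state and parameters.

    Sums the two detection likelihoods, the two occupancy log-pmfs, the
    random-effect normals, and the log-priors on slopes, intercepts,
    indicators, detection probabilities and variances.  -inf whenever the
    latent state is inconsistent with the data (Y > 0 with Z = 0).
    """
    priors = priors or PriorConfig()
    if prey_design is None or predator_design is None:
        raise ValueError("prey_design and predator_design matrices are required")
    n, T = history.k.shape
    if latent.z_hare.shape != (n, T):
        raise ValueError("latent state dimensions do not match the detection history")

    total = detection_loglik(history.y_hare, history.k, np.broadcast_to(detection.p_hare, (n, T)), latent.z_hare)
    p_b = np.broadcast_to(np.asarray(detection.p_bobcat, dtype=float).reshape(-1, 1) if np.ndim(detection.p_bobcat) == 1 else detection.p_bobcat, (n, T))
    total += detection_loglik(history.y_bobcat, history.k, p_b, latent.z_bobcat)
    if not np.isfinite(total):
        return -np.inf

    eta_h = (
        hare.intercept
        + prey_design @ (indicators.hare * hare.slopes)
    )[:, None] + latent.eps_hare
    total += bernoulli_loglik(latent.z_hare, eta_h)

    eps0 = latent.eps_bobcat if latent.eps_bobcat_absent is None else latent.eps_bobcat_absent
    eta1 = (
        bobcat.intercept_present
        + predator_design @ (indicators.present * bobcat.slopes_present)
    )[:, None] + latent.eps_bobcat
    eta0 = (
        bobcat.intercept_absent
        + predator_design @ (indicators.absent * bobcat.slopes_absent)
    )[:, None] + eps0
    eta_b = np.where(latent.z_hare == 1, eta1, eta0)
    total += bernoulli_loglik(latent.z_bobcat, eta_b)

    total += float(np.sum(stats.norm.logpdf(latent.eps_hare, 0.0, np.sqrt(hare.sigma2))))
    total += float(np.sum(stats.norm.logpdf(latent.eps_bobcat, 0.0, np.sqrt(bobcat.sigma2))))
    if latent.eps_bobcat_absent is not None:
        total += float(
            np.sum(stats.norm.logpdf(latent.eps_bobcat_absent, 0.0, np.sqrt(bobcat.sigma2)))
        )

    # priors
    total += float(stats.norm.logpdf(hare.intercept, 0.0, priors.intercept_sd))
    total += float(stats.norm.logpdf(bobcat.intercept_present, 0.0, priors.intercept_sd))
    total += float(stats.norm.logpdf(bobcat.intercept_absent, 0.0, priors.intercept_sd))
    total += float(np.sum(stats.norm.logpdf(hare.slopes, 0.0, priors.hare_slope_sd)))
    total += float(np.sum(stats.norm.logpdf(bobcat.slopes_present, 0.0, priors.bobcat_slope_sd)))
    total += float(np.sum(stats.norm.logpdf(bobcat.slopes_absent, 0.0, priors.bobcat_slope_sd)))
    w = indicators.w
    total += float(np.sum(w * np.log(priors.w_prob) + (1 - w) * np.log1p(-priors.w_prob)))
    total += float(
        np.sum(stats.beta.logpdf(np.clip(detection.p_hare, 1e-12, 1 - 1e-12), priors.detection_a, priors.detection_b))
    )
    total += float(
        np.sum(stats.beta.logpdf(np.clip(detection.p_bobcat, 1e-12, 1 - 1e-12), priors.detection_a, priors.detection_b))
    )
    for s2 in (hare.sigma2, bobcat.sigma2):
        total += float(
            stats.invgamma.logpdf(s2, priors.sigma2_shape, scale=priors.sigma2_rate)
        )
    return total


# ---------------------------------------------------------------------------
# serialization helpers


def params_to_dict(hare: HareParams, bobcat: BobcatParams) -> dict:
    d = {"hare": asdict(hare), "bobcat": asdict(bobcat)}
    d["hare"]["slopes"] = list(map(float, hare.slopes))
    d["bobcat"]["slopes_present"] = list(map(float, bobcat.slopes_present))
    d["bobcat"]["slopes_absent"] = list(map(float, bobcat.slopes_absent))
    return d


def params_from_dict(d: dict) -> tuple[HareParams, BobcatParams]:
    return HareParams(**d["hare"]), BobcatParams(**d["bobcat"])


def save_params(path, hare: HareParams, bobcat: BobcatParams) -> None:
    with open(path, "w") as fh:
        json.dump(params_to_dict(hare, bobcat), fh, indent=2)


def load_params(path) -> tuple[HareParams, BobcatParams]:
    with open(path) as fh:
        return params_from_dict(json.load(fh))
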