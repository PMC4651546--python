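"""Metropolis-within-Gibbs sampler for the co-occurrence occupancy model.

One sweep updates, in fixed order:

1. latent occupancy matrices Z (exact Bernoulli full conditionals; the prey
   conditional includes the predator field through the conditional mixture),
2. regression blocks (adaptive random-walk Metropolis per coefficient;
   within-block order randomized each sweep),
3. inclusion indicators w (Kuo-Mallick: exact Bernoulli full conditional
   comparing the likelihood with the term in vs out, with a prior refresh of
   the coefficient whenever it is excluded),
4. detection probabilities (conjugate beta given Z, pooled per the chosen
   detection structure: constant, per cell, or per cell-week),
5. random effects (elementwise Metropolis) and their variances (conjugate
   inverse-gamma).

Proposal scales adapt toward a target acceptance rate during burn-in only
and are frozen afterwards, preserving the stationary distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .landscape import CovariateTable
from .model import (
    DetectionHistory,
    N_INDICATORS,
    PriorConfig,
    log1pexp,
)

DETECTION_STRUCTURES = ("constant", "cell", "cell_week")


@dataclass
class MCMCConfig:
    """Chain protocol and model-structure switches.

    Defaults reproduce the study protocol: 3 chains, 100,000 sampling
    iterations after a 300,000-iteration burn-in, thinned by 10, with the
    selected detection structure (predator detection varying by cell, prey
    detection by cell-week).  ``test_scale`` gives a short preset for
    desk-scale runs.
    """

    n_chains: int = 3
    n_burn: int = 300_000
    n_iter: int = 100_000
    thin: int = 10
    seed: int = 0
    bobcat_detection: str = "cell"
    hare_detection: str = "cell_week"
    shared_predator_effects: bool = True
    target_accept: float = 0.37
    adapt_rate: float = 0.05
    init_proposal_scale: float = 0.5
    store_latent: bool = True

    def __post_init__(self) -> None:
        if min(self.n_chains, self.n_burn, self.n_iter, self.thin) < 1:
            raise ValueError("chain counts must be positive")
        if self.n_iter % self.thin != 0:
            raise ValueError("thin must divide n_iter")
        for s in (self.bobcat_detection, self.hare_detection):
            if s not in DETECTION_STRUCTURES:
                raise ValueError(f"unknown detection structure {s!r}")

    @classmethod
    def test_scale(cls, seed: int = 0, **overrides) -> "MCMCConfig":
        """Short preset: 3 chains x 2,000 draws after 2,000 burn-in, thin 2."""
        return cls(n_burn=2000, n_iter=2000, thin=2, seed=seed, **overrides)

    @property
    def n_kept(self) -> int:
        return self.n_iter // self.thin


@dataclass
class _Data:
    """Preprocessed data and design matrices shared by all updates."""

    y_h: np.ndarray
    y_b: np.ndarray
    k: np.ndarray
    x: np.ndarray  # (n, 9) prey design
    u: np.ndarray  # (n, 5) predator design
    g_h: np.ndarray  # (n, T) detection group index, prey
    g_b: np.ndarray
    ng_h: int
    ng_b: int

    @property
    def shape(self) -> tuple[int, int]:
        return self.y_h.shape


def _detection_groups(structure: str, n: int, T: int) -> tuple[np.ndarray, int]:
    if structure == "constant":
        return np.zeros((n, T), dtype=np.int64), 1
    if structure == "cell":
        return np.repeat(np.arange(n), T).reshape(n, T), n
    return np.arange(n * T).reshape(n, T), n * T


def prepare_data(
    history: DetectionHistory, covariates: CovariateTable, config: MCMCConfig
) -> _Data:
    n, T = history.k.shape
    if covariates.n_cells != n:
        raise ValueError("covariate table and detection history disagree on cell count")
    g_h, ng_h = _detection_groups(config.hare_detection, n, T)
    g_b, ng_b = _detection_groups(config.bobcat_detection, n, T)
    return _Data(
        y_h=history.y_hare,
        y_b=history.y_bobcat,
        k=history.k,
        x=covariates.prey_design(),
        u=covariates.predator_design(),
        g_h=g_h,
        g_b=g_b,
        ng_h=ng_h,
        ng_b=ng_b,
    )


@dataclass
class ChainState:
    """Full parameter/latent state of one chain, with cached linear predictors."""

    b_h: float
    beta_h: np.ndarray  # (9,)
    b1: float
    b0: float
    th1: np.ndarray  # (5,)
    th0: np.ndarray
    w: np.ndarray  # (19,) int
    z_h: np.ndarray  # (n, T) int8
    z_b: np.ndarray
    eps_h: np.ndarray  # (n, T)
    eps_b: np.ndarray
    eps_b0: np.ndarray | None  # separate prey-absent effects, or None if shared
    sig2_h: float
    sig2_b: float
    p_h: np.ndarray  # (ng_h,)
    p_b: np.ndarray  # (ng_b,)
    # caches
    eta_h: np.ndarray = field(default=None, repr=False)  # (n, T)
    eta1: np.ndarray = field(default=None, repr=False)
    eta0: np.ndarray = field(default=None, repr=False)
    scales: dict = field(default_factory=dict, repr=False)

    def refresh_caches(self, data: _Data) -> None:
        self.eta_h = (self.b_h + data.x @ (self.w[10:19] * self.beta_h))[:, None] + self.eps_h
        self.eta1 = (self.b1 + data.u @ (self.w[0:5] * self.th1))[:, None] + self.eps_b
        eps0 = self.eps_b if self.eps_b0 is None else self.eps_b0
        self.eta0 = (self.b0 + data.u @ (self.w[5:10] * self.th0))[:, None] + eps0


def init_state(data: _Data, config: MCMCConfig, rng: np.random.Generator) -> ChainState:
    """Deterministic-skeleton initialization: Z = 1 wherever Y > 0 (else a
    coin flip), coefficients at 0, detection at (sum Y + 1)/(sum K + 2)."""
    n, T = data.shape

    def p_init(y, k, g, ng):
        num = np.bincount(g.ravel(), weights=y.ravel().astype(float), minlength=ng) + 1.0
        den = np.bincount(g.ravel(), weights=k.ravel().astype(float), minlength=ng) + 2.0
        return num / den

    state = ChainState(
        b_h=0.0,
        beta_h=np.zeros(9),
        b1=0.0,
        b0=0.0,
        th1=np.zeros(5),
        th0=np.zeros(5),
        w=np.ones(N_INDICATORS, dtype=np.int64),
        z_h=np.where(data.y_h > 0, 1, rng.integers(0, 2, size=(n, T))).astype(np.int8),
        z_b=np.where(data.y_b > 0, 1, rng.integers(0, 2, size=(n, T))).astype(np.int8),
        eps_h=np.zeros((n, T)),
        eps_b=np.zeros((n, T)),
        eps_b0=None if config.shared_predator_effects else np.zeros((n, T)),
        sig2_h=0.5,
        sig2_b=0.5,
        p_h=p_init(data.y_h, data.k, data.g_h, data.ng_h),
        p_b=p_init(data.y_b, data.k, data.g_b, data.ng_b),
    )
    s = config.init_proposal_scale
    state.scales = {
        "b_h": s,
        "beta_h": np.full(9, s),
        "b1": s,
        "b0": s,
        "th1": np.full(5, s),
        "th0": np.full(5, s),
        "eps_h": s,
        "eps_b": s,
    }
    state.refresh_caches(data)
    return state


def _log1m(p: np.ndarray) -> np.ndarray:
    return np.log1p(-np.clip(p, 0.0, 1.0 - 1e-12))


# ---------------------------------------------------------------------------
# Gibbs updates


def update_latent_occupancy(state: ChainState, data: _Data, rng: np.random.Generator) -> None:
    """Draw Z_H then Z_B from their exact Bernoulli full conditionals.

    Any cell-week with a detection is occupied with probability one.  For the
    prey the log-odds combine its own occupancy prior, the probability of a
    zero detection history, and the predator likelihood through the mixture
    branch switch; the predator conditional has no feedback term.
    """
    n, T = data.shape
    p_h_full = state.p_h[data.g_h]
    p_b_full = state.p_b[data.g_b]

    zb = state.z_b.astype(float)
    lo = (
        state.eta_h
        + data.k * _log1m(p_h_full)
        + (zb * state.eta1 - log1pexp(state.eta1))
        - (zb * state.eta0 - log1pexp(state.eta0))
    )
    draw = rng.random((n, T)) < expit(lo)
    state.z_h = np.where(data.y_h > 0, 1, draw).astype(np.int8)

    eta_act = np.where(state.z_h == 1, state.eta1, state.eta0)
    lo_b = eta_act + data.k * _log1m(p_b_full)
    draw_b = rng.random((n, T)) < expit(lo_b)
    state.z_b = np.where(data.y_b > 0, 1, draw_b).astype(np.int8)


def _bern_delta(z: np.ndarray, eta: np.ndarray, delta: np.ndarray, mask=None) -> float:
    """Change in sum[z*eta - log1pexp(eta)] when eta moves by delta."""
    new = eta + delta
    contrib = z * delta - (log1pexp(new) - log1pexp(eta))
    if mask is not None:
        contrib = contrib[mask]
    return float(np.sum(contrib))


def _adapt(scales, key, idx, accepted: bool, config: MCMCConfig) -> None:
    factor = np.exp(config.adapt_rate * ((1.0 if accepted else 0.0) - config.target_accept))
    if idx is None:
        scales[key] *= factor
    else:
        scales[key][idx] *= factor


def update_regression_block(
    state: ChainState,
    data: _Data,
    block: str,
    rng: np.random.Generator,
    priors: PriorConfig,
    config: MCMCConfig,
    adapt: bool = False,
) -> None:
    """Random-walk Metropolis on one block's intercept and included slopes.

    Excluded slopes (w = 0) do not enter the likelihood and are refreshed
    from their prior, as the indicator-selection scheme requires.  Cached
    linear predictors are updated incrementally.
    """
    zb = state.z_b.astype(float)
    if block == "hare":
        z = state.z_h.astype(float)
        order = rng.permutation(9)
        for j in order:
            if state.w[10 + j] == 0:
                state.beta_h[j] = rng.normal(0.0, priors.hare_slope_sd)
                continue
            prop = state.beta_h[j] + state.scales["beta_h"][j] * rng.normal()
            delta = (prop - state.beta_h[j]) * data.x[:, j]
            dll = _bern_delta(z, state.eta_h, delta[:, None])
            dlp = (state.beta_h[j] ** 2 - prop**2) / (2 * priors.hare_slope_sd**2)
            acc = np.log(rng.random()) < dll + dlp
            if acc:
                state.eta_h = state.eta_h + delta[:, None]
                state.beta_h[j] = prop
            if adapt:
                _adapt(state.scales, "beta_h", j, acc, config)
        prop = state.b_h + state.scales["b_h"] * rng.normal()
        d = prop - state.b_h
        dll = _bern_delta(z, state.eta_h, d)
        dlp = (state.b_h**2 - prop**2) / (2 * priors.intercept_sd**2)
        acc = np.log(rng.random()) < dll + dlp
        if acc:
            state.eta_h = state.eta_h + d
            state.b_h = prop
        if adapt:
            _adapt(state.scales, "b_h", None, acc, config)
        return

    present = block == "bobcat_present"
    mask = (state.z_h == 1) if present else (state.z_h == 0)
    eta_key = "eta1" if present else "eta0"
    slopes = state.th1 if present else state.th0
    key = "th1" if present else "th0"
    w_off = 0 if present else 5
    order = rng.permutation(5)
    for j in order:
        if state.w[w_off + j] == 0:
            slopes[j] = rng.normal(0.0, priors.bobcat_slope_sd)
            continue
        prop = slopes[j] + state.scales[key][j] * rng.normal()
        delta = (prop - slopes[j]) * data.u[:, j]
        dll = _bern_delta(zb, getattr(state, eta_key), delta[:, None], mask)
        dlp = (slopes[j] ** 2 - prop**2) / (2 * priors.bobcat_slope_sd**2)
        acc = np.log(rng.random()) < dll + dlp
        if acc:
            setattr(state, eta_key, getattr(state, eta_key) + delta[:, None])
            slopes[j] = prop
        if adapt:
            _adapt(state.scales, key, j, acc, config)
    ikey = "b1" if present else "b0"
    cur = getattr(state, ikey)
    prop = cur + state.scales[ikey] * rng.normal()
    d = prop - cur
    dll = _bern_delta(zb, getattr(state, eta_key), d, mask)
    dlp = (cur**2 - prop**2) / (2 * priors.intercept_sd**2)
    acc = np.log(rng.random()) < dll + dlp
    if acc:
        setattr(state, eta_key, getattr(state, eta_key) + d)
        setattr(state, ikey, prop)
    if adapt:
        _adapt(state.scales, ikey, None, acc, config)


def update_indicators(
    state: ChainState, data: _Data, rng: np.random.Generator, priors: PriorConfig
) -> None:
    """Draw each w_k from its Bernoulli full conditional (Kuo-Mallick).

    The conditional odds compare the likelihood with the k-th term included
    (at the current coefficient value) against excluded; the Bernoulli(1/2)
    prior contributes even odds.  A coefficient leaving the model is
    refreshed from its prior.
    """
    zb = state.z_b.astype(float)
    zh = state.z_h.astype(float)
    prior_lo = np.log(priors.w_prob) - np.log1p(-priors.w_prob)
    for k in rng.permutation(N_INDICATORS):
        if k < 5:
            j, coef, col = k, state.th1[k], data.u[:, k]
            mask, eta_key, z = state.z_h == 1, "eta1", zb
        elif k < 10:
            j, coef, col = k - 5, state.th0[k - 5], data.u[:, k - 5]
            mask, eta_key, z = state.z_h == 0, "eta0", zb
        else:
            j, coef, col = k - 10, state.beta_h[k - 10], data.x[:, k - 10]
            mask, eta_key, z = None, "eta_h", zh
        eta = getattr(state, eta_key)
        term = coef * col[:, None]
        if state.w[k] == 1:
            ll_in_minus_out = -_bern_delta(z, eta, -term, mask)
        else:
            ll_in_minus_out = _bern_delta(z, eta, term, mask)
        p1 = expit(ll_in_minus_out + prior_lo)
        new = int(rng.random() < p1)
        if new != state.w[k]:
            setattr(state, eta_key, eta + (term if new == 1 else -term))
            state.w[k] = new
        if new == 0:
            sd = priors.bobcat_slope_sd if k < 10 else priors.hare_slope_sd
            fresh = rng.normal(0.0, sd)
            if k < 5:
                state.th1[j] = fresh
            elif k < 10:
                state.th0[j] = fresh
            else:
                state.beta_h[j] = fresh


def update_detection(
    state: ChainState, data: _Data, rng: np.random.Generator, priors: PriorConfig
) -> None:
    """Conjugate beta draw of detection probabilities given occupancy.

    Each detection group pools its occupied cell-weeks: p_g | Z, Y ~
    Beta(a + sum Y, b + sum(K - Y)); groups with no occupied exposure draw
    from the prior.
    """

    def draw(y, z, g, ng):
        occ = z == 1
        a = priors.detection_a + np.bincount(
            g[occ], weights=y[occ].astype(float), minlength=ng
        )
        b = priors.detection_b + np.bincount(
            g[occ], weights=(data.k[occ] - y[occ]).astype(float), minlength=ng
        )
        return rng.beta(a, b)

    state.p_h = draw(data.y_h, state.z_h, data.g_h, data.ng_h)
    state.p_b = draw(data.y_b, state.z_b, data.g_b, data.ng_b)


def update_random_effects_and_variances(
    state: ChainState,
    data: _Data,
    rng: np.random.Generator,
    priors: PriorConfig,
    config: MCMCConfig,
    adapt: bool = False,
) -> None:
    """Elementwise Metropolis on the random effects, conjugate variances.

    Random effects are conditionally independent across cell-weeks, so all
    are proposed and accepted in parallel.  With separate predator effects
    the branch not selected by the current prey state has no likelihood and
    is drawn directly from its prior.
    """
    n, T = data.shape
    zh = state.z_h.astype(float)
    zb = state.z_b.astype(float)

    # prey effects
    prop = state.scales["eps_h"] * rng.normal(size=(n, T))
    new_eta = state.eta_h + prop
    dll = zh * prop - (log1pexp(new_eta) - log1pexp(state.eta_h))
    dlp = (state.eps_h**2 - (state.eps_h + prop) ** 2) / (2 * state.sig2_h)
    acc = np.log(rng.random((n, T))) < dll + dlp
    state.eps_h = np.where(acc, state.eps_h + prop, state.eps_h)
    state.eta_h = np.where(acc, new_eta, state.eta_h)
    if adapt:
        _adapt(state.scales, "eps_h", None, float(acc.mean()) > config.target_accept, config)

    # predator effects
    if state.eps_b0 is None:
        eta_act = np.where(state.z_h == 1, state.eta1, state.eta0)
        prop = state.scales["eps_b"] * rng.normal(size=(n, T))
        dll = zb * prop - (log1pexp(eta_act + prop) - log1pexp(eta_act))
        dlp = (state.eps_b**2 - (state.eps_b + prop) ** 2) / (2 * state.sig2_b)
        acc = np.log(rng.random((n, T))) < dll + dlp
        step = np.where(acc, prop, 0.0)
        state.eps_b = state.eps_b + step
        state.eta1 = state.eta1 + step
        state.eta0 = state.eta0 + step
        sumsq_b = float(np.sum(state.eps_b**2))
        n_eff_b = n * T
    else:
        sd = np.sqrt(state.sig2_b)
        for eps_name, eta_name, active in (
            ("eps_b", "eta1", state.z_h == 1),
            ("eps_b0", "eta0", state.z_h == 0),
        ):
            eps = getattr(state, eps_name)
            eta = getattr(state, eta_name)
            fresh = rng.normal(0.0, sd, size=(n, T))
            prop = state.scales["eps_b"] * rng.normal(size=(n, T))
            dll = zb * prop - (log1pexp(eta + prop) - log1pexp(eta))
            dlp = (eps**2 - (eps + prop) ** 2) / (2 * state.sig2_b)
            acc = np.log(rng.random((n, T))) < dll + dlp
            new_eps = np.where(active, np.where(acc, eps + prop, eps), fresh)
            setattr(state, eps_name, new_eps)
            setattr(state, eta_name, eta + (new_eps - eps))
        sumsq_b = float(np.sum(state.eps_b**2) + np.sum(state.eps_b0**2))
        n_eff_b = 2 * n * T
    if adapt:
        _adapt(state.scales, "eps_b", None, float(acc.mean()) > config.target_accept, config)

    # conjugate inverse-gamma variance updates
    a = priors.sigma2_shape + 0.5 * n * T
    b = priors.sigma2_rate + 0.5 * float(np.sum(state.eps_h**2))
    state.sig2_h = b / rng.gamma(a, 1.0)
    a = priors.sigma2_shape + 0.5 * n_eff_b
    b = priors.sigma2_rate + 0.5 * sumsq_b
    state.sig2_b = b / rng.gamma(a, 1.0)


def sweep(
    state: ChainState,
    data: _Data,
    rng: np.random.Generator,
    priors: PriorConfig,
    config: MCMCConfig,
    adapt: bool = False,
) -> None:
    """One full Gibbs sweep over latent states, parameters and hyperparameters."""
    update_latent_occupancy(state, data, rng)
    update_regression_block(state, data, "hare", rng, priors, config, adapt)
    update_regression_block(state, data, "bobcat_present", rng, priors, config, adapt)
    update_regression_block(state, data, "bobcat_absent", rng, priors, config, adapt)
    update_indicators(state, data, rng, priors)
    update_detection(state, data, rng, priors)
    update_random_effects_and_variances(state, data, rng, priors, config, adapt)


# ---------------------------------------------------------------------------
# posterior container and driver


@dataclass
class PosteriorSamples:
    """Thinned multi-chain draws plus the bookkeeping needed to use them.

    Scalar/vector parameters live in ``params`` with shape (chains, draws)
    or (chains, draws, dim); latent occupancy draws are stored as compact
    uint8 arrays; detection draws are stored per detection *group* with the
    (cells x weeks) group-index maps needed to expand them.
    """

    params: dict[str, np.ndarray]
    z_hare: np.ndarray | None  # (C, D, n, T) uint8
    z_bobcat: np.ndarray | None
    p_hare: np.ndarray  # (C, D, ng_h)
    p_bobcat: np.ndarray  # (C, D, ng_b)
    group_hare: np.ndarray  # (n, T)
    group_bobcat: np.ndarray
    cell_ids: np.ndarray
    config: MCMCConfig
    acceptance: dict[str, float] = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return next(iter(self.params.values())).shape[0]

    @property
    def n_draws(self) -> int:
        return next(iter(self.params.values())).shape[1]

    def flat(self, name: str) -> np.ndarray:
        """All chains pooled: shape (chains*draws, ...)."""
        v = self.params[name]
        return v.reshape(-1, *v.shape[2:])

    def p_hare_full(self) -> np.ndarray:
        """(chains*draws, n, T) prey detection probabilities."""
        return self.p_hare.reshape(-1, self.p_hare.shape[-1])[:, self.group_hare]

    def p_bobcat_full(self) -> np.ndarray:
        return self.p_bobcat.reshape(-1, self.p_bobcat.shape[-1])[:, self.group_bobcat]

    def z_hare_flat(self) -> np.ndarray:
        if self.z_hare is None:
            raise ValueError("latent draws were not stored (store_latent=False)")
        return self.z_hare.reshape(-1, *self.z_hare.shape[2:])

    def z_bobcat_flat(self) -> np.ndarray:
        if self.z_bobcat is None:
            raise ValueError("latent draws were not stored (store_latent=False)")
        return self.z_bobcat.reshape(-1, *self.z_bobcat.shape[2:])


_PARAM_SPECS = {
    "b_hare": (),
    "beta_hare": (9,),
    "b_bobcat_present": (),
    "b_bobcat_absent": (),
    "slopes_present": (5,),
    "slopes_absent": (5,),
    "w": (N_INDICATORS,),
    "sigma2_hare": (),
    "sigma2_bobcat": (),
}


def run_mcmc(
    history: DetectionHistory,
    covariates: CovariateTable,
    config: MCMCConfig | None = None,
    priors: PriorConfig | None = None,
) -> PosteriorSamples:
    """Fit the model: burn-in with adaptation, then thinned sampling.

    Per-chain random streams are spawned reproducibly from ``config.seed``;
    identical configuration and data give bit-identical draws.
    """
    config = config or MCMCConfig()
    priors = priors or PriorConfig()
    data = prepare_data(history, covariates, config)
    n, T = data.shape

    C, D = config.n_chains, config.n_kept
    params = {
        name: np.empty((C, D) + shp) for name, shp in _PARAM_SPECS.items()
    }
    z_h_draws = np.empty((C, D, n, T), dtype=np.uint8) if config.store_latent else None
    z_b_draws = np.empty((C, D, n, T), dtype=np.uint8) if config.store_latent else None
    p_h_draws = np.empty((C, D, data.ng_h))
    p_b_draws = np.empty((C, D, data.ng_b))

    chain_seeds = np.random.SeedSequence(config.seed).spawn(C)
    for c in range(C):
        rng = np.random.default_rng(chain_seeds[c])
        state = init_state(data, config, rng)
        for _ in range(config.n_burn):
            sweep(state, data, rng, priors, config, adapt=True)
        kept = 0
        for it in range(config.n_iter):
            sweep(state, data, rng, priors, config, adapt=False)
            if (it + 1) % config.thin == 0:
                params["b_hare"][c, kept] = state.b_h
                params["beta_hare"][c, kept] = state.beta_h
                params["b_bobcat_present"][c, kept] = state.b1
                params["b_bobcat_absent"][c, kept] = state.b0
                params["slopes_present"][c, kept] = state.th1
                params["slopes_absent"][c, kept] = state.th0
                params["w"][c, kept] = state.w
                params["sigma2_hare"][c, kept] = state.sig2_h
                params["sigma2_bobcat"][c, kept] = state.sig2_b
                if config.store_latent:
                    z_h_draws[c, kept] = state.z_h
                    z_b_draws[c, kept] = state.z_b
                p_h_draws[c, kept] = state.p_h
                p_b_draws[c, kept] = state.p_b
                kept += 1

    return PosteriorSamples(
        params=params,
        z_hare=z_h_draws,
        z_bobcat=z_b_draws,
        p_hare=p_h_draws,
        p_bobcat=p_b_draws,
        group_hare=data.g_h,
        group_bobcat=data.g_b,
        cell_ids=np.asarray(history.cell_ids),
        config=config,
    )


def gelman_rubin(chains: np.ndarray) -> float:
    """Classic potential scale reduction factor R-hat.

    ``chains``: (n_chains, n_draws).  Uses the between/within variance
    decomposition R-hat = sqrt(((n-1)/n W + B/n) / W); chains that never
    move (W = 0) while disagreeing return +inf.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise ValueError("need at least 2 chains")
    m, ndraw = chains.shape
    if ndraw < 10:
        raise ValueError("need at least 10 draws per chain")
    means = chains.mean(axis=1)
    W = float(chains.var(axis=1, ddof=1).mean())
    B_over_n = float(means.var(ddof=1))
    if W == 0.0:
        return 1.0 if B_over_n == 0.0 else np.inf
    var_hat = (ndraw - 1) / ndraw * W + B_over_n
    # the pooled-variance estimator can dip below W for identical chains;
    # floor at 1 so the statistic respects its >= 1 contract
    return float(max(1.0, np.sqrt(var_hat / W)))


def rhat_table(samples: PosteriorSamples) -> dict[str, float]:
    """R-hat for every stored scalar component, keyed by parameter[index]."""
    out: dict[str, float] = {}
    for name, v in samples.params.items():
        if name == "w":
            continue  # binary indicators: R-hat is not meaningful
        if v.ndim == 2:
            out[name] = gelman_rubin(v)
        else:
            for j in range(v.shape[2]):
                out[f"{name}[{j}]"] = gelman_rubin(v[:, :, j])
    return out
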