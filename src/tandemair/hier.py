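"""Hierarchical Bayesian detection-function model.

Partitions detection-scale variation into platform, observer and species
components. For sighting i of species k by observer j on platform l,
with perpendicular distance d (kilometres) and truncation w_k:

    g(d) = exp(-(d / (2 sigma_jkl))^2)         (form as printed; a
                                                conventional half-normal
                                                exp(-d^2/(2 sigma^2)) is
                                                available behind
                                                ``conventional_hn=True``)
    log sigma_jkl = delta_l + eta_jl + gamma_kl

The observed-distance likelihood divides by the truncated integral
(the ESW), the standard line-transect normalization. Observer rows
(eta_j1, eta_j2) and species rows (gamma_k1, gamma_k2) get bivariate
normal random effects parameterized by per-platform scales tau and a
cross-platform correlation rho; priors are standard normal on the
platform intercepts, half-Student-t(3, 1.5) on the scales and uniform on
the correlations.

Sampling is adaptive random-walk Metropolis-within-Gibbs over scalar
coordinates; proposal scales adapt toward a 20-50% acceptance rate
during warm-up only, so detailed balance holds for the retained draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import integrate, optimize
from scipy.special import erf

__all__ = [
    "HierData",
    "HierParams",
    "McmcConfig",
    "PosteriorSample",
    "esw_paper",
    "esw_conventional",
    "hier_loglik",
    "hier_logpost",
    "sample_posterior",
    "rhat",
    "esw_summaries",
    "fit_single_sigma",
]

_LOG_SIGMA_CLIP = 20.0
SQRT_PI = math.sqrt(math.pi)


# ---------------------------------------------------------------------------
# data and parameter containers


@dataclass
class HierData:
    """Sightings with labels mapped to dense indices; distances in km."""

    d: np.ndarray  # perpendicular distances, km
    platform_idx: np.ndarray  # 0/1
    observer_idx: np.ndarray  # 0..J-1
    species_idx: np.ndarray  # 0..K-1
    w: np.ndarray  # per-sighting truncation (km), from the species table
    n_observers: int
    n_species: int

    def __post_init__(self) -> None:
        if np.any(self.d < 0) or np.any(self.d > self.w + 1e-12):
            raise ValueError("distances must lie in [0, w]")
        for name, idx, hi in (("platform", self.platform_idx, 2),
                              ("observer", self.observer_idx, self.n_observers),
                              ("species", self.species_idx, self.n_species)):
            if np.any(idx < 0) or np.any(idx >= hi):
                raise ValueError(f"{name} label without parameter")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, truncations: dict) -> "HierData":
        """Build from a frame with columns distance_km, platform,
        observer, species; ``truncations`` maps species -> w_k (km)."""
        platforms = sorted(df["platform"].unique())
        if len(platforms) > 2:
            raise ValueError("at most two platforms supported")
        observers = sorted(df["observer"].unique())
        species = sorted(df["species"].unique())
        p_idx = df["platform"].map({p: i for i, p in enumerate(platforms)}).to_numpy()
        o_idx = df["observer"].map({o: i for i, o in enumerate(observers)}).to_numpy()
        s_idx = df["species"].map({s: i for i, s in enumerate(species)}).to_numpy()
        missing = set(df["species"]) - set(truncations)
        if missing:
            raise ValueError(f"species without truncation: {missing}")
        w = df["species"].map(truncations).to_numpy(float)
        data = cls(df["distance_km"].to_numpy(float), p_idx, o_idx, s_idx, w,
                   len(observers), len(species))
        data.platform_labels = platforms  # type: ignore[attr-defined]
        data.observer_labels = observers  # type: ignore[attr-defined]
        data.species_labels = species  # type: ignore[attr-defined]
        return data


@dataclass
class HierParams:
    """Model parameters; all effect arrays are platform-columned."""

    delta: np.ndarray  # (2,)
    eta: np.ndarray  # (J, 2)
    gamma: np.ndarray  # (K, 2)
    tau_obs: np.ndarray  # (2,)
    rho_obs: float
    tau_sp: np.ndarray  # (2,)
    rho_sp: float

    def validate(self) -> None:
        if np.any(self.tau_obs < 0) or np.any(self.tau_sp < 0):
            raise ValueError("tau must be >= 0")
        if abs(self.rho_obs) > 1 or abs(self.rho_sp) > 1:
            raise ValueError("|rho| must be <= 1")

    def log_sigma(self, data: HierData) -> np.ndarray:
        ls = (self.delta[data.platform_idx]
              + self.eta[data.observer_idx, data.platform_idx]
              + self.gamma[data.species_idx, data.platform_idx])
        return np.clip(ls, -_LOG_SIGMA_CLIP, _LOG_SIGMA_CLIP)


@dataclass(frozen=True)
class McmcConfig:
    n_chains: int = 4
    n_warmup: int = 10_000
    n_iter: int = 10_000
    thin: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_chains, self.n_warmup, self.n_iter, self.thin) < 1:
            raise ValueError("all MCMC settings must be positive")

    @property
    def pooled_draws(self) -> int:
        return self.n_chains * (self.n_iter // self.thin)


@dataclass
class PosteriorSample:
    draws: np.ndarray  # (chains, kept, n_params)
    param_names: list
    data: HierData
    config: McmcConfig
    conventional_hn: bool = False
    acceptance: np.ndarray | None = None

    @property
    def pooled(self) -> np.ndarray:
        return self.draws.reshape(-1, self.draws.shape[-1])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        c, n, p = self.draws.shape
        for ci in range(c):
            for it in range(n):
                for pi in range(p):
                    rows.append((ci, it, self.param_names[pi], self.draws[ci, it, pi]))
        return pd.DataFrame(rows, columns=["chain", "iter", "parameter", "value"])

    def rhat_table(self) -> pd.DataFrame:
        vals = [rhat(self.draws[:, :, i]) for i in range(self.draws.shape[-1])]
        return pd.DataFrame({"parameter": self.param_names, "rhat": vals})


# ---------------------------------------------------------------------------
# detection function and ESW


def esw_paper(sigma, w):
    """int_0^w exp(-(x/(2 sigma))^2) dx = sigma sqrt(pi) erf(w/(2 sigma))."""
    sigma = np.asarray(sigma, float)
    return sigma * SQRT_PI * erf(w / (2.0 * sigma))


def esw_conventional(sigma, w):
    """int_0^w exp(-x^2/(2 sigma^2)) dx = sigma sqrt(pi/2) erf(w/(sigma sqrt 2))."""
    sigma = np.asarray(sigma, float)
    return sigma * math.sqrt(math.pi / 2.0) * erf(w / (sigma * math.sqrt(2.0)))


def esw_quadrature(sigma: float, w: float, conventional_hn: bool = False) -> float:
    if conventional_hn:
        g = lambda x: np.exp(-x * x / (2.0 * sigma * sigma))  # noqa: E731
    else:
        g = lambda x: np.exp(-((x / (2.0 * sigma)) ** 2))  # noqa: E731
    val, _ = integrate.quad(g, 0.0, w, limit=200)
    return val


# ---------------------------------------------------------------------------
# log density


def _log_g(d, sigma, conventional_hn):
    if conventional_hn:
        return -(d * d) / (2.0 * sigma * sigma)
    return -((d / (2.0 * sigma)) ** 2)


def hier_loglik(params: HierParams, data: HierData,
                conventional_hn: bool = False) -> float:
    """Data log-likelihood: sum of log[g(d) / ESW(sigma, w)]."""
    sigma = np.exp(params.log_sigma(data))
    esw = esw_conventional(sigma, data.w) if conventional_hn else esw_paper(sigma, data.w)
    return float(np.sum(_log_g(data.d, sigma, conventional_hn) - np.log(esw)))


def hier_loglik_grad(params: HierParams, data: HierData,
                     conventional_hn: bool = False):
    """Analytic gradient of :func:`hier_loglik` w.r.t. delta, eta, gamma.

    Per sighting, with s = log sigma:
    d/ds log g(d)      = 2 (d / 2 sigma)^2          (printed form)
                       =   d^2 / sigma^2            (conventional form)
    d/ds log ESW       = sigma * (dESW/dsigma) / ESW.
    """
    sigma = np.exp(params.log_sigma(data))
    w = data.w
    if conventional_hn:
        dlogg = data.d**2 / sigma**2
        esw = esw_conventional(sigma, w)
        desw = (math.sqrt(math.pi / 2.0) * erf(w / (sigma * math.sqrt(2.0)))
                - (w / sigma) * np.exp(-(w * w) / (2.0 * sigma * sigma)))
    else:
        dlogg = 2.0 * (data.d / (2.0 * sigma)) ** 2
        esw = esw_paper(sigma, w)
        desw = SQRT_PI * erf(w / (2.0 * sigma)) - (w / sigma) * np.exp(-((w / (2.0 * sigma)) ** 2))
    per_obs = dlogg - sigma * desw / esw
    g_delta = np.zeros(2)
    g_eta = np.zeros_like(params.eta)
    g_gamma = np.zeros_like(params.gamma)
    np.add.at(g_delta, data.platform_idx, per_obs)
    np.add.at(g_eta, (data.observer_idx, data.platform_idx), per_obs)
    np.add.at(g_gamma, (data.species_idx, data.platform_idx), per_obs)
    return g_delta, g_eta, g_gamma


_HALF_T_DF = 3.0
_HALF_T_SCALE = 1.5


def _log_half_t(tau):
    """Half-Student-t(3, 1.5) log density (unnormalized constant kept)."""
    if np.any(np.asarray(tau) < 0):
        return -np.inf
    z = np.asarray(tau) / _HALF_T_SCALE
    return float(np.sum(-0.5 * (_HALF_T_DF + 1.0) * np.log1p(z * z / _HALF_T_DF)))


def _log_bvn_rows(rows, tau, rho):
    """Sum of centred bivariate-normal log densities for effect rows."""
    if np.any(tau <= 0) or abs(rho) >= 1:
        return -np.inf
    s1, s2 = tau
    det = (1 - rho * rho) * s1 * s1 * s2 * s2
    z1 = rows[:, 0] / s1
    z2 = rows[:, 1] / s2
    quad = (z1 * z1 - 2 * rho * z1 * z2 + z2 * z2) / (1 - rho * rho)
    n = rows.shape[0]
    return float(-0.5 * quad.sum() - 0.5 * n * math.log(det) - n * math.log(2 * math.pi))


def hier_logpost(params: HierParams, data: HierData | None,
                 conventional_hn: bool = False) -> float:
    """Log posterior (data may be None for prior-only sampling)."""
    lp = float(-0.5 * np.sum(params.delta**2))  # standard normal intercepts
    lp += _log_bvn_rows(params.eta, params.tau_obs, params.rho_obs)
    lp += _log_bvn_rows(params.gamma, params.tau_sp, params.rho_sp)
    lp += _log_half_t(params.tau_obs) + _log_half_t(params.tau_sp)
    # uniform prior on rho in (-1, 1): constant
    if not np.isfinite(lp):
        return -np.inf
    if data is not None:
        lp += hier_loglik(params, data, conventional_hn)
    return lp


# ---------------------------------------------------------------------------
# sampler


def _param_layout(J: int, K: int):
    """Flat-vector layout. tau sampled as log tau, rho as atanh rho."""
    names = [f"delta[{l}]" for l in range(2)]
    names += [f"eta[{j},{l}]" for j in range(J) for l in range(2)]
    names += [f"gamma[{k},{l}]" for k in range(K) for l in range(2)]
    names += ["log_tau_obs[0]", "log_tau_obs[1]", "atanh_rho_obs",
              "log_tau_sp[0]", "log_tau_sp[1]", "atanh_rho_sp"]
    return names


def _unpack(theta: np.ndarray, J: int, K: int) -> HierParams:
    i = 0
    delta = theta[i:i + 2]; i += 2
    eta = theta[i:i + 2 * J].reshape(J, 2); i += 2 * J
    gamma = theta[i:i + 2 * K].reshape(K, 2); i += 2 * K
    tau_obs = np.exp(theta[i:i + 2]); i += 2
    rho_obs = math.tanh(theta[i]); i += 1
    tau_sp = np.exp(theta[i:i + 2]); i += 2
    rho_sp = math.tanh(theta[i]); i += 1
    return HierParams(delta, eta, gamma, tau_obs, rho_obs, tau_sp, rho_sp)


def _logpost_theta(theta: np.ndarray, J: int, K: int, data: HierData | None,
                   conventional_hn: bool) -> float:
    p = _unpack(theta, J, K)
    lp = hier_logpost(p, data, conventional_hn)
    if not np.isfinite(lp):
        return -np.inf
    # Jacobians of the transforms: log tau (+= log tau each) and
    # atanh rho (+= log(1 - rho^2))
    idx = 2 + 2 * J + 2 * K
    lp += float(theta[idx] + theta[idx + 1])  # log tau_obs
    lp += math.log(1.0 - math.tanh(theta[idx + 2]) ** 2 + 1e-300)
    lp += float(theta[idx + 3] + theta[idx + 4])  # log tau_sp
    lp += math.log(1.0 - math.tanh(theta[idx + 5]) ** 2 + 1e-300)
    return lp


try:  # optional JIT of the hot loop; the pure-numpy path is equivalent
    import numba

    @numba.njit(cache=False, fastmath=False)
    def _logpost_theta_jit(theta, d, pidx, oidx, sidx, w, J, K, conventional):
        n_par = theta.shape[0]
        tau_idx = 2 + 2 * J + 2 * K
        lp = 0.0
        # priors: standard normal intercepts
        lp += -0.5 * (theta[0] * theta[0] + theta[1] * theta[1])
        # transformed scale/correlation parameters + Jacobians
        t_obs0 = math.exp(theta[tau_idx]); t_obs1 = math.exp(theta[tau_idx + 1])
        r_obs = math.tanh(theta[tau_idx + 2])
        t_sp0 = math.exp(theta[tau_idx + 3]); t_sp1 = math.exp(theta[tau_idx + 4])
        r_sp = math.tanh(theta[tau_idx + 5])
        for tau in (t_obs0, t_obs1, t_sp0, t_sp1):
            z = tau / 1.5
            lp += -0.5 * 4.0 * math.log(1.0 + z * z / 3.0)  # half-t(3, 1.5)
        lp += theta[tau_idx] + theta[tau_idx + 1] + theta[tau_idx + 3] + theta[tau_idx + 4]
        lp += math.log(1.0 - r_obs * r_obs + 1e-300)
        lp += math.log(1.0 - r_sp * r_sp + 1e-300)
        # bivariate normal effect rows
        for (base, rows, t0, t1, rho) in ((2, J, t_obs0, t_obs1, r_obs),
                                          (2 + 2 * J, K, t_sp0, t_sp1, r_sp)):
            det = (1.0 - rho * rho) * t0 * t0 * t1 * t1
            if det <= 0.0:
                return -np.inf
            for i in range(rows):
                z1 = theta[base + 2 * i] / t0
                z2 = theta[base + 2 * i + 1] / t1
                quad = (z1 * z1 - 2.0 * rho * z1 * z2 + z2 * z2) / (1.0 - rho * rho)
                lp += -0.5 * quad - 0.5 * math.log(det) - math.log(2.0 * math.pi)
        # likelihood
        for i in range(d.shape[0]):
            ls = (theta[pidx[i]]
                  + theta[2 + 2 * oidx[i] + pidx[i]]
                  + theta[2 + 2 * J + 2 * sidx[i] + pidx[i]])
            if ls > 20.0:
                ls = 20.0
            elif ls < -20.0:
                ls = -20.0
            sigma = math.exp(ls)
            if conventional:
                lp += -(d[i] * d[i]) / (2.0 * sigma * sigma)
                esw = sigma * math.sqrt(math.pi / 2.0) * math.erf(
                    w[i] / (sigma * math.sqrt(2.0)))
            else:
                x = d[i] / (2.0 * sigma)
                lp += -x * x
                esw = sigma * math.sqrt(math.pi) * math.erf(w[i] / (2.0 * sigma))
            lp -= math.log(esw)
        return lp

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover - numba always present in CI image
    _HAVE_NUMBA = False


def _make_logpost(data: HierData | None, J: int, K: int, conventional_hn: bool):
    """Return a fast theta -> log posterior callable."""
    if data is None or not _HAVE_NUMBA:
        return lambda theta: _logpost_theta(theta, J, K, data, conventional_hn)
    d = np.ascontiguousarray(data.d, dtype=np.float64)
    pidx = np.ascontiguousarray(data.platform_idx, dtype=np.int64)
    oidx = np.ascontiguousarray(data.observer_idx, dtype=np.int64)
    sidx = np.ascontiguousarray(data.species_idx, dtype=np.int64)
    w = np.ascontiguousarray(data.w, dtype=np.float64)

    def f(theta):
        return _logpost_theta_jit(theta, d, pidx, oidx, sidx, w, J, K,
                                  conventional_hn)

    return f


def sample_posterior(data: HierData | None, config: McmcConfig,
                     J: int | None = None, K: int | None = None,
                     conventional_hn: bool = False) -> PosteriorSample:
    """Adaptive Metropolis-within-Gibbs sampler.

    Scalar coordinates are updated in turn with Gaussian random-walk
    proposals; the proposal scales adapt every 50 iterations during
    warm-up (targeting acceptance 0.2-0.5) and are frozen afterwards.
    Chains are seeded independently from ``config.seed``. A non-finite
    log density at initialization triggers up to 10 re-initializations.
    """
    if data is not None:
        J, K = data.n_observers, data.n_species
    if J is None or K is None:
        raise ValueError("J and K required for prior-only sampling")
    names = _param_layout(J, K)
    n_par = len(names)
    logpost = _make_logpost(data, J, K, conventional_hn)
    kept_per_chain = config.n_iter // config.thin
    draws = np.empty((config.n_chains, kept_per_chain, n_par))
    acc_all = np.empty((config.n_chains, n_par))
    root = np.random.default_rng(config.seed)
    chain_seeds = root.integers(0, 2**63 - 1, config.n_chains)

    for ci in range(config.n_chains):
        rng = np.random.default_rng(chain_seeds[ci])
        theta = None
        for _attempt in range(10):
            cand = rng.normal(0.0, 0.3, n_par)
            if np.isfinite(logpost(cand)):
                theta = cand
                break
        if theta is None:
            raise RuntimeError("could not initialize chain with finite log density")
        lp = logpost(theta)
        step = np.full(n_par, 0.3)
        acc = np.zeros(n_par)
        tries = np.zeros(n_par)
        # translation moves shift an intercept and recentre one effect
        # column the opposite way; the likelihood depends only on the sum
        # so these moves walk along its ridge and decorrelate delta from
        # the effect means
        eta_cols = [np.array([2 + 2 * j + l for j in range(J)]) for l in range(2)]
        gamma_cols = [np.array([2 + 2 * J + 2 * k + l for k in range(K)]) for l in range(2)]
        trans_step = np.full(4, 0.2)
        trans_acc = np.zeros(4)
        trans_tries = np.zeros(4)
        scale_step = np.full(4, 0.2)
        scale_acc = np.zeros(4)
        scale_tries = np.zeros(4)
        kept = 0
        total = config.n_warmup + config.n_iter
        for it in range(total):
            warm = it < config.n_warmup
            for pi in range(n_par):
                prop = theta.copy()
                prop[pi] += rng.normal(0.0, step[pi])
                lp_prop = logpost(prop)
                if lp_prop - lp > math.log(rng.uniform() + 1e-300):
                    theta = prop
                    lp = lp_prop
                    acc[pi] += 1
                tries[pi] += 1
            for mi, (l, cols) in enumerate(
                    ((0, eta_cols[0]), (1, eta_cols[1]),
                     (0, gamma_cols[0]), (1, gamma_cols[1]))):
                eps = rng.normal(0.0, trans_step[mi])
                prop = theta.copy()
                prop[l] += eps
                prop[cols] -= eps
                lp_prop = logpost(prop)
                if lp_prop - lp > math.log(rng.uniform() + 1e-300):
                    theta = prop
                    lp = lp_prop
                    trans_acc[mi] += 1
                trans_tries[mi] += 1
            # funnel scale moves: multiply one effect column by exp(eps)
            # and shift the matching log tau by eps (Jacobian J or K from
            # the column rescaling)
            tau_idx = 2 + 2 * J + 2 * K
            for mi, (cols, ti, ncol) in enumerate(
                    ((eta_cols[0], tau_idx, J), (eta_cols[1], tau_idx + 1, J),
                     (gamma_cols[0], tau_idx + 3, K), (gamma_cols[1], tau_idx + 4, K))):
                eps = rng.normal(0.0, scale_step[mi])
                prop = theta.copy()
                prop[ti] += eps
                prop[cols] *= math.exp(eps)
                lp_prop = logpost(prop)
                if lp_prop - lp + ncol * eps > math.log(rng.uniform() + 1e-300):
                    theta = prop
                    lp = lp_prop
                    scale_acc[mi] += 1
                scale_tries[mi] += 1
            if warm and (it + 1) % 50 == 0:
                trate = trans_acc / np.maximum(trans_tries, 1)
                trans_step *= np.exp(1.2 * (trate - 0.35))
                trans_step = np.clip(trans_step, 1e-4, 10.0)
                trans_acc[:] = 0
                trans_tries[:] = 0
                srate = scale_acc / np.maximum(scale_tries, 1)
                scale_step *= np.exp(1.2 * (srate - 0.35))
                scale_step = np.clip(scale_step, 1e-4, 10.0)
                scale_acc[:] = 0
                scale_tries[:] = 0
                rate = acc / np.maximum(tries, 1)
                step *= np.exp(1.2 * (rate - 0.35))
                step = np.clip(step, 1e-4, 10.0)
                acc[:] = 0
                tries[:] = 0
            if not warm and (it - config.n_warmup + 1) % config.thin == 0:
                draws[ci, kept] = theta
                kept += 1
        acc_all[ci] = acc / np.maximum(tries, 1)
        assert kept == kept_per_chain

    return PosteriorSample(draws=draws, param_names=names, data=data,
                           config=config, conventional_hn=conventional_hn,
                           acceptance=acc_all)


# ---------------------------------------------------------------------------
# diagnostics and summaries


def rhat(chains: np.ndarray) -> float:
    """Classic Gelman-Rubin potential scale reduction factor.

    ``chains`` has shape (m, n). Returns NaN (flagged undefined) when
    the within-chain variance is zero.
    """
    chains = np.asarray(chains, float)
    if chains.ndim != 2 or chains.shape[0] < 2 or chains.shape[1] < 10:
        raise ValueError("need >= 2 chains of >= 10 draws")
    m, n = chains.shape
    means = chains.mean(axis=1)
    W = chains.var(axis=1, ddof=1).mean()
    if W <= 0:
        return float("nan")
    B = n * means.var(ddof=1)
    var_plus = (n - 1) / n * W + B / n
    return float(math.sqrt(var_plus / W))


def esw_summaries(sample: PosteriorSample, truncations: dict | None = None,
                  level: float = 0.90) -> pd.DataFrame:
    """Posterior ESW summaries per platform-observer-species combination.

    Also attaches (as ``frame.attrs['variance_partition']``) the spread
    of species-level vs observer-level posterior-mean ESWs per platform,
    the analogue of the variance-partition comparison.
    """
    data = sample.data
    if data is None:
        raise ValueError("no data attached to the posterior sample")
    J, K = data.n_observers, data.n_species
    pooled = sample.pooled
    esw_fun = esw_conventional if sample.conventional_hn else esw_paper

    # per-species truncation (km)
    if truncations is not None and hasattr(data, "species_labels"):
        w_of_species = np.array([truncations[s] for s in data.species_labels])
    else:
        w_of_species = np.full(K, np.nan)
        for k in range(K):
            mask = data.species_idx == k
            if mask.any():
                w_of_species[k] = data.w[mask][0]

    combos = sorted({(int(l), int(j), int(k)) for l, j, k in
                     zip(data.platform_idx, data.observer_idx, data.species_idx)})
    lo_q, hi_q = 50 * (1 - level), 50 * (1 + level)
    rows = []
    for l, j, k in combos:
        ls = (pooled[:, l]
              + pooled[:, 2 + 2 * j + l]
              + pooled[:, 2 + 2 * J + 2 * k + l])
        esw = esw_fun(np.exp(ls), w_of_species[k])
        rows.append({
            "platform": l, "observer": j, "species": k,
            "esw_mean": float(esw.mean()),
            "esw_sd": float(esw.std(ddof=1)),
            "esw_cv": float(esw.std(ddof=1) / esw.mean()),
            "ci_low": float(np.percentile(esw, lo_q)),
            "ci_high": float(np.percentile(esw, hi_q)),
            "n_sightings": int(np.sum((data.platform_idx == l)
                                      & (data.observer_idx == j)
                                      & (data.species_idx == k))),
        })
    out = pd.DataFrame(rows)

    # variance partition: spread across species (eta = 0) vs across
    # observers (gamma = 0) of posterior-mean ESWs, per platform
    part = []
    for l in range(2):
        w_ref = float(np.nanmean(w_of_species))
        sp_esws = []
        for k in range(K):
            ls = pooled[:, l] + pooled[:, 2 + 2 * J + 2 * k + l]
            sp_esws.append(float(esw_fun(np.exp(ls), w_ref).mean()))
        obs_esws = []
        for j in range(J):
            ls = pooled[:, l] + pooled[:, 2 + 2 * j + l]
            obs_esws.append(float(esw_fun(np.exp(ls), w_ref).mean()))
        part.append({
            "platform": l,
            "species_spread": float(np.std(sp_esws, ddof=1)) if K > 1 else 0.0,
            "observer_spread": float(np.std(obs_esws, ddof=1)) if J > 1 else 0.0,
        })
    out.attrs["variance_partition"] = pd.DataFrame(part)
    return out


def fit_single_sigma(distances, w: float, conventional_hn: bool = False) -> float:
    """Unpooled MLE of sigma for one combination (used for shrinkage checks)."""
    d = np.asarray(distances, float)

    def nll(log_sigma):
        sigma = math.exp(log_sigma[0])
        esw = (esw_conventional(sigma, w) if conventional_hn else esw_paper(sigma, w))
        return float(-np.sum(_log_g(d, sigma, conventional_hn)) + d.size * math.log(esw))

    res = optimize.minimize(nll, np.array([math.log(max(d.std(), 1e-3))]),
                            method="Nelder-Mead",
                            options={"xatol": 1e-10, "fatol": 1e-12})
    return math.exp(res.x[0])
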