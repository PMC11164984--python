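"""Two-level hierarchical Student-t model over patch correlations.

Each biological condition c (sample S, control C) carries global
parameters: the group-level mean correlation rho_c on (-1, 1), the
between-image spread sigma_c on (0, 1), the spread-of-spreads tau_c on
(0, 1) — all with truncated Cauchy(0, 0.3) priors — and degrees of
freedom nu_c with an Exponential(1) prior.  Each image I contributes
image-level parameters rho_I ~ Normal(rho_c, sigma_c) on (-1, 1),
sigma_I ~ Normal(sigma_c, tau_c) on (0, 1) and nu_I ~ Exponential with
mean nu_c.  Every patch correlation of image I is modelled as
StudentT(nu_I, rho_I, sigma_I); the heavy tails make the fit robust to
outlier patches.

Inference is mean-field ADVI: a factorized Gaussian over the
unconstrained coordinates is optimized with Adam using exact
reparameterized gradients of the log joint.  An asymptotically exact
ensemble MCMC sampler (emcee) over the same unconstrained density is
provided as a validation fallback (``engine="mcmc"``).

The hypothesis test is a Bayes factor on the group-level difference
delta_rho = rho_S - rho_C:

    BF[H1 : delta_rho > t : H0 : delta_rho <= t]
        = P(delta_rho > t | data) / P(delta_rho <= t | data)
        * P(delta_rho <= t) / P(delta_rho > t)

with prior tail masses from Monte-Carlo draws of the truncated-Cauchy
priors and a default threshold t = 0.1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._math import (
    INTERVAL_0_1,
    INTERVAL_M1_1,
    POSITIVE,
    constrain,
    student_t_logpdf_grad,
    trunc_cauchy_dlogpdf,
    trunc_cauchy_logpdf,
    trunc_cauchy_rvs,
    unconstrain,
)

logger = logging.getLogger("bayescoloc")

GLOBAL_PARAMS = ("rho_S", "sigma_S", "tau_S", "nu_S", "rho_C", "sigma_C", "tau_C", "nu_C")


@dataclass(frozen=True)
class PriorSpec:
    """Hyperprior scales of the hierarchical model.

    ``rho_scale``/``sigma_scale``/``tau_scale`` are half-widths of the
    truncated Cauchy(0, .) priors on the group mean correlation and the
    two spread parameters; ``nu_rate`` is the Exponential rate on the
    group degrees of freedom.
    """

    rho_scale: float = 0.3
    sigma_scale: float = 0.3
    tau_scale: float = 0.3
    nu_rate: float = 1.0

    def __post_init__(self) -> None:
        for name in ("rho_scale", "sigma_scale", "tau_scale", "nu_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass(frozen=True)
class FitConfig:
    """Inference settings.

    ``vi_iterations`` Adam steps of ADVI (default 10,000) and
    ``posterior_samples`` draws from the fitted posterior (default
    100,000).  ``engine`` selects mean-field ADVI (``"vi"``) or the
    exact ensemble sampler (``"mcmc"``).
    """

    vi_iterations: int = 10_000
    posterior_samples: int = 100_000
    seed: int = 0
    engine: str = "vi"
    learning_rate: float = 0.02
    mc_samples: int = 4
    mcmc_burn: int = 1_500
    mcmc_thin: int = 3
    nu_floor: float = 0.01

    def __post_init__(self) -> None:
        if self.vi_iterations < 1 or self.posterior_samples < 1:
            raise ValueError("iteration and sample counts must be positive")
        if self.engine not in ("vi", "mcmc"):
            raise ValueError("engine must be 'vi' or 'mcmc'")


@dataclass
class HierarchicalDraws:
    """Joint posterior draws of the global and image-level parameters."""

    params: dict[str, np.ndarray]
    n_images: dict[str, int]
    engine: str
    diagnostics: dict = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return self.params["rho_S"].shape[0]

    def delta_rho(self) -> np.ndarray:
        return self.params["rho_S"] - self.params["rho_C"]

    def to_frame(self):
        """Draws as a DataFrame, image-level columns suffixed ``_i<k>``."""
        import pandas as pd

        cols: dict[str, np.ndarray] = {}
        for name, arr in self.params.items():
            if arr.ndim == 1:
                cols[name] = arr
            else:
                for k in range(arr.shape[1]):
                    cols[f"{name}_i{k}"] = arr[:, k]
        cols["delta_rho"] = self.delta_rho()
        return pd.DataFrame(cols)


@dataclass
class BayesResult:
    """Bayes-factor test result on delta_rho = rho_S - rho_C."""

    delta_rho_posterior: np.ndarray
    delta_rho_prior: np.ndarray
    delta_rho0: float
    bf: float
    bf_bound: str | None
    evidence: str
    summaries: dict[str, dict[str, float]]
    bf_thresholds: np.ndarray
    bf_log10: np.ndarray


# ---------------------------------------------------------------------------
# model internals


class _ConditionData:
    """Patch correlations of one condition, concatenated image-wise."""

    def __init__(self, corr_lists: list[np.ndarray]):
        self.n_images = len(corr_lists)
        self.r = np.concatenate(corr_lists)
        counts = np.array([len(c) for c in corr_lists])
        self.starts = np.concatenate([[0], np.cumsum(counts)[:-1]])
        self.img_idx = np.repeat(np.arange(self.n_images), counts)


class _HierarchicalModel:
    """Log joint density and gradient in unconstrained coordinates."""

    def __init__(self, sample: _ConditionData, control: _ConditionData,
                 prior: PriorSpec, nu_floor: float = 0.01):
        self.sample = sample
        self.control = control
        self.prior = prior
        self.nu_floor = nu_floor
        nS, nC = sample.n_images, control.n_images
        # layout: per condition [rho, sigma, tau, nu, rho_I*, sigma_I*, nu_I*]
        self.block = 4 + 3 * nS  # offset of the control block
        self.dim = 8 + 3 * (nS + nC)
        kinds = []
        for n in (nS, nC):
            kinds += [INTERVAL_M1_1, INTERVAL_0_1, INTERVAL_0_1, POSITIVE]
            kinds += [INTERVAL_M1_1] * n + [INTERVAL_0_1] * n + [POSITIVE] * n
        self.kinds = np.array(kinds)

    def _views(self, theta: np.ndarray, cond: str):
        off = 0 if cond == "S" else self.block
        n = (self.sample if cond == "S" else self.control).n_images
        g = theta[..., off : off + 4]
        rho_i = theta[..., off + 4 : off + 4 + n]
        sigma_i = theta[..., off + 4 + n : off + 4 + 2 * n]
        nu_i = theta[..., off + 4 + 2 * n : off + 4 + 3 * n]
        return g, rho_i, sigma_i, nu_i

    def _condition_logp_grad(self, theta, grad, cond: str, data: _ConditionData):
        from ._math import trunc_normal_logpdf_grad

        p = self.prior
        off = 0 if cond == "S" else self.block
        n = data.n_images
        g, rho_i, sigma_i, nu_i = self._views(theta, cond)
        gg, grho_i, gsigma_i, gnu_i = self._views(grad, cond)
        rho, sigma, tau, nu = g[..., 0], g[..., 1], g[..., 2], g[..., 3]

        logp = np.zeros(theta.shape[:-1])

        # global priors (truncation normalizers are parameter-free)
        logp += trunc_cauchy_logpdf(rho, p.rho_scale, -1.0, 1.0)
        gg[..., 0] += trunc_cauchy_dlogpdf(rho, p.rho_scale)
        logp += trunc_cauchy_logpdf(sigma, p.sigma_scale, 0.0, 1.0)
        gg[..., 1] += trunc_cauchy_dlogpdf(sigma, p.sigma_scale)
        logp += trunc_cauchy_logpdf(tau, p.tau_scale, 0.0, 1.0)
        gg[..., 2] += trunc_cauchy_dlogpdf(tau, p.tau_scale)
        logp += np.log(p.nu_rate) - p.nu_rate * nu
        gg[..., 3] += -p.nu_rate

        # image-level: rho_I ~ TruncNormal(rho, sigma) on (-1, 1)
        lp, dx, dmu, dsig = trunc_normal_logpdf_grad(
            rho_i, rho[..., None], sigma[..., None], -1.0, 1.0
        )
        logp += lp.sum(axis=-1)
        grho_i += dx
        gg[..., 0] += dmu.sum(axis=-1)
        gg[..., 1] += dsig.sum(axis=-1)

        # sigma_I ~ TruncNormal(sigma, tau) on (0, 1)
        lp, dx, dmu, dsig = trunc_normal_logpdf_grad(
            sigma_i, sigma[..., None], tau[..., None], 0.0, 1.0
        )
        logp += lp.sum(axis=-1)
        gsigma_i += dx
        gg[..., 1] += dmu.sum(axis=-1)
        gg[..., 2] += dsig.sum(axis=-1)

        # nu_I ~ Exponential with mean nu
        lp = -np.log(nu[..., None]) - nu_i / nu[..., None]
        logp += lp.sum(axis=-1)
        gnu_i += -1.0 / nu[..., None]
        gg[..., 3] += (-n / nu + nu_i.sum(axis=-1) / nu**2)

        # likelihood: r ~ StudentT(max(nu_I, floor), rho_I, sigma_I)
        idx = data.img_idx
        rho_p = rho_i[..., idx]
        sigma_p = sigma_i[..., idx]
        nu_p = nu_i[..., idx]
        nu_eff = np.maximum(nu_p, self.nu_floor)
        lp, ddf, dloc, dscale = student_t_logpdf_grad(data.r, nu_eff, rho_p, sigma_p)
        logp += lp.sum(axis=-1)
        ddf = np.where(nu_p > self.nu_floor, ddf, 0.0)
        grho_i += np.add.reduceat(dloc, data.starts, axis=-1)
        gsigma_i += np.add.reduceat(dscale, data.starts, axis=-1)
        gnu_i += np.add.reduceat(ddf, data.starts, axis=-1)
        return logp

    def logp_grad_theta(self, theta: np.ndarray):
        """Log joint and gradient in constrained coordinates."""
        grad = np.zeros_like(theta)
        logp = self._condition_logp_grad(theta, grad, "S", self.sample)
        logp = logp + self._condition_logp_grad(theta, grad, "C", self.control)
        return logp, grad

    def logp_grad_z(self, z: np.ndarray):
        """Log joint plus log|Jacobian| and gradient, unconstrained."""
        theta, dtheta, logjac, dlogjac = constrain(z, self.kinds)
        logp, grad_theta = self.logp_grad_theta(theta)
        g = logp + logjac.sum(axis=-1)
        grad_z = grad_theta * dtheta + dlogjac
        return g, grad_z

    def logp_z(self, z: np.ndarray):
        return self.logp_grad_z(z)[0]

    def initial_z(self) -> np.ndarray:
        """Unconstrained start near the empirical moments of the data."""
        theta = np.empty(self.dim)
        for cond, data in (("S", self.sample), ("C", self.control)):
            off = 0 if cond == "S" else self.block
            n = data.n_images
            means = np.array(
                [np.mean(data.r[data.img_idx == i]) for i in range(n)]
            ).clip(-0.9, 0.9)
            sds = np.array(
                [np.std(data.r[data.img_idx == i]) for i in range(n)]
            ).clip(0.05, 0.5)
            theta[off] = np.clip(means.mean(), -0.9, 0.9)
            theta[off + 1] = np.clip(max(means.std(), sds.mean()), 0.05, 0.5)
            theta[off + 2] = 0.1
            theta[off + 3] = 1.0
            theta[off + 4 : off + 4 + n] = means
            theta[off + 4 + n : off + 4 + 2 * n] = sds
            theta[off + 4 + 2 * n : off + 4 + 3 * n] = 1.0
        return unconstrain(theta, self.kinds)

    def unpack(self, theta_draws: np.ndarray) -> dict[str, np.ndarray]:
        """Split (n_draws, dim) constrained draws into named arrays."""
        out: dict[str, np.ndarray] = {}
        for cond, data in (("S", self.sample), ("C", self.control)):
            g, rho_i, sigma_i, nu_i = self._views(theta_draws, cond)
            out[f"rho_{cond}"] = g[..., 0]
            out[f"sigma_{cond}"] = g[..., 1]
            out[f"tau_{cond}"] = g[..., 2]
            out[f"nu_{cond}"] = g[..., 3]
            out[f"rho_img_{cond}"] = rho_i
            out[f"sigma_img_{cond}"] = sigma_i
            out[f"nu_img_{cond}"] = nu_i
        return out


def _advi(model: _HierarchicalModel, config: FitConfig, rng: np.random.Generator):
    """Mean-field Gaussian ADVI with Adam on the reparameterized ELBO."""
    d = model.dim
    mu = model.initial_z()
    omega = np.full(d, -2.0)  # log posterior sd, start tight-ish

    m_mu = np.zeros(d); v_mu = np.zeros(d)
    m_om = np.zeros(d); v_om = np.zeros(d)
    b1, b2, eps = 0.9, 0.999, 1e-8
    lr = config.learning_rate
    elbo_trace = []
    n_mc = config.mc_samples

    for it in range(1, config.vi_iterations + 1):
        epsilon = rng.standard_normal((n_mc, d))
        z = mu + np.exp(omega) * epsilon
        g, grad_z = model.logp_grad_z(z)
        grad_mu = grad_z.mean(axis=0)
        grad_om = (grad_z * epsilon).mean(axis=0) * np.exp(omega) + 1.0

        m_mu = b1 * m_mu + (1 - b1) * grad_mu
        v_mu = b2 * v_mu + (1 - b2) * grad_mu**2
        m_om = b1 * m_om + (1 - b1) * grad_om
        v_om = b2 * v_om + (1 - b2) * grad_om**2
        corr1 = 1 - b1**it
        corr2 = 1 - b2**it
        mu += lr * (m_mu / corr1) / (np.sqrt(v_mu / corr2) + eps)
        omega += lr * (m_om / corr1) / (np.sqrt(v_om / corr2) + eps)

        if it % 200 == 0 or it == config.vi_iterations:
            elbo = float(g.mean() + omega.sum())
            elbo_trace.append((it, elbo))
    logger.info("ADVI finished: %d iterations, ELBO %.2f", config.vi_iterations,
                elbo_trace[-1][1] if elbo_trace else float("nan"))
    return mu, omega, elbo_trace


def _sample_vi(model, mu, omega, n, rng):
    z = mu + np.exp(omega) * rng.standard_normal((n, model.dim))
    theta, *_ = constrain(z, model.kinds)
    return theta


def _sample_mcmc(model: _HierarchicalModel, config: FitConfig, seed: int):
    import emcee

    d = model.dim
    nwalkers = max(2 * d + 2, 48)
    nwalkers += nwalkers % 2
    rng = np.random.default_rng(seed)
    z0 = model.initial_z() + 0.1 * rng.standard_normal((nwalkers, d))

    sampler = emcee.EnsembleSampler(nwalkers, d, model.logp_z, vectorize=True)
    sampler.random_state = np.random.RandomState(seed % (2**31)).get_state()
    keep_steps = int(np.ceil(config.posterior_samples * config.mcmc_thin / nwalkers))
    sampler.run_mcmc(z0, config.mcmc_burn + keep_steps)
    chain = sampler.get_chain(discard=config.mcmc_burn, thin=config.mcmc_thin)
    z = chain.reshape(-1, d)[: config.posterior_samples]
    theta, *_ = constrain(z, model.kinds)
    acc = float(sampler.acceptance_fraction.mean())
    logger.info("MCMC finished: %d walkers, mean acceptance %.2f", nwalkers, acc)
    return theta, {"acceptance_fraction": acc, "n_walkers": nwalkers}


def _clean_condition(corr_lists, label: str) -> list[np.ndarray]:
    kept = []
    for i, corrs in enumerate(corr_lists):
        arr = np.asarray(corrs, dtype=float)
        arr = arr[np.isfinite(arr)]
        if arr.size < 2:
            logger.warning(
                "WARN-IMAGE-DROPPED condition %s image %d: %d valid patch "
                "correlations (< 2), dropped from the fit", label, i, arr.size,
            )
            continue
        if np.abs(arr).max() > 1.0:
            raise ValueError(f"condition {label}: correlations outside [-1, 1]")
        kept.append(arr)
    if not kept:
        raise ValueError(f"condition {label}: no image with >= 2 valid patch correlations")
    return kept


def fit_model(
    sample_corrs,
    control_corrs,
    prior: PriorSpec | None = None,
    config: FitConfig | None = None,
) -> HierarchicalDraws:
    """Fit the hierarchical model to per-image patch-correlation lists.

    Parameters
    ----------
    sample_corrs, control_corrs
        One array-like of patch correlations per image; images with
        fewer than two valid values are dropped with a warning.
    """
    prior = prior or PriorSpec()
    config = config or FitConfig()
    sample = _ConditionData(_clean_condition(sample_corrs, "sample"))
    control = _ConditionData(_clean_condition(control_corrs, "control"))
    model = _HierarchicalModel(sample, control, prior, config.nu_floor)

    ss = np.random.SeedSequence(config.seed)
    s_fit, s_draw = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2))
    diagnostics: dict = {"engine": config.engine}
    if config.engine == "vi":
        rng = np.random.default_rng(s_fit)
        mu, omega, trace = _advi(model, config, rng)
        theta = _sample_vi(model, mu, omega, config.posterior_samples,
                           np.random.default_rng(s_draw))
        diagnostics["elbo_trace"] = trace
    else:
        theta, mcmc_diag = _sample_mcmc(model, config, s_fit)
        diagnostics.update(mcmc_diag)

    params = model.unpack(theta)
    _check_supports(params)
    return HierarchicalDraws(
        params=params,
        n_images={"S": sample.n_images, "C": control.n_images},
        engine=config.engine,
        diagnostics=diagnostics,
    )


def _check_supports(params: dict[str, np.ndarray]) -> None:
    for key in ("rho_S", "rho_C", "rho_img_S", "rho_img_C"):
        assert np.all(np.abs(params[key]) < 1.0), f"{key} outside (-1, 1)"
    for key in ("sigma_S", "sigma_C", "tau_S", "tau_C", "sigma_img_S", "sigma_img_C"):
        assert np.all((params[key] > 0) & (params[key] < 1)), f"{key} outside (0, 1)"
    for key in ("nu_S", "nu_C", "nu_img_S", "nu_img_C"):
        assert np.all(params[key] > 0), f"{key} not positive"


# ---------------------------------------------------------------------------
# priors, Bayes factors, summaries


def sample_prior_delta_rho(prior: PriorSpec, n: int, seed: int) -> np.ndarray:
    """Monte-Carlo prior draws of delta_rho = rho_S - rho_C.

    Both group means have independent Cauchy(0, rho_scale) priors
    truncated to (-1, 1); the difference has no closed form, so it is
    sampled (inverse-CDF, rejection-free).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    rho_s = trunc_cauchy_rvs(prior.rho_scale, -1.0, 1.0, n, rng)
    rho_c = trunc_cauchy_rvs(prior.rho_scale, -1.0, 1.0, n, rng)
    return rho_s - rho_c


def compute_bf(
    posterior_delta: np.ndarray,
    prior_delta: np.ndarray,
    delta_rho0: float = 0.1,
) -> float:
    """Bayes factor BF[H1 : delta_rho > t : H0 : delta_rho <= t].

    Posterior odds of the two tails divided by the prior odds, both
    estimated as Monte-Carlo tail proportions.  A tail with zero
    sampled mass is replaced by 1/(M+1) draws, so the result is then a
    one-sided bound (see :func:`compute_bf_detail`).
    """
    return compute_bf_detail(posterior_delta, prior_delta, delta_rho0)[0]


def compute_bf_detail(posterior_delta, prior_delta, delta_rho0: float = 0.1,
                      warn: bool = True):
    """As :func:`compute_bf`, returning ``(bf, bound)``.

    ``bound`` is ``None`` for a two-sided estimate, ``"lower"`` when the
    posterior H0 tail was empty (true BF at least this large) and
    ``"upper"`` when the H1 tail was empty.
    """
    post = np.asarray(posterior_delta, dtype=float)
    prior = np.asarray(prior_delta, dtype=float)
    if post.size == 0 or prior.size == 0:
        raise ValueError("draw sets must be non-empty")

    def _tail(draws):
        m = draws.size
        k = int(np.count_nonzero(draws > delta_rho0))
        bound = None
        if k == 0:
            p1, bound = 1.0 / (m + 1), "upper"
        elif k == m:
            p1, bound = m / (m + 1.0), "lower"
        else:
            p1 = k / m
        return p1, 1.0 - p1, bound

    p1_post, p0_post, bound = _tail(post)
    p1_prior, p0_prior, prior_bound = _tail(prior)
    if warn and prior_bound is not None:
        logger.warning("WARN-BF-TAIL prior tail at %.3g has zero sampled mass", delta_rho0)
    if warn and bound is not None:
        logger.warning(
            "WARN-BF-TAIL posterior tail at %.3g empty; BF reported as %s bound",
            delta_rho0, bound,
        )
    bf = (p1_post / p0_post) * (p0_prior / p1_prior)
    return float(bf), bound


def bf_curve(
    posterior_delta: np.ndarray,
    prior_delta: np.ndarray,
    thresholds: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """log10 Bayes factor over a grid of delta_rho0 thresholds.

    The default grid spans (-0.8, 0.8) in steps of 0.02 and covers the
    default threshold 0.1.
    """
    if thresholds is None:
        thresholds = np.round(np.linspace(-0.8, 0.8, 81), 10)
    thresholds = np.asarray(thresholds, dtype=float)
    if thresholds.size and (thresholds.min() <= -1 or thresholds.max() >= 1):
        raise ValueError("thresholds must lie inside (-1, 1)")
    log10_bf = np.array([
        np.log10(compute_bf_detail(posterior_delta, prior_delta, t, warn=False)[0])
        for t in thresholds
    ])
    return thresholds, log10_bf


def summarize_draws(draws: np.ndarray, level: float = 0.95) -> dict[str, float]:
    """Mean and equal-tailed credible interval of one draw vector."""
    draws = np.asarray(draws, dtype=float)
    if draws.size == 0:
        raise ValueError("draws must be non-empty")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(draws, [alpha, 1.0 - alpha])
    return {"mean": float(draws.mean()), "lo": float(lo), "hi": float(hi)}


def posterior_summary(draws: HierarchicalDraws, level: float = 0.95):
    """Means and equal-tailed CIs of all global parameters plus delta_rho."""
    out = {name: summarize_draws(draws.params[name], level) for name in GLOBAL_PARAMS}
    out["delta_rho"] = summarize_draws(draws.delta_rho(), level)
    return out


#: Lee-Wagenmakers evidence bands (upper edges, label).
_BANDS = [
    (3.0, "anecdotal"),
    (10.0, "moderate"),
    (30.0, "strong"),
    (100.0, "very strong"),
    (np.inf, "extreme"),
]


def interpret_bf(bf: float) -> str:
    """Evidence label on the Lee-Wagenmakers 1/3/10/30/100 scale."""
    if not bf > 0:
        raise ValueError("Bayes factor must be > 0")
    if bf == 1.0:
        return "no evidence"
    hypothesis = "H1" if bf > 1 else "H0"
    ratio = bf if bf > 1 else 1.0 / bf
    for upper, label in _BANDS:
        if ratio <= upper:
            return f"{label} evidence for {hypothesis}"
    raise AssertionError("unreachable")


def make_bayes_result(
    draws: HierarchicalDraws,
    prior: PriorSpec | None = None,
    delta_rho0: float = 0.1,
    n_prior_draws: int = 100_000,
    seed: int = 0,
    thresholds: np.ndarray | None = None,
) -> BayesResult:
    """Assemble the Bayes-factor result from fitted posterior draws."""
    prior = prior or PriorSpec()
    post_delta = draws.delta_rho()
    prior_delta = sample_prior_delta_rho(prior, n_prior_draws, seed)
    bf, bound = compute_bf_detail(post_delta, prior_delta, delta_rho0)
    ts, log10_bf = bf_curve(post_delta, prior_delta, thresholds)
    return BayesResult(
        delta_rho_posterior=post_delta,
        delta_rho_prior=prior_delta,
        delta_rho0=delta_rho0,
        bf=bf,
        bf_bound=bound,
        evidence=interpret_bf(bf),
        summaries=posterior_summary(draws),
        bf_thresholds=ts,
        bf_log10=log10_bf,
    )
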