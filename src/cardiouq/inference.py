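"""Bayesian inference of maximal conductances from voltage traces.

The observation model is ``observed = simulated + noise`` with iid Normal
noise of unknown sd sigma, so the log-likelihood of a trace is the sum of
per-sample Normal log-densities of the residuals. Priors are uniform:
0.1x to 10x the published value for each conductance and (0, 25] mV for
sigma. The posterior is explored with an adaptive-covariance Metropolis
chain started from the best point found by CMA-ES.

Identifiability of a parameter is scored by its mean absolute percentage
error over the post-burn-in chain,

    M_i = (1/N) sum_t |theta_hat_i - theta_{t,i}| / theta_hat_i,

and a parameter counts as successfully inferred when ``M_i < 0.05``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .models.base import CellModel, Conditions, ParameterVector
from .protocols import Protocol
from .simulation import SimulationError, VoltageTrace, add_noise, prepace, run

__all__ = [
    "Prior",
    "PosteriorChain",
    "IdentifiabilityReport",
    "TraceLikelihood",
    "log_likelihood",
    "cmaes_minimize",
    "cmaes_start",
    "run_mcmc",
    "postprocess",
    "credible_interval",
    "mape_metric",
    "identifiability_study",
]

SUCCESS_THRESHOLD = 0.05  # M_i below this counts as successfully inferred
DEFAULT_SIGMA_UPPER = 25.0  # mV; generous proper prior for the noise sd


@dataclass(frozen=True)
class Prior:
    """Independent uniform prior box (conductances plus noise sd)."""

    names: tuple
    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self):
        if np.any(self.lower >= self.upper):
            raise ValueError("prior requires lower < upper for every parameter")

    @classmethod
    def for_model(
        cls,
        model: CellModel,
        factor_low: float = 0.1,
        factor_high: float = 10.0,
        sigma_upper: float = DEFAULT_SIGMA_UPPER,
        include_sigma: bool = True,
    ) -> "Prior":
        theta = model.defaults.to_array()
        names = list(model.parameter_names)
        lower = factor_low * theta
        upper = factor_high * theta
        if include_sigma:
            names.append("sigma")
            lower = np.append(lower, 0.0)
            upper = np.append(upper, sigma_upper)
        return cls(tuple(names), lower, upper)

    @property
    def dim(self) -> int:
        return self.lower.size

    def contains(self, x: np.ndarray) -> bool:
        return bool(np.all(x > self.lower) and np.all(x <= self.upper))

    def log_pdf(self, x: np.ndarray) -> float:
        return 0.0 if self.contains(x) else -np.inf

    def sample(self, rng: np.random.Generator, n: int | None = None) -> np.ndarray:
        size = (n, self.dim) if n is not None else self.dim
        return rng.uniform(self.lower, self.upper, size=size)


class TraceLikelihood:
    """Gaussian iid likelihood of a voltage trace under a model + protocol.

    Simulations for proposed parameters start from the same initial state that
    generated (or is assumed for) the data, so the generating parameters
    reproduce the noise-free trace exactly.
    """

    def __init__(
        self,
        model: CellModel,
        protocol: Protocol,
        data: VoltageTrace,
        initial_state: np.ndarray | None = None,
        conditions: Conditions | None = None,
        rtol: float = 1e-6,
        atol: float = 1e-8,
    ):
        self.model = model
        self.protocol = protocol
        self.data = np.asarray(data.voltages, dtype=float)
        self.n = self.data.size
        expected = int(np.floor(protocol.total_duration / protocol.sample_interval + 1e-9)) + 1
        if self.n != expected:
            raise ValueError(
                f"data has {self.n} samples but the protocol grid has {expected}; "
                "data and simulation must share the sampling grid"
            )
        self.initial_state = initial_state
        self.conditions = conditions
        self.rtol = rtol
        self.atol = atol
        self.n_evals = 0
        self.n_failures = 0

    def sum_squared_residuals(self, theta: np.ndarray) -> float:
        self.n_evals += 1
        try:
            sim = run(
                self.model,
                ParameterVector(self.model.parameter_names, theta),
                self.protocol,
                initial_state=self.initial_state,
                conditions=self.conditions,
                rtol=self.rtol,
                atol=self.atol,
            )
        except SimulationError:
            self.n_failures += 1
            return np.inf
        r = sim.voltages - self.data
        return float(r @ r)

    def loglik(self, theta: np.ndarray, sigma: float) -> float:
        if sigma <= 0:
            return -np.inf
        sse = self.sum_squared_residuals(np.asarray(theta, dtype=float))
        if not np.isfinite(sse):
            return -np.inf
        return -0.5 * self.n * math.log(2.0 * math.pi * sigma * sigma) - sse / (2.0 * sigma * sigma)

    def __call__(self, x: np.ndarray) -> float:
        """Log-likelihood of a stacked vector (theta..., sigma)."""
        x = np.asarray(x, dtype=float)
        return self.loglik(x[:-1], x[-1])


def log_likelihood(
    data: VoltageTrace,
    model: CellModel,
    protocol: Protocol,
    params: ParameterVector,
    sigma: float,
    **kwargs,
) -> float:
    """Sum over samples of Normal log-densities of (data - simulation)."""
    like = TraceLikelihood(model, protocol, data, **kwargs)
    return like.loglik(model.parameter_array(params), sigma)


# ---------------------------------------------------------------------------
# CMA-ES (covariance matrix adaptation evolution strategy)
# ---------------------------------------------------------------------------


def cmaes_minimize(
    f,
    lower: np.ndarray,
    upper: np.ndarray,
    seed: int | None = None,
    x0: np.ndarray | None = None,
    sigma0: float = 0.3,
    popsize: int | None = None,
    max_gens: int = 300,
    ftol: float = 1e-8,
    stall_gens: int = 30,
):
    """Minimise ``f`` inside the box [lower, upper] with CMA-ES.

    The search runs in box-normalised coordinates (unit cube) with initial
    step ``sigma0``. Out-of-box samples are clipped to the boundary.
    Returns ``(x_best, f_best, info)``.
    """
    lower = np.asarray(lower, float)
    upper = np.asarray(upper, float)
    span = upper - lower
    d = lower.size
    rng = np.random.default_rng(seed)

    if popsize is None:
        popsize = 4 + int(3 * math.log(d))
    mu = popsize // 2
    w = math.log(mu + 0.5) - np.log(np.arange(1, mu + 1))
    w /= w.sum()
    mu_eff = 1.0 / np.sum(w ** 2)
    cc = (4 + mu_eff / d) / (d + 4 + 2 * mu_eff / d)
    cs = (mu_eff + 2) / (d + mu_eff + 5)
    c1 = 2 / ((d + 1.3) ** 2 + mu_eff)
    cmu = min(1 - c1, 2 * (mu_eff - 2 + 1 / mu_eff) / ((d + 2) ** 2 + mu_eff))
    damps = 1 + 2 * max(0.0, math.sqrt((mu_eff - 1) / (d + 1)) - 1) + cs
    chi_n = math.sqrt(d) * (1 - 1 / (4 * d) + 1 / (21 * d ** 2))

    if x0 is None:
        m = rng.uniform(0.05, 0.95, size=d)
    else:
        m = (np.asarray(x0, float) - lower) / span
    sig = sigma0
    C = np.eye(d)
    ps = np.zeros(d)
    pc = np.zeros(d)
    eigen_ok = True
    B, D = np.eye(d), np.ones(d)

    def decode(u):
        return lower + np.clip(u, 1e-9, 1.0) * span

    x_best, f_best = decode(m), np.inf
    history = []
    n_evals = 0
    stall = 0
    for gen in range(max_gens):
        if not eigen_ok:
            C = (C + C.T) / 2
            evals_, B = np.linalg.eigh(C)
            D = np.sqrt(np.maximum(evals_, 1e-20))
            eigen_ok = True
        z = rng.standard_normal((popsize, d))
        ys = z * D @ B.T
        us = m + sig * ys
        xs = np.clip(us, 0.0, 1.0)
        fs = np.array([f(decode(u)) for u in xs])
        n_evals += popsize
        order = np.argsort(fs)
        if fs[order[0]] < f_best:
            improvement = f_best - fs[order[0]]
            f_best = float(fs[order[0]])
            x_best = decode(xs[order[0]])
            stall = 0 if improvement > ftol else stall + 1
        else:
            stall += 1
        history.append(float(np.mean(fs)))

        sel = order[:mu]
        m_old = m
        ys_sel = (xs[sel] - m_old) / sig
        y_w = w @ ys_sel
        m = m_old + sig * y_w
        # step-size path
        C_inv_sqrt = B @ np.diag(1.0 / D) @ B.T
        ps = (1 - cs) * ps + math.sqrt(cs * (2 - cs) * mu_eff) * (C_inv_sqrt @ y_w)
        sig *= math.exp((cs / damps) * (np.linalg.norm(ps) / chi_n - 1))
        sig = min(sig, 1.0)
        h_sig = (
            np.linalg.norm(ps) / math.sqrt(1 - (1 - cs) ** (2 * (gen + 1))) / chi_n
            < 1.4 + 2 / (d + 1)
        )
        pc = (1 - cc) * pc + (math.sqrt(cc * (2 - cc) * mu_eff) * y_w if h_sig else 0.0)
        rank_mu = (ys_sel * w[:, None]).T @ ys_sel
        C = (
            (1 - c1 - cmu) * C
            + c1 * (np.outer(pc, pc) + ((0.0 if h_sig else 1.0) * cc * (2 - cc)) * C)
            + cmu * rank_mu
        )
        eigen_ok = False
        if stall >= stall_gens:
            break

    return x_best, f_best, {"n_evals": n_evals, "generations": gen + 1, "history": history}


def cmaes_start(
    objective,
    prior: Prior,
    seed: int | None = None,
    n_restarts: int = 3,
    log_scale: bool = True,
    **cma_kwargs,
):
    """Run CMA-ES ``n_restarts`` times from independent prior draws on a
    negative-log-likelihood ``objective`` and return the optima sorted best
    first, as a list of ``(x, f)`` pairs.

    By default the search runs in log-parameter coordinates: conductances are
    scale parameters spanning a 100-fold prior range, and the log transform
    puts the published value near the centre of the search box and removes
    the strong anisotropy of the linear box (a lower bound of exactly zero is
    floored at 1e-4 of the upper bound). The objective itself is unchanged.

    The best point is used to start MCMC; the other optima's neighbourhoods
    can be checked against the chain afterwards.
    """
    rng = np.random.default_rng(seed)
    if log_scale:
        lo = np.log(np.maximum(prior.lower, prior.upper * 1e-4))
        hi = np.log(prior.upper)
        fun = lambda v: objective(np.exp(v))
        decode = np.exp
    else:
        lo, hi = prior.lower, prior.upper
        fun = objective
        decode = lambda v: v
    results = []
    for _ in range(max(n_restarts, 1)):
        sub_seed = int(rng.integers(2 ** 31 - 1))
        x, fval, _ = cmaes_minimize(fun, lo, hi, seed=sub_seed, **cma_kwargs)
        results.append((decode(x), fval))
    results.sort(key=lambda p: p[1])
    if not np.isfinite(results[0][1]):
        raise RuntimeError("CMA-ES failed: objective not finite anywhere it looked")
    return results


# ---------------------------------------------------------------------------
# Adaptive-covariance Metropolis MCMC
# ---------------------------------------------------------------------------


@dataclass
class PosteriorChain:
    """MCMC samples of (theta, sigma) with per-iteration log-posteriors."""

    names: tuple
    samples: np.ndarray  # iterations x dim
    log_pdfs: np.ndarray
    acceptance_rate: float
    seed: int | None = None
    burn_in: float = 0.0
    stride: int = 1
    meta: dict = field(default_factory=dict)

    def __len__(self):
        return self.samples.shape[0]

    @property
    def dim(self):
        return self.samples.shape[1]

    def parameter(self, name: str) -> np.ndarray:
        return self.samples[:, self.names.index(name)]


def run_mcmc(
    log_posterior,
    start: np.ndarray,
    n_iterations: int,
    seed: int | None = None,
    cov0: np.ndarray | None = None,
    target_acceptance: float = 0.25,
    warmup: int = 200,
    log_every: int | None = None,
    names: tuple | None = None,
) -> PosteriorChain:
    """Adaptive-covariance Metropolis (Haario-type) sampling.

    Proposals are multivariate Normal with covariance ``lambda^2 * Sigma``;
    after ``warmup`` iterations the empirical covariance ``Sigma`` and global
    scale ``lambda`` adapt with a decaying rate ``(t - warmup)^-0.6``, the
    scale steering acceptance towards ``target_acceptance``. Points outside
    the support (log-posterior -inf) are always rejected.
    """
    x = np.asarray(start, dtype=float).copy()
    d = x.size
    rng = np.random.default_rng(seed)
    lp = float(log_posterior(x))
    if not np.isfinite(lp):
        raise ValueError("MCMC start point has zero posterior density")

    if cov0 is None:
        scale = np.maximum(np.abs(x), 1e-3)
        cov0 = np.diag((0.01 * scale) ** 2)
    Sigma = np.array(cov0, dtype=float)
    mu = x.copy()
    log_lambda = 0.0
    L = np.linalg.cholesky(Sigma)

    samples = np.empty((n_iterations, d))
    lps = np.empty(n_iterations)
    accepted = 0
    recent_accepted = 0

    for t in range(n_iterations):
        prop = x + math.exp(0.5 * log_lambda) * (L @ rng.standard_normal(d))
        lp_prop = float(log_posterior(prop))
        accept = np.isfinite(lp_prop) and math.log(rng.uniform()) < lp_prop - lp
        if accept:
            x, lp = prop, lp_prop
            accepted += 1
            recent_accepted += 1
        samples[t] = x
        lps[t] = lp

        if t >= warmup:
            g = (t - warmup + 1) ** -0.6
            dx = x - mu
            mu = mu + g * dx
            Sigma = Sigma + g * (np.outer(dx, dx) - Sigma)
            log_lambda += g * ((1.0 if accept else 0.0) - target_acceptance)
            if (t - warmup) % 25 == 0:
                try:
                    L = np.linalg.cholesky(Sigma + 1e-12 * np.eye(d) * np.trace(Sigma) / d)
                except np.linalg.LinAlgError:
                    pass
        if log_every and (t + 1) % log_every == 0:
            print(
                f"iter {t + 1}: acceptance {recent_accepted / log_every:.3f}, "
                f"log-posterior {lp:.2f}"
            )
            recent_accepted = 0

    return PosteriorChain(
        names=tuple(names) if names is not None else tuple(f"p{i}" for i in range(d)),
        samples=samples,
        log_pdfs=lps,
        acceptance_rate=accepted / n_iterations,
        seed=seed,
    )


def postprocess(chain: PosteriorChain, burn_in: float = 0.25, stride: int = 10) -> PosteriorChain:
    """Discard the first ``burn_in`` fraction, then keep every ``stride``-th
    iteration."""
    if not 0 <= burn_in < 1:
        raise ValueError("burn_in must be in [0, 1)")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    n = len(chain)
    n_keep = int(np.floor(n * (1 - burn_in)))
    start = n - n_keep
    length = n_keep // stride  # kept view has exactly floor(n_keep/stride) rows
    kept = slice(start, start + length * stride, stride)
    samples = chain.samples[kept]
    if samples.shape[0] == 0:
        raise ValueError("post-processing removed every sample")
    return PosteriorChain(
        names=chain.names,
        samples=samples.copy(),
        log_pdfs=chain.log_pdfs[kept].copy(),
        acceptance_rate=chain.acceptance_rate,
        seed=chain.seed,
        burn_in=burn_in,
        stride=stride,
        meta=dict(chain.meta),
    )


def credible_interval(samples: np.ndarray, level: float = 0.95):
    """Empirical central interval by the nearest-rank (discard the outermost
    (1-level)/2 of samples on each side)."""
    samples = np.atleast_2d(np.asarray(samples, float).T).T
    n = samples.shape[0]
    if n < 40:
        raise ValueError("need at least 40 samples for a credible interval")
    k = int(np.floor((1.0 - level) / 2.0 * n))
    s = np.sort(samples, axis=0)
    lower = s[k]
    upper = s[n - 1 - k]
    if lower.size == 1:
        return float(lower[0]), float(upper[0])
    return lower, upper


def mape_metric(samples: np.ndarray, truth: np.ndarray) -> np.ndarray:
    """Mean absolute percentage error of each chain column vs its true value."""
    samples = np.atleast_2d(np.asarray(samples, float))
    truth = np.atleast_1d(np.asarray(truth, float))
    if np.any(truth == 0):
        raise ValueError("M_i is undefined for a zero true parameter value")
    return np.mean(np.abs(truth - samples) / np.abs(truth), axis=0)


# ---------------------------------------------------------------------------
# Full synthetic-data identifiability pipeline
# ---------------------------------------------------------------------------


@dataclass
class IdentifiabilityReport:
    model: str
    protocol: str
    names: tuple  # parameter names incl. sigma
    truth: np.ndarray
    m_values: np.ndarray
    success: np.ndarray
    threshold: float
    credible_intervals: np.ndarray  # dim x 2
    chain: PosteriorChain  # post-burn-in view
    full_chain: PosteriorChain
    cmaes_optima: list
    seed: int | None

    @property
    def n_success(self) -> int:
        """Successfully inferred conductances (sigma not counted)."""
        return int(np.sum(self.success[:-1]))

    def summary(self) -> str:
        lines = [
            f"identifiability: {self.model} / {self.protocol} "
            f"({self.n_success}/{len(self.names) - 1} conductances, threshold M<{self.threshold})"
        ]
        for i, n in enumerate(self.names):
            flag = "ok " if self.success[i] else "FAIL"
            lo, hi = self.credible_intervals[i]
            lines.append(
                f"  {flag} {n:<18} M={self.m_values[i]:.4f} truth={self.truth[i]:.6g} "
                f"95% CI=[{lo:.6g}, {hi:.6g}]"
            )
        return "\n".join(lines)


def identifiability_study(
    model: CellModel,
    protocol: Protocol,
    seed: int,
    sigma: float = 0.25,
    n_iterations: int = 100_000,
    burn_in: float = 0.25,
    n_prepace: int = 100,
    conditions: Conditions | None = None,
    cmaes_restarts: int = 3,
    cmaes_max_gens: int = 300,
    log_every: int | None = None,
) -> IdentifiabilityReport:
    """Simulate synthetic data at the published conductances, then run the
    full inverse pipeline (CMA-ES, adaptive MCMC, burn-in, M_i scoring).

    ``seed`` drives every random element: the noise, the CMA-ES restarts and
    the MCMC proposals.
    """
    rng = np.random.default_rng(seed)
    truth = np.append(model.defaults.to_array(), sigma)

    seg = protocol.segments[0]
    state0, _ = prepace(
        model,
        None,
        seg.period,
        n_prepace,
        conditions=conditions,
        stim_amplitude=seg.stim_amplitude,
        stim_duration=seg.stim_duration,
    ) if n_prepace > 0 else (model.initial_state.copy(), None)
    clean = run(model, None, protocol, initial_state=state0, conditions=conditions)
    data = add_noise(clean, sigma, seed=int(rng.integers(2 ** 31 - 1)))

    prior = Prior.for_model(model)
    like = TraceLikelihood(model, protocol, data, initial_state=state0, conditions=conditions)

    def log_post(x):
        if not prior.contains(x):
            return -np.inf
        return like(x)

    optima = cmaes_start(
        lambda x: -like(x),
        prior,
        seed=int(rng.integers(2 ** 31 - 1)),
        n_restarts=cmaes_restarts,
        max_gens=cmaes_max_gens,
    )
    x0 = optima[0][0]

    chain = run_mcmc(
        log_post,
        x0,
        n_iterations,
        seed=int(rng.integers(2 ** 31 - 1)),
        names=prior.names,
        log_every=log_every,
    )
    chain.meta.update({"model": model.name, "protocol": protocol.kind, "noise_sd": sigma})
    post = postprocess(chain, burn_in=burn_in, stride=1)

    m = mape_metric(post.samples, truth)
    success = m < SUCCESS_THRESHOLD
    ci = np.column_stack(credible_interval(post.samples))

    return IdentifiabilityReport(
        model=model.name,
        protocol=protocol.kind,
        names=prior.names,
        truth=truth,
        m_values=m,
        success=success,
        threshold=SUCCESS_THRESHOLD,
        credible_intervals=ci,
        chain=post,
        full_chain=chain,
        cmaes_optima=optima,
        seed=seed,
    )
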