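"""Gaussian-process emulation of an AP model over its conductance space.

Workflow: draw a Latin-hypercube design over the 13 normalised TP06 inputs
(each natural range is centre +/- 50%, mapped to [0, 1]); run the simulator
for 20 beats at 1000 ms cycle length and extract the six beat-20 biomarkers;
fit one GP per output; then interrogate the emulators analytically.

The GP uses a squared-exponential kernel with per-input length-scales and a
linear mean function, the conventions of the MUCM toolkit. For independent
Gaussian input distributions all the quantities of interest - the propagated
output mean and variance, mean-effect curves and main-effect (variance-based
sensitivity) indices - are Gaussian integrals of the fitted surface and are
evaluated in closed form (plus a 1-D Gauss-Hermite quadrature for the
variance of a mean-effect curve).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize, stats
from scipy.stats import qmc

from .biomarkers import BIOMARKER_NAMES, extract
from .models import get_model
from .models.base import CellModel, ParameterVector
from .protocols import make_protocol
from .simulation import SimulationError, run

__all__ = [
    "InputSpec",
    "DesignData",
    "GPEmulator",
    "InputDistribution",
    "PropagationResult",
    "MahalanobisReport",
    "tp06_input_spec",
    "latin_hypercube",
    "build_design",
    "gp_fit",
    "validate",
    "mean_effect",
    "main_effect_index",
    "propagate",
]


# ---------------------------------------------------------------------------
# Inputs and design
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class InputSpec:
    """Named inputs with natural ranges and the [0, 1] normalisation map.

    Ranges are centre +/- 50% (min = 0.5 x centre, max = 1.5 x centre), so
    normalised 0.5 is the published parameter value.
    """

    names: tuple
    centres: np.ndarray

    @property
    def mins(self) -> np.ndarray:
        return 0.5 * self.centres

    @property
    def maxs(self) -> np.ndarray:
        return 1.5 * self.centres

    @property
    def dim(self) -> int:
        return len(self.names)

    def to_natural(self, u: np.ndarray) -> np.ndarray:
        return self.mins + np.asarray(u) * (self.maxs - self.mins)

    def to_normalised(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x) - self.mins) / (self.maxs - self.mins)


def tp06_input_spec() -> InputSpec:
    """The 13 TP06 epicardial inputs (12 conductances + tau_f multiplier)."""
    m = get_model("tentusscher_2006_epi")
    return InputSpec(tuple(m.parameter_names), m.defaults.to_array())


def latin_hypercube(n: int, d: int, seed: int | None = None) -> np.ndarray:
    """n x d Latin hypercube in [0, 1]: one point per stratum per dimension."""
    if n < 1:
        raise ValueError("need at least one design point")
    sampler = qmc.LatinHypercube(d=d, seed=seed)
    return sampler.random(n)


@dataclass
class DesignData:
    """Simulator design: normalised inputs and beat-20 biomarker outputs."""

    spec: InputSpec
    inputs: np.ndarray  # n x d, normalised
    outputs: dict  # biomarker name -> length-n array
    apd90_beat19: np.ndarray  # for the steady-state check
    seed: int | None = None
    failures: list = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.inputs.shape[0]

    def output_array(self, name: str) -> np.ndarray:
        return self.outputs[name]


def build_design(
    n: int,
    seed: int | None = None,
    model: CellModel | None = None,
    spec: InputSpec | None = None,
    n_beats: int = 20,
    cycle_length: float = 1000.0,
) -> DesignData:
    """Run the simulator at ``n`` Latin-hypercube points.

    Each run is ``n_beats`` beats at ``cycle_length`` ms elicited with a
    -52 pA/pF x 1 ms stimulus from the model's published (CellML) initial
    conditions; outputs are the six biomarkers of the final beat.
    Non-repolarising runs are excluded with a warning; solver failures are
    recorded in ``failures``.
    """
    if model is None:
        model = get_model("tentusscher_2006_epi")
    if spec is None:
        spec = InputSpec(tuple(model.parameter_names), model.defaults.to_array())
    protocol = make_protocol("long_pacing", duration=n_beats * cycle_length)

    U = latin_hypercube(n, spec.dim, seed=seed)
    rows = {name: [] for name in BIOMARKER_NAMES}
    apd19 = []
    kept = []
    failures = []
    for i, u in enumerate(U):
        params = ParameterVector(spec.names, spec.to_natural(u))
        try:
            trace = run(model, params, protocol)
        except SimulationError as err:
            failures.append((i, str(err)))
            continue
        last = extract(trace, beat_start=(n_beats - 1) * cycle_length, beat_period=cycle_length)
        prev = extract(trace, beat_start=(n_beats - 2) * cycle_length, beat_period=cycle_length)
        if last.apd90 is None or prev.apd90 is None:
            warnings.warn(f"design point {i} did not repolarise; excluded")
            failures.append((i, "non-repolarising"))
            continue
        for name in BIOMARKER_NAMES:
            rows[name].append(getattr(last, name))
        apd19.append(prev.apd90)
        kept.append(i)

    return DesignData(
        spec=spec,
        inputs=U[kept],
        outputs={k: np.array(v, dtype=float) for k, v in rows.items()},
        apd90_beat19=np.array(apd19, dtype=float),
        seed=seed,
        failures=failures,
    )


# ---------------------------------------------------------------------------
# The GP emulator
# ---------------------------------------------------------------------------


def _corr(X1, X2, ell):
    d2 = np.zeros((X1.shape[0], X2.shape[0]))
    for k in range(X1.shape[1]):
        d2 += ((X1[:, k, None] - X2[None, :, k]) / ell[k]) ** 2
    return np.exp(-0.5 * d2)


@dataclass
class GPEmulator:
    """GP over normalised [0,1]^d inputs for one scalar output.

    Squared-exponential correlation with per-input length-scales ``ell``,
    linear mean h(x) = [1, x], process variance ``sigma2`` estimated by
    (concentrated) maximum likelihood, and a small fixed relative nugget.
    """

    X: np.ndarray
    y: np.ndarray
    ell: np.ndarray
    sigma2: float
    beta: np.ndarray
    nugget: float
    output_name: str = ""
    # cached decompositions
    _cho: tuple = field(default=None, repr=False)
    _Rinv_resid: np.ndarray = field(default=None, repr=False)
    _G_inv: np.ndarray = field(default=None, repr=False)
    _H: np.ndarray = field(default=None, repr=False)

    @property
    def n(self):
        return self.X.shape[0]

    @property
    def dim(self):
        return self.X.shape[1]

    def _finalise(self):
        R = _corr(self.X, self.X, self.ell)
        R[np.diag_indices_from(R)] += self.nugget
        cho = linalg.cho_factor(R, lower=True)
        H = np.column_stack([np.ones(self.n), self.X])
        resid = self.y - H @ self.beta
        self._cho = cho
        self._Rinv_resid = linalg.cho_solve(cho, resid)
        RinvH = linalg.cho_solve(cho, H)
        self._G_inv = np.linalg.inv(H.T @ RinvH)
        self._H = H
        return self

    def predict(self, Xs: np.ndarray, full_cov: bool = False, include_noise: bool = False):
        """Predictive mean and variance (or covariance matrix) at ``Xs``.

        The default predicts the latent smooth response surface; with
        ``include_noise`` the fitted nugget (grid/measurement jitter of the
        biomarker extraction) is added, which is the right distribution for
        comparing against freshly computed simulator outputs.
        """
        Xs = np.atleast_2d(np.asarray(Xs, float))
        r = _corr(Xs, self.X, self.ell)  # m x n
        hs = np.column_stack([np.ones(Xs.shape[0]), Xs])
        mean = hs @ self.beta + r @ self._Rinv_resid
        Rinv_rT = linalg.cho_solve(self._cho, r.T)
        u = hs.T - self._H.T @ Rinv_rT  # q x m
        g = self.nugget if include_noise else 0.0
        if full_cov:
            Rss = _corr(Xs, Xs, self.ell)
            Rss[np.diag_indices_from(Rss)] += g
            cov = self.sigma2 * (Rss - r @ Rinv_rT + u.T @ self._G_inv @ u)
            return mean, cov
        var = self.sigma2 * (
            1.0 + g - np.einsum("ij,ji->i", r, Rinv_rT)
            + np.einsum("ij,jk,ki->i", u.T, self._G_inv, u)
        )
        return mean, np.maximum(var, 0.0)


def _neg_log_ml(params, X, y, H, nugget):
    n = X.shape[0]
    if nugget is None:
        ell = np.exp(params[:-1])
        g = math.exp(params[-1])
    else:
        ell = np.exp(params)
        g = nugget
    R = _corr(X, X, ell)
    R[np.diag_indices_from(R)] += g
    try:
        cho = linalg.cho_factor(R, lower=True)
    except linalg.LinAlgError:
        return 1e10
    log_det = 2.0 * np.sum(np.log(np.diag(cho[0])))
    RinvH = linalg.cho_solve(cho, H)
    G = H.T @ RinvH
    try:
        beta = np.linalg.solve(G, H.T @ linalg.cho_solve(cho, y))
    except np.linalg.LinAlgError:
        return 1e10
    resid = y - H @ beta
    quad = resid @ linalg.cho_solve(cho, resid)
    if quad <= 0:
        return 1e10
    sigma2 = quad / n
    # concentrated: 0.5 * (n log sigma2 + log|R|) + const
    return 0.5 * (n * math.log(sigma2) + log_det)


def _loo_quantities(ell, g, X, y, H):
    """Universal-kriging leave-one-out residuals and relative variances.

    Uses Dubrule's projection form Q = R^-1 - R^-1 H (H' R^-1 H)^-1 H' R^-1,
    so the GLS mean coefficients are implicitly refit for every left-out
    point: residual_i = (Qy)_i / Q_ii, relative variance_i = 1 / Q_ii.
    """
    n = X.shape[0]
    R = _corr(X, X, ell)
    R[np.diag_indices_from(R)] += g
    cho = linalg.cho_factor(R, lower=True)
    Rinv = linalg.cho_solve(cho, np.eye(n))
    RinvH = Rinv @ H
    Qm = Rinv - RinvH @ np.linalg.solve(H.T @ RinvH, RinvH.T)
    q_ii = np.diag(Qm)
    return Qm @ y, q_ii


def _neg_loo(params, X, y, H, nugget):
    """Negative leave-one-out predictive log-density (sigma2 concentrated)."""
    if nugget is None:
        ell = np.exp(params[:-1])
        g = math.exp(params[-1])
    else:
        ell = np.exp(params)
        g = nugget
    try:
        qy, q_ii = _loo_quantities(ell, g, X, y, H)
    except (linalg.LinAlgError, np.linalg.LinAlgError):
        return 1e10
    if np.any(q_ii <= 0):
        return 1e10
    loo_sq = qy ** 2 / q_ii  # residual_i^2 / relative variance_i
    sigma2 = np.mean(loo_sq)
    if sigma2 <= 0:
        return 1e10
    return 0.5 * float(np.sum(np.log(sigma2 / q_ii)))


def gp_fit(
    design: DesignData,
    output_name: str,
    nugget: float | None = None,
    n_restarts: int = 5,
    seed: int = 0,
    objective: str = "ml",
) -> GPEmulator:
    """Fit a GP emulator for one output by multi-start maximisation of the
    concentrated marginal likelihood over the log length-scales.

    By default a relative noise nugget is estimated jointly with the
    length-scales (biomarkers computed from a sampled trace carry a small
    non-smooth component, e.g. max dVm/dt depends on where the upstroke
    falls on the sample grid). Pass an explicit small ``nugget`` (e.g. 1e-8)
    to force near-interpolation instead.

    ``objective`` selects the fitting criterion: ``"ml"`` (default)
    maximises the concentrated marginal likelihood over the log
    length-scales; ``"loo"`` maximises the leave-one-out cross-validated
    predictive log-density (Dubrule's universal-kriging form, which refits
    the mean coefficients for every left-out point). Both give similar
    predictive means here; neither fully cures the optimism of predictive
    variances that a 50-point design in 13 dimensions entails, which the
    Mahalanobis validation report makes visible.
    """
    X = np.asarray(design.inputs, float)
    y = np.asarray(design.output_array(output_name), float)
    n, d = X.shape
    if n < d + 2:
        raise ValueError(f"need at least {d + 2} design points for {d} inputs, got {n}")
    H = np.column_stack([np.ones(n), X])

    rng = np.random.default_rng(seed)
    starts = [np.zeros(d + 1)]
    for _ in range(n_restarts - 1):
        starts.append(
            np.append(
                rng.uniform(math.log(0.3), math.log(3.0), size=d),
                rng.uniform(math.log(1e-8), math.log(1e-2)),
            )
        )
    starts = [s if nugget is None else s[:d] for s in starts]

    fun = {"loo": _neg_loo, "ml": _neg_log_ml}[objective]
    best = None
    bounds = [(math.log(0.03), math.log(30.0))] * d
    if nugget is None:
        bounds = bounds + [(math.log(1e-9), math.log(0.5))]
        starts[0] = np.append(np.zeros(d), math.log(1e-6))
    for s in starts:
        res = optimize.minimize(
            fun, s, args=(X, y, H, nugget), method="L-BFGS-B", bounds=bounds
        )
        if best is None or res.fun < best.fun:
            best = res

    if nugget is None:
        ell = np.exp(best.x[:-1])
        nugget_hat = float(math.exp(best.x[-1]))
    else:
        ell = np.exp(best.x)
        nugget_hat = float(nugget)
    R = _corr(X, X, ell)
    R[np.diag_indices_from(R)] += nugget_hat
    cho = linalg.cho_factor(R, lower=True)
    RinvH = linalg.cho_solve(cho, H)
    G = H.T @ RinvH
    beta = np.linalg.solve(G, H.T @ linalg.cho_solve(cho, y))
    resid = y - H @ beta
    if objective == "loo":
        qy, q_ii = _loo_quantities(ell, nugget_hat, X, y, H)
        sigma2 = float(np.mean(qy ** 2 / q_ii))
    else:
        sigma2 = float(resid @ linalg.cho_solve(cho, resid) / n)

    em = GPEmulator(
        X=X, y=y, ell=ell, sigma2=sigma2, beta=beta, nugget=nugget_hat, output_name=output_name
    )
    return em._finalise()


def fit_all(design: DesignData, **kwargs) -> dict:
    """Fit one emulator per biomarker output."""
    return {name: gp_fit(design, name, **kwargs) for name in design.outputs}


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MahalanobisReport:
    distance: float
    n_test: int
    lower_95: float
    upper_95: float
    standardised_errors: np.ndarray

    @property
    def passed(self) -> bool:
        return self.lower_95 <= self.distance <= self.upper_95


def validate(emulator: GPEmulator, X_test: np.ndarray, y_test: np.ndarray) -> MahalanobisReport:
    """Joint Mahalanobis distance of held-out simulator runs under the
    emulator's predictive distribution.

    For data drawn from the predictive distribution the statistic has
    expectation ``n_test``; the pass band is the central 95% of the
    chi-squared reference distribution with ``n_test`` degrees of freedom.
    """
    X_test = np.atleast_2d(X_test)
    y_test = np.asarray(y_test, float)
    mean, cov = emulator.predict(X_test, full_cov=True, include_noise=True)
    m = y_test.size
    try:
        cho = linalg.cho_factor(cov, lower=True)
    except linalg.LinAlgError as err:
        raise ValueError("singular predictive covariance in validation") from err
    resid = y_test - mean
    d2 = float(resid @ linalg.cho_solve(cho, resid))
    sd = np.sqrt(np.maximum(np.diag(cov), 1e-300))
    return MahalanobisReport(
        distance=d2,
        n_test=m,
        lower_95=float(stats.chi2.ppf(0.025, m)),
        upper_95=float(stats.chi2.ppf(0.975, m)),
        standardised_errors=resid / sd,
    )


# ---------------------------------------------------------------------------
# Analytic integrals against independent Gaussian inputs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class InputDistribution:
    """Independent Gaussian measures on the normalised inputs."""

    mean: np.ndarray  # length d
    var: np.ndarray  # length d, entries >= 0

    def __post_init__(self):
        object.__setattr__(self, "mean", np.asarray(self.mean, float))
        object.__setattr__(self, "var", np.asarray(self.var, float))
        if np.any(self.var < 0):
            raise ValueError("input variances must be non-negative")

    @classmethod
    def uniform_spec(cls, d: int, mean: float = 0.5, var: float = 0.04) -> "InputDistribution":
        return cls(np.full(d, mean), np.full(d, var))

    def with_var(self, index: int, var: float) -> "InputDistribution":
        v = self.var.copy()
        v[index] = var
        return InputDistribution(self.mean.copy(), v)


def _gauss_kernel_moments(em: GPEmulator, b: np.ndarray, B: np.ndarray):
    """Gaussian integrals of the correlation function against x ~ N(b, diag B).

    Returns (q, M, Q, P) with
      q_i   = E[r(x, x_i)]
      M[i,d]= E[x_d r(x, x_i)] / q_i   (posterior-product means)
      Q[i,j]= E[r(x, x_i) r(x, x_j)]
      P[i,j,d] = E[x_d r_i r_j] / Q[i,j]
    """
    X = em.X
    l2 = em.ell ** 2
    # single-kernel integrals
    s1 = l2 / (l2 + B)
    q = np.prod(np.sqrt(s1)) * np.exp(
        -0.5 * np.sum((b - X) ** 2 / (l2 + B), axis=1)
    )
    M = (X * B + b * l2) / (l2 + B)

    # pairwise integrals
    xbar = 0.5 * (X[:, None, :] + X[None, :, :])
    dist2 = (X[:, None, :] - X[None, :, :]) ** 2
    s2 = l2 / (l2 + 2.0 * B)
    Q = (
        np.prod(np.sqrt(s2))
        * np.exp(-0.25 * np.sum(dist2 / l2, axis=2))
        * np.exp(-np.sum((b - xbar) ** 2 / (l2 + 2.0 * B), axis=2))
    )
    P = (2.0 * B * xbar + l2 * b) / (l2 + 2.0 * B)
    return q, M, Q, P


@dataclass(frozen=True)
class PropagationResult:
    """Propagated output distribution under Gaussian input uncertainty."""

    mean: float
    variance_input: float  # variance of the posterior-mean surface
    variance_code: float  # expected predictive (emulator) variance
    output_name: str = ""

    @property
    def sd(self) -> float:
        return math.sqrt(max(self.variance_input, 0.0))

    @property
    def variance_total(self) -> float:
        return self.variance_input + self.variance_code

    @property
    def sd_total(self) -> float:
        return math.sqrt(max(self.variance_total, 0.0))


def propagate(em: GPEmulator, dist: InputDistribution) -> PropagationResult:
    """Closed-form mean and variance of the emulator output when the inputs
    are independent Gaussians (used un-truncated; with sd <= 0.2 the mass
    outside [0, 1] is small and covered by the quoted tolerances)."""
    b, B = dist.mean, dist.var
    q, M, Q, P = _gauss_kernel_moments(em, b, B)
    w = em._Rinv_resid
    beta = em.beta

    Eh = np.concatenate(([1.0], b))
    Ehh = np.empty((em.dim + 1, em.dim + 1))
    Ehh[0, 0] = 1.0
    Ehh[0, 1:] = b
    Ehh[1:, 0] = b
    Ehh[1:, 1:] = np.outer(b, b) + np.diag(B)

    # E[h r^T]: (d+1) x n
    Ehr = np.empty((em.dim + 1, em.n))
    Ehr[0] = q
    Ehr[1:] = (q[:, None] * M).T

    mean = float(beta @ Eh + w @ q)
    Em2 = float(beta @ Ehh @ beta + 2.0 * beta @ (Ehr @ w) + w @ Q @ w)
    var_input = max(Em2 - mean ** 2, 0.0)

    # expected code (predictive) variance, including the mean-function term
    cho = em._cho
    A = linalg.cho_solve(cho, em._H).T  # q x n, equals H^T R^-1
    tr_RQ = float(np.sum(linalg.cho_solve(cho, Q).diagonal()))
    EuuT = Ehh - A @ Ehr.T - Ehr @ A.T + A @ Q @ A.T
    var_code = em.sigma2 * (1.0 - tr_RQ + float(np.sum(em._G_inv * EuuT)))
    return PropagationResult(
        mean=mean,
        variance_input=var_input,
        variance_code=max(var_code, 0.0),
        output_name=em.output_name,
    )


def conditional_mean(em: GPEmulator, index: int, value, dist: InputDistribution) -> np.ndarray:
    """E[output | x_index = value] with the other inputs integrated over
    their Gaussian distribution. ``value`` may be an array (a grid)."""
    values = np.atleast_1d(np.asarray(value, float))
    out = np.empty(values.size)
    for k, g in enumerate(values):
        b = dist.mean.copy()
        B = dist.var.copy()
        b[index] = g
        B[index] = 0.0
        q, M, Q, P = _gauss_kernel_moments(em, b, B)
        Eh = np.concatenate(([1.0], b))
        out[k] = float(em.beta @ Eh + em._Rinv_resid @ q)
    return out if np.ndim(value) else float(out[0])


def mean_effect(
    em: GPEmulator,
    index: int,
    dist: InputDistribution | None = None,
    grid: np.ndarray | None = None,
):
    """Mean-effect curve: expected output as input ``index`` sweeps its range
    while the other inputs keep their Gaussian distribution (default mean
    0.5, variance 0.04). Returns (grid, curve)."""
    if dist is None:
        dist = InputDistribution.uniform_spec(em.dim)
    if grid is None:
        grid = np.linspace(0.0, 1.0, 101)
    return grid, conditional_mean(em, index, grid, dist)


def main_effect_index(em: GPEmulator, index: int, dist: InputDistribution | None = None) -> float:
    """Variance-based first-order sensitivity index
    S_i = Var(E[Y | X_i]) / Var(Y), both under the Gaussian input measure.

    The outer 1-D integral over X_i uses Gauss-Hermite quadrature on the
    analytic conditional mean.
    """
    if dist is None:
        dist = InputDistribution.uniform_spec(em.dim)
    total = propagate(em, dist).variance_input
    if total <= 0:
        raise ValueError("total output variance is zero")
    nodes, weights = np.polynomial.hermite_e.hermegauss(41)
    g = dist.mean[index] + math.sqrt(dist.var[index]) * nodes
    m = conditional_mean(em, index, g, dist)
    wnorm = weights / weights.sum()
    mbar = float(wnorm @ m)
    var_i = float(wnorm @ (m - mbar) ** 2)
    return var_i / total


def main_effect_indices(em: GPEmulator, dist: InputDistribution | None = None) -> np.ndarray:
    return np.array([main_effect_index(em, i, dist) for i in range(em.dim)])


def sample_output(
    em: GPEmulator,
    dist: InputDistribution,
    n: int = 10_000,
    seed: int | None = None,
    include_code_uncertainty: bool = False,
) -> np.ndarray:
    """Monte-Carlo draws of the emulator output under the input measure
    (for histograms; the analytic moments come from :func:`propagate`)."""
    rng = np.random.default_rng(seed)
    Xs = rng.normal(dist.mean, np.sqrt(dist.var), size=(n, em.dim))
    mean, var = em.predict(Xs)
    if include_code_uncertainty:
        return mean + rng.standard_normal(n) * np.sqrt(var)
    return mean
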