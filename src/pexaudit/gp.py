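"""Lung-function model: linear fixed effects + random intercept/slope +
integrated Brownian motion, with likelihood, fitting, conditional forecasting
and horizon PEx probabilities.

The measured FEV1 % predicted of patient ``i`` at day ``t`` is modeled as

    y_i(t) = x_i(t)' beta + b0_i + b1_i * t + W_i(t) + eps_i(t)

with (b0, b1) ~ N(0, G) the between-patient heterogeneity, W an integrated
Brownian motion with scale ``sigma_w2`` giving smooth nonstationary
within-patient serial correlation, and iid measurement noise with variance
``sigma_e2``.  All patients share ``beta``; random terms are independent
across patients, so the marginal covariance is block diagonal by patient.

Forecasting is standard Gaussian conditioning of the joint normal vector of
(observed history, future values) on the history; the probability of a future
FIES-defined pulmonary exacerbation is the predictive probability that the
FEV1 path dips below baseline - 10 at any point of a monthly grid over the
horizon, estimated by Monte Carlo from the joint predictive distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve

from pexaudit.registry import DAYS_PER_MONTH, Registry

#: default fixed-effect design; extensible via the ``terms`` argument
DEFAULT_DESIGN = (
    "intercept",
    "age",
    "f508del_heterozygous",
    "f508del_neither_unknown",
    "sex_male",
    "medicaid",
)


class ParameterError(ValueError):
    """Invalid model parameters (e.g. non-PSD G, nonpositive noise variance)."""


@dataclass
class ModelParams:
    """Parameters of the stochastic-process model.

    Attributes
    ----------
    beta : coefficient vector aligned with ``terms``.
    G : 2x2 covariance of the random intercept and slope (slope per day).
    sigma_w2 : integrated-Brownian-motion scale, %predicted^2 / day^3.
    sigma_e2 : residual measurement variance, %predicted^2.
    terms : names of the fixed-effect design columns.
    """

    beta: np.ndarray
    G: np.ndarray
    sigma_w2: float
    sigma_e2: float
    terms: tuple[str, ...] = DEFAULT_DESIGN

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        self.G = np.asarray(self.G, dtype=float)
        if self.G.shape != (2, 2):
            raise ParameterError("G must be 2x2")
        if not np.allclose(self.G, self.G.T):
            raise ParameterError("G must be symmetric")
        eig = np.linalg.eigvalsh(self.G)
        if eig.min() < -1e-10 * max(1.0, eig.max()):
            raise ParameterError("G must be positive semidefinite")
        if self.sigma_w2 < 0:
            raise ParameterError("sigma_w2 must be >= 0")
        if self.sigma_e2 <= 0:
            raise ParameterError("sigma_e2 must be > 0")
        if len(self.beta) != len(self.terms):
            raise ParameterError("beta length must match number of design terms")

    def to_dict(self) -> dict:
        return {
            "terms": list(self.terms),
            "beta": self.beta.tolist(),
            "G": self.G.tolist(),
            "sigma_w2": float(self.sigma_w2),
            "sigma_e2": float(self.sigma_e2),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        return cls(
            beta=np.asarray(d["beta"], dtype=float),
            G=np.asarray(d["G"], dtype=float),
            sigma_w2=float(d["sigma_w2"]),
            sigma_e2=float(d["sigma_e2"]),
            terms=tuple(d["terms"]),
        )


@dataclass
class PredictiveDistribution:
    """Joint Gaussian forecast of measured FEV1 at future times."""

    times: np.ndarray
    mean: np.ndarray
    covariance: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.mean = np.asarray(self.mean, dtype=float)
        self.covariance = np.asarray(self.covariance, dtype=float)
        k = len(self.times)
        if self.mean.shape != (k,) or self.covariance.shape != (k, k):
            raise ValueError("dimension mismatch in predictive distribution")


# -- kernel and covariance --------------------------------------------------

def ibm_kernel(s, t, sigma_w2: float = 1.0):
    """Covariance of integrated Brownian motion W(t) = int_0^t B(u) du.

    cov(W(s), W(t)) = sigma_w2 * min(s,t)^2 * (3*max(s,t) - min(s,t)) / 6,
    the double integral of min(u, v) over [0,s] x [0,t].  Symmetric in (s, t);
    zero whenever either argument is 0.  Accepts scalars or arrays
    (broadcast elementwise).
    """
    s = np.asarray(s, dtype=float)
    t = np.asarray(t, dtype=float)
    if (s < 0).any() if s.ndim else s < 0:
        raise ValueError("times must be >= 0")
    if (t < 0).any() if t.ndim else t < 0:
        raise ValueError("times must be >= 0")
    lo = np.minimum(s, t)
    hi = np.maximum(s, t)
    out = sigma_w2 * lo * lo * (3.0 * hi - lo) / 6.0
    return out if out.ndim else float(out)


def ibm_kernel_matrix(times: np.ndarray, sigma_w2: float = 1.0) -> np.ndarray:
    t = np.asarray(times, dtype=float)
    return ibm_kernel(t[:, None], t[None, :], sigma_w2)


def marginal_covariance(times: np.ndarray, params: ModelParams) -> np.ndarray:
    """Marginal covariance of one patient's measurements at ``times``:
    Z G Z' + sigma_w2 * K_ibm + sigma_e2 * I with Z = [1, t]."""
    t = np.asarray(times, dtype=float)
    if t.ndim != 1:
        raise ValueError("times must be a 1-d array")
    Z = np.column_stack([np.ones_like(t), t])
    return Z @ params.G @ Z.T + ibm_kernel_matrix(t, params.sigma_w2) + params.sigma_e2 * np.eye(len(t))


def _cross_covariance(times_a: np.ndarray, times_b: np.ndarray, params: ModelParams) -> np.ndarray:
    """Covariance between measurements at times_a and times_b of one patient
    (no measurement-noise term: noise is independent across occasions)."""
    ta = np.asarray(times_a, dtype=float)
    tb = np.asarray(times_b, dtype=float)
    Za = np.column_stack([np.ones_like(ta), ta])
    Zb = np.column_stack([np.ones_like(tb), tb])
    return Za @ params.G @ Zb.T + ibm_kernel(ta[:, None], tb[None, :], params.sigma_w2)


_JITTER_COUNT = {"n": 0}


def _chol_with_jitter(V: np.ndarray):
    """Cholesky factor; on failure add jitter 1e-8 * trace/n once, warn."""
    try:
        return cho_factor(V, lower=True)
    except np.linalg.LinAlgError:
        jitter = 1e-8 * np.trace(V) / len(V)
        _JITTER_COUNT["n"] += 1
        warnings.warn(
            f"covariance not positive definite; added jitter {jitter:.3e}",
            RuntimeWarning, stacklevel=3,
        )
        return cho_factor(V + jitter * np.eye(len(V)), lower=True)


# -- design matrices --------------------------------------------------------

def design_matrix(patient: pd.Series, encounters: pd.DataFrame,
                  terms: tuple[str, ...] = DEFAULT_DESIGN) -> np.ndarray:
    """Fixed-effect design for one patient's encounters.

    Supported terms: intercept; age (encounter-level, years); dummies
    f508del_heterozygous / f508del_neither_unknown (reference homozygous);
    sex_male; and any boolean encounter column (medicaid, cfrd, pa_positive,
    mrsa_positive) or numeric patient column named directly.
    """
    n = len(encounters)
    cols = []
    for term in terms:
        if term == "intercept":
            cols.append(np.ones(n))
        elif term == "age":
            cols.append(encounters["age"].to_numpy(dtype=float))
        elif term == "f508del_heterozygous":
            cols.append(np.full(n, float(patient["f508del"] == "heterozygous")))
        elif term == "f508del_neither_unknown":
            cols.append(np.full(n, float(patient["f508del"] == "neither_unknown")))
        elif term == "sex_male":
            cols.append(np.full(n, float(patient["sex"] == "male")))
        elif term in encounters.columns:
            cols.append(encounters[term].to_numpy(dtype=float))
        elif term in patient.index:
            cols.append(np.full(n, float(patient[term])))
        else:
            raise KeyError(f"unknown design term {term!r}")
    return np.column_stack(cols)


def _patient_blocks(registry: Registry, terms: tuple[str, ...]):
    """Per-patient (times, y, X) triples, encounters sorted by t."""
    enc = registry.sorted_encounters()
    pat = registry.patients.set_index("patient_id")
    blocks = []
    for pid, grp in enc.groupby("patient_id", sort=False):
        grp = grp.reset_index(drop=True)
        X = design_matrix(pat.loc[pid], grp, terms)
        blocks.append((pid, grp["t"].to_numpy(dtype=float),
                       grp["fev1_pp"].to_numpy(dtype=float), X))
    return blocks


# -- likelihood -------------------------------------------------------------

def log_likelihood(registry: Registry, params: ModelParams) -> float:
    """Marginal log-likelihood: sum over patients of the multivariate normal
    log-density of (y - X beta) under the per-patient covariance."""
    total = 0.0
    for _, t, y, X in _patient_blocks(registry, params.terms):
        V = marginal_covariance(t, params)
        c, low = _chol_with_jitter(V)
        r = y - X @ params.beta
        alpha = cho_solve((c, low), r)
        logdet = 2.0 * np.sum(np.log(np.diag(c)))
        total += -0.5 * (len(t) * np.log(2.0 * np.pi) + logdet + r @ alpha)
    return float(total)


# -- fitting ----------------------------------------------------------------

@dataclass
class FitResult:
    """Fitted parameters plus convergence diagnostics."""

    params: ModelParams
    converged: bool
    log_likelihood: float
    n_iter: int
    message: str
    beta_se: np.ndarray = field(default=None)  # GLS standard errors at optimum


_DPY = 365.25  # optimizer works in per-year units so all components are O(1)
_YEAR_SCALE = np.diag([1.0, 1.0 / _DPY])


def _theta_to_var(theta: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Unpack optimizer vector: G via its Cholesky factor (slope in per-year
    units for conditioning), process variance per year^3, noise on log scale;
    returns day-unit quantities."""
    l11, l21, l22, log_sw2, log_se2 = theta
    L = np.array([[l11, 0.0], [l21, l22]])
    G_yr = L @ L.T
    G = _YEAR_SCALE @ G_yr @ _YEAR_SCALE
    return G, float(np.exp(log_sw2)) / _DPY ** 3, float(np.exp(log_se2))


def _profiled_nll(theta: np.ndarray, blocks, reml: bool):
    """Negative log-likelihood with beta profiled out by GLS, plus the GLS
    beta and its covariance. Returns (nll, beta, cov_beta)."""
    G, sw2, se2 = _theta_to_var(theta)
    p = blocks[0][3].shape[1]
    A = np.zeros((p, p))
    bvec = np.zeros(p)
    pieces = []
    n_total = 0
    logdet_total = 0.0
    for _, t, y, X in blocks:
        Z = np.column_stack([np.ones_like(t), t])
        V = Z @ G @ Z.T + ibm_kernel_matrix(t, sw2) + se2 * np.eye(len(t))
        try:
            c, low = cho_factor(V, lower=True)
        except np.linalg.LinAlgError:
            return 1e15, None, None  # finite penalty keeps L-BFGS-B stable
        Vi_X = cho_solve((c, low), X)
        Vi_y = cho_solve((c, low), y)
        A += X.T @ Vi_X
        bvec += X.T @ Vi_y
        logdet_total += 2.0 * np.sum(np.log(np.diag(c)))
        n_total += len(t)
        pieces.append((y, X, (c, low)))
    try:
        cov_beta = np.linalg.inv(A)
    except np.linalg.LinAlgError:
        return 1e15, None, None
    beta = cov_beta @ bvec
    quad = 0.0
    for y, X, cf in pieces:
        r = y - X @ beta
        quad += r @ cho_solve(cf, r)
    nll = 0.5 * (n_total * np.log(2.0 * np.pi) + logdet_total + quad)
    if reml:
        sign, logdet_A = np.linalg.slogdet(A)
        nll += 0.5 * logdet_A - 0.5 * p * np.log(2.0 * np.pi)
    return nll, beta, cov_beta


def fit_model(
    registry: Registry,
    terms: tuple[str, ...] = DEFAULT_DESIGN,
    init: ModelParams | None = None,
    reml: bool = False,
    maxiter: int = 400,
) -> FitResult:
    """Fit the model by maximum (or restricted maximum) marginal likelihood.

    Variance components are optimized on unconstrained scales (G via its
    Cholesky factor, noise/process variances on log scale) with L-BFGS-B and
    numerical gradients; the fixed-effect vector is profiled out by
    generalized least squares at every evaluation.  Non-convergence returns
    the best parameters found with ``converged=False`` rather than raising.
    """
    if registry.n_patients < 2:
        raise ValueError("fitting needs at least 2 patients")
    blocks = _patient_blocks(registry, terms)

    if init is not None:
        scale = np.diag([1.0, _DPY])
        G_yr = scale @ init.G @ scale
        L = np.linalg.cholesky(G_yr + 1e-10 * np.eye(2))
        theta0 = np.array([L[0, 0], L[1, 0], L[1, 1],
                           np.log(max(init.sigma_w2 * _DPY ** 3, 1e-10)),
                           np.log(init.sigma_e2)])
    else:
        # moments-based starting point: split the raw variance of y; random
        # slope starts at sd 1 point/year, process drift at ~sd 0.6 at 1 year
        y_all = np.concatenate([b[2] for b in blocks])
        v = max(float(np.var(y_all)), 1e-3)
        theta0 = np.array([np.sqrt(0.5 * v), 0.0, 1.0,
                           np.log(1.0), np.log(0.25 * v)])

    def objective(theta):
        return _profiled_nll(theta, blocks, reml)[0]

    res = optimize.minimize(objective, theta0, method="L-BFGS-B",
                            options={"maxiter": maxiter, "maxfun": 10 * maxiter})
    nll, beta, cov_beta = _profiled_nll(res.x, blocks, reml)
    if not np.isfinite(nll):  # fall back to the starting point
        nll, beta, cov_beta = _profiled_nll(theta0, blocks, reml)
        res.x, res.success = theta0, False
    G, sw2, se2 = _theta_to_var(res.x)
    params = ModelParams(beta=beta, G=(G + G.T) / 2, sigma_w2=sw2, sigma_e2=se2, terms=terms)
    return FitResult(
        params=params,
        converged=bool(res.success),
        log_likelihood=float(-nll),
        n_iter=int(res.nit),
        message=str(res.message),
        beta_se=np.sqrt(np.diag(cov_beta)),
    )


# -- conditional forecasting ------------------------------------------------

def conditional_prediction(
    history: pd.DataFrame,
    future_times: np.ndarray,
    params: ModelParams,
    patient: pd.Series,
) -> PredictiveDistribution:
    """Gaussian forecast of measured FEV1 at ``future_times`` given one
    patient's observed history (columns t, fev1_pp, age, ...).

    Fixed-effect covariates for the future are frozen at their values at the
    prediction time (the last history row); with an empty history the prior
    mean X beta and prior covariance are returned, building the design from
    patient-level covariates (age = baseline_age, encounter-level booleans at
    their reference level).  The predictive covariance includes the
    measurement-noise term, since FIES operates on measured FEV1.
    """
    ft = np.asarray(future_times, dtype=float)
    if len(history) == 0:
        row = {"t": 0.0, "age": float(patient["baseline_age"]),
               "medicaid": 0.0, "cfrd": 0.0, "pa_positive": 0.0, "mrsa_positive": 0.0}
        X = np.repeat(design_matrix(patient, pd.DataFrame([row]), params.terms), len(ft), axis=0)
        return PredictiveDistribution(times=ft, mean=X @ params.beta,
                                      covariance=marginal_covariance(ft, params))
    t_obs = history["t"].to_numpy(dtype=float)
    if len(ft) and len(t_obs) and ft.min() <= t_obs.max():
        raise ValueError("future_times must lie strictly after the history")

    X_obs = design_matrix(patient, history, params.terms)
    last = history.iloc[[-1]]
    X_fut = np.repeat(design_matrix(patient, last, params.terms), len(ft), axis=0)

    mu_obs = X_obs @ params.beta
    mu_fut = X_fut @ params.beta

    V_obs = marginal_covariance(t_obs, params)
    V_fut = marginal_covariance(ft, params)
    C = _cross_covariance(ft, t_obs, params)  # (future, obs)

    cf = _chol_with_jitter(V_obs)
    r = history["fev1_pp"].to_numpy(dtype=float) - mu_obs
    mean = mu_fut + C @ cho_solve(cf, r)
    cov = V_fut - C @ cho_solve(cf, C.T)
    cov = (cov + cov.T) / 2
    return PredictiveDistribution(times=ft, mean=mean, covariance=cov)


# -- PEx probability --------------------------------------------------------

def pex_probability(
    history: pd.DataFrame,
    t: float,
    fies_baseline: float,
    horizon: float,
    params: ModelParams,
    patient: pd.Series,
    n_samples: int = 500,
    grid_step_days: float = DAYS_PER_MONTH,
    seed: int | np.random.Generator = 0,
    threshold_drop: float = 10.0,
    method: str = "mc",
) -> float:
    """Probability of a FIES-defined PEx within ``(t, t + horizon]``.

    The event is the predictive FEV1 path dipping to ``fies_baseline -
    threshold_drop`` or below at any point of a grid with spacing
    ``grid_step_days`` over the horizon (the horizon endpoint is always on the
    grid).  ``method='mc'`` (default) draws joint samples from the conditional
    predictive Gaussian; under a fixed seed, estimates at nested horizons use
    common random numbers, so the probability is nondecreasing in the horizon.
    ``method='union_bound'`` returns the cheaper analytic Bonferroni upper
    bound min(1, sum_j Phi((thr - mu_j)/sd_j)); it is not the default and
    overstates the probability when grid points are correlated.
    """
    if not np.isfinite(fies_baseline):
        raise ValueError("FIES baseline undefined at this encounter; skip it")
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    k = int(np.ceil(horizon / grid_step_days - 1e-9))
    grid = t + grid_step_days * np.arange(1, k + 1)
    grid[-1] = t + horizon
    pred = conditional_prediction(history, grid, params, patient)
    thr = fies_baseline - threshold_drop

    if method == "union_bound":
        from scipy.stats import norm
        sd = np.sqrt(np.clip(np.diag(pred.covariance), 0, None))
        return float(min(1.0, norm.cdf((thr - pred.mean) / np.maximum(sd, 1e-12)).sum()))
    if method != "mc":
        raise ValueError(f"unknown method {method!r}")

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cov = pred.covariance + 1e-10 * np.eye(k)
    L = np.linalg.cholesky(cov)
    # (k, n) draw: with a common seed the first rows coincide across nested
    # grids, making the estimate monotone in the horizon.
    z = rng.standard_normal((k, n_samples))
    paths = pred.mean[:, None] + L @ z
    return float(np.mean(paths.min(axis=0) <= thr))
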