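"""Maximum-likelihood path analysis for three-node recursive chain models.

The model is a directed chain x1 -> x2 -> x3 (e.g. centromedial amygdala ->
posterior medial OFC -> lateral OFC) with free parameters b1, b2 (path
coefficients), the exogenous variance of x1 and the residual variances of x2
and x3 — five parameters against the six distinct moments of a 3x3 covariance
matrix, hence one degree of freedom.

Fitting minimises the Wishart ML discrepancy

    F(S, Sigma(theta)) = ln|Sigma| + tr(S Sigma^-1) - ln|S| - p

and tests fit with chi2 = (N - 1) * F_min on df = p(p+1)/2 - q.  By default
variables are z-scored first, so the reported coefficients are standardized;
standard errors come from the curvature (numerical Hessian) of the discrepancy
scaled by 2 / (N - 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
from scipy.optimize import minimize


@dataclass(frozen=True)
class PathModel:
    """A recursive 3-variable chain: variables[0] -> variables[1] -> variables[2]."""

    variables: tuple[str, str, str] = ("CMA", "pmOFC", "lOFC")

    @property
    def n_free_params(self) -> int:
        return 5  # two paths + one exogenous variance + two residual variances

    @property
    def edges(self) -> tuple[tuple[str, str], tuple[str, str]]:
        v = self.variables
        return ((v[0], v[1]), (v[1], v[2]))


@dataclass
class SEMData:
    """Sample covariance matrix (3x3) and the sample size it came from."""

    cov: np.ndarray
    n: int

    def __post_init__(self) -> None:
        self.cov = np.asarray(self.cov, dtype=float)
        if self.cov.shape != (3, 3):
            raise ValueError("covariance matrix must be 3x3")
        if not np.allclose(self.cov, self.cov.T):
            raise ValueError("covariance matrix must be symmetric")
        if np.any(np.linalg.eigvalsh(self.cov) <= 0):
            raise ValueError("covariance matrix must be positive definite")

    @classmethod
    def from_observations(cls, x: np.ndarray, standardize: bool = True) -> "SEMData":
        x = np.asarray(x, dtype=float)
        if x.ndim != 2 or x.shape[1] != 3:
            raise ValueError("observations must be N x 3")
        if standardize:
            x = (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)
        return cls(cov=np.cov(x, rowvar=False, ddof=1), n=x.shape[0])


@dataclass
class SEMFit:
    model: PathModel
    paths: np.ndarray          # (b1, b2)
    path_se: np.ndarray
    path_p: np.ndarray         # Wald two-sided
    variances: np.ndarray      # (var1, resid2, resid3)
    chi2: float
    df: int
    p: float
    converged: bool
    n: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (src, dst), b, se, p in zip(
            self.model.edges, self.paths, self.path_se, self.path_p
        ):
            rows.append({"path": f"{src}->{dst}", "estimate": b, "se": se, "p": p})
        return pd.DataFrame(rows)


def implied_covariance(theta: np.ndarray) -> np.ndarray:
    """Model-implied covariance of the chain for theta = (b1, b2, v1, v2, v3).

    v1 is the exogenous variance of node 1; v2, v3 the residual variances of
    nodes 2 and 3.
    """
    b1, b2, v1, v2, v3 = np.asarray(theta, dtype=float)
    if v1 <= 0 or v2 <= 0 or v3 <= 0:
        raise ValueError("variances must be positive")
    s11 = v1
    s12 = b1 * v1
    s22 = b1**2 * v1 + v2
    s13 = b1 * b2 * v1
    s23 = b2 * s22
    s33 = b2**2 * s22 + v3
    return np.array([[s11, s12, s13], [s12, s22, s23], [s13, s23, s33]])


def model_df(model: PathModel, n_variables: int = 3) -> int:
    """Degrees of freedom: distinct moments minus free parameters."""
    return n_variables * (n_variables + 1) // 2 - model.n_free_params


def sample_size_check(n: int, n_params: int, factor: int = 5) -> bool:
    """True iff the sample size is at least ``factor`` times the parameter count."""
    if n <= 0 or n_params <= 0:
        raise ValueError("n and n_params must be positive")
    return n >= factor * n_params


def _discrepancy(s: np.ndarray, sigma: np.ndarray, logdet_s: float) -> float:
    sign, logdet = np.linalg.slogdet(sigma)
    if sign <= 0:
        return np.inf
    return logdet + float(np.trace(np.linalg.solve(sigma, s))) - logdet_s - 3.0


def fit_sem(data: SEMData, model: PathModel | None = None) -> SEMFit:
    """Fit the 3-node chain by ML on the sample covariance matrix.

    Optimises over (b1, b2, log v1, log v2, log v3) with a quasi-Newton method;
    the closed-form regression solution seeds the search, so convergence is
    essentially immediate on well-conditioned data.
    """
    if model is None:
        model = PathModel()
    s = data.cov
    _, logdet_s = np.linalg.slogdet(s)

    def pack_nll(x: np.ndarray) -> float:
        theta = np.array([x[0], x[1], np.exp(x[2]), np.exp(x[3]), np.exp(x[4])])
        return _discrepancy(s, implied_covariance(theta), logdet_s)

    # closed-form start: chain paths are the simple regression slopes
    b1_0 = s[0, 1] / s[0, 0]
    b2_0 = s[1, 2] / s[1, 1]
    v1_0 = s[0, 0]
    v2_0 = max(s[1, 1] - b1_0**2 * s[0, 0], 1e-6)
    v3_0 = max(s[2, 2] - b2_0**2 * s[1, 1], 1e-6)
    x0 = np.array([b1_0, b2_0, np.log(v1_0), np.log(v2_0), np.log(v3_0)])

    res = minimize(pack_nll, x0, method="BFGS", options={"gtol": 1e-10, "maxiter": 500})
    x = res.x
    theta = np.array([x[0], x[1], np.exp(x[2]), np.exp(x[3]), np.exp(x[4])])
    sigma = implied_covariance(theta)
    fmin = max(_discrepancy(s, sigma, logdet_s), 0.0)
    df = model_df(model)
    chi2 = (data.n - 1) * fmin
    p = float(scipy.stats.chi2.sf(chi2, df)) if df > 0 else float("nan")

    # SEs: curvature of (N-1)/2 * F at the optimum, on the (b1, b2, ...) scale
    hess = _numerical_hessian(pack_nll, x)
    fisher = (data.n - 1) / 2.0 * hess
    try:
        cov_theta = np.linalg.inv(fisher)
        se = np.sqrt(np.clip(np.diag(cov_theta)[:2], 0.0, None))
    except np.linalg.LinAlgError:
        se = np.full(2, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = theta[:2] / se
    path_p = 2.0 * scipy.stats.norm.sf(np.abs(z))

    return SEMFit(
        model=model,
        paths=theta[:2],
        path_se=se,
        path_p=path_p,
        variances=theta[2:],
        chi2=float(chi2),
        df=df,
        p=p,
        converged=bool(res.success),
        n=data.n,
    )


def _numerical_hessian(f, x: np.ndarray, eps: float = 1e-5) -> np.ndarray:
    """Central-difference Hessian."""
    k = len(x)
    h = np.empty((k, k))
    f0 = f(x)
    for i in range(k):
        for j in range(i, k):
            xpp = x.copy(); xpp[i] += eps; xpp[j] += eps
            xpm = x.copy(); xpm[i] += eps; xpm[j] -= eps
            xmp = x.copy(); xmp[i] -= eps; xmp[j] += eps
            xmm = x.copy(); xmm[i] -= eps; xmm[j] -= eps
            h[i, j] = h[j, i] = (f(xpp) - f(xpm) - f(xmp) + f(xmm)) / (4 * eps**2)
    return h


def standardized_chain_theta(b1: float, b2: float) -> np.ndarray:
    """Generating parameters for a chain with unit-variance (standardized) nodes.

    With Var(x1) = 1, choosing residual variances 1 - b1^2 and 1 - b2^2 makes
    every node's marginal variance 1, so b1 and b2 are the standardized path
    coefficients.
    """
    if not (abs(b1) < 1 and abs(b2) < 1):
        raise ValueError("standardized paths must lie in (-1, 1)")
    return np.array([b1, b2, 1.0, 1.0 - b1**2, 1.0 - b2**2])


def generate_sem_samples(
    theta: np.ndarray, n: int, rng: np.random.Generator, standardize: bool = True
) -> SEMData:
    """Draw N observations from the recursive chain and return their covariance."""
    b1, b2, v1, v2, v3 = np.asarray(theta, dtype=float)
    x1 = np.sqrt(v1) * rng.standard_normal(n)
    x2 = b1 * x1 + np.sqrt(v2) * rng.standard_normal(n)
    x3 = b2 * x2 + np.sqrt(v3) * rng.standard_normal(n)
    obs = np.column_stack([x1, x2, x3])
    return SEMData.from_observations(obs, standardize=standardize)
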