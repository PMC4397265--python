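"""Maximum-likelihood covariance-structure estimation.

Fits a :class:`~fixedlinks.model.ModelSpec` to sample moments by
minimizing the normal-theory ML discrepancy

    F_ML(theta) = ln|Sigma(theta)| - ln|S| + tr(S Sigma(theta)^-1) - p

over the free parameters.  The test statistic is T = (n-1) * F_min by
default (multiplier configurable); standard errors come from the inverse
of the numerically evaluated observed information of (multiplier * F)/2.
Robust (Satorra-Bentler-type) rescaling of T from fourth-order sample
moments is available when raw data are supplied.

Variances are estimated unbounded: negative (Heywood) estimates are
reported and flagged rather than constrained away.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .model import ModelSpec, validate_spec

__all__ = [
    "SampleMoments",
    "FitResult",
    "FitOptions",
    "implied_covariance",
    "ml_discrepancy",
    "fit",
    "satorra_bentler_scale",
    "variance_z_test",
    "wald_constraint_test",
]


# ----------------------------------------------------------------------
# Sample moments
# ----------------------------------------------------------------------


@dataclass
class SampleMoments:
    """A sample covariance (or correlation) matrix with its sample size.

    ``raw`` (an n x p table) is only needed for robust rescaling, which
    requires fourth-order moments.  The covariance divisor used for raw
    data is n - 1.
    """

    S: np.ndarray
    names: list[str]
    n: int
    raw: pd.DataFrame | None = None
    is_correlation: bool = False

    def __post_init__(self):
        self.S = np.asarray(self.S, dtype=float)
        p = len(self.names)
        if self.S.shape != (p, p):
            raise ValueError(f"S must be {p}x{p} to match names")
        if not np.allclose(self.S, self.S.T, atol=1e-10):
            raise ValueError("S must be symmetric")
        if np.linalg.eigvalsh(self.S).min() <= 0:
            raise ValueError("sample matrix S is not positive definite")
        if self.n < 2:
            raise ValueError("sample size n must be >= 2")
        if self.raw is not None:
            raw_cov = np.cov(np.asarray(self.raw, dtype=float), rowvar=False, ddof=1)
            target = np.corrcoef(np.asarray(self.raw, float), rowvar=False) if self.is_correlation else raw_cov
            if not np.allclose(target, self.S, atol=1e-10):
                raise ValueError("raw data moments do not reproduce S")

    @property
    def p(self) -> int:
        return len(self.names)

    @classmethod
    def from_raw(cls, data: pd.DataFrame, as_correlation: bool = False) -> "SampleMoments":
        """Compute moments from an n x p data table (divisor n - 1)."""
        X = np.asarray(data, dtype=float)
        S = np.corrcoef(X, rowvar=False) if as_correlation else np.cov(X, rowvar=False, ddof=1)
        return cls(S=S, names=list(data.columns), n=len(data), raw=data, is_correlation=as_correlation)

    @classmethod
    def from_csv(cls, path: str | Path, n: int, is_correlation: bool = False) -> "SampleMoments":
        """Read a square labelled covariance/correlation CSV."""
        df = pd.read_csv(path, index_col=0)
        return cls(S=df.to_numpy(float), names=list(df.columns), n=n, is_correlation=is_correlation)

    def subset(self, names: list[str]) -> "SampleMoments":
        idx = [self.names.index(v) for v in names]
        raw = self.raw[names] if self.raw is not None else None
        return SampleMoments(
            S=self.S[np.ix_(idx, idx)], names=list(names), n=self.n,
            raw=raw, is_correlation=self.is_correlation,
        )

    def to_correlation(self) -> "SampleMoments":
        d = 1.0 / np.sqrt(np.diag(self.S))
        return SampleMoments(S=self.S * np.outer(d, d), names=list(self.names),
                             n=self.n, is_correlation=True)


# ----------------------------------------------------------------------
# Model algebra
# ----------------------------------------------------------------------


def _matrices(spec: ModelSpec, theta: dict[str, float]):
    """Assemble Lambda, B, Psi, Theta from fixed values and theta."""
    p, m = spec.p, spec.m
    yi = {y: i for i, y in enumerate(spec.manifest_names)}
    li = {l: i for i, l in enumerate(spec.latent_names)}
    Lam = np.zeros((p, m))
    for (y, l), par in spec.loadings.items():
        Lam[yi[y], li[l]] = theta[f"{l}=~{y}"] if par.free else par.value
    B = np.zeros((m, m))
    for (t, s), par in spec.structural_paths.items():
        B[li[t], li[s]] = theta[f"{t}~{s}"] if par.free else par.value
    Psi = np.zeros((m, m))
    for l, par in spec.latent_variances.items():
        Psi[li[l], li[l]] = theta[f"{l}~~{l}"] if par.free else par.value
    for (a, b), par in spec.latent_covariances.items():
        v = theta[f"{a}~~{b}"] if par.free else par.value
        Psi[li[a], li[b]] = Psi[li[b], li[a]] = v
    Th = np.zeros((p, p))
    for y, par in spec.residual_variances.items():
        Th[yi[y], yi[y]] = theta[f"{y}~~{y}"] if par.free else par.value
    return Lam, B, Psi, Th


def _latent_cov(B: np.ndarray, Psi: np.ndarray) -> np.ndarray:
    m = B.shape[0]
    A = np.linalg.solve(np.eye(m) - B, np.eye(m))
    return A @ Psi @ A.T


def implied_covariance(spec: ModelSpec, theta: dict[str, float]) -> np.ndarray:
    """Model-implied covariance Sigma(theta).

    Sigma = Lambda (I-B)^-1 Psi (I-B)^-T Lambda^T + Theta, with theta
    supplying a value for every free parameter (keyed by the names from
    :meth:`ModelSpec.free_parameter_names`).
    """
    missing = [k for k in spec.free_parameter_names() if k not in theta]
    if missing:
        raise ValueError(f"theta missing free parameters: {missing}")
    Lam, B, Psi, Th = _matrices(spec, theta)
    if abs(np.linalg.det(np.eye(spec.m) - B)) < 1e-12:
        raise np.linalg.LinAlgError("I - B is singular (cyclic structural paths)")
    C = _latent_cov(B, Psi)
    Sigma = Lam @ C @ Lam.T + Th
    return (Sigma + Sigma.T) / 2


def ml_discrepancy(S: np.ndarray, Sigma: np.ndarray) -> float:
    """Normal-theory ML discrepancy between sample and implied matrices.

    F_ML = ln|Sigma| - ln|S| + tr(S Sigma^-1) - p; zero iff Sigma == S.
    """
    S = np.asarray(S, float)
    Sigma = np.asarray(Sigma, float)
    p = S.shape[0]
    if Sigma.shape != (p, p):
        raise ValueError("S and Sigma must have the same dimension")
    sign_s, logdet_s = np.linalg.slogdet(S)
    if sign_s <= 0:
        raise ValueError("sample matrix S is not positive definite")
    sign_m, logdet_m = np.linalg.slogdet(Sigma)
    if sign_m <= 0:
        raise ValueError("implied matrix Sigma is not positive definite")
    return float(logdet_m - logdet_s + np.trace(np.linalg.solve(Sigma, S)) - p)


# ----------------------------------------------------------------------
# Fitting
# ----------------------------------------------------------------------


@dataclass
class FitOptions:
    """Optimizer and inference settings.

    ``multiplier``: the factor turning F_min into the test statistic
    (default n - 1, i.e. T = (n-1) F_min); ``None`` means n - 1.
    """

    multiplier: float | None = None
    f_tol: float = 1e-8
    max_evals: int = 5000
    compute_se: bool = True


@dataclass
class FitResult:
    """Estimates, standard errors and fit information for one model."""

    spec: ModelSpec
    moments: SampleMoments
    theta_hat: dict[str, float]
    se: dict[str, float]
    standardized: dict[str, float]
    T: float
    df: int
    F_min: float
    converged: bool
    multiplier: float
    heywood: bool
    vcov: np.ndarray | None = None
    T_scaled: float | None = None
    c: float | None = None
    implied: np.ndarray = field(default=None, repr=False)

    @property
    def p_value(self) -> float:
        if self.df == 0:
            return float("nan")
        return float(stats.chi2.sf(self.T, self.df))


def _theta_vec_to_dict(names, x):
    return dict(zip(names, (float(v) for v in x)))


def _latent_variance_start(spec: ModelSpec, moments: SampleMoments, latent: str) -> float:
    """Moment-based start for a latent variance.

    With fixed loadings l_i the off-diagonal covariances satisfy
    s_ij ~ psi * l_i * l_j (+ other latents), so a least-squares
    projection of the observed off-diagonals onto the course gives a
    well-scaled start.  Latents without fixed loadings (congeneric /
    endogenous) start at half the variance of their first indicator.
    """
    yi = {y: i for i, y in enumerate(spec.manifest_names)}
    entries = [(y, par) for (y, l), par in spec.loadings.items() if l == latent]
    fixed_entries = [(y, par.value) for y, par in entries if not par.free]
    if len(fixed_entries) >= 2:
        num = den = 0.0
        for a in range(len(fixed_entries)):
            for b in range(a + 1, len(fixed_entries)):
                (ya, la), (yb, lb) = fixed_entries[a], fixed_entries[b]
                num += moments.S[yi[ya], yi[yb]] * la * lb
                den += (la * lb) ** 2
        if den > 0 and num > 0:
            return 0.5 * num / den
    if entries:
        y0 = entries[0][0]
        return 0.5 * moments.S[yi[y0], yi[y0]]
    return 0.5 * float(np.mean(np.diag(moments.S)))


def _start_values(spec: ModelSpec, moments: SampleMoments) -> np.ndarray:
    """Heuristic starts: free loadings 0.5*sd(indicator), residual
    variances half the observed variance, latent variances from a
    moment projection, structural paths 0."""
    sds = np.sqrt(np.diag(moments.S))
    yi = {y: i for i, y in enumerate(spec.manifest_names)}
    x0 = []
    for name in spec.free_parameter_names():
        if "=~" in name:
            _l, y = name.split("=~")
            x0.append(0.5 * sds[yi[y]])
        elif "~~" in name:
            a, _b = name.split("~~")
            if a in yi:
                x0.append(0.5 * moments.S[yi[a], yi[a]])
            else:
                x0.append(_latent_variance_start(spec, moments, a))
        else:  # structural path
            x0.append(0.0)
    return np.array(x0, float)


def _objective_factory(spec: ModelSpec, S: np.ndarray):
    names = spec.free_parameter_names()

    def f(x):
        theta = _theta_vec_to_dict(names, x)
        try:
            Sigma = implied_covariance(spec, theta)
            return ml_discrepancy(S, Sigma)
        except (ValueError, np.linalg.LinAlgError):
            # outside the PD region: steep finite penalty keeps the
            # quasi-Newton search inside admissible territory
            return 1e6 + float(np.sum(x**2))

    return names, f


def _num_hessian(f, x, h=1e-5):
    k = len(x)
    H = np.empty((k, k))
    f0 = f(x)
    for i in range(k):
        for j in range(i, k):
            hi = h * max(1.0, abs(x[i]))
            hj = h * max(1.0, abs(x[j]))
            if i == j:
                e = np.zeros(k); e[i] = hi
                H[i, i] = (f(x + e) - 2 * f0 + f(x - e)) / hi**2
            else:
                ei = np.zeros(k); ei[i] = hi
                ej = np.zeros(k); ej[j] = hj
                H[i, j] = H[j, i] = (
                    f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
                ) / (4 * hi * hj)
    return H


def _num_gradient(f, x, h=1e-6):
    g = np.empty(len(x))
    for i in range(len(x)):
        hi = h * max(1.0, abs(x[i]))
        e = np.zeros(len(x)); e[i] = hi
        g[i] = (f(x + e) - f(x - e)) / (2 * hi)
    return g


def standardized_solution(spec: ModelSpec, theta: dict[str, float]) -> dict[str, float]:
    """Standardized loadings, paths, covariances and residual variances.

    Loadings are scaled by sd(latent)/sd(manifest), structural paths by
    sd(source)/sd(target), residual variances by the implied manifest
    variance; latent sds come from the implied latent covariance matrix.
    """
    Lam, B, Psi, Th = _matrices(spec, theta)
    C = _latent_cov(B, Psi)
    Sigma = Lam @ C @ Lam.T + Th
    sd_lat = np.sqrt(np.abs(np.diag(C)))
    sd_man = np.sqrt(np.diag(Sigma))
    yi = {y: i for i, y in enumerate(spec.manifest_names)}
    li = {l: i for i, l in enumerate(spec.latent_names)}
    out = {}
    for (y, l) in spec.loadings:
        out[f"{l}=~{y}"] = float(Lam[yi[y], li[l]] * sd_lat[li[l]] / sd_man[yi[y]])
    for (t, s) in spec.structural_paths:
        out[f"{t}~{s}"] = float(B[li[t], li[s]] * sd_lat[li[s]] / sd_lat[li[t]])
    for (a, b) in spec.latent_covariances:
        denom = sd_lat[li[a]] * sd_lat[li[b]]
        out[f"{a}~~{b}"] = float(C[li[a], li[b]] / denom) if denom > 0 else 0.0
    for y in spec.manifest_names:
        out[f"{y}~~{y}"] = float(Th[yi[y], yi[y]] / Sigma[yi[y], yi[y]])
    return out


def fit(spec: ModelSpec, moments: SampleMoments, options: FitOptions | None = None) -> FitResult:
    """Fit a model specification to sample moments by maximum likelihood.

    Minimizes ``ml_discrepancy`` over the free parameters with a
    quasi-Newton (BFGS) search from deterministic heuristic starts;
    T = multiplier * F_min (multiplier defaults to n - 1).  Standard
    errors are the square roots of the diagonal of the inverse observed
    information of (multiplier * F)/2 evaluated at the optimum.
    """
    options = options or FitOptions()
    report = validate_spec(spec)
    if not report.ok:
        raise ValueError("invalid model spec: " + "; ".join(report.messages))
    names, objective = _objective_factory(spec, moments.S)
    x0 = _start_values(spec, moments)
    res = optimize.minimize(
        objective, x0, method="BFGS",
        options={"gtol": options.f_tol * 10, "maxiter": options.max_evals},
    )
    # polish: a second start from the first optimum guards against a
    # premature line-search exit
    res2 = optimize.minimize(
        objective, res.x, method="Nelder-Mead",
        options={"fatol": options.f_tol, "xatol": 1e-10, "maxfev": options.max_evals},
    )
    if res2.fun < res.fun:
        res = res2
    x_hat = res.x
    F_min = float(res.fun)
    grad_norm = float(np.max(np.abs(_num_gradient(objective, x_hat)))) if len(x_hat) else 0.0
    converged = bool(F_min < 1e6) and grad_norm < 1e-4
    if not converged:
        warnings.warn(f"fit of {spec.name or 'model'} did not converge (|grad|={grad_norm:.2e})")
    theta_hat = _theta_vec_to_dict(names, x_hat)
    multiplier = float(options.multiplier if options.multiplier is not None else moments.n - 1)
    T = multiplier * F_min

    # sign convention: first free loading per latent nonnegative.
    # Flipping a latent's sign (eta -> -eta) leaves Sigma unchanged only
    # if paths and covariances touching it flip too.
    flips = set()
    for l in spec.latent_names:
        keys = [k for k in names if k.startswith(f"{l}=~")]
        if keys and theta_hat[keys[0]] < 0:
            flips.add(l)
    if flips:
        for (y, l), par in spec.loadings.items():
            if par.free and l in flips:
                theta_hat[f"{l}=~{y}"] *= -1
        for (t, s), par in spec.structural_paths.items():
            if par.free and (t in flips) != (s in flips):
                theta_hat[f"{t}~{s}"] *= -1
        for (a, b), par in spec.latent_covariances.items():
            if par.free and (a in flips) != (b in flips):
                theta_hat[f"{a}~~{b}"] *= -1
    x_hat = np.array([theta_hat[k] for k in names])

    heywood = any(
        theta_hat[k] < 0 for k in names if "~~" in k
    )
    se = {}
    vcov = None
    if options.compute_se and names:
        H = _num_hessian(lambda x: multiplier * objective(x) / 2.0, x_hat)
        try:
            vcov = np.linalg.inv(H)
            diag = np.diag(vcov)
            se = {k: (float(np.sqrt(d)) if d > 0 else float("nan")) for k, d in zip(names, diag)}
        except np.linalg.LinAlgError:
            se = {k: float("nan") for k in names}
    std = standardized_solution(spec, theta_hat)
    return FitResult(
        spec=spec, moments=moments, theta_hat=theta_hat, se=se, standardized=std,
        T=T, df=spec.df, F_min=F_min, converged=converged, multiplier=multiplier,
        heywood=heywood, vcov=vcov, implied=implied_covariance(spec, theta_hat),
    )


# ----------------------------------------------------------------------
# Robust rescaling (Satorra-Bentler type)
# ----------------------------------------------------------------------


def _duplication_matrix(p: int) -> np.ndarray:
    """D such that vec(A) = D vech(A) for symmetric A."""
    rows = p * p
    cols = p * (p + 1) // 2
    D = np.zeros((rows, cols))
    col = 0
    for j in range(p):
        for i in range(j, p):
            D[i * p + j, col] = 1.0
            D[j * p + i, col] = 1.0
            col += 1
    return D


def _vech(A: np.ndarray) -> np.ndarray:
    p = A.shape[0]
    return np.concatenate([A[j:, j] for j in range(p)])


def _gamma_adf(X: np.ndarray) -> np.ndarray:
    """Asymptotic covariance of sqrt(n) vech(S) from fourth moments.

    Gamma_(ij),(kl) = m4_ijkl - s_ij s_kl with central moments using
    divisor n (the asymptotically distribution-free estimate).
    """
    n, p = X.shape
    Xc = X - X.mean(axis=0)
    S_n = (Xc.T @ Xc) / n
    pairs = [(i, j) for j in range(p) for i in range(j, p)]
    Y = np.empty((n, len(pairs)))
    for idx, (i, j) in enumerate(pairs):
        Y[:, idx] = Xc[:, i] * Xc[:, j]
    s = np.array([S_n[i, j] for (i, j) in pairs])
    return (Y.T @ Y) / n - np.outer(s, s)


def _delta_matrix(spec: ModelSpec, theta: dict[str, float], h: float = 1e-6) -> np.ndarray:
    """Jacobian of vech(Sigma(theta)) w.r.t. the free parameters."""
    names = spec.free_parameter_names()
    base = _vech(implied_covariance(spec, theta))
    Delta = np.empty((len(base), len(names)))
    for j, name in enumerate(names):
        t_plus = dict(theta); t_minus = dict(theta)
        step = h * max(1.0, abs(theta[name]))
        t_plus[name] += step
        t_minus[name] -= step
        Delta[:, j] = (_vech(implied_covariance(spec, t_plus)) -
                       _vech(implied_covariance(spec, t_minus))) / (2 * step)
    return Delta


def satorra_bentler_scale(spec: ModelSpec, moments: SampleMoments, fitresult: FitResult):
    """Satorra-Bentler rescaling of the ML test statistic.

    Computes the scaling factor c = tr(U Gamma)/df, where Gamma is the
    ADF estimate of the asymptotic covariance of the sample covariances
    (fourth-order moments of the raw data) and U is the normal-theory
    residual weight matrix at the estimates; returns (T_scaled, c) with
    T_scaled = T / c and stores both on the fit result.

    Under multivariate normality c -> 1; excess kurtosis gives c > 1 and
    deflates the statistic accordingly.
    """
    if moments.raw is None:
        raise ValueError("robust rescaling requires raw data (fourth moments)")
    if not fitresult.converged:
        raise ValueError("fit did not converge; rescaling would be meaningless")
    p = moments.p
    if moments.n < p * (p + 1) // 2:
        warnings.warn("sample size too small for stable fourth-order moments")
    X = np.asarray(moments.raw, float)
    Gamma = _gamma_adf(X)
    Sigma = fitresult.implied
    Sig_inv = np.linalg.inv(Sigma)
    D = _duplication_matrix(p)
    V = 0.5 * D.T @ np.kron(Sig_inv, Sig_inv) @ D
    Delta = _delta_matrix(spec, fitresult.theta_hat)
    VD = V @ Delta
    U = V - VD @ np.linalg.solve(Delta.T @ VD, VD.T)
    df = fitresult.df
    if df == 0:
        raise ValueError("saturated model: scaling undefined (df = 0)")
    c = float(np.trace(U @ Gamma) / df)
    T_scaled = fitresult.T / c
    fitresult.c = c
    fitresult.T_scaled = T_scaled
    return T_scaled, c


# ----------------------------------------------------------------------
# Inference helpers
# ----------------------------------------------------------------------


def variance_z_test(fitresult: FitResult, latent: str):
    """z-test of a freely estimated latent variance against zero.

    z = psi_hat / SE(psi_hat), two-sided normal p-value.  In fixed-links
    models a significant variance is the evidence that the latent
    captures a real process; a nonsignificant dynamic variance is
    grounds for discarding the model regardless of global fit.
    """
    key = f"{latent}~~{latent}"
    par = fitresult.spec.latent_variances.get(latent)
    if par is None or not par.free:
        raise ValueError(f"latent variance of {latent!r} is not a free parameter")
    psi = fitresult.theta_hat[key]
    se = fitresult.se.get(key, float("nan"))
    z = psi / se if se and np.isfinite(se) and se > 0 else float("nan")
    if psi == 0:
        z = 0.0
    p = float(2 * stats.norm.sf(abs(z))) if np.isfinite(z) else float("nan")
    return z, p


def _standardized_path_fn(spec: ModelSpec, names: list[str], key: str):
    def g(x):
        theta = _theta_vec_to_dict(names, x)
        return standardized_solution(spec, theta)[key]

    return g


def wald_constraint_test(
    spec: ModelSpec,
    moments: SampleMoments,
    path: tuple[str, str],
    value: float,
    fitresult: FitResult | None = None,
    method: str = "delta",
    options: FitOptions | None = None,
):
    """Wald test of a standardized structural path against a fixed value.

    ``method="delta"``: W = (beta_std - value)^2 / Var(beta_std), with
    the variance of the standardized coefficient from the delta method;
    referred to chi-square(1).  ``method="fit_difference"``: refits with
    the standardized path constrained to ``value`` (SLSQP equality
    constraint) and reports T_constrained - T.

    Returns ``(W, p, beta_std)``.
    """
    tgt, src = path
    if (tgt, src) not in spec.structural_paths or not spec.structural_paths[(tgt, src)].free:
        raise ValueError(f"path {tgt}~{src} is not a free structural parameter")
    if not -1 < value < 1:
        warnings.warn("constraint outside (-1, 1) for a standardized path")
    if fitresult is None:
        fitresult = fit(spec, moments, options)
    key = f"{tgt}~{src}"
    beta = fitresult.standardized[key]
    names = spec.free_parameter_names()
    x_hat = np.array([fitresult.theta_hat[k] for k in names])
    if method == "delta":
        if fitresult.vcov is None:
            raise ValueError("fit result lacks a parameter covariance matrix")
        g = _standardized_path_fn(spec, names, key)
        grad = _num_gradient(g, x_hat)
        var_beta = float(grad @ fitresult.vcov @ grad)
        if var_beta <= 0:
            raise ValueError("delta-method variance of the standardized path is not positive")
        W = (beta - value) ** 2 / var_beta
    elif method == "fit_difference":
        _names, objective = _objective_factory(spec, moments.S)
        g = _standardized_path_fn(spec, names, key)
        con = {"type": "eq", "fun": lambda x: g(x) - value}
        res = optimize.minimize(objective, x_hat, method="SLSQP", constraints=[con],
                                options={"maxiter": 2000, "ftol": 1e-12})
        W = fitresult.multiplier * (float(res.fun) - fitresult.F_min)
        W = max(W, 0.0)
    else:
        raise ValueError(f"unknown method {method!r}")
    p = float(stats.chi2.sf(W, 1))
    return float(W), p, float(beta)
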