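"""Maximum-likelihood simultaneous-autoregressive (SAR) error model.

The model for each structural equation is

    y = X b + u,    u = lambda W u + eps,    eps ~ N(0, sigma^2 I)

with W a row-standardized spatial weight matrix.  Writing
A = I - lambda W, the transformed regression A y = A X b + eps is ordinary
least squares for fixed lambda, so the likelihood is profiled over lambda:

    l(lambda) = -(n/2) (ln 2 pi sigma^2(lambda) + 1) + sum_i ln|1 - lambda w_i|

with w_i the eigenvalues of W (computed once per weights object).  The
profile is maximized by bounded Brent search over the admissible interval
(1/w_min, 1/w_max).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .spatial import SpatialWeights

__all__ = ["SarFit", "fit_sar_error", "aicc", "nagelkerke_r2", "sar_error_sample"]

_BOUND_DELTA = 1e-5


@dataclass
class SarFit:
    """Fitted SAR error model for one structural equation."""

    response: str
    predictors: list[str]          # includes "intercept" first
    beta: np.ndarray
    se: np.ndarray
    z_values: np.ndarray
    p_values: np.ndarray
    lam: float
    sigma2: float
    loglik: float
    k: int                         # p coefficients + lambda + sigma^2
    n: int
    aic: float
    aicc: float
    residuals_raw: np.ndarray      # y - X beta
    residuals_filtered: np.ndarray # A(y - X beta), spatially filtered

    def coefficient(self, name: str) -> float:
        return float(self.beta[self.predictors.index(name)])

    def p_value(self, name: str) -> float:
        return float(self.p_values[self.predictors.index(name)])


def _profile_pieces(y, X, weights):
    """Precompute W y and W X so each lambda evaluation is a cheap lstsq."""
    W = weights.W
    return W @ y, W @ X


def fit_sar_error(
    y: np.ndarray,
    X: np.ndarray,
    weights: SpatialWeights,
    response: str = "y",
    predictors: list[str] | None = None,
    add_intercept: bool = True,
    xtol: float = 1e-8,
) -> SarFit:
    """Fit the SAR error model by profile maximum likelihood.

    ``X`` holds the slope columns; an intercept column is prepended unless
    ``add_intercept`` is False (in which case ``X`` must already contain
    one).  Coefficient standard errors are the asymptotic
    sigma^2 (X_f' X_f)^{-1} at the profile optimum, with X_f = (I - lam W) X;
    p-values are two-sided normal.  A lambda estimate at the admissibility
    boundary (within 1e-6) raises with diagnostics.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = len(y)
    if add_intercept:
        X = np.column_stack([np.ones(n), X])
        if predictors is not None:
            predictors = ["intercept"] + list(predictors)
    if predictors is None:
        predictors = ["intercept"] + [f"x{i}" for i in range(1, X.shape[1])]
    p = X.shape[1]
    if n <= p + 3:
        raise ValueError(f"n = {n} too small for p = {p} predictors")
    if X.shape[0] != n:
        raise ValueError("y and X row counts differ")
    if not (np.all(np.isfinite(y)) and np.all(np.isfinite(X))):
        raise ValueError("missing or non-finite values in y or X")

    ev = weights.eigenvalues()
    Wy, WX = _profile_pieces(y, X, weights)

    def fit_at(lam: float):
        Ay = y - lam * Wy
        AX = X - lam * WX
        beta, *_ = np.linalg.lstsq(AX, Ay, rcond=None)
        e = Ay - AX @ beta
        sigma2 = float(e @ e) / n
        return beta, sigma2, AX, e

    def negloglik(lam: float) -> float:
        _, sigma2, _, _ = fit_at(lam)
        logjac = float(np.sum(np.log(np.abs(1.0 - lam * ev))))
        return (n / 2.0) * (np.log(2.0 * np.pi * sigma2) + 1.0) - logjac

    if np.all(np.abs(ev) < 1e-12):
        # empty weight structure: the model degenerates to OLS
        lam_hat = 0.0
    else:
        lo = 1.0 / ev.min() + _BOUND_DELTA if ev.min() < 0 else -1.0 + _BOUND_DELTA
        hi = 1.0 / ev.max() - _BOUND_DELTA
        res = optimize.minimize_scalar(
            negloglik, bounds=(lo, hi), method="bounded",
            options={"xatol": xtol},
        )
        if not res.success:
            raise RuntimeError(f"SAR profile optimization failed: {res.message}")
        lam_hat = float(res.x)
        if min(lam_hat - lo, hi - lam_hat) < 1e-6:
            raise RuntimeError(
                f"lambda estimate {lam_hat:.6f} at the boundary of the "
                f"admissible interval ({lo:.6f}, {hi:.6f}); the spatial "
                "process is degenerate or the weights are inappropriate"
            )

    beta, sigma2, AX, e_filt = fit_at(lam_hat)
    loglik = -negloglik(lam_hat)
    XtX = AX.T @ AX
    cov = sigma2 * np.linalg.inv(XtX)
    se = np.sqrt(np.diag(cov))
    zv = beta / se
    pv = 2.0 * stats.norm.sf(np.abs(zv))
    k = p + 2  # slopes + intercept already in p; plus lambda and sigma^2
    aic = -2.0 * loglik + 2.0 * k
    fit = SarFit(
        response=response,
        predictors=list(predictors),
        beta=beta,
        se=se,
        z_values=zv,
        p_values=pv,
        lam=lam_hat,
        sigma2=sigma2,
        loglik=loglik,
        k=k,
        n=n,
        aic=aic,
        aicc=np.nan,
        residuals_raw=y - X @ beta,
        residuals_filtered=e_filt,
    )
    fit.aicc = aicc(fit, n)
    return fit


def aicc(fit: SarFit, n: int | None = None) -> float:
    """Small-sample corrected AIC: AIC + 2k(k+1)/(n - k - 1)."""
    if n is None:
        n = fit.n
    k = fit.k
    if n <= k + 1:
        raise ValueError(f"AICc undefined: n = {n} <= k + 1 = {k + 1}")
    return fit.aic + 2.0 * k * (k + 1) / (n - k - 1)


def nagelkerke_r2(fit: SarFit, null_fit: SarFit) -> float:
    """Likelihood-ratio pseudo-R^2: 1 - exp((2/n)(l_null - l_model)).

    ``null_fit`` must be the intercept-plus-lambda model on the same data.
    A model log-likelihood below the null reports 0 with a warning.
    """
    if fit.n != null_fit.n:
        raise ValueError("fits compare different sample sizes")
    if fit.loglik < null_fit.loglik:
        import logging
        logging.getLogger(__name__).warning(
            "model log-likelihood below null (%.3f < %.3f); reporting R^2 = 0",
            fit.loglik, null_fit.loglik,
        )
        return 0.0
    return float(1.0 - np.exp((2.0 / fit.n) * (null_fit.loglik - fit.loglik)))


def sar_error_sample(
    weights: SpatialWeights,
    lam: float,
    sd: float,
    rng: np.random.Generator,
    size: int = 1,
) -> np.ndarray:
    """Draw SAR-correlated errors u = (I - lam W)^{-1} eps, eps ~ N(0, sd^2).

    Returns shape (n,) for size 1, else (size, n).  lambda outside the
    admissible interval of W's eigenvalue bounds raises.
    """
    ev = weights.eigenvalues()
    lo = 1.0 / ev.min() if ev.min() < 0 else -np.inf
    hi = 1.0 / ev.max() if ev.max() > 0 else np.inf
    if not lo < lam < hi:
        raise ValueError(f"lambda = {lam} outside admissible interval ({lo}, {hi})")
    n = weights.n
    A = np.eye(n) - lam * weights.W.toarray()
    eps = rng.normal(0.0, sd, size=(size, n))
    u = np.linalg.solve(A, eps.T).T
    return u[0] if size == 1 else u
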