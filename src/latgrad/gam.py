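"""Penalized-spline smooth models of a response against latitude.

A univariate generalized additive model in the P-spline tradition: the
smooth is a cubic B-spline basis on equally spaced knots with a
second-order difference penalty on the coefficients,

    minimize  Dev(y, B beta) + lambda * ||D2 beta||^2 ,

fitted by (penalized, iteratively reweighted) least squares.  The penalty
null space is exactly the linear functions, so lambda -> infinity recovers
the ordinary least-squares line and the effective degrees of freedom range
from 2 (linear) to k (unpenalized spline).  The smoothing parameter is
chosen by generalized cross-validation over a log-spaced grid unless fixed
by the caller.

Two families are supported: gaussian with identity link (default for both
richness and mean root distance responses) and poisson with log link for
count responses.  Model fit is summarized by deviance explained,
1 - deviance/null_deviance, the GAM analogue of R².
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from scipy.interpolate import BSpline
from scipy.linalg import cho_factor, cho_solve
from sklearn.base import BaseEstimator, RegressorMixin

_DEFAULT_LAMBDA_GRID = np.logspace(-6.0, 10.0, 49)


def _bspline_basis(x: np.ndarray, xmin: float, xmax: float, k: int) -> np.ndarray:
    """Cubic B-spline design matrix with k equally spaced basis functions.

    Knots extend three spacings beyond [xmin, xmax] (no clamping), so the
    Greville abscissae are equally spaced and the second-difference
    penalty leaves linear functions exactly unpenalized.
    """
    if k < 4:
        raise ValueError("basis dimension k must be >= 4")
    h = (xmax - xmin) / (k - 3)
    knots = xmin + h * np.arange(-3, k + 1)
    return BSpline.design_matrix(x, knots, 3, extrapolate=True).toarray()


def _second_difference_penalty(k: int) -> np.ndarray:
    d = np.diff(np.eye(k), n=2, axis=0)
    return d.T @ d


class PenalizedSplineGAM(BaseEstimator, RegressorMixin):
    """Univariate penalized cubic-spline smoother (GAM with one smooth).

    Parameters
    ----------
    k : int, default 10
        Basis dimension of the smooth.
    family : {"gaussian", "poisson"}
        Error distribution and link (identity resp. log).
    lam : "gcv" or float
        Smoothing parameter rule: generalized cross-validation over
        ``lam_grid``, or a fixed value.
    lam_grid : array-like or None
        Candidate lambdas for GCV; defaults to a 49-point log grid over
        [1e-6, 1e10].
    selection_gamma : float, default 2.5
        Inflation factor on the effective degrees of freedom in the GCV
        score, GCV(λ) = n·Dev / (n − γ·edf)².  Plain GCV (γ = 1) is prone
        to occasional severe undersmoothing, which makes the subsequent
        smooth-term test anticonservative; inflating the df cost (values
        well above 1 are advocated in the smoothing literature) restores
        near-nominal type-I error.  γ = 2.5 gives a calibrated smooth-term
        test in this implementation's null simulations.

    Attributes (after ``fit``)
    --------------------------
    lambda_ : float              selected smoothing parameter
    coef_ : ndarray (k,)         spline coefficients
    edf_ : float                 effective degrees of freedom, in [2, k]
    fitted_values_ : ndarray     fitted mean on the response scale
    residuals_ : ndarray         response residuals y - fitted
    deviance_, null_deviance_ : float
    deviance_explained_ : float  1 - deviance/null_deviance (0 if y constant)
    p_value_ : float             significance of the smooth vs intercept-only
    """

    def __init__(self, k: int = 10, family: str = "gaussian",
                 lam="gcv", lam_grid=None, selection_gamma: float = 2.5):
        self.k = k
        self.family = family
        self.lam = lam
        self.lam_grid = lam_grid
        self.selection_gamma = selection_gamma

    # -- family helpers -------------------------------------------------
    def _check_family(self):
        if self.family not in ("gaussian", "poisson"):
            raise ValueError(f"unknown family {self.family!r}")

    @staticmethod
    def _poisson_deviance(y, mu):
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(y > 0, y * np.log(y / mu), 0.0)
        return 2.0 * float(np.sum(term - (y - mu)))

    # -- fitting --------------------------------------------------------
    def fit(self, X, y):
        self._check_family()
        x = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if x.shape[0] != y.shape[0]:
            raise ValueError("x and y must have equal length")
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
            raise ValueError("non-finite values in input")
        n = x.shape[0]
        if n < self.k + 2:
            raise ValueError(f"need at least k+2={self.k + 2} observations, got {n}")
        if self.family == "poisson":
            if np.any(y < 0) or np.any(y != np.round(y)):
                raise ValueError("poisson family requires non-negative integer y")
        self.x_min_, self.x_max_ = float(x.min()), float(x.max())
        if self.x_max_ == self.x_min_:
            raise ValueError("x is constant")
        B = _bspline_basis(x, self.x_min_, self.x_max_, self.k)
        P = _second_difference_penalty(self.k)

        if np.ptp(y) == 0.0:
            # constant response: intercept-only model, no smooth signal
            self._finalize_constant(y, B)
            return self

        if isinstance(self.lam, str) and self.lam == "gcv":
            grid = np.asarray(
                self.lam_grid if self.lam_grid is not None else _DEFAULT_LAMBDA_GRID,
                dtype=float,
            )
            best = None
            for lam in grid:
                fitres = self._fit_fixed(B, P, y, lam)
                if best is None or fitres["gcv"] < best["gcv"] - 1e-12:
                    best = fitres
            res = best
        else:
            res = self._fit_fixed(B, P, y, float(self.lam))
        self._finalize(y, res)
        return self

    def _fit_fixed(self, B, P, y, lam):
        n = y.shape[0]
        if self.family == "gaussian":
            beta, edf = self._pls_solve(B, P, y, np.ones(n), lam)
            mu = B @ beta
            dev = float(np.sum((y - mu) ** 2))
        else:
            mu = np.maximum(y, 0.5)
            eta = np.log(mu)
            beta = None
            for _ in range(50):
                w = mu
                z = eta + (y - mu) / mu
                beta, edf = self._pls_solve(B, P, z, w, lam)
                eta_new = B @ beta
                if beta is not None and np.max(np.abs(eta_new - eta)) < 1e-10:
                    eta = eta_new
                    mu = np.exp(eta)
                    break
                eta = eta_new
                mu = np.exp(np.clip(eta, -30, 30))
            dev = self._poisson_deviance(y, mu)
        gcv = n * dev / max(n - self.selection_gamma * edf, 1e-8) ** 2
        return {"lam": lam, "beta": beta, "mu": mu, "edf": edf,
                "deviance": dev, "gcv": gcv}

    @staticmethod
    def _pls_solve(B, P, z, w, lam):
        """Solve the penalized weighted LS problem; returns (beta, edf)."""
        Bw = B * w[:, None]
        BtWB = B.T @ Bw
        A = BtWB + lam * P
        try:
            # jitter scaled to the data part only: a jitter proportional to
            # the penalty would bias the unpenalized (linear) directions
            jitter = 1e-12 * (np.trace(BtWB) / A.shape[0] + 1.0)
            cf = cho_factor(A + jitter * np.eye(A.shape[0]))
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                f"penalized design rank-deficient at lambda={lam:g}: {exc}"
            ) from exc
        beta = cho_solve(cf, B.T @ (w * z))
        edf = float(np.trace(cho_solve(cf, BtWB)))
        return beta, edf

    # -- summaries ------------------------------------------------------
    def _null_deviance(self, y):
        ybar = float(np.mean(y))
        if self.family == "gaussian":
            return float(np.sum((y - ybar) ** 2))
        return self._poisson_deviance(y, np.full_like(y, ybar, dtype=float))

    def _finalize(self, y, res):
        n = y.shape[0]
        self.lambda_ = float(res["lam"])
        self.coef_ = res["beta"]
        self.edf_ = float(res["edf"])
        self.fitted_values_ = res["mu"]
        self.residuals_ = y - res["mu"]
        self.deviance_ = float(res["deviance"])
        self.null_deviance_ = self._null_deviance(y)
        self.deviance_explained_ = (
            1.0 - self.deviance_ / self.null_deviance_
            if self.null_deviance_ > 0 else 0.0
        )
        self.n_obs_ = n
        self.p_value_ = self._smooth_p_value()
        return self

    def _finalize_constant(self, y, B):
        n = y.shape[0]
        # representable exactly: constant coefficients (basis sums to 1)
        self.lambda_ = np.inf
        self.coef_ = np.full(self.k, float(y[0]))
        self.edf_ = 1.0
        self.fitted_values_ = np.full(n, float(y[0]))
        self.residuals_ = y - self.fitted_values_
        self.deviance_ = 0.0
        self.null_deviance_ = 0.0
        self.deviance_explained_ = 0.0
        self.n_obs_ = n
        self.p_value_ = 1.0

    def _smooth_p_value(self) -> float:
        """Approximate test of the smooth against the intercept-only model.

        Gaussian: F-type statistic with df1 = edf - 1 and df2 = n - edf.
        Poisson: deviance-difference chi-square with df = edf - 1.
        """
        n, edf = self.n_obs_, self.edf_
        df1 = edf - 1.0
        if df1 <= 1e-8 or self.null_deviance_ <= 0:
            return 1.0
        drop = self.null_deviance_ - self.deviance_
        if self.family == "gaussian":
            df2 = max(n - edf, 1e-8)
            if self.deviance_ <= 0:
                return 0.0
            f_stat = (drop / df1) / (self.deviance_ / df2)
            return float(stats.f.sf(f_stat, df1, df2))
        return float(stats.chi2.sf(drop, df1))

    def predict(self, X):
        x = np.asarray(X, dtype=float).reshape(-1)
        B = _bspline_basis(x, self.x_min_, self.x_max_, self.k)
        eta = B @ self.coef_
        return np.exp(eta) if self.family == "poisson" else eta


def fit_smooth(x, y, family: str = "gaussian", k: int = 10,
               lambda_rule="gcv") -> PenalizedSplineGAM:
    """Fit a penalized-spline smooth of y on x; returns the fitted model."""
    return PenalizedSplineGAM(k=k, family=family, lam=lambda_rule).fit(x, y)


def smooth_significance(fit: PenalizedSplineGAM) -> float:
    """P-value of the smooth term against the intercept-only model."""
    return fit.p_value_


def residuals(fit: PenalizedSplineGAM, kind: str = "response") -> np.ndarray:
    """Residuals of a fitted smooth, aligned to the input order.

    kind="response" (default): y - fitted mean.  kind="working": working
    residuals of the final IRLS step, (y - mu)/mu for the poisson-log
    family (identical to response residuals for gaussian).
    """
    if kind == "response":
        return fit.residuals_
    if kind == "working":
        if fit.family == "poisson":
            return fit.residuals_ / fit.fitted_values_
        return fit.residuals_
    raise ValueError(f"unknown residual kind {kind!r}")
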