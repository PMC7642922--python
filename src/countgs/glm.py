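"""Penalized Poisson regression with an elastic-net penalty.

The model is a log-link Poisson GLM,

    E(y_i | x_i) = mu_i = exp(eta + x_i . beta),

fitted by minimizing the penalized negative log-likelihood (the log y! term
is constant and dropped):

    sum_i [mu_i - y_i log mu_i] + n * lam * [(1 - alpha) * ||beta||_2^2 / 2
                                             + alpha * ||beta||_1],

with the intercept eta unpenalized.  alpha = 0 gives ridge, alpha = 1 lasso,
anything between an elastic net.  Optimization is iteratively reweighted
least squares with a coordinate-descent inner loop (soft-thresholding),
warm-started along a decreasing lambda path; lambda is selected by K-fold
cross-validation on the mean held-out Poisson deviance.

The penalty is scaled by n so a lambda value means the same thing across
sample sizes (the per-observation convention of the usual lasso-path
solvers).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import KFold

_Z_CLIP = 30.0  # linear-predictor clamp; exp(30) ~ 1e13 is already absurd for counts


class DomainError(ValueError):
    """Raised when inputs leave the domain of the Poisson likelihood."""


def poisson_nll(y, mu) -> float:
    """Poisson negative log-likelihood sum_i [mu_i - y_i log mu_i].

    The additive log(y!) term is omitted; the y = 0 terms contribute mu_i.
    """
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if y.shape != mu.shape:
        raise DomainError(f"length mismatch: y {y.shape} vs mu {mu.shape}")
    if np.any(mu <= 0):
        raise DomainError("all rates mu must be strictly positive")
    out = mu - y * np.log(mu)
    return float(np.sum(out))


def poisson_deviance(y, mu) -> float:
    """Mean Poisson deviance 2 * mean[y log(y/mu) - (y - mu)] (0 log 0 := 0)."""
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if np.any(mu <= 0):
        raise DomainError("all rates mu must be strictly positive")
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(y / mu), 0.0)
    return float(2.0 * np.mean(term - (y - mu)))


@dataclass
class GPRConfig:
    """Settings for one penalized Poisson regression fit."""

    alpha: float = 1.0
    lambda_grid: np.ndarray | str = "auto"
    n_lambda: int = 100
    n_inner_folds: int = 10
    max_iter: int = 100
    tol: float = 1e-7

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must lie in [0, 1]; got {self.alpha}")
        if self.n_inner_folds < 2:
            raise ValueError("n_inner_folds must be >= 2")
        if not isinstance(self.lambda_grid, str):
            grid = np.asarray(self.lambda_grid, dtype=float)
            if np.any(grid <= 0):
                raise ValueError("lambda values must be > 0")
            self.lambda_grid = np.sort(grid)[::-1]


def _objective(X, y, eta, beta, alpha, lam):
    z = np.clip(eta + X @ beta, -_Z_CLIP, _Z_CLIP)
    pen = lam * ((1.0 - alpha) * 0.5 * np.dot(beta, beta) + alpha * np.abs(beta).sum())
    return poisson_nll(y, np.exp(z)) + len(y) * pen


try:
    from numba import njit
except ImportError:  # pragma: no cover - numba is a hard dependency
    def njit(*a, **k):
        def deco(f):
            return f
        return deco if not a else a[0]


@njit(cache=False)
def _cd_solve(X, w, u, eta, beta, l1, l2, max_sweeps, tol):  # pragma: no cover - jitted
    """Cyclic coordinate descent with soft-thresholding on the weighted LS
    surrogate; updates ``beta`` in place, returns the new intercept."""
    n, d = X.shape
    r = u - eta
    for j in range(d):
        bj = beta[j]
        if bj != 0.0:
            for i in range(n):
                r[i] -= X[i, j] * bj
    sw = 0.0
    for i in range(n):
        sw += w[i]
    swx2 = np.zeros(d)
    for j in range(d):
        s = 0.0
        for i in range(n):
            s += w[i] * X[i, j] * X[i, j]
        swx2[j] = s
    for _ in range(max_sweeps):
        max_delta = 0.0
        for j in range(d):
            sj = swx2[j]
            if sj <= 0.0:
                continue
            bj = beta[j]
            rho = sj * bj
            for i in range(n):
                rho += w[i] * X[i, j] * r[i]
            if rho > l1:
                new = (rho - l1) / (sj + l2)
            elif rho < -l1:
                new = (rho + l1) / (sj + l2)
            else:
                new = 0.0
            diff = new - bj
            if diff != 0.0:
                for i in range(n):
                    r[i] -= X[i, j] * diff
                beta[j] = new
                if abs(diff) > max_delta:
                    max_delta = abs(diff)
        num = 0.0
        for i in range(n):
            num += w[i] * r[i]
        d_eta = num / sw
        eta += d_eta
        for i in range(n):
            r[i] -= d_eta
        if abs(d_eta) > max_delta:
            max_delta = abs(d_eta)
        if max_delta < tol:
            break
    return eta


def _fit_single(X, y, alpha, lam, eta, beta, max_iter, tol):
    """IRLS with coordinate-descent inner loop; warm-startable.

    For alpha = 0 (pure ridge, no soft-thresholding needed) each IRLS step
    solves the penalized weighted least squares directly.  Step-halving
    keeps the penalized objective monotone non-increasing.
    Returns (eta, beta, n_iter, converged).
    """
    n, d = X.shape
    l1 = n * lam * alpha
    l2 = n * lam * (1.0 - alpha)
    beta = beta.copy()
    obj = _objective(X, y, eta, beta, alpha, lam)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        z = np.clip(eta + X @ beta, -_Z_CLIP, _Z_CLIP)
        mu = np.exp(z)
        w = mu
        u = z + (y - mu) / mu
        if alpha == 0.0 and d > 0:
            # augmented system for [eta; beta] with ridge on beta only
            Xa = np.concatenate([np.ones((n, 1)), X], axis=1)
            A = (Xa * w[:, None]).T @ Xa
            A[1:, 1:] += l2 * np.eye(d)
            b = (Xa * w[:, None]).T @ u
            sol = np.linalg.solve(A, b)
            eta_new, beta_new = float(sol[0]), sol[1:]
        else:
            beta_new = beta.copy()
            eta_new = _cd_solve(X, w, u, eta, beta_new, l1, l2, 100, 1e-8)

        # step-halving: back off toward the current point if the penalized
        # objective rose (IRLS can overshoot for the Poisson log link)
        new_obj = _objective(X, y, eta_new, beta_new, alpha, lam)
        if new_obj > obj + 1e-12:
            e_full, b_full = eta_new, beta_new
            step = 0.5
            while step > 1e-10:
                eta_new = eta + step * (e_full - eta)
                beta_new = beta + step * (b_full - beta)
                new_obj = _objective(X, y, eta_new, beta_new, alpha, lam)
                if new_obj <= obj + 1e-12:
                    break
                step *= 0.5
            else:
                eta_new, beta_new, new_obj = eta, beta, obj
        param_delta = max(
            abs(eta_new - eta),
            float(np.max(np.abs(beta_new - beta))) if d else 0.0,
        )
        if obj - new_obj < tol * (abs(obj) + 1.0) or param_delta < 1e-8:
            eta, beta, obj = eta_new, beta_new, new_obj
            converged = True
            break
        eta, beta, obj = eta_new, beta_new, new_obj
    return eta, beta, it, converged


def lambda_max(X, y, alpha) -> float:
    """Smallest lambda that zeroes every coefficient (alpha > 0); for ridge
    the alpha = 0.001 value is used, mirroring the usual path convention."""
    n = len(y)
    a = max(alpha, 1e-3)
    ybar = y.mean()
    g = np.abs(X.T @ (y - ybar))
    gmax = float(g.max()) if g.size else 0.0
    return max(gmax / (n * a), 1e-10)


def _auto_grid(X, y, alpha, n_lambda):
    lmax = lambda_max(X, y, alpha)
    return np.geomspace(lmax, lmax * 1e-3, n_lambda)


def _fit_path(X, y, alpha, lambdas, max_iter, tol, eta0=None, beta0=None):
    """Fit the full decreasing-lambda path with warm starts.

    Once a fit explains essentially all the null deviance (ratio > 0.999)
    or an extra path step no longer improves it meaningfully (< 1e-4), the
    remaining entries reuse the last fit — the usual lasso-path early stop;
    p > n fits saturate at small lambda and never win the CV anyway.
    """
    n, d = X.shape
    eta = float(np.log(max(y.mean(), 1e-12))) if eta0 is None else eta0
    beta = np.zeros(d) if beta0 is None else beta0.copy()
    dev_null = poisson_deviance(y, np.full(n, max(y.mean(), 1e-12)))
    Xf = np.asfortranarray(X)  # column-contiguous for the CD kernel
    out = []
    stopped = False
    prev_ratio = 0.0
    for lam in lambdas:
        if not stopped:
            eta, beta, it, conv = _fit_single(Xf, y, alpha, lam, eta, beta, max_iter, tol)
            if dev_null > 0:
                mu = np.exp(np.clip(eta + X @ beta, -_Z_CLIP, _Z_CLIP))
                ratio = 1.0 - poisson_deviance(y, mu) / dev_null
                if ratio > 0.999 or (ratio > 0.5 and ratio - prev_ratio < 1e-4):
                    stopped = True
                prev_ratio = ratio
        out.append((eta, beta.copy(), it, conv))
    return out


class PoissonElasticNet:
    """Penalized Poisson regression model for one count trait.

    Parameters
    ----------
    endog : array-like
        Non-negative integer counts, length n.
    exog : array-like or DesignMatrix
        n x d predictor matrix (an intercept is always included and must
        not be in ``exog``).
    config : GPRConfig, optional
        Penalty mixing, lambda grid, inner-CV and convergence settings.
    """

    def __init__(self, endog, exog, config: GPRConfig | None = None):
        from .data import DesignMatrix

        if isinstance(exog, DesignMatrix):
            self.column_labels = list(exog.column_labels)
            exog = exog.X
        else:
            exog = np.asarray(exog, dtype=float)
            self.column_labels = [f"x{j}" for j in range(exog.shape[1])]
        y = np.asarray(endog, dtype=float).ravel()
        if np.any(y < 0) or np.any(y != np.floor(y)):
            raise DomainError("endog must contain non-negative integer counts")
        if exog.ndim != 2 or exog.shape[0] != len(y):
            raise DomainError("exog must be 2-D with one row per observation")
        self.endog = y
        self.exog = np.ascontiguousarray(exog)
        self.config = config or GPRConfig()

    @classmethod
    def from_dataframe(cls, df, response: str, predictors=None, config=None):
        predictors = [c for c in df.columns if c != response] if predictors is None else list(predictors)
        return cls(df[response].to_numpy(), df[predictors].to_numpy(dtype=float), config)

    def fit(self, lam: float | None = None, seed: int = 0) -> "PoissonElasticNetResults":
        """Fit the model; when ``lam`` is None it is selected by inner CV."""
        cfg = self.config
        X, y = self.exog, self.endog
        n, d = X.shape

        if np.all(y == 0):
            # degenerate response: rate floored at 0.5/n keeps the objective finite
            warnings.warn("all-zero response; intercept floored at log(0.5/n)")
            return PoissonElasticNetResults(
                self, eta=float(np.log(0.5 / n)), beta=np.zeros(d),
                lambda_selected=np.nan, cv_curve=None, n_iter=0,
                converged=True, all_zero_floor=True,
            )

        if d == 0:
            return PoissonElasticNetResults(
                self, eta=float(np.log(y.mean())), beta=np.zeros(0),
                lambda_selected=np.nan, cv_curve=None, n_iter=0, converged=True,
            )

        grid = (
            _auto_grid(X, y, cfg.alpha, cfg.n_lambda)
            if isinstance(cfg.lambda_grid, str)
            else cfg.lambda_grid
        )

        cv_curve = None
        if lam is None:
            if len(grid) == 1:
                lam = float(grid[0])
            else:
                lam, cv_curve = self._select_lambda(grid, seed)
        else:
            if not isinstance(cfg.lambda_grid, str) and not np.any(np.isclose(grid, lam)):
                grid = np.sort(np.r_[grid, lam])[::-1]

        path_lams = grid[grid >= lam - 1e-15] if np.any(grid >= lam - 1e-15) else np.array([lam])
        if not np.any(np.isclose(path_lams, lam)):
            path_lams = np.r_[path_lams, lam]
        path = _fit_path(X, y, cfg.alpha, path_lams, cfg.max_iter, cfg.tol)
        eta, beta, n_iter, converged = path[-1]
        if not converged:
            warnings.warn("penalized Poisson fit did not converge; flagging the result")
        return PoissonElasticNetResults(
            self, eta=eta, beta=beta, lambda_selected=float(lam),
            cv_curve=cv_curve, n_iter=n_iter, converged=converged,
        )

    def fit_path(self, lambdas=None):
        """Coefficients along a decreasing lambda path (no CV)."""
        cfg = self.config
        grid = (
            _auto_grid(self.exog, self.endog, cfg.alpha, cfg.n_lambda)
            if lambdas is None
            else np.sort(np.asarray(lambdas, dtype=float))[::-1]
        )
        path = _fit_path(self.exog, self.endog, cfg.alpha, grid, cfg.max_iter, cfg.tol)
        return grid, path

    def _select_lambda(self, grid, seed):
        import pandas as pd

        cfg = self.config
        X, y = self.exog, self.endog
        kf = KFold(n_splits=cfg.n_inner_folds, shuffle=True, random_state=seed)
        dev = np.zeros((cfg.n_inner_folds, len(grid)))
        for f, (tr, te) in enumerate(kf.split(X)):
            if np.all(y[tr] == 0):
                mu0 = 0.5 / len(tr)
                dev[f, :] = poisson_deviance(y[te], np.full(len(te), mu0))
                continue
            path = _fit_path(X[tr], y[tr], cfg.alpha, grid, cfg.max_iter, cfg.tol)
            for k, (eta, beta, _, _) in enumerate(path):
                mu = np.exp(np.clip(eta + X[te] @ beta, -_Z_CLIP, _Z_CLIP))
                dev[f, k] = poisson_deviance(y[te], mu)
        mean_dev = dev.mean(axis=0)
        # ties -> largest lambda; grid is decreasing so the first argmin wins
        best = int(np.argmin(mean_dev))
        curve = pd.DataFrame({"lam": grid, "mean_deviance": mean_dev})
        return float(grid[best]), curve


@dataclass
class PoissonElasticNetResults:
    """Fitted penalized Poisson regression: estimates and diagnostics."""

    model: PoissonElasticNet
    eta: float
    beta: np.ndarray
    lambda_selected: float
    cv_curve: object | None
    n_iter: int
    converged: bool
    all_zero_floor: bool = False

    @property
    def params(self) -> np.ndarray:
        """Intercept followed by the coefficient vector."""
        return np.r_[self.eta, self.beta]

    @property
    def alpha(self) -> float:
        return self.model.config.alpha

    def predict(self, exog=None) -> np.ndarray:
        """Predicted rates exp(eta + X beta); strictly positive."""
        from .data import DesignMatrix

        X = self.model.exog if exog is None else exog
        if isinstance(X, DesignMatrix):
            X = X.X
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != len(self.beta):
            raise DomainError(
                f"exog has {X.shape[1] if X.ndim == 2 else 'bad'} columns; "
                f"fit used {len(self.beta)}"
            )
        return np.exp(self.eta + X @ self.beta)

    def objective(self) -> float:
        lam = 0.0 if np.isnan(self.lambda_selected) else self.lambda_selected
        return _objective(self.model.exog, self.model.endog, self.eta, self.beta,
                          self.alpha, lam)

    def summary(self) -> str:
        nz = int(np.sum(self.beta != 0))
        lines = [
            "Penalized Poisson regression (elastic net)",
            "=" * 44,
            f"n obs            {len(self.model.endog):>10d}",
            f"n predictors     {len(self.beta):>10d}",
            f"alpha (mixing)   {self.alpha:>10.3f}",
            f"lambda           {self.lambda_selected:>10.5g}",
            f"nonzero coefs    {nz:>10d}",
            f"intercept eta    {self.eta:>10.4f}",
            f"converged        {str(self.converged):>10s}",
            f"penalized NLL    {self.objective():>10.4f}",
        ]
        return "\n".join(lines)

    def to_json(self) -> str:
        return json.dumps({
            "eta": self.eta,
            "beta": dict(zip(self.model.column_labels, map(float, self.beta))),
            "alpha": self.alpha,
            "lambda": None if np.isnan(self.lambda_selected) else self.lambda_selected,
            "converged": self.converged,
            "all_zero_floor": self.all_zero_floor,
        })

    def plot_cv_curve(self, ax=None):  # pragma: no cover - thin plotting helper
        import matplotlib.pyplot as plt

        if self.cv_curve is None:
            raise ValueError("no CV curve: lambda was supplied, not selected")
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.cv_curve["lam"], self.cv_curve["mean_deviance"], marker="o", ms=3)
        ax.axvline(self.lambda_selected, ls="--", color="grey")
        ax.set_xscale("log")
        ax.set_xlabel("lambda")
        ax.set_ylabel("mean held-out Poisson deviance")
        return ax


def fit_gpr(X, y, cfg: GPRConfig | None = None, seed: int = 0) -> PoissonElasticNetResults:
    """Functional wrapper: fit a penalized Poisson regression with CV lambda."""
    return PoissonElasticNet(y, X, cfg).fit(seed=seed)


def predict_gpr(fit: PoissonElasticNetResults, X) -> np.ndarray:
    return fit.predict(X)
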