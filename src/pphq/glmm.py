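"""Random-intercept logistic regression by maximum marginal likelihood.

Model: women i nested in maternity units j, binary outcome y_ij with

    logit P(y_ij = 1 | u_j) = x_ij' beta + u_j,      u_j ~ Normal(0, sigma^2)

The marginal likelihood integrates the unit effect out of each cluster's
contribution:

    L(beta, sigma) = prod_j  integral  prod_{i in j} p_ij^y_ij (1-p_ij)^(1-y_ij)
                     phi(u; 0, sigma^2) du

The integral has no closed form; it is approximated by adaptive
Gauss-Hermite quadrature: each cluster's integrand is re-centred at its
posterior mode (found by Newton iteration) and re-scaled by the curvature
there, so a modest number of nodes (default 15) is accurate even for large
clusters.  A Laplace approximation (the one-node special case) is available
as a fallback.  At sigma = 0 the model collapses exactly to ordinary
logistic regression, which is also the starting point of the optimisation.

Confidence intervals are Wald intervals on the log-odds scale from the
numerical Hessian of the marginal log-likelihood, exponentiated into odds
ratios.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy import optimize, special, stats
from statsmodels.tools import numdiff

__all__ = ["FitResult", "RandomInterceptLogit", "fit_random_intercept_logistic"]

_SIGMA_COLLAPSE = 1e-6  # below this the marginal likelihood is exactly logistic
_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


@dataclass
class FitResult:
    """Estimates from one random-intercept logistic fit."""

    coefficients: dict[str, float]
    standard_errors: dict[str, float]
    random_intercept_sd: float
    odds_ratios: dict[str, tuple[float, float, float]]
    log_likelihood: float
    converged: bool
    n_obs: int
    n_clusters: int
    sigma_se: float = float("nan")
    sigma_at_boundary: bool = False
    n_quad: int = 15
    message: str = ""

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for term, beta in self.coefficients.items():
            point, lo, hi = self.odds_ratios[term]
            rows.append(
                {
                    "term": term,
                    "coef": beta,
                    "se": self.standard_errors[term],
                    "OR": point,
                    "ci_low": lo,
                    "ci_high": hi,
                }
            )
        return pd.DataFrame(rows).set_index("term")


class RandomInterceptLogit:
    """Maximum-marginal-likelihood fitter for clustered binary outcomes.

    Parameters
    ----------
    y : (n,) binary outcome.
    X : (n, k) design matrix (include the intercept column explicitly);
        a DataFrame's column names are used as term names.
    groups : (n,) cluster labels (any hashable dtype).
    n_quad : number of adaptive Gauss-Hermite nodes.
    """

    def __init__(self, y, X, groups, n_quad: int = 15):
        if isinstance(X, pd.DataFrame):
            self.exog_names = list(X.columns)
            X = X.to_numpy(dtype=float)
        else:
            X = np.asarray(X, dtype=float)
            self.exog_names = [f"x{i}" for i in range(X.shape[1])]
        y = np.asarray(y, dtype=float).ravel()
        groups = np.asarray(groups)
        if not set(np.unique(y)) <= {0.0, 1.0}:
            raise ValueError("y must be binary 0/1")
        if len(y) != len(X) or len(y) != len(groups):
            raise ValueError("y, X and groups must have equal length")
        order = np.argsort(groups, kind="stable")
        self.y = y[order]
        self.X = X[order]
        g = groups[order]
        change = np.nonzero(np.r_[True, g[1:] != g[:-1]])[0]
        self._starts = change
        self.cluster_labels = g[change]
        self.n_clusters = len(change)
        self.n_obs = len(y)
        self.n_quad = int(n_quad)
        self._z, self._w = hermgauss(self.n_quad)
        self._logw = np.log(self._w)
        self._gidx = np.repeat(np.arange(self.n_clusters), np.diff(np.r_[change, len(y)]))
        self._u_cache = np.zeros(self.n_clusters)

    # ------------------------------------------------------------------
    def _cluster_sums(self, values: np.ndarray) -> np.ndarray:
        """Sum a per-observation array within clusters (last axis)."""
        return np.add.reduceat(values, self._starts, axis=-1)

    def _posterior_modes(self, eta: np.ndarray, sigma: float):
        """Newton iteration for the per-cluster mode of the log-integrand."""
        inv_s2 = 1.0 / (sigma * sigma)
        u = self._u_cache.copy()
        for _ in range(100):
            p = special.expit(eta + u[self._gidx])
            grad = self._cluster_sums(self.y - p) - u * inv_s2
            hess = -(self._cluster_sums(p * (1.0 - p)) + inv_s2)
            step = grad / hess
            u = u - step
            if np.max(np.abs(step)) < 1e-10:
                break
        p = special.expit(eta + u[self._gidx])
        hess = -(self._cluster_sums(p * (1.0 - p)) + inv_s2)
        self._u_cache = u
        return u, hess

    def _log_integrand(self, eta: np.ndarray, u_per_cluster: np.ndarray, sigma: float):
        """log f_j(u) summed within clusters, for (K, J) node matrix."""
        theta = eta[None, :] + u_per_cluster[:, self._gidx]
        ll = self.y[None, :] * theta - np.logaddexp(0.0, theta)
        cluster_ll = self._cluster_sums(ll)
        prior = (
            -0.5 * (u_per_cluster / sigma) ** 2 - np.log(sigma) - _LOG_SQRT_2PI
        )
        return cluster_ll + prior

    def loglik(self, beta: np.ndarray, sigma: float) -> float:
        """Marginal log-likelihood at (beta, sigma)."""
        beta = np.asarray(beta, dtype=float)
        eta = self.X @ beta
        if sigma < _SIGMA_COLLAPSE:
            return float(np.sum(self.y * eta - np.logaddexp(0.0, eta)))
        u_hat, hess = self._posterior_modes(eta, sigma)
        tau = 1.0 / np.sqrt(-hess)
        nodes = u_hat[None, :] + np.sqrt(2.0) * tau[None, :] * self._z[:, None]
        logf = self._log_integrand(eta, nodes, sigma)
        # integral_j ~ sqrt(2) tau_j sum_k w_k exp(z_k^2) f_j(node_jk)
        log_terms = self._logw[:, None] + self._z[:, None] ** 2 + logf
        log_int = 0.5 * np.log(2.0) + np.log(tau) + special.logsumexp(log_terms, axis=0)
        return float(np.sum(log_int))

    def loglik_laplace(self, beta: np.ndarray, sigma: float) -> float:
        """Laplace approximation to the marginal log-likelihood."""
        beta = np.asarray(beta, dtype=float)
        eta = self.X @ beta
        if sigma < _SIGMA_COLLAPSE:
            return float(np.sum(self.y * eta - np.logaddexp(0.0, eta)))
        u_hat, hess = self._posterior_modes(eta, sigma)
        logf = self._log_integrand(eta, u_hat[None, :], sigma)[0]
        return float(np.sum(logf + 0.5 * np.log(2.0 * np.pi) - 0.5 * np.log(-hess)))

    # ------------------------------------------------------------------
    def fit(
        self,
        start_beta: np.ndarray | None = None,
        start_sigma: float = 0.5,
        method: str = "agq",
        gtol: float = 1e-5,
        maxiter: int = 200,
        fix_sigma: float | None = None,
    ) -> FitResult:
        """Maximise the marginal likelihood; Wald CIs from the numerical Hessian."""
        k = self.X.shape[1]
        if start_beta is None:
            start_beta = self._logit_start()
        objective = self.loglik if method == "agq" else self.loglik_laplace

        def negll(params):
            return -objective(params[:-1], params[-1])

        if fix_sigma is not None:
            start_sigma = fix_sigma
        x0 = np.r_[start_beta, start_sigma]
        sigma_bounds = (0.0, 10.0) if fix_sigma is None else (fix_sigma, fix_sigma)
        bounds = [(None, None)] * k + [sigma_bounds]
        self._u_cache = np.zeros(self.n_clusters)
        res = optimize.minimize(
            negll,
            x0,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": maxiter, "ftol": 1e-11, "gtol": gtol},
        )
        beta_hat = res.x[:-1]
        sigma_hat = float(res.x[-1])
        at_boundary = sigma_hat < 1e-4
        # observed information; drop the sigma row at the boundary, where the
        # Hessian of the profile in sigma is one-sided and unusable for Wald.
        if at_boundary:
            hess = numdiff.approx_hess(beta_hat, lambda b: -objective(b, sigma_hat))
            cov = _safe_inv(hess)
            se = np.sqrt(np.diag(cov))
            sigma_se = float("nan")
        else:
            hess = numdiff.approx_hess(res.x, negll)
            cov = _safe_inv(hess)
            diag = np.diag(cov).copy()
            diag[diag < 0] = np.nan
            se_all = np.sqrt(diag)
            se = se_all[:-1]
            sigma_se = float(se_all[-1])
        zcrit = stats.norm.ppf(0.975)
        coefs = dict(zip(self.exog_names, beta_hat))
        ses = dict(zip(self.exog_names, se))
        with np.errstate(over="ignore"):  # an unbounded CI limit is inf, not an error
            ors = {
                name: (
                    float(np.exp(b)),
                    float(np.exp(b - zcrit * s)),
                    float(np.exp(b + zcrit * s)),
                )
                for (name, b), s in zip(coefs.items(), se)
            }
        return FitResult(
            coefficients={k_: float(v) for k_, v in coefs.items()},
            standard_errors={k_: float(v) for k_, v in ses.items()},
            random_intercept_sd=sigma_hat,
            odds_ratios=ors,
            log_likelihood=-float(res.fun),
            converged=bool(res.success),
            n_obs=self.n_obs,
            n_clusters=self.n_clusters,
            sigma_se=sigma_se,
            sigma_at_boundary=at_boundary,
            n_quad=self.n_quad,
            message=str(res.message),
        )

    def _logit_start(self) -> np.ndarray:
        """Plain-logistic warm start (falls back to zeros if separated)."""
        import statsmodels.api as sm

        try:
            with np.errstate(all="ignore"):
                fit = sm.Logit(self.y, self.X).fit(disp=0, maxiter=100)
            beta = np.asarray(fit.params, dtype=float)
            if np.all(np.isfinite(beta)) and np.max(np.abs(beta)) < 15:
                return beta
        except Exception:
            pass
        return np.zeros(self.X.shape[1])


def _safe_inv(hess: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        return np.linalg.pinv(hess)


def fit_random_intercept_logistic(
    y,
    X,
    cluster_ids,
    n_quad: int = 15,
    method: str = "agq",
    **fit_kwargs,
) -> FitResult:
    """Convenience wrapper: build the model and fit in one call."""
    return RandomInterceptLogit(y, X, cluster_ids, n_quad=n_quad).fit(
        method=method, **fit_kwargs
    )
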