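"""Panel mixed logit estimation by maximum simulated likelihood.

The estimator follows scikit-learn conventions: hyperparameters in the
constructor, data in :meth:`MixedLogit.fit`, fitted quantities in trailing-
underscore attributes.  Estimation maximizes the simulated log-likelihood
over (means, SDs, left constant) by quasi-Newton ascent with analytic
gradients, starting from a plain conditional-logit fit of the means.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator

from .dataset import ChoiceDataset, PanelArrays
from .likelihood import _panel_mixture_stats, halton_normal_draws
from .params import MXLParams

__all__ = ["FitResult", "MixedLogit", "fit_mxl"]

SD_START = 0.1  # initial value for every coefficient SD in the MSL stage


class EstimabilityError(ValueError):
    """Raised when the design matrix cannot identify every coefficient."""


@dataclass
class FitResult:
    """Estimates and diagnostics of a maximum (simulated) likelihood fit.

    ``table`` has one row per parameter with columns estimate, se, ci_low,
    ci_high and p (Wald intervals, estimate +/- 1.96 se).  ``n_obs`` counts
    choice observations (respondents x tasks), the sample-size convention
    used in the BIC penalty.
    """

    table: pd.DataFrame
    loglik: float
    n_params: int
    n_obs: int
    n_respondents: int
    aic: float
    bic: float
    n_draws: int
    seed: int
    converged: bool
    grad_norm: float
    n_iter: int
    message: str = ""
    extra: dict = field(default_factory=dict)


def _information_criteria(loglik: float, p: int, n_obs: int) -> tuple[float, float]:
    return 2 * p - 2 * loglik, p * np.log(n_obs) - 2 * loglik


def _wald_table(names, est, se) -> pd.DataFrame:
    se = np.asarray(se, dtype=float)
    zval = np.divide(est, se, out=np.full_like(se, np.nan), where=se > 0)
    return pd.DataFrame(
        {
            "estimate": est,
            "se": se,
            "ci_low": est - 1.96 * se,
            "ci_high": est + 1.96 * se,
            "p": 2 * stats.norm.sf(np.abs(zval)),
        },
        index=pd.Index(names, name="parameter"),
    )


def _check_estimable(panel: PanelArrays) -> None:
    N, T, A, K = panel.X.shape
    flat = panel.X[panel.mask].reshape(-1, K)
    rank = np.linalg.matrix_rank(flat)
    if rank < K:
        zero_cols = [
            panel.feature_names[j] for j in range(K) if np.allclose(flat[:, j], 0)
        ]
        detail = (
            f"never-observed levels: {zero_cols}"
            if zero_cols
            else "collinear columns (no level is entirely absent)"
        )
        raise EstimabilityError(
            f"design matrix is rank deficient (rank {rank} < {K}); {detail}"
        )


class MixedLogit(BaseEstimator):
    """Panel mixed logit with independent normal random coefficients.

    Every attribute-level dummy and the opt-out constant receive a normally
    distributed random coefficient; the left-position constant is fixed.
    Estimation is by maximum simulated likelihood over scrambled-Halton
    draws, one block of draws per respondent.

    Parameters
    ----------
    n_draws : int
        Quasi-random draws per respondent for the mixing integral.
    seed : int
        Seed for draw scrambling; fits are deterministic given data and seed.
    fix_sds : bool
        Fix every SD at zero, collapsing the model to a plain conditional
        logit estimated through the same code path.
    compute_se : bool
        Compute standard errors from the numerical Hessian of the simulated
        log-likelihood (finite differences of the analytic gradient).
    se_method : {"hessian", "sandwich"}
        Plain inverse-Hessian or robust sandwich standard errors.
    include_validity : bool
        Keep internal-validity task rows in the estimation sample.
    """

    def __init__(
        self,
        n_draws: int = 500,
        seed: int = 0,
        fix_sds: bool = False,
        compute_se: bool = True,
        se_method: str = "hessian",
        include_validity: bool = False,
        maxiter: int = 1000,
        gtol: float = 1e-5,
        ftol: float = 1e-11,
        max_restarts: int = 5,
        restart_tol: float = 1e-3,
        start: MXLParams | None = None,
    ):
        self.n_draws = n_draws
        self.seed = seed
        self.fix_sds = fix_sds
        self.compute_se = compute_se
        self.se_method = se_method
        self.include_validity = include_validity
        self.maxiter = maxiter
        self.gtol = gtol
        self.ftol = ftol
        self.max_restarts = max_restarts
        self.restart_tol = restart_tol
        self.start = start

    # -- internals ----------------------------------------------------------

    @staticmethod
    def _as_panel(X, include_validity: bool) -> PanelArrays:
        if isinstance(X, PanelArrays):
            return X
        if isinstance(X, ChoiceDataset):
            ds = X if include_validity else X.drop_validity_tasks()
            return ds.to_panel()
        raise TypeError("X must be a ChoiceDataset or PanelArrays")

    def _objective(self, panel, z, fix_sds):
        K = panel.n_random

        def fun(theta):
            if fix_sds:
                mu, s, delta = theta[:K], np.zeros(K), theta[K]
            else:
                mu, s, delta = theta[:K], theta[K : 2 * K], theta[2 * K]
            a, G = _panel_mixture_stats(mu, s, delta, panel, z, want_grad=True)
            g = G.sum(axis=0)
            if fix_sds:
                g = np.concatenate([g[:K], g[2 * K :]])
            return -a.sum(), -g

        return fun

    def _minimize(self, fun, x0, bounds=None):
        # L-BFGS can report convergence on a plateau while a restart (which
        # resets its curvature memory) still finds substantial improvement;
        # restart until the objective stops moving.
        res = None
        x = x0
        total_iter = 0
        for _ in range(1 + self.max_restarts):
            prev = res.fun if res is not None else np.inf
            res = optimize.minimize(
                fun,
                x,
                jac=True,
                method="L-BFGS-B",
                bounds=bounds,
                options={
                    "maxiter": self.maxiter,
                    "gtol": self.gtol,
                    "ftol": self.ftol,
                    "maxcor": 25,
                },
            )
            total_iter += res.nit
            x = res.x
            if prev - res.fun < self.restart_tol:
                break
        res.nit = total_iter
        return res

    def _mnl_start(self, panel: PanelArrays) -> np.ndarray:
        """Conditional-logit estimates of means and left constant."""
        K = panel.n_random
        z1 = np.zeros((panel.n_respondents, 1, K))
        res = self._minimize(self._objective(panel, z1, True), np.zeros(K + 1))
        return res.x

    # -- estimator API ------------------------------------------------------

    def fit(self, X, y=None):
        """Fit the model to a :class:`ChoiceDataset` (or prebuilt panel)."""
        panel = self._as_panel(X, self.include_validity)
        _check_estimable(panel)
        K = panel.n_random
        N = panel.n_respondents

        mnl = self._mnl_start(panel)
        if self.fix_sds:
            z = np.zeros((N, 1, K))
            x0 = mnl if self.start is None else self._theta_from(self.start, True)
        else:
            z = halton_normal_draws(self.n_draws, K, seed=self.seed, n_units=N)
            if self.start is None:
                x0 = np.concatenate([mnl[:K], np.full(K, SD_START), mnl[K:]])
            else:
                x0 = self._theta_from(self.start, False)

        fun = self._objective(panel, z, self.fix_sds)
        if self.fix_sds:
            bounds = None
        else:
            # SDs are identified up to sign only; constraining them to be
            # nonnegative keeps the reported parameters exactly at the
            # optimum found (an unconstrained fit followed by |s| would not
            # reproduce the fitted likelihood under the same draws)
            bounds = (
                [(None, None)] * K + [(0.0, None)] * K + [(None, None)]
            )
        res = self._minimize(fun, x0, bounds=bounds)
        theta = res.x
        if self.fix_sds:
            mu, s, delta = theta[:K], np.zeros(K), float(theta[K])
        else:
            mu, s, delta = theta[:K], theta[K : 2 * K].copy(), float(theta[2 * K])

        names = panel.feature_names[:K]
        self.params_ = MXLParams(coef_names=list(names), means=mu, sds=s, left=delta)
        self.panel_ = panel
        self.draws_ = z
        self.loglik_ = -float(res.fun)
        self.n_iter_ = int(res.nit)
        self.converged_ = bool(res.success)
        grad_norm = float(np.max(np.abs(res.jac)))

        p = theta.size
        n_obs = panel.n_choices
        aic, bic = _information_criteria(self.loglik_, p, n_obs)
        par_names = [f"mean:{n}" for n in names]
        if not self.fix_sds:
            par_names += [f"sd:{n}" for n in names]
        par_names += ["left"]
        est = np.concatenate([mu, s, [delta]]) if not self.fix_sds else np.concatenate([mu, [delta]])

        if self.compute_se:
            se = self._standard_errors(fun, theta, panel, z)
        else:
            se = np.full(p, np.nan)
        self.result_ = FitResult(
            table=_wald_table(par_names, est, se),
            loglik=self.loglik_,
            n_params=p,
            n_obs=n_obs,
            n_respondents=N,
            aic=aic,
            bic=bic,
            n_draws=1 if self.fix_sds else self.n_draws,
            seed=self.seed,
            converged=self.converged_,
            grad_norm=grad_norm,
            n_iter=self.n_iter_,
            message=str(res.message),
        )
        return self

    def _theta_from(self, params: MXLParams, fix_sds: bool) -> np.ndarray:
        if fix_sds:
            return np.concatenate([params.means, [params.left]])
        return np.concatenate([params.means, params.sds, [params.left]])

    def _standard_errors(self, fun, theta, panel, z) -> np.ndarray:
        H = _numerical_hessian(lambda t: fun(t)[1], theta)
        try:
            cov = np.linalg.inv(H)  # H is the Hessian of the *negative* loglik
        except np.linalg.LinAlgError:
            return np.full(theta.size, np.nan)
        if self.se_method == "sandwich":
            K = panel.n_random
            if self.fix_sds:
                mu, s, delta = theta[:K], np.zeros(K), theta[K]
            else:
                mu, s, delta = theta[:K], theta[K : 2 * K], theta[2 * K]
            _, G = _panel_mixture_stats(mu, s, delta, panel, z, want_grad=True)
            if self.fix_sds:
                G = np.concatenate([G[:, :K], G[:, 2 * K :]], axis=1)
            B = G.T @ G
            cov = cov @ B @ cov
        var = np.diag(cov).copy()
        var[var < 0] = np.nan
        return np.sqrt(var)

    def score(self, X, y=None) -> float:
        """Average simulated log-likelihood per choice observation."""
        from .likelihood import simulated_loglik

        panel = self._as_panel(X, self.include_validity)
        z = halton_normal_draws(
            self.n_draws, panel.n_random, seed=self.seed, n_units=panel.n_respondents
        )
        return simulated_loglik(self.params_, panel, z) / panel.n_choices

    def predict_proba(self, X) -> np.ndarray:
        """Mean choice probabilities (over the mixing distribution) per task.

        Returns an (N, T, 3) array aligned with the panel encoding.
        """
        panel = self._as_panel(X, self.include_validity)
        params = self.params_
        z = halton_normal_draws(
            self.n_draws, panel.n_random, seed=self.seed, n_units=panel.n_respondents
        )
        return mean_choice_probabilities(params, panel, z)


def mean_choice_probabilities(
    params: MXLParams, panel: PanelArrays, z: np.ndarray
) -> np.ndarray:
    """Choice probabilities averaged over coefficient draws, (N, T, A)."""
    from .likelihood import mnl_probabilities

    X = panel.X
    K = panel.n_random
    out = np.zeros(X.shape[:3])
    for i0 in range(0, X.shape[0], 256):
        i1 = min(i0 + 256, X.shape[0])
        beta = params.means[None, None, :] + params.sds[None, None, :] * z[i0:i1]
        V = np.einsum("ntak,nrk->nrta", X[i0:i1, ..., :K], beta, optimize=True)
        V += (params.left * X[i0:i1, ..., K])[:, None, :, :]
        out[i0:i1] = mnl_probabilities(V).mean(axis=1)
    return out


def _numerical_hessian(grad_fn, theta: np.ndarray, h: float = 1e-5) -> np.ndarray:
    """Central finite differences of an analytic gradient."""
    p = theta.size
    H = np.empty((p, p))
    for j in range(p):
        step = h * max(1.0, abs(theta[j]))
        tp, tm = theta.copy(), theta.copy()
        tp[j] += step
        tm[j] -= step
        H[:, j] = (grad_fn(tp) - grad_fn(tm)) / (2 * step)
    return 0.5 * (H + H.T)


def fit_mxl(
    dataset,
    n_draws: int = 500,
    seed: int = 0,
    **kwargs,
) -> tuple[FitResult, MXLParams]:
    """Convenience wrapper: fit a :class:`MixedLogit` and return its results."""
    est = MixedLogit(n_draws=n_draws, seed=seed, **kwargs).fit(dataset)
    return est.result_, est.params_
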