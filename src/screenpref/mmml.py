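"""Latent-class panel mixed logit (mixed-mixed multinomial logit).

A finite mixture of panel mixed logits: each latent class has its own
normally distributed random coefficients, and a multinomial-logit membership
model maps respondent covariates to prior class probabilities (class 1 is
the reference).  Estimation is by direct maximum simulated likelihood with
multiple random starts; classes are labelled post hoc by their opt-out
constant — the class most averse to opting out is the "strong supporters"
of screening and is reported first.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from ._rng import substream, substream_seed
from .dataset import ChoiceDataset, PanelArrays
from .likelihood import _panel_mixture_stats, class_prior_probs, halton_normal_draws
from .mxl import (
    FitResult,
    MixedLogit,
    _check_estimable,
    _information_criteria,
    _numerical_hessian,
    _wald_table,
)
from .params import MMMLParams, MXLParams

from sklearn.base import BaseEstimator

__all__ = [
    "PosteriorMembership",
    "LatentClassMixedLogit",
    "fit_mmml",
    "posterior_class_probs",
    "select_n_classes",
]

STRONG_LABEL = "strong_supporters"
WEAK_LABEL = "weak_supporters"


@dataclass
class PosteriorMembership:
    """Per-respondent posterior class probabilities and derived shares."""

    probabilities: np.ndarray  # (N, C)
    modal_class: np.ndarray  # (N,)
    shares_posterior: np.ndarray  # (C,) mean posterior probability
    shares_modal: np.ndarray  # (C,) modal-assignment proportions
    counts_modal: np.ndarray  # (C,) integer respondent counts
    class_labels: list[str]


def _theta_pack(params: MMMLParams) -> np.ndarray:
    parts = []
    for cls in params.classes:
        parts += [cls.means, cls.sds, [cls.left]]
    parts.append(params.gamma.ravel())
    return np.concatenate(parts)


def _theta_unpack(theta, C, K, P, coef_names, membership_names) -> MMMLParams:
    per = 2 * K + 1
    classes = []
    for c in range(C):
        seg = theta[c * per : (c + 1) * per]
        classes.append(
            MXLParams(
                coef_names=list(coef_names),
                means=seg[:K].copy(),
                sds=np.abs(seg[K : 2 * K]),
                left=float(seg[2 * K]),
            )
        )
    gamma = theta[C * per :].reshape(C - 1, P)
    return MMMLParams(
        classes=classes, gamma=gamma.copy(), membership_names=list(membership_names)
    )


class LatentClassMixedLogit(BaseEstimator):
    """C-class mixture of panel mixed logits with a membership model.

    Parameters
    ----------
    n_classes : int
        Number of latent classes (>= 2).
    n_draws : int
        Quasi-random draws per respondent and class.
    n_starts : int
        Random restarts; each start is run for ``start_iters`` iterations,
        the best is then polished to convergence (latent-class likelihoods
        are multimodal).
    min_share : float
        Prior class shares below this flag the solution as degenerate.
    """

    def __init__(
        self,
        n_classes: int = 2,
        n_draws: int = 100,
        seed: int = 0,
        n_starts: int = 10,
        start_iters: int = 40,
        compute_se: bool = True,
        maxiter: int = 1000,
        gtol: float = 1e-5,
        min_share: float = 0.01,
        start: MMMLParams | None = None,
    ):
        self.n_classes = n_classes
        self.n_draws = n_draws
        self.seed = seed
        self.n_starts = n_starts
        self.start_iters = start_iters
        self.compute_se = compute_se
        self.maxiter = maxiter
        self.gtol = gtol
        self.min_share = min_share
        self.start = start

    # -- likelihood ---------------------------------------------------------

    def _objective(self, panel, Z, draws):
        C, K = self.n_classes, panel.n_random
        P = Z.shape[1]
        per = 2 * K + 1
        N = panel.n_respondents

        def fun(theta):
            A = np.empty((N, C))
            Gc = []
            for c in range(C):
                seg = theta[c * per : (c + 1) * per]
                a, G = _panel_mixture_stats(
                    seg[:K], seg[K : 2 * K], seg[2 * K], panel, draws[c], True
                )
                A[:, c] = a
                Gc.append(G)
            gamma = theta[C * per :].reshape(C - 1, P)
            eta = np.column_stack([np.zeros(N), Z @ gamma.T])
            logpi = eta - logsumexp(eta, axis=1, keepdims=True)
            M = logpi + A
            ll_i = logsumexp(M, axis=1)
            w = np.exp(M - ll_i[:, None])  # posterior class probabilities
            grad = np.empty_like(theta)
            for c in range(C):
                grad[c * per : (c + 1) * per] = w[:, c] @ Gc[c]
            pi = np.exp(logpi)
            dgamma = (w - pi)[:, 1:].T @ Z  # (C-1, P)
            grad[C * per :] = dgamma.ravel()
            return -ll_i.sum(), -grad

        return fun

    def _starts(self, panel: PanelArrays, Z: np.ndarray) -> list[np.ndarray]:
        """Random perturbations of a conditional-logit baseline."""
        C, K = self.n_classes, panel.n_random
        P = Z.shape[1]
        mnl = MixedLogit(fix_sds=True, compute_se=False, include_validity=True)
        mnl_theta = mnl._mnl_start(panel)
        mu0, delta0 = mnl_theta[:K], mnl_theta[K]
        optout_ix = panel.feature_names.index("optout")
        rng = substream(self.seed, "starts")
        starts = []
        for _ in range(self.n_starts):
            theta = []
            spread = rng.uniform(0.5, 2.5)  # class separation on the opt-out ASC
            offsets = np.linspace(-spread, spread, C)
            for c in range(C):
                mu_c = mu0 * rng.uniform(0.7, 1.3, size=K) + rng.normal(0, 0.15, K)
                mu_c[optout_ix] = mu0[optout_ix] + offsets[c] * max(
                    1.0, abs(mu0[optout_ix])
                )
                s_c = np.full(K, 0.1)
                theta += [mu_c, s_c, [delta0 + rng.normal(0, 0.05)]]
            gamma = rng.normal(0, 0.05, size=(C - 1) * P)
            starts.append(np.concatenate(theta + [gamma]))
        return starts

    # -- estimator API ------------------------------------------------------

    def fit(self, X, y=None):
        """Fit to a :class:`ChoiceDataset` carrying a covariate table."""
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if not isinstance(X, ChoiceDataset):
            raise TypeError("X must be a ChoiceDataset with covariates")
        ds = X.drop_validity_tasks()
        panel = ds.to_panel()
        _check_estimable(panel)
        Z, z_names = ds.covariate_matrix()
        if np.isnan(Z).any():
            raise ValueError(
                "covariate table has missing values; apply the sample filters first"
            )
        C, K = self.n_classes, panel.n_random
        N = panel.n_respondents
        draws = [
            halton_normal_draws(
                self.n_draws, K, seed=substream_seed(self.seed, f"class{c}"), n_units=N
            )
            for c in range(C)
        ]
        fun = self._objective(panel, Z, draws)

        from scipy import optimize

        # SDs are sign-identified only: box-constrain them at zero so the
        # reported parameters sit exactly at the optimum under these draws
        P = Z.shape[1]
        bounds = (
            ([(None, None)] * K + [(0.0, None)] * K + [(None, None)]) * C
            + [(None, None)] * ((C - 1) * P)
        )
        if self.start is not None:
            starts = [_theta_pack(self.start)]
        else:
            starts = self._starts(panel, Z)
        short = []
        for x0 in starts:
            r = optimize.minimize(
                fun,
                x0,
                jac=True,
                method="L-BFGS-B",
                bounds=bounds,
                options={"maxiter": self.start_iters, "gtol": self.gtol, "maxcor": 25},
            )
            short.append(r)
        best = min(short, key=lambda r: r.fun)
        # polish with L-BFGS restarts: restarting resets the curvature
        # memory and escapes plateaus these likelihoods are prone to
        res, x, total_iter = None, best.x, 0
        for _ in range(6):
            prev = res.fun if res is not None else best.fun
            res = optimize.minimize(
                fun,
                x,
                jac=True,
                method="L-BFGS-B",
                bounds=bounds,
                options={"maxiter": self.maxiter, "gtol": self.gtol, "maxcor": 25},
            )
            total_iter += res.nit
            x = res.x
            if prev - res.fun < 1e-3:
                break
        res.nit = total_iter
        P = Z.shape[1]
        params = _theta_unpack(
            res.x, C, K, P, panel.feature_names[:K], z_names[1:]
        )
        params, order = _relabel_by_optout(params)
        theta = _theta_pack(params)

        self.params_ = params
        self.panel_ = panel
        self.Z_ = Z
        self.draws_ = [draws[c] for c in order]
        self.loglik_ = -float(res.fun)
        self.converged_ = bool(res.success)
        self.n_iter_ = int(res.nit)
        self.posterior_ = posterior_class_probs(params, panel, Z, self.draws_)
        self.degenerate_ = bool(
            (class_prior_probs(params.gamma, Z).mean(axis=0) < self.min_share).any()
        )

        p = theta.size
        n_obs = panel.n_choices
        aic, bic = _information_criteria(self.loglik_, p, n_obs)
        names = []
        labels = params.class_labels or [f"class{c + 1}" for c in range(C)]
        for c, lab in enumerate(labels):
            names += [f"{lab}:mean:{n}" for n in params.classes[c].coef_names]
            names += [f"{lab}:sd:{n}" for n in params.classes[c].coef_names]
            names += [f"{lab}:left"]
        for c in range(1, C):
            names += [f"membership:{labels[c]}:{n}" for n in z_names]
        if self.compute_se:
            se = self._standard_errors(fun, theta)
        else:
            se = np.full(p, np.nan)
        self.result_ = FitResult(
            table=_wald_table(names, theta.copy(), se),
            loglik=self.loglik_,
            n_params=p,
            n_obs=n_obs,
            n_respondents=N,
            aic=aic,
            bic=bic,
            n_draws=self.n_draws,
            seed=self.seed,
            converged=self.converged_,
            grad_norm=float(np.max(np.abs(res.jac))),
            n_iter=self.n_iter_,
            message=str(res.message),
            extra={
                "degenerate": self.degenerate_,
                "shares_modal": self.posterior_.shares_modal.tolist(),
                "shares_posterior": self.posterior_.shares_posterior.tolist(),
                "n_starts": len(starts),
            },
        )
        return self

    def _standard_errors(self, fun, theta):
        H = _numerical_hessian(lambda t: fun(t)[1], theta)
        try:
            cov = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            return np.full(theta.size, np.nan)
        var = np.diag(cov).copy()
        var[var < 0] = np.nan
        return np.sqrt(var)


def _relabel_by_optout(params: MMMLParams) -> tuple[MMMLParams, list[int]]:
    """Order classes by opt-out constant: most negative (strong) first.

    Reordering the classes requires re-referencing the membership logit so
    the new class 1 is the reference.
    """
    optout = [cls.means[cls.index("optout")] for cls in params.classes]
    order = list(np.argsort(optout))  # ascending: most screening-keen first
    C = params.n_classes
    P = params.gamma.shape[1]
    eta = np.vstack([np.zeros(P), params.gamma])  # full membership coefficients
    eta = eta[order]
    gamma = eta[1:] - eta[0]
    labels = (
        [STRONG_LABEL, WEAK_LABEL]
        if C == 2
        else [STRONG_LABEL] + [f"class{c + 1}" for c in range(1, C)]
    )
    out = MMMLParams(
        classes=[params.classes[c] for c in order],
        gamma=gamma,
        membership_names=list(params.membership_names),
        class_labels=labels,
    )
    return out, order


def posterior_class_probs(
    params: MMMLParams,
    panel: PanelArrays,
    Z: np.ndarray,
    draws: list[np.ndarray] | np.ndarray,
) -> PosteriorMembership:
    """Bayes-rule class membership given each respondent's choices.

    Posterior ∝ prior x simulated within-class panel likelihood; shares are
    reported both as mean posterior probabilities and as modal-assignment
    proportions (with integer counts).
    """
    C = params.n_classes
    if isinstance(draws, np.ndarray):
        draws = [draws] * C
    N = panel.n_respondents
    A = np.empty((N, C))
    for c, cls in enumerate(params.classes):
        a, _ = _panel_mixture_stats(
            cls.means, cls.sds, cls.left, panel, draws[c], want_grad=False
        )
        A[:, c] = a
    with np.errstate(divide="ignore"):
        M = np.log(class_prior_probs(params.gamma, Z)) + A
    probs = np.exp(M - logsumexp(M, axis=1, keepdims=True))
    modal = probs.argmax(axis=1)
    counts = np.bincount(modal, minlength=C)
    labels = params.class_labels or [f"class{c + 1}" for c in range(C)]
    return PosteriorMembership(
        probabilities=probs,
        modal_class=modal,
        shares_posterior=probs.mean(axis=0),
        shares_modal=counts / N,
        counts_modal=counts,
        class_labels=list(labels),
    )


def fit_mmml(
    dataset: ChoiceDataset,
    n_classes: int = 2,
    n_draws: int = 100,
    seed: int = 0,
    n_starts: int = 10,
    **kwargs,
) -> tuple[FitResult, MMMLParams, PosteriorMembership]:
    """Fit a :class:`LatentClassMixedLogit`; returns (result, params, posterior)."""
    est = LatentClassMixedLogit(
        n_classes=n_classes,
        n_draws=n_draws,
        seed=seed,
        n_starts=n_starts,
        **kwargs,
    ).fit(dataset)
    return est.result_, est.params_, est.posterior_


def select_n_classes(
    dataset: ChoiceDataset,
    candidate_C=(2, 3),
    n_draws: int = 100,
    seed: int = 0,
    n_starts: int = 5,
    include_mxl_baseline: bool = True,
    **kwargs,
) -> tuple[int, pd.DataFrame]:
    """Choose the number of classes by BIC over candidate class counts.

    The single-population mixed logit serves as the C=1 baseline.  Returns
    the BIC-minimizing C and a criterion table (one row per candidate; a
    failed fit is recorded with NaN criteria and excluded from selection).
    """
    rows = []
    if include_mxl_baseline:
        try:
            est = MixedLogit(n_draws=n_draws, seed=seed, compute_se=False).fit(dataset)
            r = est.result_
            rows.append(
                {"n_classes": 1, "loglik": r.loglik, "n_params": r.n_params,
                 "aic": r.aic, "bic": r.bic, "converged": r.converged, "error": ""}
            )
        except Exception as e:  # pragma: no cover - defensive
            rows.append(
                {"n_classes": 1, "loglik": np.nan, "n_params": np.nan,
                 "aic": np.nan, "bic": np.nan, "converged": False, "error": str(e)}
            )
    for C in candidate_C:
        try:
            r, _, _ = fit_mmml(
                dataset, n_classes=C, n_draws=n_draws, seed=seed,
                n_starts=n_starts, compute_se=False, **kwargs
            )
            rows.append(
                {"n_classes": C, "loglik": r.loglik, "n_params": r.n_params,
                 "aic": r.aic, "bic": r.bic, "converged": r.converged, "error": ""}
            )
        except Exception as e:
            rows.append(
                {"n_classes": C, "loglik": np.nan, "n_params": np.nan,
                 "aic": np.nan, "bic": np.nan, "converged": False, "error": str(e)}
            )
    table = pd.DataFrame(rows)
    valid = table.dropna(subset=["bic"])
    if valid.empty:
        raise RuntimeError("every candidate fit failed")
    chosen = int(valid.loc[valid["bic"].idxmin(), "n_classes"])
    return chosen, table
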