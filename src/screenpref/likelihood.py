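"""Simulated-likelihood machinery for panel mixed logit models.

The panel mixed logit treats each respondent's coefficient vector as a draw
from a normal population distribution and integrates the product of their
task-level logit probabilities over that distribution.  The integral is
replaced by an average over scrambled-Halton quasi-random draws (maximum
simulated likelihood).  All heavy routines are vectorized over respondents,
draws, tasks and alternatives, carry analytic gradients, and chunk over
respondents to bound memory.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from scipy.special import logsumexp
from scipy.stats import qmc

from .dataset import PanelArrays
from .params import MMMLParams, MXLParams

__all__ = [
    "mnl_probabilities",
    "panel_loglik_at_beta",
    "halton_normal_draws",
    "simulated_loglik",
    "mmml_loglik",
    "class_prior_probs",
]

_CHUNK = 128  # respondents per block in vectorized likelihood passes


def mnl_probabilities(utilities) -> np.ndarray:
    """Multinomial logit (softmax) choice probabilities, overflow-safe.

    Operates along the last axis; at least two alternatives are required.
    """
    u = np.asarray(utilities, dtype=float)
    if u.size == 0 or u.shape[-1] < 2:
        raise ValueError("need at least two alternatives")
    u = u - u.max(axis=-1, keepdims=True)
    e = np.exp(u)
    return e / e.sum(axis=-1, keepdims=True)


def panel_loglik_at_beta(X, chosen, beta) -> float:
    """Log-probability of one respondent's choice sequence at a fixed beta.

    Parameters
    ----------
    X : array, shape (T, A, K)
        Feature array over the respondent's T tasks and A alternatives.
    chosen : array of int, shape (T,)
        Index of the chosen alternative in each task.
    beta : array, shape (K,)

    Returns the sum over tasks of the log softmax probability of the chosen
    alternative — the within-respondent panel product in log space.
    """
    X = np.asarray(X, dtype=float)
    chosen = np.asarray(chosen, dtype=int)
    if X.ndim != 3 or chosen.shape[0] != X.shape[0]:
        raise ValueError("X must be (tasks, alternatives, features) matching chosen")
    if X.shape[0] == 0:
        raise ValueError("respondent has no tasks")
    V = X @ np.asarray(beta, dtype=float)
    logp = V - logsumexp(V, axis=-1, keepdims=True)
    return float(logp[np.arange(len(chosen)), chosen].sum())


def halton_normal_draws(
    n_draws: int,
    dims: int,
    seed: int = 0,
    n_units: int | None = None,
    burn: int = 16,
) -> np.ndarray:
    """Scrambled-Halton standard-normal draws for simulated likelihood.

    Generates scrambled Halton sequences (Owen scrambling seeded by
    ``seed``), skips ``burn`` initial points, and maps the uniforms through
    the standard normal quantile after clipping away 0 and 1, so no draw is
    infinite.  With ``n_units`` set (one block of draws per respondent),
    every unit receives its own independently scrambled sequence: each
    respondent's mixing integral is approximated by a full low-discrepancy
    point set, and the integration errors are independent across
    respondents, so they average out in the sample log-likelihood.  Returns
    (n_units, n_draws, dims), or (n_draws, dims) without ``n_units``.
    """
    if n_draws < 1 or dims < 1:
        raise ValueError("n_draws and dims must be >= 1")
    eps = 1e-12
    if n_units is None:
        sampler = qmc.Halton(d=dims, scramble=True, seed=seed)
        if burn:
            sampler.fast_forward(burn)
        return stats.norm.ppf(np.clip(sampler.random(n_draws), eps, 1.0 - eps))
    child_seeds = np.random.SeedSequence(seed).spawn(n_units)
    u = np.empty((n_units, n_draws, dims))
    for i in range(n_units):
        sampler = qmc.Halton(
            d=dims, scramble=True, seed=np.random.default_rng(child_seeds[i])
        )
        if burn:
            sampler.fast_forward(burn)
        u[i] = sampler.random(n_draws)
    return stats.norm.ppf(np.clip(u, eps, 1.0 - eps))


# ---------------------------------------------------------------------------
# Core vectorized pass
# ---------------------------------------------------------------------------

def _panel_mixture_stats(
    mu: np.ndarray,
    s: np.ndarray,
    delta: float,
    panel: PanelArrays,
    z: np.ndarray,
    want_grad: bool,
):
    """Per-respondent simulated log-likelihood and its parameter gradient.

    For respondent i with draws r, beta_ir = mu + s*z_ir and

        a_i = ln (1/R) sum_r exp( sum_t ln p_it(chosen | beta_ir) ).

    Returns ``a`` (N,) and, when ``want_grad``, per-respondent gradients of
    ``a_i`` with respect to (mu, s, delta) stacked as an (N, 2K+1) array.
    The likelihood is invariant to the sign of ``s`` (only |s| is
    identified); gradients are exact in the unconstrained parameterization.
    """
    X, chosen, mask = panel.X, panel.chosen, panel.mask
    N, T, A, Kfull = X.shape
    K = Kfull - 1  # last column = left-position flag with fixed coef delta
    R = z.shape[1]
    a = np.empty(N)
    G = np.empty((N, 2 * K + 1)) if want_grad else None
    fmask = mask.astype(float)

    for i0 in range(0, N, _CHUNK):
        i1 = min(i0 + _CHUNK, N)
        Xc = X[i0:i1]
        Xr = Xc[..., :K]
        xleft = Xc[..., K]
        zc = z[i0:i1]
        idx = chosen[i0:i1]
        mk = fmask[i0:i1]

        beta = mu[None, None, :] + s[None, None, :] * zc  # (n, R, K)
        V = np.einsum("ntak,nrk->nrta", Xr, beta, optimize=True)
        V += (delta * xleft)[:, None, :, :]
        V -= V.max(axis=-1, keepdims=True)
        expV = np.exp(V)
        denom = expV.sum(axis=-1)  # (n, R, T)
        lp_ch = np.take_along_axis(
            V, idx[:, None, :, None], axis=3
        )[..., 0] - np.log(denom)  # (n, R, T)
        pl = np.einsum("nrt,nt->nr", lp_ch, mk)  # panel loglik per draw
        m = pl.max(axis=1)
        w = np.exp(pl - m[:, None])
        sw = w.sum(axis=1)
        a[i0:i1] = m + np.log(sw) - np.log(R)

        if want_grad:
            w /= sw[:, None]  # softmax over draws, (n, R)
            p = expV / denom[..., None]  # (n, R, T, A)
            xbar = np.einsum("nrta,ntak->nrtk", p, Xc, optimize=True)
            xch = np.take_along_axis(Xc, idx[:, :, None, None], axis=2)[:, :, 0, :]
            g = np.einsum(
                "nrtk,nt->nrk", xch[:, None, :, :] - xbar, mk, optimize=True
            )  # (n, R, Kfull)
            gr = g[..., :K]
            G[i0:i1, :K] = np.einsum("nr,nrk->nk", w, gr)
            G[i0:i1, K : 2 * K] = np.einsum("nr,nrk,nrk->nk", w, gr, zc)
            G[i0:i1, 2 * K] = np.einsum("nr,nr->n", w, g[..., K])
    return a, G


def simulated_loglik(
    params: MXLParams, panel: PanelArrays, draws: np.ndarray
) -> float:
    """Total simulated log-likelihood of a mixed logit on a choice panel.

    ``draws`` is an (N, R, K) array of standard-normal quasi-random draws,
    one block per respondent, K = number of random coefficients.  With all
    SDs zero this reduces exactly to the plain conditional-logit
    log-likelihood at the means, for any number of draws.
    """
    if draws.ndim != 3 or draws.shape[2] != panel.n_random:
        raise ValueError(
            f"draws must be (n_respondents, n_draws, {panel.n_random})"
        )
    if draws.shape[0] != panel.n_respondents:
        raise ValueError("draws respondent dimension does not match the panel")
    a, _ = _panel_mixture_stats(
        params.means, params.sds, params.left, panel, draws, want_grad=False
    )
    return float(a.sum())


# ---------------------------------------------------------------------------
# Latent-class mixture
# ---------------------------------------------------------------------------

def class_prior_probs(gamma: np.ndarray, Z: np.ndarray) -> np.ndarray:
    """Prior class probabilities from the membership multinomial logit.

    ``gamma`` has one row per non-reference class over the columns of ``Z``
    (intercept first); class 1 is the reference with a zero coefficient
    vector.  Returns an (N, C) array of probabilities summing to one.
    """
    gamma = np.atleast_2d(np.asarray(gamma, dtype=float))
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    if Z.shape[1] != gamma.shape[1]:
        raise ValueError(
            f"covariate row length {Z.shape[1]} does not match "
            f"membership coefficients {gamma.shape[1]}"
        )
    eta = np.column_stack([np.zeros(Z.shape[0]), Z @ gamma.T])
    return mnl_probabilities(eta)


def mmml_loglik(
    params: MMMLParams,
    panel: PanelArrays,
    Z: np.ndarray,
    draws: list[np.ndarray] | np.ndarray,
) -> float:
    """Total log-likelihood of the mixed-mixed multinomial logit.

    Per respondent: log of the prior-weighted sum over classes of the
    within-class simulated panel likelihood.  ``draws`` is one (N, R, K)
    array per class (a single array is shared across classes).
    """
    C = params.n_classes
    if isinstance(draws, np.ndarray):
        draws = [draws] * C
    if len(draws) != C:
        raise ValueError("need one draw array per class")
    pi = class_prior_probs(params.gamma, Z)
    A = np.empty((panel.n_respondents, C))
    for c, cls in enumerate(params.classes):
        a, _ = _panel_mixture_stats(
            cls.means, cls.sds, cls.left, panel, draws[c], want_grad=False
        )
        A[:, c] = a
    return float(logsumexp(np.log(pi) + A, axis=1).sum())
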