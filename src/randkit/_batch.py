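"""Vectorized batch machinery behind the experiment grids.

Everything here advances whole Monte Carlo ensembles at once: t-tests
across replicates, re-randomization tests as matrix products against a
shared bank of re-drawn sequences, and a Newton solver for the Cox
partial likelihood vectorized across replicates.  The public, per-dataset
interfaces live in :mod:`randkit.inference`; tests cross-check the batch
Cox fitter against lifelines.

Re-randomization banks are refreshed per block of replicates: within a
block the L re-drawn sequences are shared (each replicate's p-value is
still a valid Monte Carlo randomization p-value; sharing only induces a
small correlation between replicates, which inflates the standard error
of a rejection-rate estimate slightly but leaves it unbiased).
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .designs import DesignSpec, generate_sequences

_TOL = 1e-9


def t_reject_batch(y: np.ndarray, delta: np.ndarray, alpha: float) -> np.ndarray:
    """Two-sided pooled t-test rejections, one per replicate row."""
    reps, n = y.shape
    ne = delta.sum(axis=1)
    ne_safe = np.clip(ne, 1, n - 1)
    sum_e = np.einsum("rn,rn->r", y, delta)
    mean_e = sum_e / ne_safe
    mean_c = (y.sum(axis=1) - sum_e) / (n - ne_safe)
    ss_e = np.einsum("rn,rn->r", (y - mean_e[:, None]) ** 2, delta)
    ss_c = np.einsum("rn,rn->r", (y - mean_c[:, None]) ** 2, 1 - delta)
    sp2 = (ss_e + ss_c) / (n - 2)
    se = np.sqrt(sp2 * (1.0 / ne_safe + 1.0 / (n - ne_safe)))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (mean_e - mean_c) / se
    crit = stats.t.ppf(1.0 - alpha / 2.0, df=n - 2)
    reject = np.abs(t) > crit
    reject[(ne == 0) | (ne == n)] = False  # one-arm replicate: no comparison
    return reject


def _sequence_bank(
    spec: DesignSpec, n: int, L: int, rng: np.random.Generator, need_two_arms: bool
) -> np.ndarray:
    seqs, _ = generate_sequences(spec, n, L, rng)
    if need_two_arms:
        ne = seqs.sum(axis=1)
        bad = (ne == 0) | (ne == n)
        while bad.any():
            fresh, _ = generate_sequences(spec, n, int(bad.sum()), rng)
            seqs[bad] = fresh
            ne = seqs.sum(axis=1)
            bad = (ne == 0) | (ne == n)
    return seqs


def randomization_reject_batch(
    spec: DesignSpec,
    delta_obs: np.ndarray,
    scores: np.ndarray,
    alpha: float,
    L: int,
    rng: np.random.Generator,
    statistic: str = "mean_diff",
    n_blocks: int = 50,
) -> np.ndarray:
    """Two-sided Monte Carlo randomization-test rejections per replicate.

    ``scores`` holds the per-subject values the linear statistic is built
    from: raw responses for the mean difference, centered ranks (or
    martingale residuals, for the survival score test) for the plain
    linear statistic ``S = sum_i delta_i s_i``.
    """
    reps, n = delta_obs.shape
    use_weights = statistic == "mean_diff"
    reject = np.empty(reps, dtype=bool)
    bounds = np.linspace(0, reps, min(n_blocks, reps) + 1).astype(int)
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        if lo == hi:
            continue
        bank = _sequence_bank(spec, n, L, rng, need_two_arms=use_weights)
        blk_scores = scores[lo:hi]
        blk_delta = delta_obs[lo:hi]
        if use_weights:
            ne = bank.sum(axis=1)
            w = bank / ne[:, None] - (1 - bank) / (n - ne)[:, None]
            s_mat = w @ blk_scores.T  # (L, block)
            ne_obs = blk_delta.sum(axis=1)
            sum_e = np.einsum("rn,rn->r", blk_scores, blk_delta)
            s_obs = sum_e / ne_obs - (blk_scores.sum(axis=1) - sum_e) / (n - ne_obs)
        else:
            s_mat = bank.astype(float) @ blk_scores.T
            s_obs = np.einsum("rn,rn->r", blk_scores, blk_delta)
        tol = _TOL * np.maximum(1.0, np.abs(s_obs))
        p_hat = np.mean(np.abs(s_mat) >= np.abs(s_obs)[None, :] - tol[None, :], axis=0)
        reject[lo:hi] = p_hat < alpha
    return reject


def centered_rank_rows(y: np.ndarray) -> np.ndarray:
    a = stats.rankdata(y, axis=1)
    return a - a.mean(axis=1, keepdims=True)


# -- batch Cox partial-likelihood fitting --------------------------------------

def cox_wald_batch(
    times: np.ndarray, covariates: np.ndarray, n_iter: int = 10
) -> tuple[np.ndarray, np.ndarray]:
    """Newton fit of the Cox partial likelihood for every replicate row.

    ``times``: event times, shape ``(reps, n)``, all events observed;
    ``covariates``: shape ``(reps, n, p)``.  Returns ``(beta, se)`` of
    shapes ``(reps, p)``.  Breslow handling of ties (ties occur with
    probability zero under the continuous generators).  Covariates are
    centered per replicate for conditioning; the estimates are invariant
    to this shift.
    """
    reps, n, p = covariates.shape
    order = np.argsort(-times, axis=1)
    x = np.take_along_axis(covariates, order[:, :, None], axis=1)
    x = x - x.mean(axis=1, keepdims=True)
    beta = np.zeros((reps, p))
    info = np.empty((reps, p, p))
    for _ in range(n_iter):
        eta = np.einsum("rnp,rp->rn", x, beta)
        eta = np.clip(eta, -500, 500)
        w = np.exp(eta)
        s0 = np.cumsum(w, axis=1)  # risk sets are prefixes in reverse-time order
        s1 = np.cumsum(w[:, :, None] * x, axis=1)
        s2 = np.cumsum(w[:, :, None, None] * x[:, :, :, None] * x[:, :, None, :], axis=1)
        xbar = s1 / s0[:, :, None]
        score = (x - xbar).sum(axis=1)
        info = (
            s2 / s0[:, :, None, None] - xbar[:, :, :, None] * xbar[:, :, None, :]
        ).sum(axis=1)
        step = np.linalg.solve(info, score[:, :, None])[:, :, 0]
        beta = beta + step
        if np.max(np.abs(step)) < 1e-10:
            break
    se = np.sqrt(np.diagonal(np.linalg.inv(info), axis1=1, axis2=2))
    return beta, se


def martingale_residuals_batch(
    times: np.ndarray, u: np.ndarray | None, beta_u: np.ndarray | None = None
) -> np.ndarray:
    """Martingale residuals with all events observed, per replicate row.

    With ``u`` ``None`` these are the null-model residuals
    ``1 - NelsonAalen(t_i)``, whose weighted sum against the treatment
    indicator is the logrank score.  With a covariate and its fitted
    coefficient they are the residuals of the covariate-only Cox model
    (Breslow baseline), giving a covariate-adjusted score statistic.
    Residuals sum to zero within each replicate.
    """
    reps, n = times.shape
    order = np.argsort(-times, axis=1)  # reverse-time: risk sets are prefixes
    if u is None:
        w_sorted = np.ones((reps, n))
        risk_score = np.ones((reps, n))
    else:
        uu = np.broadcast_to(u, (reps, n))
        risk_score = np.exp(uu * beta_u[:, None])
        w_sorted = np.take_along_axis(risk_score, order, axis=1)
    s0 = np.cumsum(w_sorted, axis=1)
    # cumulative hazard at each subject's own event time: suffix sum of 1/S0
    lam = np.cumsum((1.0 / s0)[:, ::-1], axis=1)[:, ::-1]
    lam_unsorted = np.empty_like(lam)
    np.put_along_axis(lam_unsorted, order, lam, axis=1)
    return 1.0 - risk_score * lam_unsorted
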