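"""Likelihoods, maximum-likelihood fitting, and interpretation utilities.

The model: each candidate event (s, r[, c]) in the risk set carries a
log-linear rate, log lambda = sum_p beta_p x_p.  Under the piecewise
constant hazard assumption the waiting time to the next event is
exponential with rate sum_R lambda, and the identity of the next event is
multinomial with probabilities lambda / sum lambda.  Combining the two
pieces, the full log-likelihood of an observed sequence is

    sum_e [ beta . x_obs(e)  -  dt_e * sum_{R(t_e)} exp(beta . x) ],

i.e. per event, the log-rate of the realized candidate minus the
integrated total hazard over the waiting interval (the hazard is constant
between events, so the integral is dt times the rate sum).  When only the
order of events is known, the waiting-time factor drops and the ordinal
log-likelihood is the sum of log conditional choice probabilities,

    sum_e [ beta . x_obs(e)  -  log sum_{R(t_e)} exp(beta . x) ].

Both objectives are concave in beta; fitting uses Newton's method with
analytic gradient and Hessian, started at zero.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

from .core import DesignArray, FitResult, ValidationError

GRAD_TOL = 1e-8
MAX_ITER = 200


def event_rate(beta: np.ndarray, x: np.ndarray) -> float:
    """exp(beta . x): the hazard of one candidate event."""
    beta = np.asarray(beta, dtype=float)
    x = np.asarray(x, dtype=float)
    if beta.shape != x.shape:
        raise ValidationError(f"shape mismatch: beta {beta.shape} vs x {x.shape}")
    if not (np.isfinite(beta).all() and np.isfinite(x).all()):
        raise ValidationError("non-finite inputs to event_rate")
    return float(np.exp(beta @ x))


def _block_quantities(beta: np.ndarray, design: DesignArray):
    """Per-block log-rates (masked) and per-event observed log-rates."""
    eta = design.X @ beta  # (G, E)
    eta = np.where(design.active, eta, -np.inf)
    eta_obs = eta[design.event_block, design.obs_index]
    return eta, eta_obs


def loglik(beta: np.ndarray, design: DesignArray, kind: str = "full") -> float:
    """Full or ordinal log-likelihood at beta."""
    beta = np.asarray(beta, dtype=float)
    eta, eta_obs = _block_quantities(beta, design)
    if kind == "full":
        rate_sum = np.exp(eta, where=design.active, out=np.zeros_like(eta)).sum(axis=1)
        return float(eta_obs.sum() - design.dt @ rate_sum[design.event_block])
    if kind == "ordinal":
        lse = logsumexp(eta, axis=1)
        return float(eta_obs.sum() - lse[design.event_block].sum())
    raise ValidationError(f"unknown likelihood kind {kind!r}")


def loglik_grad_hess(
    beta: np.ndarray, design: DesignArray, kind: str = "full"
) -> tuple[float, np.ndarray, np.ndarray]:
    """Log-likelihood with analytic gradient and Hessian."""
    beta = np.asarray(beta, dtype=float)
    X, act = design.X, design.active
    eta, eta_obs = _block_quantities(beta, design)
    x_obs_sum = design.x_observed().sum(axis=0)

    if kind == "full":
        w = np.exp(eta, where=act, out=np.zeros_like(eta))  # (G, E) rates
        rate_sum = w.sum(axis=1)
        # weight per block: total waiting time (full) spent exposed to it
        block_w = np.bincount(design.event_block, weights=design.dt, minlength=X.shape[0])
        ll = float(eta_obs.sum() - design.dt @ rate_sum[design.event_block])
        s1 = np.einsum("ge,gep->gp", w, X)  # sum of x * rate per block
        grad = x_obs_sum - block_w @ s1
        s2 = np.einsum("g,ge,gep,geq->pq", block_w, w, X, X)
        hess = -s2
        return ll, grad, hess
    if kind == "ordinal":
        lse = logsumexp(eta, axis=1)
        p = np.exp(eta - lse[:, None], where=act, out=np.zeros_like(eta))  # (G, E)
        block_m = np.bincount(design.event_block, minlength=X.shape[0]).astype(float)
        ll = float(eta_obs.sum() - lse[design.event_block].sum())
        mu = np.einsum("ge,gep->gp", p, X)  # choice-probability mean of x per block
        grad = x_obs_sum - block_m @ mu
        exx = np.einsum("g,ge,gep,geq->pq", block_m, p, X, X)
        hess = -(exx - np.einsum("g,gp,gq->pq", block_m, mu, mu))
        return ll, grad, hess
    raise ValidationError(f"unknown likelihood kind {kind!r}")


def _check_collinearity(design: DesignArray) -> None:
    X, act = design.X, design.active
    gram = np.einsum("ge,gep,geq->pq", act.astype(float), X, X)
    scale = np.sqrt(np.clip(np.diag(gram), 1e-300, None))
    corr = gram / np.outer(scale, scale)
    eigvals, eigvecs = np.linalg.eigh(corr)
    if eigvals[0] < 1e-10:
        involved = np.nonzero(np.abs(eigvecs[:, 0]) > 0.1)[0]
        names = [design.effect_names[i] for i in involved]
        raise ValidationError(f"collinear design columns: {names}")


def _check_ordinal_identifiability(design: DesignArray) -> None:
    # A column constant over the choice set at every event cancels from all
    # conditional choice probabilities, leaving a flat likelihood direction.
    flat = []
    for p, name in enumerate(design.effect_names):
        spread = 0.0
        for g in range(design.X.shape[0]):
            col = design.X[g, design.active[g], p]
            spread = max(spread, float(col.max() - col.min()))
        if spread < 1e-12:
            flat.append(name)
    if flat:
        raise ValidationError(
            f"columns constant over the risk set at every event are not "
            f"identified under the ordinal likelihood: {flat}; drop them "
            "(e.g. baseline, weekend, group) or use the full likelihood"
        )


def fit_rem(
    design: DesignArray,
    kind: str = "full",
    grad_tol: float = GRAD_TOL,
    max_iter: int = MAX_ITER,
) -> FitResult:
    """Maximize the REM likelihood by Newton's method with step halving.

    Starts at beta = 0 (deterministic); converges when the gradient
    max-norm drops below ``grad_tol``.  Standard errors come from the
    observed information (inverse negative Hessian at the maximum).
    """
    _check_collinearity(design)
    if kind == "ordinal":
        _check_ordinal_identifiability(design)
    p = design.n_effects
    beta = np.zeros(p)
    ll, grad, hess = loglik_grad_hess(beta, design, kind)
    trace = [ll]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        gnorm = float(np.abs(grad).max())
        if gnorm < grad_tol:
            converged = True
            break
        try:
            step = np.linalg.solve(hess, -grad)
        except np.linalg.LinAlgError:
            step = -grad  # fall back on steepest ascent for a singular Hessian
        # step halving: the objective is concave, a damped Newton step
        # eventually improves it
        scale = 1.0
        for _ in range(60):
            cand = beta + scale * step
            ll_new = loglik(cand, design, kind)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        else:
            raise ValidationError(
                f"line search failed at iteration {it}; loglik trace: {trace[-5:]}"
            )
        beta = beta + scale * step
        ll, grad, hess = loglik_grad_hess(beta, design, kind)
        trace.append(ll)
    gnorm = float(np.abs(grad).max())
    if gnorm < grad_tol:
        converged = True
    if not converged:
        raise ValidationError(
            f"no convergence in {max_iter} iterations (|grad| = {gnorm:.3g}); "
            f"loglik trace tail: {trace[-5:]}"
        )
    cov = np.linalg.inv(-hess)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    m = design.n_events
    return FitResult(
        effect_names=design.effect_names,
        beta=beta,
        se=se,
        loglik=ll,
        bic=-2.0 * ll + p * math.log(m),
        n_events=m,
        kind=kind,
        converged=True,
        n_iter=it,
        grad_norm=gnorm,
    )


def bic(fit: FitResult) -> float:
    """-2 loglik + p ln(M); M counts the observed (split) dyadic events."""
    if not fit.converged:
        raise ValidationError("BIC requested for an unconverged fit")
    return -2.0 * fit.loglik + fit.n_params * math.log(fit.n_events)


def rate_multiplier(beta_p: float) -> float:
    """exp(beta_p): multiplicative effect on the event rate per unit of x_p."""
    if not np.isfinite(beta_p):
        raise ValidationError("non-finite coefficient")
    return float(np.exp(beta_p))


def expected_waiting_time(
    beta_baseline: float,
    riskset_size: int,
    extra: Sequence[tuple[float, float]] = (),
) -> float:
    """Expected minutes between events: 1 / (R * exp(beta_0 + sum beta*x)).

    ``extra`` lists additional (coefficient, statistic value) contributions
    shared by all candidates, e.g. a weekend indicator.
    """
    if riskset_size < 1:
        raise ValidationError("risk-set size must be positive")
    log_rate = beta_baseline + sum(b * x for b, x in extra)
    return float(1.0 / (riskset_size * np.exp(log_rate)))


def net_group_effect(beta_group: float, n_raw: int, n_dyadic: int) -> float:
    """Group coefficient net of the artificial log-rate inflation from splitting.

    Splitting group interactions into dyadic events multiplies the event
    rate by n_dyadic / n_raw; subtracting ln of that ratio from the fitted
    group coefficient leaves the substantive tendency to interact in groups
    versus pairs.
    """
    from .ingest import expansion_log_factor

    return float(beta_group - expansion_log_factor(n_raw, n_dyadic))
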