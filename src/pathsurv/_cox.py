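"""Cox partial-likelihood internals.

Newton–Raphson maximization of the Cox proportional-hazards partial
likelihood with Efron (default) or Breslow handling of tied event times.
Two entry points:

* :func:`newton_fit` — one design matrix with ``c`` covariates;
* :func:`newton_fit_1cov_batch` — ``B`` independent single-covariate
  problems sharing the same survival outcome, solved simultaneously with
  column-vectorized Newton steps.  This is what makes permutation
  calibration (tens of thousands of refits) tractable.

The log partial likelihood under Efron's correction, for a tie group of
``D`` events at one time with risk-set sums ``R`` and tied-event sums ``T``:

    ll += sum_i eta_i  -  sum_{l=0}^{D-1} log(R - (l/D) T)

with the gradient and information following by differentiation.  Breslow is
the ``l/D -> 0`` special case.  All exponentials are computed after
subtracting the per-problem maximum of ``eta``; the shift is restored
exactly in the log terms, so the likelihood is comparable across Newton
steps without overflow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import NonIdentifiableError, ValidationError

_MAX_HALVINGS = 30


@dataclass(frozen=True)
class _RiskStructure:
    """Sort order and tie-group bookkeeping for one survival outcome."""

    order: np.ndarray          # ascending time permutation
    time: np.ndarray           # sorted times
    event: np.ndarray          # sorted events
    event_rows: np.ndarray     # sorted positions of events, time-ascending
    group_starts: np.ndarray   # reduceat starts into event_rows (tie groups)
    group_id: np.ndarray       # per event row: index of its tie group
    first_risk: np.ndarray     # per event row: first sorted position at risk
    l_frac: np.ndarray         # per event row: (rank within tie group)/D
    n_events: int


def build_risk_structure(time, event, ties: str = "efron") -> _RiskStructure:
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if time.ndim != 1 or time.shape != event.shape:
        raise ValidationError("time and event must be aligned 1-D arrays")
    n_events = int(event.sum())
    if n_events == 0:
        raise NonIdentifiableError("no observed events: partial likelihood is constant")
    order = np.argsort(time, kind="stable")
    ts, es = time[order], event[order]
    event_rows = np.nonzero(es == 1)[0]
    etimes = ts[event_rows]
    # tie groups: runs of equal event time
    new_group = np.ones(len(event_rows), dtype=bool)
    new_group[1:] = etimes[1:] != etimes[:-1]
    group_starts = np.nonzero(new_group)[0]
    group_id = np.cumsum(new_group) - 1
    sizes = np.bincount(group_id)
    rank_in_group = np.arange(len(event_rows)) - group_starts[group_id]
    if ties == "efron":
        l_frac = rank_in_group / sizes[group_id]
    elif ties == "breslow":
        l_frac = np.zeros(len(event_rows))
    else:
        raise ValidationError(f"unknown tie method {ties!r}")
    # all samples with time >= t are at risk at event time t
    first_risk = np.searchsorted(ts, etimes, side="left")
    return _RiskStructure(order, ts, es, event_rows, group_starts, group_id,
                          first_risk, l_frac, n_events)


def _revcumsum(a: np.ndarray) -> np.ndarray:
    return np.cumsum(a[::-1], axis=0)[::-1]


def _group_to_events(values: np.ndarray, rs: _RiskStructure) -> np.ndarray:
    """Broadcast per-tie-group sums back to one value per event row."""
    return values[rs.group_id]


def loglik_grad_info(beta, x_sorted, rs: _RiskStructure):
    """Log partial likelihood, gradient and observed information at ``beta``.

    ``x_sorted`` is (n, c), already permuted by ``rs.order``.
    """
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    n, c = x_sorted.shape
    # near-separated data drives beta to the boundary: intermediate
    # underflow / 0-division is expected there and handled by the caller's
    # finite-likelihood check, so numpy warnings are silenced locally
    with np.errstate(divide="ignore", invalid="ignore", over="ignore", under="ignore"):
        eta = x_sorted @ beta
        shift = eta.max()
        w = np.exp(eta - shift)
        wx = w[:, None] * x_sorted
        wxx = wx[:, :, None] * x_sorted[:, None, :]

        rcs_w = _revcumsum(w)
        rcs_wx = _revcumsum(wx)
        rcs_wxx = _revcumsum(wxx)

        er = rs.event_rows
        R = rcs_w[rs.first_risk]
        Rx = rcs_wx[rs.first_risk]
        Rxx = rcs_wxx[rs.first_risk]
        Tw = _group_to_events(np.add.reduceat(w[er], rs.group_starts), rs)
        Tx = _group_to_events(np.add.reduceat(wx[er], rs.group_starts, axis=0), rs)
        Txx = _group_to_events(np.add.reduceat(wxx[er], rs.group_starts, axis=0), rs)

        l = rs.l_frac
        phi = R - l * Tw
        psi = (Rx - l[:, None] * Tx) / phi[:, None]
        ll = float(eta[er].sum() - (np.log(phi) + shift).sum())
        grad = x_sorted[er].sum(axis=0) - psi.sum(axis=0)
        info = ((Rxx - l[:, None, None] * Txx) / phi[:, None, None]
                - psi[:, :, None] * psi[:, None, :]).sum(axis=0)
    return ll, grad, info


def newton_fit(covariates, time, event, ties: str = "efron",
               tol: float = 1e-7, max_iter: int = 100):
    """Maximize the partial likelihood; returns (beta, se, p, ll, converged, n_iter).

    Convergence is declared when the sup-norm of the gradient falls below
    ``tol``.  Steps that fail to improve the likelihood are halved (up to 30
    times); a singular information matrix raises
    :class:`~pathsurv.errors.NonIdentifiableError`.
    """
    x = np.asarray(covariates, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if not np.all(np.isfinite(x)):
        raise ValidationError("non-finite covariate values")
    if np.any(x.std(axis=0) == 0):
        raise NonIdentifiableError("constant covariate column")
    rs = build_risk_structure(time, event, ties=ties)
    xs = x[rs.order]

    beta = np.zeros(x.shape[1])
    ll, grad, info = loglik_grad_info(beta, xs, rs)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        if np.max(np.abs(grad)) < tol:
            converged = True
            break
        try:
            delta = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as exc:
            raise NonIdentifiableError(f"singular information matrix: {exc}") from exc
        step = 1.0
        for _ in range(_MAX_HALVINGS):
            cand = beta + step * delta
            ll_new, grad_new, info_new = loglik_grad_info(cand, xs, rs)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                break
            step *= 0.5
        beta, ll, grad, info = cand, ll_new, grad_new, info_new
    else:
        converged = bool(np.max(np.abs(grad)) < tol)

    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError as exc:
        raise NonIdentifiableError(f"singular information matrix at optimum: {exc}") from exc
    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, beta / se, np.inf)
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return beta, se, p, ll, converged, it


def newton_fit_1cov_batch(covariate_matrix, time, event, ties: str = "efron",
                          tol: float = 1e-7, max_iter: int = 100,
                          block_size: int = 4096):
    """Fit ``B`` independent single-covariate Cox models sharing one outcome.

    ``covariate_matrix`` is (n, B): column ``b`` is the covariate of problem
    ``b``.  Returns dict of 1-D arrays: beta, se, p, loglik, converged.
    """
    X = np.asarray(covariate_matrix, dtype=float)
    if X.ndim != 2:
        raise ValidationError("covariate_matrix must be 2-D (n, B)")
    rs = build_risk_structure(time, event, ties=ties)
    n, B = X.shape
    out = {k: np.empty(B) for k in ("beta", "se", "p", "loglik")}
    out["converged"] = np.empty(B, dtype=bool)
    for start in range(0, B, block_size):
        sl = slice(start, min(start + block_size, B))
        res = _batch_block(X[:, sl][rs.order], rs, tol, max_iter)
        for k in out:
            out[k][sl] = res[k]
    return out


def _batch_ll_grad_info(beta, xs, rs: _RiskStructure):
    # xs: (n, B) sorted; beta: (B,)
    with np.errstate(divide="ignore", invalid="ignore", over="ignore", under="ignore"):
        eta = xs * beta[None, :]
        shift = eta.max(axis=0)
        w = np.exp(eta - shift[None, :])
        wx = w * xs
        wxx = wx * xs
        rcs_w = _revcumsum(w)
        rcs_wx = _revcumsum(wx)
        rcs_wxx = _revcumsum(wxx)
        er = rs.event_rows
        R = rcs_w[rs.first_risk]
        Rx = rcs_wx[rs.first_risk]
        Rxx = rcs_wxx[rs.first_risk]
        Tw = _group_to_events(np.add.reduceat(w[er], rs.group_starts, axis=0), rs)
        Tx = _group_to_events(np.add.reduceat(wx[er], rs.group_starts, axis=0), rs)
        Txx = _group_to_events(np.add.reduceat(wxx[er], rs.group_starts, axis=0), rs)
        l = rs.l_frac[:, None]
        phi = R - l * Tw
        psi = (Rx - l * Tx) / phi
        ll = eta[er].sum(axis=0) - (np.log(phi) + shift[None, :]).sum(axis=0)
        grad = xs[er].sum(axis=0) - psi.sum(axis=0)
        info = ((Rxx - l * Txx) / phi - psi * psi).sum(axis=0)
    return ll, grad, info


def _batch_block(xs, rs: _RiskStructure, tol: float, max_iter: int):
    B = xs.shape[1]
    beta = np.zeros(B)
    ll, grad, info = _batch_ll_grad_info(beta, xs, rs)
    # constant columns never move: grad == 0 exactly, flagged unconverged below
    degenerate = xs.std(axis=0) == 0
    active = (np.abs(grad) >= tol) & ~degenerate
    for _ in range(max_iter):
        if not active.any():
            break
        with np.errstate(divide="ignore", invalid="ignore"):
            delta = np.where(active & (info > 0), grad / np.where(info > 0, info, 1.0), 0.0)
        step = np.where(active, 1.0, 0.0)
        for _ in range(_MAX_HALVINGS):
            cand = beta + step * delta
            ll_new, grad_new, info_new = _batch_ll_grad_info(cand, xs, rs)
            bad = active & ~(np.isfinite(ll_new) & (ll_new >= ll - 1e-12))
            if not bad.any():
                break
            step = np.where(bad, step * 0.5, step)
        upd = active
        beta = np.where(upd, cand, beta)
        ll = np.where(upd, ll_new, ll)
        grad = np.where(upd, grad_new, grad)
        info = np.where(upd, info_new, info)
        active = (np.abs(grad) >= tol) & ~degenerate
    converged = (np.abs(grad) < tol) & ~degenerate
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.where(info > 0, 1.0 / np.sqrt(np.where(info > 0, info, 1.0)), np.nan)
        z = np.where(se > 0, beta / se, np.inf)
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    p = np.where(degenerate, np.nan, p)
    return {"beta": beta, "se": se, "p": p, "loglik": ll, "converged": converged}
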