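"""Cox proportional-hazards scans of pathway activities and FDR correction.

The hazard model is lambda(t | X_i) = lambda0(t) * exp(X_i . beta): covariates
scale a shared, unestimated baseline hazard multiplicatively.  Fitting
maximizes the partial likelihood (Efron ties by default), so the baseline
never needs to be specified.  One pathway is tested at a time, optionally
with a confounder pathway's activity as a second covariate so the tested
coefficient reflects residual association.  The scan's Wald p-values are
corrected to Storey q-values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import UnivariateSpline

from . import _cox
from .errors import NonIdentifiableError, ValidationError
from .io_formats import SurvivalData

logger = logging.getLogger(__name__)

__all__ = [
    "CoxResult",
    "PathwayResult",
    "fit_cox",
    "pathway_scan",
    "compute_qvalues",
    "estimate_pi0",
    "multi_eigengene_fit",
]


@dataclass
class CoxResult:
    """One fitted Cox model: coefficients in log-hazard units per unit covariate."""

    covariate_names: list[str]
    beta: np.ndarray
    se: np.ndarray
    p_values: np.ndarray
    log_partial_likelihood: float
    converged: bool
    n_events: int
    n_iter: int = 0


@dataclass
class PathwayResult:
    pathway_id: str
    n_genes_used: int
    beta: float
    se: float
    p: float
    q: float = float("nan")
    adjusted: bool = False
    c_index: float | None = None
    status: str = "ok"
    name: str = ""


def fit_cox(covariates, surv: SurvivalData, names=None, ties: str = "efron",
            tol: float = 1e-7, max_iter: int = 100) -> CoxResult:
    """Fit a Cox model of ``surv`` on an (m, c) covariate matrix.

    Rows must align with ``surv.sample_ids``.  Raises
    :class:`~pathsurv.errors.NonIdentifiableError` for constant or collinear
    covariates and when no event was observed.
    """
    x = np.asarray(covariates, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if x.shape[0] != surv.n_samples:
        raise ValidationError(
            f"covariate rows ({x.shape[0]}) do not match samples ({surv.n_samples})"
        )
    beta, se, p, ll, converged, n_iter = _cox.newton_fit(
        x, surv.time, surv.event, ties=ties, tol=tol, max_iter=max_iter
    )
    if names is None:
        names = [f"x{i}" for i in range(x.shape[1])]
    return CoxResult(list(names), beta, se, p, ll, converged, surv.n_events, n_iter)


def pathway_scan(activity: pd.DataFrame, surv: SurvivalData,
                 confounder=None, sizes: dict[str, int] | None = None,
                 names: dict[str, str] | None = None,
                 qvalue_method: str = "storey", ties: str = "efron") -> list[PathwayResult]:
    """Cox-regress survival on each activity row, one pathway at a time.

    ``activity`` is pathways x samples, columns aligned to
    ``surv.sample_ids``.  When ``confounder`` (per-sample vector) is given,
    each fit includes it as a second covariate and the reported statistics
    belong to the pathway coefficient.  q-values are computed over the
    successful fits only; failed fits are reported with an explicit status.
    """
    if activity.shape[0] == 0:
        raise ValidationError("empty activity table")
    if list(activity.columns) != list(surv.sample_ids):
        surv = surv.align_to(list(activity.columns))
    conf = None if confounder is None else np.asarray(confounder, dtype=float)
    results: list[PathwayResult] = []
    for pid, row in activity.iterrows():
        v = row.to_numpy(dtype=float)
        size = (sizes or {}).get(pid, 0)
        name = (names or {}).get(pid, "")
        design = v[:, None] if conf is None else np.column_stack([v, conf])
        try:
            fit = fit_cox(design, surv, ties=ties)
        except NonIdentifiableError as exc:
            logger.warning("pathway %s: non-identifiable fit (%s)", pid, exc)
            results.append(PathwayResult(pid, size, np.nan, np.nan, np.nan,
                                         adjusted=conf is not None,
                                         status=f"non_identifiable: {exc}", name=name))
            continue
        status = "ok" if fit.converged else "not_converged"
        results.append(PathwayResult(
            pid, size, float(fit.beta[0]), float(fit.se[0]), float(fit.p_values[0]),
            adjusted=conf is not None, status=status, name=name,
        ))
    ok = [r for r in results if r.status == "ok"]
    logger.info("pathway scan: %d fits, %d usable for FDR", len(results), len(ok))
    if ok:
        qs = compute_qvalues([r.p for r in ok], method=qvalue_method)
        for r, q in zip(ok, qs):
            r.q = float(q)
    return results


# ---------------------------------------------------------------------------
# q-values
# ---------------------------------------------------------------------------

def estimate_pi0(p, lambdas=None) -> float:
    """Storey's estimate of the null proportion pi0.

    pi0(lambda) = #{p > lambda} / (m (1 - lambda)) is evaluated on a grid
    (default 0, 0.05, ..., 0.9), smoothed with a cubic spline and read off at
    the largest lambda, then clipped to (0, 1].
    """
    p = np.asarray(p, dtype=float)
    if lambdas is None:
        lambdas = np.arange(0.0, 0.95, 0.05)
    lambdas = np.asarray(lambdas, dtype=float)
    m = len(p)
    pi0_grid = np.array([(p > lam).sum() / (m * (1.0 - lam)) for lam in lambdas])
    if m < 100:
        # the smoother is unstable for small test counts; be conservative
        return 1.0
    spline = UnivariateSpline(lambdas, pi0_grid, k=3)
    pi0 = float(spline(lambdas[-1]))
    if not np.isfinite(pi0) or pi0 <= 0:
        pi0 = float(min(pi0_grid[pi0_grid > 0], default=1.0))
    return float(min(pi0, 1.0))


def compute_qvalues(p, method: str = "storey", pi0: float | None = None):
    """Convert p-values to q-values (minimum FDR at which each is significant).

    ``method="storey"`` estimates pi0 from the data; ``method="bh"`` (or
    ``pi0=1``) reduces to Benjamini–Hochberg.  Output order matches input.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in (0, 1]")
    if pi0 is None:
        pi0 = 1.0 if method == "bh" else estimate_pi0(p)
    if not 0 < pi0 <= 1:
        raise ValidationError(f"pi0 must lie in (0, 1], got {pi0}")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    q_sorted = pi0 * m * ranked / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.clip(q_sorted, 0.0, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


# ---------------------------------------------------------------------------
# multi-component extension
# ---------------------------------------------------------------------------

def multi_eigengene_fit(activities, surv: SurvivalData, mode: str = "joint",
                        confounder=None, ties: str = "efron"):
    """Fit survival on several SVD components of one pathway.

    ``activities`` is (k, m): one row per component.  ``mode="joint"`` fits a
    single model with k covariates (plus the confounder if given) and returns
    one :class:`CoxResult`; ``mode="separate"`` fits each component alone and
    returns a list of k results.  Per-coefficient Wald p-values support
    fraction-significant comparisons across k.
    """
    a = np.atleast_2d(np.asarray(activities, dtype=float))
    k, m = a.shape
    if m != surv.n_samples:
        raise ValidationError("activities not aligned to survival samples")
    conf = None if confounder is None else np.asarray(confounder, dtype=float)
    if mode == "joint":
        design = a.T if conf is None else np.column_stack([a.T, conf])
        names = [f"component_{i + 1}" for i in range(k)] + ([] if conf is None else ["confounder"])
        return fit_cox(design, surv, names=names, ties=ties)
    if mode == "separate":
        out = []
        for i in range(k):
            design = a[i][:, None] if conf is None else np.column_stack([a[i], conf])
            names = [f"component_{i + 1}"] + ([] if conf is None else ["confounder"])
            out.append(fit_cox(design, surv, names=names, ties=ties))
        return out
    raise ValidationError(f"unknown mode {mode!r}")
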