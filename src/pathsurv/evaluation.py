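"""Prognostic-performance metrics and validation diagnostics.

Harrell's concordance index with k-fold cross-validation, eigensample
stability under sample subsampling, adaptive permutation calibration of the
Cox p-values, a size-matched random-gene-set null, and a per-transcript scan
for pathway-vs-transcript comparisons.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold

from . import _cox
from .errors import NonIdentifiableError, UndefinedSignalError, ValidationError
from .io_formats import ExpressionMatrix, GeneSet, PathwayCollection, SurvivalData
from .pathway_activity import decompose, subset_pathway
from .survival_stats import fit_cox

logger = logging.getLogger(__name__)

__all__ = [
    "ConcordanceResult",
    "StabilityReport",
    "CalibrationRecord",
    "concordance_index",
    "make_folds",
    "cross_validated_cindex",
    "stability_analysis",
    "permutation_calibration",
    "gene_set_null",
    "transcript_scan",
]


# ---------------------------------------------------------------------------
# concordance
# ---------------------------------------------------------------------------

def concordance_index(time, event, hazard_score) -> float:
    """Harrell's C: fraction of comparable pairs ranked correctly.

    A pair (i, j) with t_i < t_j is comparable iff the earlier subject's
    event was observed (d_i = 1); pairs tied in time are not comparable.
    A comparable pair is concordant when the earlier subject has the higher
    hazard score; ties in the score count 1/2.  C = 0.5 is a null
    prediction, 1 a perfect ranking.
    """
    t = np.asarray(time, dtype=float)
    d = np.asarray(event, dtype=int)
    eta = np.asarray(hazard_score, dtype=float)
    if not (t.shape == d.shape == eta.shape) or t.ndim != 1:
        raise ValidationError("time, event and hazard_score must be aligned 1-D arrays")
    comparable = (t[:, None] < t[None, :]) & (d[:, None] == 1)
    n_comparable = int(comparable.sum())
    if n_comparable == 0:
        raise UndefinedSignalError("no comparable pairs: concordance undefined")
    concordant = int((comparable & (eta[:, None] > eta[None, :])).sum())
    tied = int((comparable & (eta[:, None] == eta[None, :])).sum())
    return (concordant + 0.5 * tied) / n_comparable


@dataclass
class ConcordanceResult:
    pathway_id: str
    per_fold_c: list[float]
    n_comparable_pairs: list[int]
    status: str = "ok"

    @property
    def mean_c(self) -> float:
        return float(np.mean(self.per_fold_c)) if self.per_fold_c else float("nan")


def make_folds(n_samples: int, n_folds: int = 5, seed: int = 0):
    """Seeded shuffled k-fold split, shared across pathways within one run."""
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return list(kf.split(np.arange(n_samples)))


def cross_validated_cindex(activity, surv: SurvivalData, n_folds: int = 5,
                           seed: int = 0, pathway_id: str = "",
                           folds=None, ties: str = "efron") -> ConcordanceResult:
    """Out-of-sample concordance: fit Cox on each training split, score the
    held-out samples with eta = X . beta, and evaluate C on the holdout.

    Folds with zero training events (or a non-identifiable training fit) are
    skipped with a warning; the mean is over the evaluated folds.
    """
    x = np.asarray(activity, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if n_folds < 2:
        raise ValidationError("n_folds must be >= 2")
    if folds is None:
        folds = make_folds(surv.n_samples, n_folds=n_folds, seed=seed)
    per_fold, n_pairs = [], []
    for train, test in folds:
        if surv.event[train].sum() == 0:
            logger.warning("pathway %s: fold skipped (no training events)", pathway_id)
            continue
        try:
            beta, *_ = _cox.newton_fit(x[train], surv.time[train], surv.event[train], ties=ties)
        except NonIdentifiableError as exc:
            logger.warning("pathway %s: fold skipped (%s)", pathway_id, exc)
            continue
        eta = x[test] @ beta
        try:
            c = concordance_index(surv.time[test], surv.event[test], eta)
        except UndefinedSignalError:
            logger.warning("pathway %s: fold skipped (no comparable holdout pairs)", pathway_id)
            continue
        comparable = ((surv.time[test][:, None] < surv.time[test][None, :])
                      & (surv.event[test][:, None] == 1)).sum()
        per_fold.append(float(c))
        n_pairs.append(int(comparable))
    status = "ok" if per_fold else "no_valid_folds"
    return ConcordanceResult(pathway_id, per_fold, n_pairs, status=status)


# ---------------------------------------------------------------------------
# stability
# ---------------------------------------------------------------------------

@dataclass
class StabilityReport:
    """Sign-invariant cosine distances (1 - |cos|) between replicate
    eigensamples, with a matched random-direction background."""

    pathway_id: str
    pairwise_distances: np.ndarray
    background_distances: np.ndarray
    n_replicates: int
    subsample_size: int


def _pairwise_abs_cosine_distances(vectors: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(vectors, axis=1, keepdims=True)
    unit = vectors / norms
    cos = np.abs(unit @ unit.T)
    iu = np.triu_indices(len(vectors), k=1)
    return np.clip(1.0 - cos[iu], 0.0, 1.0)


def stability_analysis(x: ExpressionMatrix, pathway: GeneSet, n_rep: int = 100,
                       fraction: float = 0.2, seed: int = 0,
                       min_size: int = 3) -> StabilityReport:
    """Decompose the pathway on ``n_rep`` random sample subsets and compare
    the resulting eigensample directions pairwise.

    The background repeats the pairwise statistic for uniformly random unit
    vectors of the same dimension (normalized independent standard normals),
    so a structured pathway shows up as distances well below background.
    """
    b, genes_used, _ = subset_pathway(x, pathway, min_size=min_size)
    m = b.shape[1]
    n_sub = math.floor(fraction * m)
    if n_sub < 3:
        raise ValidationError(f"subsample of {n_sub} samples is too small (fraction={fraction})")
    rng = np.random.default_rng(seed)
    eigensamples = np.empty((n_rep, b.shape[0]))
    for r in range(n_rep):
        cols = rng.choice(m, size=n_sub, replace=False)
        d = decompose(b[:, cols], k=1, pathway_id=pathway.pathway_id, genes_used=genes_used)[0]
        eigensamples[r] = d.eigensample
    background = rng.standard_normal((n_rep, b.shape[0]))
    return StabilityReport(
        pathway_id=pathway.pathway_id,
        pairwise_distances=_pairwise_abs_cosine_distances(eigensamples),
        background_distances=_pairwise_abs_cosine_distances(background),
        n_replicates=n_rep,
        subsample_size=n_sub,
    )


# ---------------------------------------------------------------------------
# permutation calibration
# ---------------------------------------------------------------------------

@dataclass
class CalibrationRecord:
    pathway_id: str
    nominal_p: float
    n_permutations: int
    empirical_p: float
    a: float                 # the sampled exponent targeting p ~ 10**a
    capped: bool = False


def _empirical_p_for_pathway(activity: np.ndarray, surv: SurvivalData,
                             p_observed: float, n_perms: int,
                             rng: np.random.Generator, ties: str,
                             estimator: str, block: int = 2000) -> float:
    """Permute the sample<->(time, event) association ``n_perms`` times and
    refit; returns the fraction of permutations at least as extreme."""
    n = surv.n_samples
    more_extreme = 0
    done = 0
    while done < n_perms:
        b = min(block, n_perms - done)
        cols = np.empty((n, b))
        for j in range(b):
            cols[:, j] = activity[rng.permutation(n)]
        res = _cox.newton_fit_1cov_batch(cols, surv.time, surv.event, ties=ties)
        more_extreme += int(np.sum(res["p"] <= p_observed))
        done += b
    if estimator == "plus_one":
        return (more_extreme + 1) / (n_perms + 1)
    return more_extreme / n_perms


def permutation_calibration(activity: pd.DataFrame, surv: SurvivalData,
                            scan_results, n_select: int = 100,
                            max_perms: int = 100_000, seed: int = 0,
                            ties: str = "efron",
                            estimator: str = "fraction") -> list[CalibrationRecord]:
    """Adaptive permutation check of the Cox p-values.

    Pathways are selected without replacement by repeatedly sampling an
    exponent ``a ~ Uniform[-5, 0]`` and taking the not-yet-selected pathway
    whose nominal p is closest to ``10**a``; each selected pathway is then
    permuted ``N = min(ceil(100 / p), max_perms)`` times and the empirical p
    (fraction of permutations with a smaller-or-equal refitted p) is
    recorded against the nominal one.
    """
    usable = [r for r in scan_results
              if getattr(r, "status", "ok") == "ok" and np.isfinite(r.p)]
    if len(usable) < n_select:
        raise ValidationError(
            f"only {len(usable)} usable scan results for n_select={n_select}"
        )
    if list(activity.columns) != list(surv.sample_ids):
        surv = surv.align_to(list(activity.columns))
    rng = np.random.default_rng(seed)
    remaining = {r.pathway_id: r.p for r in usable}
    records: list[CalibrationRecord] = []
    for _ in range(n_select):
        a = float(rng.uniform(-5.0, 0.0))
        target = 10.0 ** a
        pid = min(remaining, key=lambda k: abs(remaining[k] - target))
        p_obs = remaining.pop(pid)
        n_req = math.ceil(100.0 / p_obs)
        capped = n_req > max_perms
        n_perms = min(n_req, max_perms)
        if capped:
            logger.info("pathway %s: permutation count capped at %d (rule requested %d)",
                        pid, max_perms, n_req)
        emp = _empirical_p_for_pathway(
            activity.loc[pid].to_numpy(dtype=float), surv, p_obs, n_perms,
            rng, ties, estimator,
        )
        records.append(CalibrationRecord(pid, float(p_obs), n_perms, float(emp), a, capped))
    return records


# ---------------------------------------------------------------------------
# random-gene-set null
# ---------------------------------------------------------------------------

def gene_set_null(x: ExpressionMatrix, surv: SurvivalData, set_size: int,
                  n_draws: int, seed: int = 0, min_size: int = 3,
                  ties: str = "efron") -> np.ndarray:
    """Null p-value distribution for random gene sets of a given size.

    Each draw picks ``set_size`` measured genes uniformly without
    replacement, scores the set (rank-1 SVD eigengene) and Cox-regresses
    survival on the score.  Comparing a real pathway's p against its
    size-matched null separates curated structure from arbitrary gene
    groupings.
    """
    if set_size < min_size:
        raise ValidationError(f"set_size={set_size} below minimum pathway size {min_size}")
    if set_size > x.n_genes:
        raise ValidationError("set_size exceeds number of measured genes")
    if list(x.sample_ids) != list(surv.sample_ids):
        surv = surv.align_to(list(x.sample_ids))
    rng = np.random.default_rng(seed)
    ps = np.empty(n_draws)
    for i in range(n_draws):
        rows = rng.choice(x.n_genes, size=set_size, replace=False)
        d = decompose(x.values[np.sort(rows)], k=1)[0]
        fit = fit_cox(d.eigengene, surv, ties=ties)
        ps[i] = fit.p_values[0]
    return ps


# ---------------------------------------------------------------------------
# per-transcript scan
# ---------------------------------------------------------------------------

def transcript_scan(x: ExpressionMatrix, surv: SurvivalData, n_folds: int = 5,
                    seed: int = 0, ties: str = "efron"):
    """Cross-validated concordance with each single transcript as the
    covariate, for pathway-vs-transcript comparisons.

    Returns ``(results, skipped)``: constant transcripts are skipped with
    their IDs listed.  Folds are shared across transcripts.
    """
    if list(x.sample_ids) != list(surv.sample_ids):
        surv = surv.align_to(list(x.sample_ids))
    folds = make_folds(surv.n_samples, n_folds=n_folds, seed=seed)
    results: list[ConcordanceResult] = []
    skipped: list[str] = []
    for gid, row in zip(x.gene_ids, x.values):
        if row.std() == 0:
            skipped.append(gid)
            continue
        results.append(cross_validated_cindex(row, surv, pathway_id=gid,
                                              folds=folds, ties=ties))
    if skipped:
        logger.info("transcript scan: skipped %d constant transcripts", len(skipped))
    return results, skipped
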