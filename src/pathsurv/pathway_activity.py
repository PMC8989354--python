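"""Single-sample pathway activity scoring by truncated SVD (PLAGE).

For a standardized genes x samples matrix, the submatrix ``B`` of a
pathway's measured genes is factorized as ``B ~ U S V^T``.  Following the
eigengene/eigensample nomenclature, the left singular vector ``U`` (one
weight per gene) is the *eigensample* — the expression pattern of a typical
sample — and the right singular vector ``V`` (one element per sample) is the
*eigengene*, whose elements are the per-sample pathway activity scores.
Because the SVD sign is mathematically arbitrary, a deterministic sign
convention is applied so scores are reproducible across linear-algebra
backends.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import PathwayExcludedError, ValidationError
from .io_formats import ExpressionMatrix, GeneSet, PathwayCollection

logger = logging.getLogger(__name__)

__all__ = [
    "PathwayDecomposition",
    "preprocess",
    "subset_pathway",
    "decompose",
    "fix_sign",
    "activity_scores",
]

DEFAULT_MIN_SIZE = 3


@dataclass
class PathwayDecomposition:
    """One singular triple of a pathway submatrix.

    ``component_index`` is 1-based; component 1's eigengene elements are the
    pathway activity scores.
    """

    pathway_id: str
    component_index: int
    eigensample: np.ndarray    # length-p unit vector, gene weights (U)
    singular_value: float      # S >= 0
    eigengene: np.ndarray      # length-m unit vector, per-sample scores (V)
    genes_used: list[str]

    def validate(self, b: np.ndarray | None = None) -> None:
        if abs(np.linalg.norm(self.eigensample) - 1) > 1e-8:
            raise ValidationError("eigensample is not unit-norm")
        if abs(np.linalg.norm(self.eigengene) - 1) > 1e-8:
            raise ValidationError("eigengene is not unit-norm")
        if self.singular_value < 0:
            raise ValidationError("negative singular value")
        if b is not None:
            s = float(self.eigensample @ (b @ self.eigengene))
            if abs(s - self.singular_value) > 1e-6 * max(1.0, self.singular_value):
                raise ValidationError("inconsistent singular triple")


def preprocess(x: ExpressionMatrix, log_transform: bool = False,
               log_offset: float = 1.0) -> ExpressionMatrix:
    """Optionally log2-transform, then z-score every gene row.

    Standardization uses the population standard deviation (divide by m).
    Zero-variance rows carry no information for a correlation-driven
    decomposition and are dropped with a warning.
    """
    values = np.asarray(x.values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValidationError("expression matrix contains non-finite values")
    if log_transform:
        shifted = values + log_offset
        if np.any(shifted <= 0):
            raise ValidationError(
                f"log transform undefined: value + offset <= 0 (offset={log_offset})"
            )
        values = np.log2(shifted)
    sds = values.std(axis=1)
    keep = sds > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        dropped = [g for g, k in zip(x.gene_ids, keep) if not k]
        logger.warning("dropping %d zero-variance gene rows: %s%s",
                       n_dropped, dropped[:5], "..." if n_dropped > 5 else "")
    values = values[keep]
    means = values.mean(axis=1, keepdims=True)
    values = (values - means) / values.std(axis=1, keepdims=True)
    return ExpressionMatrix(
        gene_ids=[g for g, k in zip(x.gene_ids, keep) if k],
        sample_ids=list(x.sample_ids),
        values=values,
        is_standardized=True,
    )


def subset_pathway(x: ExpressionMatrix, pathway: GeneSet,
                   min_size: int = DEFAULT_MIN_SIZE):
    """Extract the pathway's p' x m submatrix ``B`` in matrix row order.

    Returns ``(B, genes_used, absent_members)``.  Raises
    :class:`~pathsurv.errors.PathwayExcludedError` when fewer than
    ``min_size`` members are measured.
    """
    if not x.is_standardized:
        raise ValidationError("expression matrix must be standardized first")
    members = set(pathway.genes)
    rows = [i for i, g in enumerate(x.gene_ids) if g in members]
    genes_used = [x.gene_ids[i] for i in rows]
    absent = [g for g in pathway.genes if g not in set(genes_used)]
    if len(rows) < min_size:
        raise PathwayExcludedError(
            pathway.pathway_id,
            f"only {len(rows)} of {pathway.size} members measured (min_size={min_size})",
        )
    return x.values[rows], genes_used, absent


def decompose(b: np.ndarray, k: int = 1, pathway_id: str = "",
              genes_used=None) -> list[PathwayDecomposition]:
    """Return the ``k`` leading sign-fixed singular triples of ``B``.

    Uses a full (deterministic) SVD; pathway submatrices are small enough
    that no randomized solver is needed.
    """
    b = np.asarray(b, dtype=float)
    if b.ndim != 2 or b.shape[0] < 1 or b.shape[1] < 2:
        raise ValidationError(f"submatrix must be p x m with m >= 2, got {b.shape}")
    if not np.all(np.isfinite(b)):
        raise ValidationError("non-finite entries in pathway submatrix")
    bound = min(b.shape)
    if not 1 <= k <= bound:
        raise ValidationError(f"k={k} outside [1, min(p, m)={bound}]")
    u, s, vt = np.linalg.svd(b, full_matrices=False)
    if genes_used is None:
        genes_used = [f"g{i}" for i in range(b.shape[0])]
    out = []
    for i in range(k):
        d = PathwayDecomposition(
            pathway_id=pathway_id,
            component_index=i + 1,
            eigensample=u[:, i].copy(),
            singular_value=float(s[i]),
            eigengene=vt[i].copy(),
            genes_used=list(genes_used),
        )
        out.append(fix_sign(d))
    return out


def fix_sign(d: PathwayDecomposition, b: np.ndarray | None = None) -> PathwayDecomposition:
    """Apply the deterministic sign convention, flipping U and V jointly.

    The orientation makes the eigengene correlate non-negatively with the
    pathway's mean expression profile across genes: since the column mean of
    ``B`` is ``(1/p) 1^T B`` and ``B V = S U``, that correlation has the sign
    of ``sum_j U_j``.  Flip iff ``sum_j U_j < 0``; on an exact zero sum, flip
    iff the first nonzero eigensample element is negative.  The joint flip
    preserves the singular triple.
    """
    total = float(d.eigensample.sum())
    if total < 0:
        flip = True
    elif total > 0:
        flip = False
    else:
        nonzero = d.eigensample[d.eigensample != 0]
        flip = bool(len(nonzero)) and nonzero[0] < 0
    if flip:
        d.eigensample = -d.eigensample
        d.eigengene = -d.eigengene
    if b is not None:
        d.validate(b)
    return d


def activity_scores(x: ExpressionMatrix, sets: PathwayCollection, k: int = 1,
                    min_size: int = DEFAULT_MIN_SIZE):
    """Score every pathway: one activity row per (pathway, component).

    Returns ``(table, exclusions)`` where ``table`` is a DataFrame indexed by
    ``pathway_id`` (k = 1) or ``pathway_id.component`` (k > 1) with one
    column per sample, and ``exclusions`` maps excluded pathway IDs to the
    reason.  Pathways already flagged in the collection are passed through to
    ``exclusions`` unscored.
    """
    if not x.is_standardized:
        raise ValidationError("expression matrix must be standardized first")
    rows: dict[str, np.ndarray] = {}
    meta: dict[str, dict] = {}
    exclusions: dict[str, str] = {}
    for entry in sets:
        if entry.excluded_reason is not None:
            exclusions[entry.pathway_id] = entry.excluded_reason
            continue
        try:
            b, genes_used, absent = subset_pathway(x, entry, min_size=min_size)
        except PathwayExcludedError as exc:
            exclusions[entry.pathway_id] = exc.reason
            continue
        k_eff = min(k, min(b.shape))
        if k_eff < k:
            logger.warning("pathway %s: only %d components available (k=%d requested)",
                           entry.pathway_id, k_eff, k)
        for d in decompose(b, k=k_eff, pathway_id=entry.pathway_id, genes_used=genes_used):
            key = entry.pathway_id if k == 1 else f"{entry.pathway_id}.{d.component_index}"
            rows[key] = d.eigengene
            meta[key] = {"n_genes_used": len(genes_used), "n_absent": len(absent)}
    table = pd.DataFrame.from_dict(rows, orient="index", columns=x.sample_ids, dtype=float)
    table.attrs["meta"] = meta
    return table, exclusions
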