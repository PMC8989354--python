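"""Readers, writers and validated in-memory containers for every external format.

All downstream modules operate on the dataclasses defined here:

* :class:`ExpressionMatrix` — genes x samples intensities (TSV),
* :class:`PathwayCollection` — named gene sets (GMT),
* :class:`PathwayHierarchy` — parent->child pathway relations (2-column TSV, DAG),
* :class:`SurvivalData` — per-sample follow-up time and event indicator (TSV),
* :class:`GeneIdMapping` — many-to-many identifier translation (2-column TSV).

Every reader rejects malformed input with a named error instead of returning a
partial structure, and every read/write pair round-trips losslessly to the
stated precision.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .errors import CycleError, FormatError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "GeneSet",
    "PathwayCollection",
    "PathwayHierarchy",
    "SurvivalData",
    "GeneIdMapping",
    "read_expression",
    "write_expression",
    "drop_duplicate_samples",
    "read_gene_sets",
    "write_gene_sets",
    "apply_gene_mapping",
    "read_mapping",
    "read_hierarchy",
    "write_hierarchy",
    "read_survival",
    "write_survival",
    "write_results_table",
    "read_results_table",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """A genes x samples matrix of (unitless) expression intensities.

    ``values[i, j]`` is the intensity of ``gene_ids[i]`` in ``sample_ids[j]``.
    ``is_standardized`` marks that every row has zero mean and unit standard
    deviation (population convention); survival fits require it.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    is_standardized: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids) and self.is_standardized:
            raise ValidationError("duplicate gene IDs in a standardized matrix")
        if self.is_standardized:
            self.validate_standardized()

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def validate_standardized(self, mean_tol: float = 1e-8, sd_tol: float = 1e-6) -> None:
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("standardized matrix contains non-finite values")
        means = self.values.mean(axis=1)
        sds = self.values.std(axis=1)
        if np.any(np.abs(means) >= mean_tol):
            raise ValidationError("standardized matrix has a row with non-zero mean")
        if np.any(np.abs(sds - 1.0) >= sd_tol):
            raise ValidationError("standardized matrix has a row with sd != 1")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, is_standardized: bool = False) -> "ExpressionMatrix":
        return cls(
            gene_ids=[str(g) for g in frame.index],
            sample_ids=[str(s) for s in frame.columns],
            values=frame.to_numpy(dtype=float),
            is_standardized=is_standardized,
        )


@dataclass
class GeneSet:
    """One named pathway: an identifier, a display name and its member genes.

    ``excluded_reason`` flags sets that cannot be scored (too small/large or
    empty after intersection with the measured genes); flagged sets stay in
    the collection so nothing is dropped silently.
    """

    pathway_id: str
    name: str
    genes: list[str]
    excluded_reason: str | None = None

    def __post_init__(self):
        # preserve order, drop repeats (GMT lines may list a member twice)
        seen: dict[str, None] = dict.fromkeys(self.genes)
        self.genes = list(seen)

    @property
    def size(self) -> int:
        return len(self.genes)


@dataclass
class PathwayCollection:
    entries: list[GeneSet] = field(default_factory=list)

    def __post_init__(self):
        ids = [e.pathway_id for e in self.entries]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate pathway IDs: {dupes}")

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, pathway_id: str) -> GeneSet:
        for e in self.entries:
            if e.pathway_id == pathway_id:
                return e
        raise KeyError(pathway_id)

    @property
    def active(self) -> list[GeneSet]:
        return [e for e in self.entries if e.excluded_reason is None]

    @property
    def excluded(self) -> list[GeneSet]:
        return [e for e in self.entries if e.excluded_reason is not None]

    def intersect_with(self, gene_ids, min_size: int = 3, max_size: int | None = None) -> "PathwayCollection":
        """Restrict every set to the measured genes and flag size violations.

        Returns a new collection; sets falling outside [min_size, max_size]
        after intersection are flagged via ``excluded_reason``, never removed.
        """
        measured = set(gene_ids)
        out = []
        for e in self.entries:
            genes = [g for g in e.genes if g in measured]
            absent = e.size - len(genes)
            reason = None
            if len(genes) == 0:
                reason = "no members among measured genes"
            elif len(genes) < min_size:
                reason = f"only {len(genes)} measured members (min_size={min_size})"
            elif max_size is not None and len(genes) > max_size:
                reason = f"{len(genes)} measured members exceeds max_size={max_size}"
            if absent:
                logger.debug("pathway %s: %d annotated members not measured", e.pathway_id, absent)
            out.append(GeneSet(e.pathway_id, e.name, genes, excluded_reason=reason))
        return PathwayCollection(out)


@dataclass
class PathwayHierarchy:
    """Parent->child pathway relations. A DAG: multiple parents are allowed."""

    edges: list[tuple[str, str]]
    roots: list[str] = field(default_factory=list)

    def __post_init__(self):
        for parent, child in self.edges:
            if parent == child:
                raise ValidationError(f"self-edge on {parent!r}")
        graph = nx.DiGraph(self.edges)
        if not nx.is_directed_acyclic_graph(graph):
            cycle = [u for u, _ in nx.find_cycle(graph)]
            raise CycleError(cycle + [cycle[0]])
        children = {c for _, c in self.edges}
        self.roots = sorted(n for n in graph.nodes if n not in children)

    @property
    def nodes(self) -> list[str]:
        seen: dict[str, None] = {}
        for p, c in self.edges:
            seen.setdefault(p)
            seen.setdefault(c)
        return list(seen)

    def children_of(self, node: str) -> list[str]:
        return [c for p, c in self.edges if p == node]


@dataclass
class SurvivalData:
    """Right-censored follow-up per sample: time > 0 and event in {0, 1}."""

    sample_ids: list[str]
    time: np.ndarray
    event: np.ndarray

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event)
        if not (len(self.sample_ids) == len(self.time) == len(self.event)):
            raise ValidationError("sample_ids, time and event lengths differ")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample IDs in survival table")
        if not np.all(np.isfinite(self.time)) or np.any(self.time <= 0):
            bad = [self.sample_ids[i] for i in np.nonzero(~(self.time > 0))[0][:5]]
            raise ValidationError(f"non-positive survival time for samples {bad}")
        if not np.isin(self.event, (0, 1)).all():
            bad = [self.sample_ids[i] for i in np.nonzero(~np.isin(self.event, (0, 1)))[0][:5]]
            raise ValidationError(f"event indicator not in {{0, 1}} for samples {bad}")
        self.event = self.event.astype(int)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def align_to(self, sample_ids) -> "SurvivalData":
        """Reorder to ``sample_ids``; every requested sample must be present."""
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in index]
        if missing:
            raise ValidationError(f"survival data missing samples: {missing[:5]}")
        idx = [index[s] for s in sample_ids]
        return SurvivalData(list(sample_ids), self.time[idx], self.event[idx])


@dataclass
class GeneIdMapping:
    """Many-to-many (source_id, target_id) pairs, e.g. Ensembl gene -> probe."""

    pairs: list[tuple[str, str]]

    def __post_init__(self):
        if len(set(self.pairs)) != len(self.pairs):
            raise ValidationError("duplicate identical pairs in gene ID mapping")

    def targets_of(self, source: str) -> list[str]:
        return [t for s, t in self.pairs if s == source]

    def as_dict(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for s, t in self.pairs:
            out.setdefault(s, []).append(t)
        return out


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def read_expression(
    path,
    transpose: bool = False,
    duplicate_genes: str = "error",
    missing: str = "error",
) -> ExpressionMatrix:
    """Read a tab-delimited genes x samples matrix (first column = gene IDs).

    Parameters
    ----------
    transpose
        Set when the file is samples x genes.
    duplicate_genes
        ``"error"`` (default) or ``"mean"`` to collapse duplicate gene rows
        by averaging.
    missing
        ``"error"`` (default) or ``"row_mean"`` to impute missing cells with
        the gene's row mean.
    """
    try:
        frame = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except OSError as exc:
        raise FormatError(f"cannot read expression file {path}: {exc}") from exc
    except pd.errors.ParserError as exc:
        raise FormatError(f"ragged or malformed expression file {path}: {exc}") from exc
    if frame.columns.empty or frame.index.name is None and frame.columns.size == 0:
        raise FormatError(f"expression file {path} has no header row")
    if transpose:
        frame = frame.T

    numeric = frame.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & frame.notna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise FormatError(
            f"non-numeric cell {frame.iat[i, j]!r} at gene {frame.index[i]!r}, "
            f"sample {frame.columns[j]!r}"
        )
    if numeric.isna().to_numpy().any():
        if missing == "row_mean":
            numeric = numeric.apply(lambda row: row.fillna(row.mean()), axis=1)
        else:
            i, j = np.argwhere(numeric.isna().to_numpy())[0]
            raise FormatError(
                f"missing value at gene {numeric.index[i]!r}, sample {numeric.columns[j]!r} "
                "(pass missing='row_mean' to impute)"
            )

    if numeric.index.duplicated().any():
        if duplicate_genes == "mean":
            numeric = numeric.groupby(level=0, sort=False).mean()
        else:
            dupes = sorted(set(numeric.index[numeric.index.duplicated()]))[:5]
            raise FormatError(
                f"duplicate gene IDs {dupes} (pass duplicate_genes='mean' to collapse)"
            )

    matrix = ExpressionMatrix.from_frame(numeric.astype(float))
    logger.info("read expression: %d genes x %d samples", matrix.n_genes, matrix.n_samples)
    return matrix


def write_expression(matrix: ExpressionMatrix, path) -> None:
    frame = matrix.to_frame()
    frame.index.name = "gene_id"
    frame.to_csv(path, sep="\t", float_format="%.12g")


def drop_duplicate_samples(matrix: ExpressionMatrix) -> tuple[ExpressionMatrix, list[str]]:
    """Keep the first occurrence of each sample ID; return the removed IDs."""
    seen: set[str] = set()
    keep_idx, removed = [], []
    for j, sid in enumerate(matrix.sample_ids):
        if sid in seen:
            removed.append(sid)
        else:
            seen.add(sid)
            keep_idx.append(j)
    if not removed:
        return matrix, []
    logger.info("removed %d duplicate samples: %s", len(removed), removed[:12])
    kept = ExpressionMatrix(
        gene_ids=list(matrix.gene_ids),
        sample_ids=[matrix.sample_ids[j] for j in keep_idx],
        values=matrix.values[:, keep_idx],
        is_standardized=matrix.is_standardized,
    )
    return kept, removed


# ---------------------------------------------------------------------------
# gene sets (GMT)
# ---------------------------------------------------------------------------

def read_gene_sets(path, min_size: int = 3, max_size: int | None = None) -> PathwayCollection:
    """Read a GMT file: one set per line — ID, description, then member IDs.

    Sets outside [min_size, max_size] are flagged ``excluded_reason`` but kept;
    the size check is repeated after mapping/intersection downstream.
    """
    entries = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(f"{path}:{lineno}: GMT line has fewer than 2 fields")
            pathway_id, name, *genes = fields
            genes = [g for g in genes if g]
            entry = GeneSet(pathway_id, name, genes)
            if entry.size < min_size:
                entry.excluded_reason = f"{entry.size} members (min_size={min_size})"
            elif max_size is not None and entry.size > max_size:
                entry.excluded_reason = f"{entry.size} members exceeds max_size={max_size}"
            entries.append(entry)
    if not entries:
        raise FormatError(f"empty GMT file: {path}")
    logger.info("read %d gene sets (%d flagged by size)", len(entries),
                sum(e.excluded_reason is not None for e in entries))
    return PathwayCollection(entries)


def write_gene_sets(sets: PathwayCollection, path) -> None:
    with open(path, "w") as handle:
        for entry in sets:
            handle.write("\t".join([entry.pathway_id, entry.name, *entry.genes]) + "\n")


def read_mapping(path) -> GeneIdMapping:
    """Read a two-column source<TAB>target mapping table (no header)."""
    pairs: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 tab-separated columns")
            pair = (fields[0], fields[1])
            if pair not in seen:
                seen.add(pair)
                pairs.append(pair)
    if not pairs:
        raise FormatError(f"empty mapping table: {path}")
    return GeneIdMapping(pairs)


def apply_gene_mapping(sets: PathwayCollection, mapping: GeneIdMapping) -> PathwayCollection:
    """Translate every member through the mapping (union over all targets).

    A member with several targets expands to all of them; members with no
    mapping are dropped and counted. Sets emptied by the mapping are flagged.
    """
    if not mapping.pairs:
        raise ValidationError("empty gene ID mapping")
    table = mapping.as_dict()
    out = []
    total_unmapped = 0
    for entry in sets:
        mapped: list[str] = []
        unmapped = 0
        for gene in entry.genes:
            targets = table.get(gene)
            if targets:
                mapped.extend(targets)
            else:
                unmapped += 1
        total_unmapped += unmapped
        new = GeneSet(entry.pathway_id, entry.name, mapped, excluded_reason=entry.excluded_reason)
        if new.size == 0:
            new.excluded_reason = "empty after gene ID mapping"
        if unmapped:
            logger.debug("pathway %s: %d members had no mapping", entry.pathway_id, unmapped)
        out.append(new)
    if total_unmapped:
        logger.info("gene mapping dropped %d unmapped members in total", total_unmapped)
    return PathwayCollection(out)


# ---------------------------------------------------------------------------
# hierarchy
# ---------------------------------------------------------------------------

def read_hierarchy(path) -> PathwayHierarchy:
    """Read parent<TAB>child relations (Reactome relation-file dialect)."""
    edges: list[tuple[str, str]] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2 or not fields[0] or not fields[1]:
                raise FormatError(f"{path}:{lineno}: expected parent<TAB>child")
            edges.append((fields[0], fields[1]))
    if not edges:
        raise FormatError(f"empty hierarchy file: {path}")
    return PathwayHierarchy(edges)


def write_hierarchy(hierarchy: PathwayHierarchy, path) -> None:
    with open(path, "w") as handle:
        for parent, child in hierarchy.edges:
            handle.write(f"{parent}\t{child}\n")


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------

def read_survival(path) -> SurvivalData:
    """Read a 3-column TSV: sample ID, follow-up time, event indicator."""
    try:
        frame = pd.read_csv(path, sep="\t", header=0)
    except (OSError, pd.errors.ParserError) as exc:
        raise FormatError(f"cannot read survival file {path}: {exc}") from exc
    if frame.shape[1] != 3:
        raise FormatError(f"survival file {path} must have 3 columns, found {frame.shape[1]}")
    sample_ids = [str(s) for s in frame.iloc[:, 0]]
    time = pd.to_numeric(frame.iloc[:, 1], errors="coerce")
    event = pd.to_numeric(frame.iloc[:, 2], errors="coerce")
    if time.isna().any() or event.isna().any():
        raise FormatError(f"non-numeric time/event value in {path}")
    return SurvivalData(sample_ids, time.to_numpy(), event.to_numpy())


def write_survival(surv: SurvivalData, path) -> None:
    frame = pd.DataFrame({"sample_id": surv.sample_ids, "time": surv.time, "event": surv.event})
    frame.to_csv(path, sep="\t", index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

RESULT_COLUMNS = ["pathway_id", "name", "size", "beta", "se", "p", "q", "c_index"]


def write_results_table(results, path) -> None:
    """Write per-pathway scan results sorted by (q, p) ascending.

    ``results`` is an iterable of objects exposing the attributes in
    ``RESULT_COLUMNS`` (see :class:`pathsurv.survival_stats.PathwayResult`).
    """
    rows = []
    for r in results:
        rows.append({
            "pathway_id": r.pathway_id,
            "name": getattr(r, "name", ""),
            "size": getattr(r, "n_genes_used", ""),
            "beta": r.beta,
            "se": r.se,
            "p": r.p,
            "q": r.q,
            "c_index": r.c_index if getattr(r, "c_index", None) is not None else "",
        })
    frame = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    if len(frame):
        frame = frame.sort_values(["q", "p"], kind="stable")
    frame.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_results_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
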