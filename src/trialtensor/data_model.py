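"""Containers and I/O for the evidence tensor, outcome matrix and side data.

The central object is a sparse three-mode binary tensor of
target x indication x evidence-source association calls, augmented with one
extra slice holding clinical outcomes (1 = at least one drug succeeded,
0 = all drugs failed in Phase I-III).  Cells absent from the input files are
*unknown*, never implicit zeros: an explicit 0 row is an observed negative.

All files are tab-separated with a header row and use string ids; integer
indices exist only in memory (0-based).
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "EntityRegistry",
    "AugmentedTensor",
    "OutcomeMatrix",
    "TargetAttributes",
    "GroupMap",
    "DatasetSummary",
    "LoadError",
    "binarize_evidence",
    "load_evidence_table",
    "load_outcome_table",
    "load_attribute_table",
    "load_group_table",
    "encode_target_attributes",
    "assemble_tensor",
    "dataset_summary",
    "coverage_percent",
    "mask_outcome_cells",
    "write_evidence_table",
    "write_outcome_table",
    "write_attribute_table",
    "write_group_table",
]


class LoadError(ValueError):
    """A table could not be parsed into a valid container."""


# ---------------------------------------------------------------------------
# registry


@dataclass(frozen=True)
class EntityRegistry:
    """Ordered id lists for the three tensor modes.

    ``M``, ``N``, ``K`` are the number of targets, indications and evidence
    sources; the outcome slice, when present, is slice index ``K``.
    """

    targets: tuple[str, ...]
    indications: tuple[str, ...]
    evidence_sources: tuple[str, ...]

    def __post_init__(self) -> None:
        for name, ids in (
            ("targets", self.targets),
            ("indications", self.indications),
            ("evidence_sources", self.evidence_sources),
        ):
            if len(ids) < 1:
                raise ValueError(f"registry axis {name!r} is empty")
            if len(set(ids)) != len(ids):
                raise ValueError(f"duplicate ids on axis {name!r}")

    @property
    def M(self) -> int:
        return len(self.targets)

    @property
    def N(self) -> int:
        return len(self.indications)

    @property
    def K(self) -> int:
        return len(self.evidence_sources)

    def target_index(self) -> dict[str, int]:
        return {t: i for i, t in enumerate(self.targets)}

    def indication_index(self) -> dict[str, int]:
        return {d: j for j, d in enumerate(self.indications)}

    def evidence_index(self) -> dict[str, int]:
        return {s: k for k, s in enumerate(self.evidence_sources)}


# ---------------------------------------------------------------------------
# tensor / matrix containers


def _dedupe_check(keys: np.ndarray, what: str) -> None:
    if len(keys) and len(np.unique(keys, axis=0)) != len(keys):
        raise ValueError(f"duplicate {what} cells")


@dataclass(frozen=True)
class AugmentedTensor:
    """Sparse binary tensor; slice ``K`` (if ``has_outcome_slice``) is outcomes.

    Cells are parallel arrays ``(i, j, k, value)``; absence means unknown.
    """

    registry: EntityRegistry
    i: np.ndarray
    j: np.ndarray
    k: np.ndarray
    values: np.ndarray
    has_outcome_slice: bool = False

    def __post_init__(self) -> None:
        i = np.asarray(self.i, dtype=np.int64)
        j = np.asarray(self.j, dtype=np.int64)
        k = np.asarray(self.k, dtype=np.int64)
        v = np.asarray(self.values, dtype=np.int8)
        if not (len(i) == len(j) == len(k) == len(v)):
            raise ValueError("cell arrays have unequal lengths")
        n_slices = self.registry.K + (1 if self.has_outcome_slice else 0)
        if len(i):
            if i.min() < 0 or i.max() >= self.registry.M:
                raise ValueError("target index out of range")
            if j.min() < 0 or j.max() >= self.registry.N:
                raise ValueError("indication index out of range")
            if k.min() < 0 or k.max() >= n_slices:
                raise ValueError("slice index out of range")
            if not np.isin(v, (0, 1)).all():
                raise ValueError("cell values must be binary")
        _dedupe_check(np.stack([i, j, k], axis=1), "tensor")
        object.__setattr__(self, "i", i)
        object.__setattr__(self, "j", j)
        object.__setattr__(self, "k", k)
        object.__setattr__(self, "values", v)

    @property
    def n_slices(self) -> int:
        return self.registry.K + (1 if self.has_outcome_slice else 0)

    @property
    def outcome_slice_index(self) -> int:
        if not self.has_outcome_slice:
            raise ValueError("tensor has no outcome slice")
        return self.registry.K

    @property
    def n_cells(self) -> int:
        return len(self.i)

    def outcome_cells(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """``(i, j, value)`` arrays of the outcome slice."""
        m = self.k == self.outcome_slice_index
        return self.i[m], self.j[m], self.values[m]

    def outcome_matrix(self) -> "OutcomeMatrix":
        oi, oj, ov = self.outcome_cells()
        return OutcomeMatrix(self.registry, oi, oj, ov)

    def evidence_only(self) -> "AugmentedTensor":
        m = self.k < self.registry.K
        return AugmentedTensor(
            self.registry, self.i[m], self.j[m], self.k[m], self.values[m], False
        )


@dataclass(frozen=True)
class OutcomeMatrix:
    """Sparse binary clinical-outcome matrix R (1 Succeeded, 0 Clinical Failure)."""

    registry: EntityRegistry
    i: np.ndarray
    j: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        i = np.asarray(self.i, dtype=np.int64)
        j = np.asarray(self.j, dtype=np.int64)
        v = np.asarray(self.values, dtype=np.int8)
        if not (len(i) == len(j) == len(v)):
            raise ValueError("cell arrays have unequal lengths")
        if len(i):
            if i.min() < 0 or i.max() >= self.registry.M:
                raise ValueError("target index out of range")
            if j.min() < 0 or j.max() >= self.registry.N:
                raise ValueError("indication index out of range")
            if not np.isin(v, (0, 1)).all():
                raise ValueError("outcomes must be binary")
        _dedupe_check(np.stack([i, j], axis=1), "outcome")
        object.__setattr__(self, "i", i)
        object.__setattr__(self, "j", j)
        object.__setattr__(self, "values", v)

    @property
    def n_cells(self) -> int:
        return len(self.i)

    def pairs(self) -> np.ndarray:
        return np.stack([self.i, self.j], axis=1) if len(self.i) else np.empty((0, 2), int)


@dataclass(frozen=True)
class TargetAttributes:
    """M x G one-hot matrix of target-only categorical attributes.

    ``columns`` carries ``(source, category)`` metadata per column; within one
    source's column block each row has at most one 1.
    """

    target_ids: tuple[str, ...]
    matrix: np.ndarray
    columns: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=np.int8)
        if m.ndim != 2 or m.shape != (len(self.target_ids), len(self.columns)):
            raise ValueError("attribute matrix shape mismatch")
        if len(m) and not np.isin(m, (0, 1)).all():
            raise ValueError("attributes must be binary")
        for source in {s for s, _ in self.columns}:
            block = m[:, [c for c, (s, _) in enumerate(self.columns) if s == source]]
            if len(m) and block.sum(axis=1).max(initial=0) > 1:
                raise ValueError(f"overlapping categories within source {source!r}")
        object.__setattr__(self, "matrix", m)

    @property
    def G(self) -> int:
        return len(self.columns)

    def as_float(self) -> np.ndarray:
        return self.matrix.astype(np.float64)


@dataclass(frozen=True)
class GroupMap:
    """Entity -> group label for one axis (target classes / indication clusters)."""

    axis: str
    mapping: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.axis not in ("target", "indication"):
            raise ValueError(f"axis must be 'target' or 'indication', got {self.axis!r}")

    def labels(self) -> list[str]:
        return sorted(set(self.mapping.values()))


# ---------------------------------------------------------------------------
# operations


def binarize_evidence(score: float | None) -> int | None:
    """Binarize one association score: positive -> 1, zero -> 0, missing -> missing."""
    if score is None or (isinstance(score, float) and math.isnan(score)):
        return None
    if score < 0:
        raise ValueError(f"negative evidence score {score!r}")
    return 1 if score > 0 else 0


def _registry_from_frame(
    df: pd.DataFrame, registry: EntityRegistry | None
) -> EntityRegistry:
    if registry is not None:
        return registry
    return EntityRegistry(
        tuple(sorted(df["target"].unique())),
        tuple(sorted(df["indication"].unique())),
        tuple(sorted(df["source"].unique())),
    )


def load_evidence_table(
    path: str | Path, registry: EntityRegistry | None = None
) -> AugmentedTensor:
    """Read a long-format evidence table into a (evidence-only) tensor.

    Columns ``target, indication, source, score``; duplicate keys are
    aggregated by maximum after binarization (positive evidence dominates).
    """
    df = _read_tsv(path, ("target", "indication", "source", "score"))
    if df.empty:
        raise LoadError(f"{path}: no data rows")
    scores = pd.to_numeric(df["score"], errors="coerce")
    bad = scores.isna() & df["score"].notna() & (df["score"].astype(str).str.len() > 0)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # 1-based + header
        raise LoadError(f"{path}: unparseable score at row {row}")
    if (scores < 0).any():
        row = int(np.flatnonzero((scores < 0).to_numpy())[0]) + 2
        raise LoadError(f"{path}: negative score at row {row}")
    df = df.assign(value=(scores > 0).astype(int)).dropna(subset=["score"])
    reg = _registry_from_frame(df, registry)
    ti, di, si = reg.target_index(), reg.indication_index(), reg.evidence_index()
    try:
        i = df["target"].map(ti).to_numpy(dtype=np.int64)
        j = df["indication"].map(di).to_numpy(dtype=np.int64)
        k = df["source"].map(si).to_numpy(dtype=np.int64)
    except (TypeError, ValueError) as exc:
        raise LoadError(f"{path}: id not present in registry ({exc})") from exc
    agg = (
        pd.DataFrame({"i": i, "j": j, "k": k, "v": df["value"].to_numpy()})
        .groupby(["i", "j", "k"], as_index=False)["v"]
        .max()
        .sort_values(["k", "i", "j"])
    )
    return AugmentedTensor(
        reg,
        agg["i"].to_numpy(),
        agg["j"].to_numpy(),
        agg["k"].to_numpy(),
        agg["v"].to_numpy(),
        has_outcome_slice=False,
    )


def load_outcome_table(path: str | Path, registry: EntityRegistry) -> OutcomeMatrix:
    df = _read_tsv(path, ("target", "indication", "outcome"))
    ti, di = registry.target_index(), registry.indication_index()
    unknown_t = set(df["target"]) - set(ti)
    unknown_d = set(df["indication"]) - set(di)
    if unknown_t or unknown_d:
        raise LoadError(
            f"{path}: outcome rows reference unregistered entities "
            f"{sorted(unknown_t) + sorted(unknown_d)}"
        )
    v = pd.to_numeric(df["outcome"], errors="coerce")
    if v.isna().any() or not v.isin((0, 1)).all():
        raise LoadError(f"{path}: outcomes must be 0/1")
    return OutcomeMatrix(
        registry,
        df["target"].map(ti).to_numpy(dtype=np.int64),
        df["indication"].map(di).to_numpy(dtype=np.int64),
        v.to_numpy(dtype=np.int8),
    )


def load_attribute_table(path: str | Path) -> pd.DataFrame:
    return _read_tsv(path, ("target", "attribute_source", "category"))


def load_group_table(path: str | Path, axis: str) -> GroupMap:
    df = _read_tsv(path, ("axis", "entity_id", "group"))
    df = df[df["axis"] == axis]
    return GroupMap(axis, dict(zip(df["entity_id"], df["group"])))


def _read_tsv(path: str | Path, required: tuple[str, ...]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise LoadError(f"{path}: empty file") from exc
    except OSError as exc:
        raise LoadError(f"{path}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise LoadError(f"{path}: missing required columns {missing}")
    return df


def encode_target_attributes(
    table: pd.DataFrame,
    target_ids: tuple[str, ...] | list[str],
    vocabularies: dict[str, list[str]] | None = None,
) -> TargetAttributes:
    """One-hot-encode target-only categorical attributes.

    One binary column per category of each attribute source; a target with no
    label for a source gets an all-zero block (unclassified semantics).
    """
    table = table[["target", "attribute_source", "category"]]
    if vocabularies is None:
        vocabularies = {
            s: sorted(table.loc[table["attribute_source"] == s, "category"].unique())
            for s in sorted(table["attribute_source"].unique())
        }
    columns: list[tuple[str, str]] = [
        (s, c) for s in vocabularies for c in vocabularies[s]
    ]
    col_index = {sc: g for g, sc in enumerate(columns)}
    tid_index = {t: i for i, t in enumerate(target_ids)}
    mat = np.zeros((len(target_ids), len(columns)), dtype=np.int8)
    for _, row in table.iterrows():
        t, s, c = row["target"], row["attribute_source"], row["category"]
        if t not in tid_index:
            continue
        if s not in vocabularies:
            raise ValueError(f"unknown attribute source {s!r} for target {t!r}")
        if c not in vocabularies[s]:
            raise ValueError(
                f"label {c!r} outside vocabulary of source {s!r} for target {t!r}"
            )
        mat[tid_index[t], col_index[(s, c)]] = 1
    return TargetAttributes(tuple(target_ids), mat, tuple(columns))


def assemble_tensor(evidence: AugmentedTensor, outcomes: OutcomeMatrix) -> AugmentedTensor:
    """Append the clinical-outcome matrix as the tensor's extra slice."""
    if evidence.has_outcome_slice:
        raise ValueError("evidence tensor already has an outcome slice")
    if outcomes.registry is not evidence.registry and (
        outcomes.registry.targets != evidence.registry.targets
        or outcomes.registry.indications != evidence.registry.indications
    ):
        raise ValueError("evidence and outcomes use different registries")
    K = evidence.registry.K
    i = np.concatenate([evidence.i, outcomes.i])
    j = np.concatenate([evidence.j, outcomes.j])
    k = np.concatenate([evidence.k, np.full(len(outcomes.i), K, dtype=np.int64)])
    v = np.concatenate([evidence.values, outcomes.values])
    return AugmentedTensor(evidence.registry, i, j, k, v, has_outcome_slice=True)


def coverage_percent(n_observed: int, M: int, N: int, n_slices: int) -> float:
    """Observed coverage of an M x N x n_slices tensor, in %, 2 decimals."""
    return round(100.0 * n_observed / (M * N * n_slices), 2)


@dataclass(frozen=True)
class DatasetSummary:
    M: int
    N: int
    n_slices: int
    n_cells: int
    coverage_pct: float
    cells_per_slice: dict[int, int]
    outcome_positive_fraction: float | None


def dataset_summary(tensor: AugmentedTensor) -> DatasetSummary:
    reg = tensor.registry
    per_slice = {
        int(k): int(c) for k, c in zip(*np.unique(tensor.k, return_counts=True))
    }
    pos_frac = None
    if tensor.has_outcome_slice:
        _, _, ov = tensor.outcome_cells()
        pos_frac = float(ov.mean()) if len(ov) else None
    return DatasetSummary(
        M=reg.M,
        N=reg.N,
        n_slices=tensor.n_slices,
        n_cells=tensor.n_cells,
        coverage_pct=coverage_percent(tensor.n_cells, reg.M, reg.N, tensor.n_slices),
        cells_per_slice=per_slice,
        outcome_positive_fraction=pos_frac,
    )


def mask_outcome_cells(
    tensor: AugmentedTensor, pairs: np.ndarray
) -> tuple[AugmentedTensor, np.ndarray]:
    """Remove the given outcome cells; return the training tensor and the labels.

    ``pairs`` is an (n, 2) array of (i, j); every pair must be an observed
    outcome cell.  Labels are returned in the input order of ``pairs``.
    Evidence slices are untouched.
    """
    pairs = np.asarray(pairs, dtype=np.int64).reshape(-1, 2)
    K = tensor.outcome_slice_index
    key = tensor.i * tensor.registry.N + tensor.j
    cell_of: dict[int, int] = {
        int(key[c]): c for c in np.flatnonzero(tensor.k == K)
    }
    drop = np.zeros(tensor.n_cells, dtype=bool)
    labels = np.empty(len(pairs), dtype=np.int8)
    for r, (pi, pj) in enumerate(pairs):
        c = cell_of.get(int(pi) * tensor.registry.N + int(pj))
        if c is None:
            raise ValueError(f"pair ({pi}, {pj}) is not an observed outcome cell")
        drop[c] = True
        labels[r] = tensor.values[c]
    keep = ~drop
    train = AugmentedTensor(
        tensor.registry,
        tensor.i[keep],
        tensor.j[keep],
        tensor.k[keep],
        tensor.values[keep],
        has_outcome_slice=True,
    )
    return train, labels


# ---------------------------------------------------------------------------
# writers (inverse of the loaders; round-trips exactly for padded ids)


def write_evidence_table(tensor: AugmentedTensor, path: str | Path) -> None:
    reg = tensor.registry
    m = tensor.k < reg.K
    pd.DataFrame(
        {
            "target": [reg.targets[i] for i in tensor.i[m]],
            "indication": [reg.indications[j] for j in tensor.j[m]],
            "source": [reg.evidence_sources[k] for k in tensor.k[m]],
            "score": tensor.values[m].astype(float),
        }
    ).to_csv(path, sep="\t", index=False)


def write_outcome_table(outcomes: OutcomeMatrix, path: str | Path) -> None:
    reg = outcomes.registry
    pd.DataFrame(
        {
            "target": [reg.targets[i] for i in outcomes.i],
            "indication": [reg.indications[j] for j in outcomes.j],
            "outcome": outcomes.values.astype(int),
        }
    ).to_csv(path, sep="\t", index=False)


def write_attribute_table(attrs: TargetAttributes, path: str | Path) -> None:
    rows = []
    for r, tid in enumerate(attrs.target_ids):
        for g, (source, category) in enumerate(attrs.columns):
            if attrs.matrix[r, g]:
                rows.append((tid, source, category))
    pd.DataFrame(rows, columns=["target", "attribute_source", "category"]).to_csv(
        path, sep="\t", index=False
    )


def write_group_table(groups: list[GroupMap], path: str | Path) -> None:
    rows = [
        (gm.axis, eid, grp)
        for gm in groups
        for eid, grp in sorted(gm.mapping.items())
    ]
    pd.DataFrame(rows, columns=["axis", "entity_id", "group"]).to_csv(
        path, sep="\t", index=False
    )
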