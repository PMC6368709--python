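"""Nested cross-validation harness over the outcome cells.

Three outer-fold schemes mirror three drug-discovery scenarios:

* ``random_stratified`` — standard k-fold over target-indication pairs,
  each fold keeping the global fraction of successes;
* ``target_group`` — leave one pre-defined target class out entirely
  (can the model generalise to untried target families?);
* ``indication_group`` — leave one indication cluster out entirely.

Inner stratified folds of the training cells drive hyperparameter tuning;
test cells are masked from the tensor before any fitting, so no test label
can influence training or tuning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .data_model import AugmentedTensor, GroupMap, OutcomeMatrix, TargetAttributes, mask_outcome_cells
from .metrics import UndefinedMetricError, auprc, auroc, bootstrap_ci, topk_metrics

__all__ = [
    "FoldSpec",
    "MetricReport",
    "ModelSpec",
    "stratified_random_folds",
    "group_folds",
    "nested_cv",
    "auroc",
    "auprc",
    "topk_metrics",
    "bootstrap_ci",
    "UndefinedMetricError",
]

SCHEMES = ("random_stratified", "target_group", "indication_group")
MODEL_NAMES = ("btf", "soft_impute", "logreg", "l1_logreg", "random_forest", "gradient_boosting")


@dataclass(frozen=True)
class FoldSpec:
    """An ordered partition of the observed outcome cells."""

    scheme: str
    folds: tuple[np.ndarray, ...]  # each an (n, 2) array of (i, j)
    fold_names: tuple[str, ...]
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if len(self.folds) != len(self.fold_names):
            raise ValueError("folds and fold_names length mismatch")

    @property
    def k(self) -> int:
        return len(self.folds)

    def all_cells(self) -> np.ndarray:
        return np.concatenate([f for f in self.folds]) if self.folds else np.empty((0, 2), int)


def stratified_random_folds(outcomes: OutcomeMatrix, k: int, seed: int) -> FoldSpec:
    """Shuffle positives and negatives separately and deal them round-robin."""
    if k < 2:
        raise ValueError("need k >= 2 folds")
    pairs = outcomes.pairs()
    v = outcomes.values
    pos_idx = np.flatnonzero(v == 1)
    neg_idx = np.flatnonzero(v == 0)
    if len(pos_idx) < k or len(neg_idx) < k:
        raise ValueError(
            f"need at least {k} positives and negatives for {k}-fold stratification"
        )
    rng = np.random.default_rng(seed)
    pos_idx = rng.permutation(pos_idx)
    neg_idx = rng.permutation(neg_idx)
    folds = []
    for f in range(k):
        members = np.concatenate([pos_idx[f::k], neg_idx[f::k]])
        folds.append(pairs[np.sort(members)])
    return FoldSpec(
        scheme="random_stratified",
        folds=tuple(folds),
        fold_names=tuple(f"fold_{f:02d}" for f in range(k)),
        seed=seed,
    )


def group_folds(outcomes: OutcomeMatrix, group_map: GroupMap) -> FoldSpec:
    """One fold per pre-defined group, all outcome cells of its entities."""
    reg = outcomes.registry
    ids = reg.targets if group_map.axis == "target" else reg.indications
    ax = outcomes.i if group_map.axis == "target" else outcomes.j
    entity_ids_with_outcomes = {ids[e] for e in np.unique(ax)}
    ungrouped = sorted(entity_ids_with_outcomes - set(group_map.mapping))
    if ungrouped:
        raise ValueError(
            f"{group_map.axis} entities with outcomes but no group: {ungrouped}"
        )
    pairs = outcomes.pairs()
    folds, names = [], []
    for label in group_map.labels():
        members = {e for e, g in group_map.mapping.items() if g == label}
        mask = np.array([ids[e] in members for e in ax])
        if not mask.any():
            warnings.warn(f"group {label!r} has no outcome cells; dropped", stacklevel=2)
            continue
        folds.append(pairs[mask])
        names.append(label)
    scheme = "target_group" if group_map.axis == "target" else "indication_group"
    return FoldSpec(scheme=scheme, folds=tuple(folds), fold_names=tuple(names))


@dataclass(frozen=True)
class MetricReport:
    """Per-fold and aggregate metrics for one model under one fold scheme."""

    model: str
    scheme: str
    per_fold: tuple[dict, ...]
    aggregate: dict
    n: int
    n_positive: int

    def summary_line(self) -> str:
        a = self.aggregate
        return (
            f"{self.model:18s} {self.scheme:18s} "
            f"AUROC {a['auroc_mean']:.3f} ± {a['auroc_sd']:.3f}  "
            f"AUPRC {a['auprc_mean']:.3f} ± {a['auprc_sd']:.3f}"
        )


@dataclass(frozen=True)
class ModelSpec:
    """Which model to benchmark and its tuning/config knobs."""

    name: str
    gibbs: "object | None" = None  # GibbsConfig for btf
    lambda_grid: tuple[float, ...] = (0.5, 1.0, 2.0, 4.0)
    tuning: "object | None" = None  # TuningConfig for tabular models
    rank_grid: tuple[int, ...] | None = None  # inner-CV rank grid for btf

    def __post_init__(self) -> None:
        if self.name not in MODEL_NAMES:
            raise ValueError(f"unknown model {self.name!r}; expected one of {MODEL_NAMES}")


def _fit_and_score_fold(
    spec: ModelSpec,
    tensor: AugmentedTensor,
    attrs: TargetAttributes,
    test_pairs: np.ndarray,
    inner_k: int,
    seed: int,
) -> np.ndarray:
    """Mask the fold's cells, tune on inner folds of the rest, refit, score."""
    from . import baselines, btf

    train_tensor, _ = mask_outcome_cells(tensor, test_pairs)
    train_outcomes = train_tensor.outcome_matrix()
    k_eff = _inner_k_for(train_outcomes, inner_k)

    if spec.name == "btf":
        cfg = spec.gibbs if spec.gibbs is not None else btf.GibbsConfig(D=8)
        cfg = replace(cfg, seed=seed)
        if spec.rank_grid and len(spec.rank_grid) > 1:
            inner = stratified_random_folds(train_outcomes, k_eff, seed)
            d = btf.select_rank(train_tensor, attrs, list(spec.rank_grid), inner, cfg)
            cfg = replace(cfg, D=d)
        cells = np.column_stack(
            [test_pairs, np.full(len(test_pairs), tensor.outcome_slice_index)]
        )
        return btf.run_mcmc(train_tensor, attrs, cfg, cells).mean
    if spec.name == "soft_impute":
        if len(spec.lambda_grid) > 1:
            inner = stratified_random_folds(train_outcomes, k_eff, seed)
            lam = baselines.tune_soft_impute(train_outcomes, spec.lambda_grid, inner)
        else:
            lam = spec.lambda_grid[0]
        result = baselines.soft_impute(train_outcomes, lam)
        return baselines.predict_completion(result, train_outcomes, test_pairs)
    # tabular models
    tuning = spec.tuning if spec.tuning is not None else baselines.TuningConfig(seed=seed)
    train_pairs = train_outcomes.pairs()
    feats = baselines.build_pair_features(train_tensor, attrs, train_pairs)
    scorer = baselines.fit_tabular(feats, train_outcomes.values, spec.name, tuning)
    test_feats = baselines.build_pair_features(train_tensor, attrs, test_pairs)
    return baselines.predict_tabular(scorer, test_feats)


def _inner_k_for(outcomes: OutcomeMatrix, inner_k: int) -> int:
    n_min = int(min((outcomes.values == 1).sum(), (outcomes.values == 0).sum()))
    return max(2, min(inner_k, n_min))


def nested_cv(
    model_spec: ModelSpec,
    tensor: AugmentedTensor,
    attrs: TargetAttributes,
    fold_spec: FoldSpec,
    inner_k: int = 5,
    seed: int = 0,
    topk: int = 30,
    compute_ci: bool = False,
    n_boot: int = 1000,
) -> MetricReport:
    """Outer-fold evaluation with inner-fold tuning; aggregates mean ± sd.

    Folds on which a metric is undefined (single class) are excluded from
    that metric's aggregate with a warning, never imputed.
    """
    outcome_matrix = tensor.outcome_matrix()
    label_of = {
        (int(a), int(b)): int(v)
        for a, b, v in zip(outcome_matrix.i, outcome_matrix.j, outcome_matrix.values)
    }
    per_fold = []
    for f, (name, test_pairs) in enumerate(zip(fold_spec.fold_names, fold_spec.folds)):
        scores = _fit_and_score_fold(
            model_spec, tensor, attrs, test_pairs, inner_k, seed + f
        )
        labels = np.array([label_of[(int(a), int(b))] for a, b in test_pairs])
        entry: dict = {
            "fold": name,
            "n": int(len(labels)),
            "n_positive": int(labels.sum()),
        }
        try:
            entry["auroc"] = auroc(labels, scores)
            entry["auprc"] = auprc(labels, scores)
            p_at_k, r_at_k, f_score = topk_metrics(labels, scores, k=min(topk, len(labels)))
            entry.update(
                {"precision_at_k": p_at_k, "recall_at_k": r_at_k, "f_score": f_score}
            )
            if compute_ci:
                entry["auroc_ci"] = bootstrap_ci(labels, scores, auroc, n_boot, seed + f)
                entry["auprc_ci"] = bootstrap_ci(labels, scores, auprc, n_boot, seed + f)
        except UndefinedMetricError as exc:
            warnings.warn(
                f"fold {name!r}: metric undefined ({exc}); excluded from aggregate",
                stacklevel=2,
            )
            entry["undefined"] = str(exc)
        per_fold.append(entry)
    aggregate: dict = {}
    for m in ("auroc", "auprc", "precision_at_k", "recall_at_k", "f_score"):
        vals = [e[m] for e in per_fold if m in e]
        if vals:
            aggregate[f"{m}_mean"] = float(np.mean(vals))
            aggregate[f"{m}_sd"] = float(np.std(vals, ddof=0))
    return MetricReport(
        model=model_spec.name,
        scheme=fold_spec.scheme,
        per_fold=tuple(per_fold),
        aggregate=aggregate,
        n=int(outcome_matrix.n_cells),
        n_positive=int(outcome_matrix.values.sum()),
    )
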