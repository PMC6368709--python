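"""Comparison models: nuclear-norm matrix completion and tabular learners.

The tabular learners see each (target, indication) pair as one row.  Every
evidence source contributes a ternary feature — no association (0), positive
association (1), unknown — dummy-coded as two binary columns with "unknown"
as the reference level, so an all-missing pair sits at the intercept.
Target-only attribute columns are duplicated across all indications of a
target.

``soft_impute`` is implemented here (iterative SVD with singular-value
soft-thresholding, solving min 1/2 ||P_Omega(R - Z)||_F^2 + lambda ||Z||_*);
the tabular learners wrap scikit-learn / xgboost and only the tuned scorer
is the contract.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from xgboost import XGBClassifier

from .data_model import AugmentedTensor, OutcomeMatrix, TargetAttributes

__all__ = [
    "MODEL_KINDS",
    "PairFeatureTable",
    "CompletionResult",
    "build_pair_features",
    "soft_impute",
    "soft_impute_objective",
    "tune_soft_impute",
    "fit_tabular",
    "predict_tabular",
]

MODEL_KINDS = ("logreg", "l1_logreg", "random_forest", "gradient_boosting")


@dataclass(frozen=True)
class PairFeatureTable:
    """(target, indication) pair rows x (2 per evidence source + G) columns."""

    pairs: np.ndarray  # n x 2
    X: np.ndarray  # n x (2K + G)
    feature_names: tuple[str, ...]


@dataclass(frozen=True)
class CompletionResult:
    Z: np.ndarray  # completed dense M x N score matrix
    lam: float
    iterations: int
    objective_trace: np.ndarray


def build_pair_features(
    tensor: AugmentedTensor, attrs: TargetAttributes, pairs: np.ndarray
) -> PairFeatureTable:
    """Encode pairs as rows: evidence 1 -> (1,0), 0 -> (0,1), unknown -> (0,0)."""
    pairs = np.asarray(pairs, dtype=np.int64).reshape(-1, 2)
    reg = tensor.registry
    if len(pairs):
        if pairs[:, 0].min() < 0 or pairs[:, 0].max() >= reg.M:
            raise ValueError("pair references unregistered target")
        if pairs[:, 1].min() < 0 or pairs[:, 1].max() >= reg.N:
            raise ValueError("pair references unregistered indication")
    K, G = reg.K, attrs.G
    ev = tensor.k < K
    # dense lookup of observed evidence: -1 unknown, else 0/1
    lookup = np.full((reg.M, reg.N, K), -1, dtype=np.int8)
    lookup[tensor.i[ev], tensor.j[ev], tensor.k[ev]] = tensor.values[ev]
    X = np.zeros((len(pairs), 2 * K + G), dtype=np.float64)
    if len(pairs):
        vals = lookup[pairs[:, 0], pairs[:, 1], :]  # n x K
        X[:, 0 : 2 * K : 2] = vals == 1
        X[:, 1 : 2 * K : 2] = vals == 0
        X[:, 2 * K :] = attrs.as_float()[pairs[:, 0]]
    names = tuple(
        f"{reg.evidence_sources[k]}_{flag}" for k in range(K) for flag in ("pos", "neg")
    ) + tuple(f"{s}:{c}" for s, c in attrs.columns)
    return PairFeatureTable(pairs=pairs, X=X, feature_names=names)


def soft_impute_objective(R_obs: np.ndarray, mask: np.ndarray, Z: np.ndarray, lam: float) -> float:
    resid = np.where(mask, R_obs - Z, 0.0)
    nuclear = np.linalg.svd(Z, compute_uv=False).sum()
    return 0.5 * float((resid**2).sum()) + lam * float(nuclear)


def soft_impute(
    outcomes: OutcomeMatrix | np.ndarray,
    lam: float,
    tol: float = 1e-5,
    max_iter: int = 500,
) -> CompletionResult:
    """Matrix completion by iterative SVD soft-thresholding.

    ``outcomes`` is either a sparse binary OutcomeMatrix or a dense float
    array with NaN marking unobserved entries.  Iterates
    ``Z <- S_lambda( P_Omega(R) + P_Omega_perp(Z) )`` from Z = 0, where
    S_lambda shrinks singular values by lambda (clipping at 0), until the
    relative Frobenius change drops below ``tol`` or ``max_iter``.  The
    objective 1/2 ||P_Omega(R - Z)||^2 + lambda ||Z||_* is non-increasing
    across iterations.
    """
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    if isinstance(outcomes, np.ndarray):
        R = np.where(np.isnan(outcomes), 0.0, outcomes.astype(float))
        mask = ~np.isnan(outcomes)
        M, N = R.shape
    else:
        if outcomes.n_cells == 0:
            raise ValueError("empty outcome matrix")
        M, N = outcomes.registry.M, outcomes.registry.N
        R = np.zeros((M, N))
        mask = np.zeros((M, N), dtype=bool)
        R[outcomes.i, outcomes.j] = outcomes.values
        mask[outcomes.i, outcomes.j] = True
    if not mask.any():
        raise ValueError("empty outcome matrix")
    Z = np.zeros((M, N))
    trace = []
    it = 0
    for it in range(1, max_iter + 1):
        filled = np.where(mask, R, Z)
        u, s, vt = np.linalg.svd(filled, full_matrices=False)
        s_shrunk = np.maximum(s - lam, 0.0)
        Z_new = (u * s_shrunk) @ vt
        trace.append(soft_impute_objective(R, mask, Z_new, lam))
        denom = max(np.linalg.norm(Z, "fro"), 1e-12)
        delta = np.linalg.norm(Z_new - Z, "fro") / denom
        Z = Z_new
        if delta < tol:
            break
    return CompletionResult(Z=Z, lam=lam, iterations=it, objective_trace=np.array(trace))


def tune_soft_impute(
    outcomes: OutcomeMatrix,
    lambda_grid,
    inner_folds,
    tol: float = 1e-5,
    max_iter: int = 500,
) -> float:
    """Pick lambda maximizing mean inner-fold AUPRC; ties -> larger lambda."""
    from .metrics import UndefinedMetricError, auprc

    lambda_grid = sorted(set(float(l) for l in lambda_grid))
    if not lambda_grid:
        raise ValueError("empty lambda grid")
    if len(lambda_grid) == 1:
        return lambda_grid[0]
    reg = outcomes.registry
    cell_val = {(int(a), int(b)): int(v) for a, b, v in zip(outcomes.i, outcomes.j, outcomes.values)}
    best_lam, best_score = lambda_grid[-1], -np.inf
    for lam in lambda_grid:
        fold_scores = []
        for fold in inner_folds.folds:
            held = {(int(a), int(b)) for a, b in fold}
            keep = [
                (a, b, v) for (a, b), v in cell_val.items() if (a, b) not in held
            ]
            if not keep:
                continue
            ka, kb, kv = (np.array(x) for x in zip(*keep))
            train = OutcomeMatrix(reg, ka, kb, kv)
            result = soft_impute(train, lam, tol=tol, max_iter=max_iter)
            preds = predict_completion(result, train, fold)
            labels = np.array([cell_val[(int(a), int(b))] for a, b in fold])
            try:
                fold_scores.append(auprc(labels, preds))
            except UndefinedMetricError:
                continue
        score = float(np.mean(fold_scores)) if fold_scores else -np.inf
        if score >= best_score - 1e-12:  # ties resolved toward larger lambda
            if score > best_score + 1e-12 or lam > best_lam:
                best_lam, best_score = lam, max(score, best_score)
    return best_lam


def predict_completion(
    result: CompletionResult, train: OutcomeMatrix, pairs: np.ndarray
) -> np.ndarray:
    """Scores for pairs from a completed matrix.

    A target or indication with no training outcome at all carries no signal
    for pure matrix completion; such pairs get the observed global success
    rate instead of the (arbitrary, near-zero) completed entry.
    """
    pairs = np.asarray(pairs, dtype=np.int64).reshape(-1, 2)
    seen_rows = np.zeros(result.Z.shape[0], dtype=bool)
    seen_cols = np.zeros(result.Z.shape[1], dtype=bool)
    seen_rows[train.i] = True
    seen_cols[train.j] = True
    base_rate = float(train.values.mean())
    out = result.Z[pairs[:, 0], pairs[:, 1]].astype(float)
    cold = ~(seen_rows[pairs[:, 0]] & seen_cols[pairs[:, 1]])
    out[cold] = base_rate
    return out


# ---------------------------------------------------------------------------
# tabular learners


@dataclass(frozen=True)
class TuningConfig:
    """Inner-fold hyperparameter search settings for the tabular learners."""

    inner_k: int = 5
    seed: int = 0
    l1_C_grid: tuple[float, ...] = (0.01, 0.1, 1.0, 10.0)
    rf_n_estimators: int = 300
    gbm_grid: dict | None = None  # overrides the default xgboost grid

    def default_gbm_grid(self) -> dict:
        return {
            "learning_rate": [0.1, 0.3],
            "max_depth": [2, 4],
            "colsample_bytree": [0.7, 1.0],
            "n_estimators": [50, 150],
        }


def fit_tabular(features: PairFeatureTable, labels, model_kind: str, tuning: TuningConfig | None = None):
    """Fit one tuned tabular scorer on pair features.

    logreg: plain logistic regression.  l1_logreg: L1-penalised logistic
    regression, penalty strength tuned on inner stratified folds by average
    precision.  random_forest: feature-subsample size tuned by out-of-bag
    score.  gradient_boosting: xgboost with learning rate, depth, feature
    subsample and iteration count tuned on inner folds.
    """
    if model_kind not in MODEL_KINDS:
        raise ValueError(f"unknown model_kind {model_kind!r}; expected one of {MODEL_KINDS}")
    tuning = tuning or TuningConfig()
    y = np.asarray(labels, dtype=np.int64).ravel()
    X = features.X
    if len(np.unique(y)) < 2:
        raise ValueError("need at least one example of each class")
    n_min = int(min((y == 0).sum(), (y == 1).sum()))
    inner_k = max(2, min(tuning.inner_k, n_min))
    cv = StratifiedKFold(n_splits=inner_k, shuffle=True, random_state=tuning.seed)

    if model_kind == "logreg":
        model = LogisticRegression(C=1e6, max_iter=2000)
        model.fit(X, y)
        return model
    if model_kind == "l1_logreg":
        search = GridSearchCV(
            LogisticRegression(l1_ratio=1.0, solver="liblinear", max_iter=2000),
            {"C": list(tuning.l1_C_grid)},
            scoring="average_precision",
            cv=cv,
        )
        search.fit(X, y)
        return search.best_estimator_
    if model_kind == "random_forest":
        # out-of-bag search over max_features, as in tuneRF
        p = X.shape[1]
        start = max(1, int(np.sqrt(p)))
        grid = sorted({max(1, start // 2), start, min(p, 2 * start)})
        best, best_oob = None, -np.inf
        for mf in grid:
            rf = RandomForestClassifier(
                n_estimators=tuning.rf_n_estimators,
                max_features=mf,
                oob_score=True,
                bootstrap=True,
                random_state=tuning.seed,
                n_jobs=1,
            )
            rf.fit(X, y)
            if rf.oob_score_ > best_oob:
                best, best_oob = rf, rf.oob_score_
        return best
    # gradient_boosting
    grid = tuning.gbm_grid or tuning.default_gbm_grid()
    search = GridSearchCV(
        XGBClassifier(
            objective="binary:logistic",
            eval_metric="logloss",
            random_state=tuning.seed,
            n_jobs=1,
            verbosity=0,
        ),
        grid,
        scoring="average_precision",
        cv=cv,
    )
    search.fit(X, y)
    return search.best_estimator_


def predict_tabular(scorer, features: PairFeatureTable) -> np.ndarray:
    """Probability of success per feature row, in [0, 1]."""
    X = features.X
    if X.shape[0] == 0:
        return np.empty(0)
    n_expected = getattr(scorer, "n_features_in_", X.shape[1])
    if X.shape[1] != n_expected:
        raise ValueError(
            f"feature width {X.shape[1]} does not match training width {n_expected}"
        )
    return scorer.predict_proba(X)[:, 1]
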