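"""Post-fit analyses: precision-anchored ranking of untested pairs,
phase-wise score comparison, and latent-embedding export.

Once a factorization is fitted on all known outcomes, pairs that have never
produced a clinical readout can be ranked by posterior score; a score
threshold anchored at a chosen precision on the cross-validation predictions
(e.g. 0.8) turns the ranking into a shortlist of promoted hypotheses.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .btf import PosteriorSummary
from .data_model import EntityRegistry, GroupMap, OutcomeMatrix

__all__ = [
    "ThresholdResult",
    "RankedHypotheses",
    "threshold_from_precision",
    "rank_untested_pairs",
    "compare_phase_scores",
    "export_latent_embedding",
]

EXACT_MAX_GROUP = 10  # exact rank-sum enumeration up to this group size


@dataclass(frozen=True)
class ThresholdResult:
    attainable: bool
    threshold: float | None
    achieved_precision: float | None
    achieved_recall: float | None
    target_precision: float


@dataclass(frozen=True)
class RankedHypotheses:
    """Untested pairs sorted by posterior mean, with a promotion flag."""

    table: pd.DataFrame  # target, indication, posterior_mean, posterior_sd, promoted
    threshold: float
    threshold_provenance: ThresholdResult | None = None

    @property
    def n_promoted(self) -> int:
        return int(self.table["promoted"].sum())


def threshold_from_precision(
    cv_labels, cv_scores, target_precision: float
) -> ThresholdResult:
    """Smallest score threshold whose CV precision reaches the target.

    Precision at threshold t counts predictions with score >= t; the recall
    at the chosen threshold is returned alongside.  If no threshold attains
    the target precision, an explicit no-threshold result is returned.
    """
    labels = np.asarray(cv_labels, dtype=np.int64).ravel()
    scores = np.asarray(cv_scores, dtype=np.float64).ravel()
    if labels.shape != scores.shape or len(labels) == 0:
        raise ValueError("labels and scores must be non-empty and equal length")
    if labels.sum() == 0:
        raise ValueError("need at least one positive CV example")
    if not (0 < target_precision <= 1):
        raise ValueError("target_precision must be in (0, 1]")
    n_pos = labels.sum()
    best: tuple[float, float, float] | None = None
    for t in np.unique(scores):  # ascending: first hit is the smallest threshold
        pred = scores >= t
        tp = int(labels[pred].sum())
        precision = tp / pred.sum()
        if precision >= target_precision:
            best = (float(t), precision, tp / n_pos)
            break
    if best is None:
        return ThresholdResult(False, None, None, None, target_precision)
    return ThresholdResult(True, best[0], best[1], best[2], target_precision)


def rank_untested_pairs(
    posterior: PosteriorSummary,
    pairs: np.ndarray,
    threshold: float,
    registry: EntityRegistry,
    training_outcomes: OutcomeMatrix,
    provenance: ThresholdResult | None = None,
) -> RankedHypotheses:
    """Rank untested pairs by posterior mean; flag those above the threshold.

    Guards against leakage: a pair with an observed training outcome is
    rejected rather than silently re-ranked.
    """
    pairs = np.asarray(pairs, dtype=np.int64).reshape(-1, 2)
    observed = {(int(a), int(b)) for a, b in training_outcomes.pairs()}
    leaked = [tuple(p) for p in pairs if (int(p[0]), int(p[1])) in observed]
    if leaked:
        raise ValueError(f"pairs with observed outcomes cannot be ranked: {leaked[:5]}")
    cell_pos = {
        (int(i), int(j)): q for q, (i, j, _) in enumerate(posterior.query_cells)
    }
    rows = []
    for a, b in pairs:
        q = cell_pos.get((int(a), int(b)))
        if q is None:
            raise ValueError(f"posterior does not cover pair ({a}, {b})")
        rows.append(
            (
                registry.targets[a],
                registry.indications[b],
                float(posterior.mean[q]),
                float(posterior.sd[q]),
            )
        )
    df = pd.DataFrame(rows, columns=["target", "indication", "posterior_mean", "posterior_sd"])
    df = df.sort_values("posterior_mean", ascending=False, kind="stable").reset_index(drop=True)
    df["promoted"] = df["posterior_mean"] >= threshold
    return RankedHypotheses(table=df, threshold=float(threshold), threshold_provenance=provenance)


def compare_phase_scores(phase_table: pd.DataFrame) -> pd.DataFrame:
    """Pairwise two-sided rank-sum tests of prediction scores between phases.

    Exact enumeration when both groups have <= 10 scores, normal
    approximation with tie correction otherwise.  Empty phases are excluded
    with a warning.  Returns a symmetric p-value matrix (diagonal 1).
    """
    if not {"phase", "score"} <= set(phase_table.columns):
        raise ValueError("phase_table needs 'phase' and 'score' columns")
    groups = {
        str(ph): sub["score"].to_numpy(dtype=float)
        for ph, sub in phase_table.groupby("phase")
    }
    empty = [ph for ph, s in groups.items() if len(s) == 0]
    for ph in empty:
        warnings.warn(f"phase {ph!r} has no scores; excluded", stacklevel=2)
        del groups[ph]
    phases = sorted(groups)
    if len(phases) < 2:
        raise ValueError("need at least two non-empty phases")
    pmat = pd.DataFrame(1.0, index=phases, columns=phases)
    for a, b in itertools.combinations(phases, 2):
        xa, xb = groups[a], groups[b]
        method = "exact" if max(len(xa), len(xb)) <= EXACT_MAX_GROUP else "asymptotic"
        p = float(mannwhitneyu(xa, xb, alternative="two-sided", method=method).pvalue)
        pmat.loc[a, b] = pmat.loc[b, a] = min(p, 1.0)
    return pmat


def export_latent_embedding(
    posterior: PosteriorSummary,
    mode: str,
    registry: EntityRegistry,
    group_map: GroupMap | None = None,
    failure_counts: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Per-entity posterior-mean latent vectors, ready for external 2-D embedding.

    Columns: ``entity_id, group, n_failures, f1..fD``.  Requires the fit to
    have been run with factor archiving enabled.
    """
    if posterior.factor_means is None:
        raise ValueError(
            "no retained factors in this fit; refit with save_factors=True"
        )
    if mode not in posterior.factor_means:
        raise ValueError(f"unknown mode {mode!r}")
    F = posterior.factor_means[mode]  # D x n
    ids = {
        "target": registry.targets,
        "indication": registry.indications,
        "evidence": tuple(registry.evidence_sources) + ("outcome",),
    }[mode]
    D = F.shape[0]
    df = pd.DataFrame(F.T, columns=[f"f{d + 1}" for d in range(D)])
    df.insert(0, "entity_id", list(ids))
    df.insert(1, "group", [group_map.mapping.get(e, "") if group_map else "" for e in ids])
    df.insert(2, "n_failures", [int((failure_counts or {}).get(e, 0)) for e in ids])
    return df
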