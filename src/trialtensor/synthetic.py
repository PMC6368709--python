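"""Seeded synthetic worlds with known low-rank and group structure.

The generator emulates the statistical shape of the real problem — a sparse
binary evidence tensor over targets x indications x sources, a sparse binary
clinical-outcome matrix, one-hot target attributes that carry signal about
the latent target factors, and block-wise target/indication groups that make
within-group outcomes mutually informative — at desk scale, so every
downstream stage is testable without the commercial outcome data.

Generative model (mirrors the factorization model being tested):
``s_ijk = sum_d u*_di v*_dj e*_dk + eps``, cells binarized by a quantile
threshold chosen to hit the requested positive rate, then thinned to the
requested observation density.  Target attributes one-hot-encode the target
group, and the true link matrix maps that indicator to the group's latent
mean, so ``u*_i ~= B*^T g_i`` exactly as the model's prior assumes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .data_model import (
    AugmentedTensor,
    EntityRegistry,
    GroupMap,
    OutcomeMatrix,
    TargetAttributes,
    assemble_tensor,
    write_attribute_table,
    write_evidence_table,
    write_group_table,
    write_outcome_table,
)

__all__ = ["WorldConfig", "SyntheticWorld", "make_world", "plant_group_structure", "world_to_files"]


@dataclass(frozen=True)
class WorldConfig:
    """Study conditions for one synthetic world.

    Defaults are a desk-scale analogue of the real analysis slice
    (875 targets x 574 indications x 17 sources, ~30% of pairs with a known
    outcome within that slice): 60 x 40 x 5 with rank-3 structure, 6 target
    classes and 4 indication clusters.
    """

    M: int = 60
    N: int = 40
    K: int = 5
    G: int = 12
    D_true: int = 3
    evidence_density: float = 0.10
    outcome_density: float = 0.30
    noise_sd: float = 0.1
    link_strength: float = 3.0
    n_target_groups: int = 6
    n_indication_groups: int = 4
    positive_rate_target: float = 0.3
    within_group_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.M, self.N, self.K, self.G, self.D_true) < 1:
            raise ValueError("dimensions must be positive")
        if self.D_true > min(self.M, self.N):
            raise ValueError("D_true must be <= min(M, N)")
        for name, d in (
            ("evidence_density", self.evidence_density),
            ("outcome_density", self.outcome_density),
        ):
            if not (0 < d <= 1):
                raise ValueError(f"{name} must be in (0, 1], got {d}")
        if not (0 < self.positive_rate_target < 1):
            raise ValueError("positive_rate_target must be in (0, 1)")
        if self.noise_sd < 0 or self.link_strength < 0:
            raise ValueError("noise_sd and link_strength must be >= 0")
        if self.n_target_groups < 1 or self.n_indication_groups < 1:
            raise ValueError("need at least one group per axis")
        if self.n_target_groups > self.M:
            raise ValueError("more target groups than targets")
        if self.n_indication_groups > self.N:
            raise ValueError("more indication groups than indications")


@dataclass(frozen=True)
class SyntheticWorld:
    config: WorldConfig
    registry: EntityRegistry
    U_true: np.ndarray  # D_true x M
    V_true: np.ndarray  # D_true x N
    E_true: np.ndarray  # D_true x (K+1)
    B_true: np.ndarray  # G x D_true
    attributes: TargetAttributes
    tensor: AugmentedTensor  # K evidence slices + outcome slice
    outcomes: OutcomeMatrix
    target_groups: GroupMap
    indication_groups: GroupMap
    true_outcome_scores: np.ndarray  # dense M x N continuous scores, outcome slice
    evidence_threshold: float = 0.0
    outcome_threshold: float = 0.0


def _block_assignment(n_entities: int, n_groups: int) -> np.ndarray:
    """Contiguous-block group labels 0..n_groups-1 (first blocks get the remainder)."""
    sizes = np.full(n_groups, n_entities // n_groups, dtype=int)
    sizes[: n_entities % n_groups] += 1
    return np.repeat(np.arange(n_groups), sizes)


def _group_means(n_groups: int, D: int, link_strength: float) -> np.ndarray:
    """n_groups x D means whose pairwise distances are >= link_strength.

    Group g sits at ``link_strength * (g // D + 1)`` along axis ``g % D``:
    distinct groups on the same axis differ by at least one step of
    ``link_strength``; groups on different axes are separated by the
    hypotenuse of two such steps.
    """
    means = np.zeros((n_groups, D))
    for g in range(n_groups):
        means[g, g % D] = link_strength * (g // D + 1)
    return means


def plant_group_structure(config: WorldConfig) -> tuple[GroupMap, GroupMap, np.ndarray, np.ndarray]:
    """Deterministic contiguous-block group maps and separated group means."""
    t_assign = _block_assignment(config.M, config.n_target_groups)
    d_assign = _block_assignment(config.N, config.n_indication_groups)
    t_map = GroupMap(
        "target",
        {f"T{i:04d}": f"class_{t_assign[i]:02d}" for i in range(config.M)},
    )
    d_map = GroupMap(
        "indication",
        {f"D{j:04d}": f"cluster_{d_assign[j]:02d}" for j in range(config.N)},
    )
    return t_map, d_map, t_assign, d_assign


def make_world(config: WorldConfig) -> SyntheticWorld:
    """Generate one world as a pure function of its config."""
    rng = np.random.default_rng(config.seed)
    M, N, K, D = config.M, config.N, config.K, config.D_true

    registry = EntityRegistry(
        tuple(f"T{i:04d}" for i in range(M)),
        tuple(f"D{j:04d}" for j in range(N)),
        tuple(f"S{k:02d}" for k in range(K)),
    )
    t_map, d_map, t_assign, d_assign = plant_group_structure(config)

    # group means separated by >= link_strength; entities scatter around them
    t_means = _group_means(config.n_target_groups, D, config.link_strength)
    d_means = _group_means(config.n_indication_groups, D, config.link_strength)

    # attributes: one-hot group indicator in the first n_target_groups columns,
    # padded with inert binary columns up to G; B* maps indicator -> group mean
    G = max(config.G, config.n_target_groups)
    attr_mat = np.zeros((M, G), dtype=np.int8)
    attr_mat[np.arange(M), t_assign] = 1
    if G > config.n_target_groups:
        attr_mat[:, config.n_target_groups :] = rng.integers(
            0, 2, size=(M, G - config.n_target_groups)
        )
    columns = tuple(
        ("target_class", f"class_{g:02d}") for g in range(config.n_target_groups)
    ) + tuple(
        (f"extra_{c:02d}", "present") for c in range(G - config.n_target_groups)
    )
    attributes = TargetAttributes(registry.targets, attr_mat, columns)
    B_true = np.zeros((G, D))
    B_true[: config.n_target_groups] = t_means

    U = (B_true.T @ attr_mat[:, :].astype(float).T)  # D x M, = group mean per target
    U = U + rng.normal(0.0, config.within_group_sd, size=(D, M))
    V = d_means[d_assign].T + rng.normal(0.0, config.within_group_sd, size=(D, N))
    E = rng.normal(0.0, 1.0, size=(D, K + 1))

    # continuous CP scores + observation noise
    scores = np.einsum("dm,dn,dk->mnk", U, V, E)
    if config.noise_sd > 0:
        scores = scores + rng.normal(0.0, config.noise_sd, size=scores.shape)

    ev_scores = scores[:, :, :K]
    out_scores = scores[:, :, K]
    ev_thresh = float(np.quantile(ev_scores, 1 - config.positive_rate_target))
    out_thresh = float(np.quantile(out_scores, 1 - config.positive_rate_target))

    # thin to the stated densities: exactly ceil(density * cells) per slice set
    n_ev = math.ceil(config.evidence_density * M * N * K)
    ev_flat = rng.choice(M * N * K, size=n_ev, replace=False)
    ei, ej, ek = np.unravel_index(np.sort(ev_flat), (M, N, K))
    ev_vals = (ev_scores[ei, ej, ek] > ev_thresh).astype(np.int8)

    n_out = math.ceil(config.outcome_density * M * N)
    out_flat = rng.choice(M * N, size=n_out, replace=False)
    oi, oj = np.unravel_index(np.sort(out_flat), (M, N))
    out_vals = (out_scores[oi, oj] > out_thresh).astype(np.int8)

    evidence = AugmentedTensor(registry, ei, ej, ek, ev_vals, has_outcome_slice=False)
    outcomes = OutcomeMatrix(registry, oi, oj, out_vals)
    tensor = assemble_tensor(evidence, outcomes)

    return SyntheticWorld(
        config=config,
        registry=registry,
        U_true=U,
        V_true=V,
        E_true=E,
        B_true=B_true,
        attributes=attributes,
        tensor=tensor,
        outcomes=outcomes,
        target_groups=t_map,
        indication_groups=d_map,
        true_outcome_scores=out_scores,
        evidence_threshold=ev_thresh,
        outcome_threshold=out_thresh,
    )


def world_to_files(world: SyntheticWorld, directory) -> dict[str, str]:
    """Write the world's tables in the package's TSV dialects; round-trips exactly."""
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "evidence": directory / "evidence.tsv",
        "outcomes": directory / "outcomes.tsv",
        "attributes": directory / "attributes.tsv",
        "groups": directory / "groups.tsv",
    }
    write_evidence_table(world.tensor, paths["evidence"])
    write_outcome_table(world.outcomes, paths["outcomes"])
    write_attribute_table(world.attributes, paths["attributes"])
    write_group_table([world.target_groups, world.indication_groups], paths["groups"])
    return {k: str(v) for k, v in paths.items()}
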