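"""Bayesian CP tensor factorization with target side information.

The model (Macau-style): each observed tensor cell is Gaussian around a CP
score,

    x_ijk ~ N( sum_d u_di v_dj e_dk , alpha^{-1} ),

with conjugate Gaussian priors per mode,

    u_i ~ N( mu_t + B^T g_i , Lambda_t^{-1} )      (targets, with side info)
    v_j ~ N( mu_d , Lambda_d^{-1} )                (indications)
    e_k ~ N( mu_e , Lambda_e^{-1} )                (evidence slices + outcome)

and a Normal-Wishart hyperprior on each mode's (mu, Lambda).  The link
matrix B in R^{G x D} projects target-only one-hot attributes g_i into the
latent space, which is what lets the model score targets that have no
observed outcomes.  Entries of B carry an i.i.d. N(0, 1/lambda_B) prior, so
its full conditional is a (matrix-)Gaussian ridge posterior.

Inference is plain Gibbs sampling; every update below is the exact full
conditional, so the chain's stationary distribution is the joint posterior.
Predictions for a query cell are the posterior mean of the CP score
1^T (u_i o v_j o e_k) over the retained sweeps.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.linalg import cho_factor, cho_solve, cholesky, solve_triangular
from scipy.stats import wishart

from .data_model import AugmentedTensor, TargetAttributes

__all__ = [
    "GibbsConfig",
    "LatentState",
    "PosteriorSummary",
    "init_state",
    "sample_mode_vectors",
    "sample_hyperparameters",
    "sample_link_matrix",
    "run_mcmc",
    "predict_cp",
    "select_rank",
]

MODES = ("target", "indication", "evidence")


@dataclass(frozen=True)
class GibbsConfig:
    """Sampler settings; chain-length defaults follow the reference analysis
    (500 burn-in sweeps discarded, 300 retained; observation precision 1)."""

    D: int
    burn_in: int = 500
    n_samples: int = 300
    alpha: float = 1.0
    mu0: float = 0.0
    beta0: float = 2.0
    nu0: int | None = None  # defaults to D
    lambda_b: float = 1.0
    seed: int = 0
    save_factors: bool = False

    def __post_init__(self) -> None:
        if self.D < 1:
            raise ValueError("latent dimension D must be >= 1")
        if self.burn_in < 0 or self.n_samples < 0:
            raise ValueError("burn_in and n_samples must be >= 0")
        if self.alpha <= 0:
            raise ValueError("observation precision alpha must be > 0")
        if self.nu0 is not None and self.nu0 < self.D:
            raise ValueError("Wishart degrees of freedom nu0 must be >= D")
        if self.lambda_b <= 0:
            raise ValueError("link-matrix prior precision lambda_b must be > 0")

    @property
    def nu0_eff(self) -> int:
        return self.D if self.nu0 is None else self.nu0


@dataclass
class LatentState:
    """Factor matrices, link matrix and per-mode Gaussian hyperparameters."""

    U: np.ndarray  # D x M
    V: np.ndarray  # D x N
    E: np.ndarray  # D x (K+1)
    B: np.ndarray  # G x D
    mu: dict[str, np.ndarray] = field(default_factory=dict)  # mode -> D
    Lam: dict[str, np.ndarray] = field(default_factory=dict)  # mode -> D x D

    def factor(self, mode: str) -> np.ndarray:
        return {"target": self.U, "indication": self.V, "evidence": self.E}[mode]


@dataclass(frozen=True)
class PosteriorSummary:
    """Per-query-cell posterior of the CP score over retained Gibbs sweeps."""

    query_cells: np.ndarray  # Q x 3 (i, j, k)
    samples: np.ndarray  # n_samples x Q
    mean: np.ndarray  # Q
    sd: np.ndarray  # Q
    factor_means: dict[str, np.ndarray] | None = None

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]


# ---------------------------------------------------------------------------
# cell indexing: group observed cells by entity per mode, once per fit


class _CellIndex:
    """Observed cells grouped by entity along each mode."""

    def __init__(self, tensor: AugmentedTensor):
        self.i = tensor.i
        self.j = tensor.j
        self.k = tensor.k
        self.x = tensor.values.astype(np.float64)
        reg = tensor.registry
        self.sizes = {
            "target": reg.M,
            "indication": reg.N,
            "evidence": tensor.n_slices,
        }
        self._by_mode: dict[str, list[np.ndarray]] = {}
        for mode, axis in (("target", self.i), ("indication", self.j), ("evidence", self.k)):
            order = np.argsort(axis, kind="stable")
            bounds = np.searchsorted(axis[order], np.arange(self.sizes[mode] + 1))
            self._by_mode[mode] = [
                order[bounds[e] : bounds[e + 1]] for e in range(self.sizes[mode])
            ]

    def cells_of(self, mode: str, entity: int) -> np.ndarray:
        return self._by_mode[mode][entity]


def predict_cp(u: np.ndarray, v: np.ndarray, e: np.ndarray) -> float:
    """CP score 1^T (u o v o e) = sum_d u_d v_d e_d."""
    u, v, e = np.asarray(u, float), np.asarray(v, float), np.asarray(e, float)
    if not (u.shape == v.shape == e.shape) or u.ndim != 1:
        raise ValueError("u, v, e must be 1-d vectors of equal length")
    return float(np.sum(u * v * e))


def init_state(
    tensor: AugmentedTensor,
    attrs: TargetAttributes,
    config: GibbsConfig,
    rng: np.random.Generator | None = None,
) -> LatentState:
    """Factors at N(0, 1/D)-scaled draws, hyperparameters at prior means, B = 0."""
    reg = tensor.registry
    if len(attrs.target_ids) != reg.M:
        raise ValueError(
            f"attributes cover {len(attrs.target_ids)} targets, tensor has {reg.M}"
        )
    rng = np.random.default_rng(config.seed) if rng is None else rng
    D = config.D
    scale = 1.0 / np.sqrt(D)
    state = LatentState(
        U=rng.normal(0, scale, size=(D, reg.M)),
        V=rng.normal(0, scale, size=(D, reg.N)),
        E=rng.normal(0, scale, size=(D, tensor.n_slices)),
        B=np.zeros((attrs.G, D)),
    )
    for mode in MODES:
        state.mu[mode] = np.full(D, config.mu0)
        state.Lam[mode] = np.eye(D) * config.nu0_eff  # E[Wishart(W0=I, nu0)]
    return state


def _prior_means(state: LatentState, mode: str, attrs: TargetAttributes) -> np.ndarray:
    """Per-entity prior mean vectors, D x n_entities."""
    n = state.factor(mode).shape[1]
    m = np.tile(state.mu[mode][:, None], (1, n))
    if mode == "target":
        m = m + state.B.T @ attrs.as_float().T
    return m


def sample_mode_vectors(
    state: LatentState,
    index: _CellIndex,
    mode: str,
    config: GibbsConfig,
    attrs: TargetAttributes,
    rng: np.random.Generator,
) -> np.ndarray:
    """Redraw every entity vector of one mode from its exact full conditional.

    For entity ``a`` with observed cells ``c`` and companion products
    ``q_c`` (elementwise product of the other two modes' vectors), the
    conditional is Gaussian with precision ``P = Lambda + alpha sum q q^T``
    and mean ``P^{-1} (Lambda m + alpha sum x q)``.  An entity with no
    observed cells is drawn from its prior.
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}")
    F = state.factor(mode)
    D = F.shape[0]
    Lam = state.Lam[mode]
    prior_m = _prior_means(state, mode, attrs)
    others = {
        "target": (state.V, state.E, index.j, index.k),
        "indication": (state.U, state.E, index.i, index.k),
        "evidence": (state.U, state.V, index.i, index.j),
    }[mode]
    A, C, ax_a, ax_c = others
    new = np.empty_like(F)
    alpha = config.alpha
    for a in range(F.shape[1]):
        cells = index.cells_of(mode, a)
        if len(cells) == 0:
            P = Lam
            rhs = Lam @ prior_m[:, a]
        else:
            Q = A[:, ax_a[cells]] * C[:, ax_c[cells]]  # D x n_cells
            P = Lam + alpha * (Q @ Q.T)
            rhs = Lam @ prior_m[:, a] + alpha * (Q @ index.x[cells])
        try:
            cf = cho_factor(P, lower=True)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - numerically impossible
            raise FloatingPointError(f"non-PD conditional precision for {mode} {a}") from exc
        mean = cho_solve(cf, rhs)
        z = rng.standard_normal(D)
        new[:, a] = mean + solve_triangular(cf[0].T, z, lower=False)
    return new


def sample_hyperparameters(
    state: LatentState,
    mode: str,
    config: GibbsConfig,
    attrs: TargetAttributes,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (mu, Lambda) for one mode from its Normal-Wishart full conditional.

    For targets the conditioning vectors are the side-information residuals
    ``u_i - B^T g_i`` so that mu_target models what the attributes do not.
    """
    D = config.D
    F = state.factor(mode)
    if mode == "target":
        F = F - state.B.T @ attrs.as_float().T
    n = F.shape[1]
    mu0 = np.full(D, config.mu0)
    beta0, nu0 = config.beta0, config.nu0_eff
    W0_inv = np.eye(D)  # W0 = I
    if n == 0:
        Lam = wishart.rvs(df=nu0, scale=np.eye(D), random_state=rng).reshape(D, D)
        mu = rng.multivariate_normal(mu0, np.linalg.inv(beta0 * Lam))
        return mu, Lam
    fbar = F.mean(axis=1)
    S = (F - fbar[:, None]) @ (F - fbar[:, None]).T
    dev = (fbar - mu0)[:, None]
    W_star_inv = W0_inv + S + (beta0 * n / (beta0 + n)) * (dev @ dev.T)
    W_star = np.linalg.inv(W_star_inv)
    W_star = (W_star + W_star.T) / 2
    Lam = wishart.rvs(df=nu0 + n, scale=W_star, random_state=rng).reshape(D, D)
    beta_star = beta0 + n
    mu_star = (beta0 * mu0 + n * fbar) / beta_star
    cov = np.linalg.inv(beta_star * Lam)
    mu = rng.multivariate_normal(mu_star, (cov + cov.T) / 2)
    return mu, Lam


def sample_link_matrix(
    state: LatentState,
    attrs: TargetAttributes,
    config: GibbsConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw B from its Gaussian full conditional (ridge posterior).

    With ``u_i - mu_t = B^T g_i + eps_i``, ``eps ~ N(0, Lambda_t^{-1})`` and
    prior ``B_gd ~ N(0, 1/lambda_B)``, rotating the latent axes to the
    eigenbasis of Lambda_t decouples the rows: each rotated row of ``B^T``
    is an independent ridge regression of the rotated residuals on the
    attributes.  The i.i.d. prior is rotation invariant, so rotating back
    yields an exact draw.
    """
    G, D = attrs.G, config.D
    if G < 1:
        raise ValueError("need at least one attribute column")
    Fmat = attrs.as_float()  # M x G
    R = state.U - state.mu["target"][:, None]  # D x M residuals about mu_t
    Lam = state.Lam["target"]
    evals, Q = np.linalg.eigh(Lam)
    Rp = Q.T @ R  # rotated residuals, D x M
    FtF = Fmat.T @ Fmat  # G x G
    Bp = np.empty((D, G))
    for d in range(D):
        P = evals[d] * FtF + config.lambda_b * np.eye(G)
        rhs = evals[d] * (Fmat.T @ Rp[d])
        cf = cho_factor(P, lower=True)
        mean = cho_solve(cf, rhs)
        z = rng.standard_normal(G)
        Bp[d] = mean + solve_triangular(cf[0].T, z, lower=False)
    return (Q @ Bp).T  # back to original axes; G x D


def _cp_scores(state: LatentState, cells: np.ndarray) -> np.ndarray:
    i, j, k = cells[:, 0], cells[:, 1], cells[:, 2]
    return np.einsum("dq,dq,dq->q", state.U[:, i], state.V[:, j], state.E[:, k])


def run_mcmc(
    tensor: AugmentedTensor,
    attrs: TargetAttributes,
    config: GibbsConfig,
    query_cells: np.ndarray,
) -> PosteriorSummary:
    """Run ``burn_in + n_samples`` full Gibbs sweeps and summarise predictions.

    Sweep order: per-mode hyperparameters, link matrix, then U, V, E.  After
    burn-in the CP score of every query cell is recorded each sweep; the
    summary holds the per-cell mean and sd over the retained sweeps, plus
    posterior-mean factors when ``save_factors`` is set.
    """
    if config.n_samples < 1:
        raise ValueError("n_samples must be >= 1 (nothing to average otherwise)")
    query_cells = np.asarray(query_cells, dtype=np.int64).reshape(-1, 3)
    if len(query_cells):
        if query_cells[:, 0].max() >= tensor.registry.M or query_cells[:, 0].min() < 0:
            raise ValueError("query target index out of range")
        if query_cells[:, 1].max() >= tensor.registry.N or query_cells[:, 1].min() < 0:
            raise ValueError("query indication index out of range")
        if query_cells[:, 2].max() >= tensor.n_slices or query_cells[:, 2].min() < 0:
            raise ValueError("query slice index out of range")
    rng = np.random.default_rng(config.seed)
    index = _CellIndex(tensor)
    state = init_state(tensor, attrs, config, rng)
    draws = np.empty((config.n_samples, len(query_cells)))
    fsum = (
        {m: np.zeros_like(state.factor(m)) for m in MODES} if config.save_factors else None
    )
    for sweep in range(config.burn_in + config.n_samples):
        for mode in MODES:
            state.mu[mode], state.Lam[mode] = sample_hyperparameters(
                state, mode, config, attrs, rng
            )
        state.B = sample_link_matrix(state, attrs, config, rng)
        state.U = sample_mode_vectors(state, index, "target", config, attrs, rng)
        state.V = sample_mode_vectors(state, index, "indication", config, attrs, rng)
        state.E = sample_mode_vectors(state, index, "evidence", config, attrs, rng)
        s = sweep - config.burn_in
        if s >= 0:
            draws[s] = _cp_scores(state, query_cells)
            if fsum is not None:
                for m in MODES:
                    fsum[m] += state.factor(m)
    factor_means = (
        {m: fsum[m] / config.n_samples for m in MODES} if fsum is not None else None
    )
    return PosteriorSummary(
        query_cells=query_cells,
        samples=draws,
        mean=draws.mean(axis=0),
        sd=draws.std(axis=0, ddof=0),
        factor_means=factor_means,
    )


def select_rank(
    tensor: AugmentedTensor,
    attrs: TargetAttributes,
    grid: list[int],
    inner_folds,
    config: GibbsConfig,
) -> int:
    """Pick the latent dimension maximizing mean inner-fold AUPRC (ties -> smallest)."""
    from .data_model import mask_outcome_cells
    from .metrics import UndefinedMetricError, auprc

    if not grid:
        raise ValueError("empty rank grid")
    grid = sorted(set(grid))
    if len(grid) == 1:
        return grid[0]
    K_out = tensor.outcome_slice_index
    best_d, best_score = grid[0], -np.inf
    for d in grid:
        scores = []
        for fold in inner_folds.folds:
            train, labels = mask_outcome_cells(tensor, fold)
            cells = np.column_stack([fold, np.full(len(fold), K_out)])
            cfg = replace(config, D=d)
            summary = run_mcmc(train, attrs, cfg, cells)
            try:
                scores.append(auprc(labels, summary.mean))
            except UndefinedMetricError:
                continue
        mean_score = float(np.mean(scores)) if scores else -np.inf
        if mean_score > best_score + 1e-12:
            best_d, best_score = d, mean_score
    return best_d
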