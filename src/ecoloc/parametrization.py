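"""Interaction matrix W and community matrix Φ for mutualistic dynamics.

Off-diagonal mutualistic weights follow a degree trade-off,

    W_ij = γ0 · B_ij / k_i^δ ,      W_ii = −d_i ,

where ``B`` is the (block) adjacency, ``k_i`` the species degree, ``γ0`` the
basal mutualistic strength and ``δ`` the trade-off exponent: δ=0 is the
mean-field case with constant interaction strength, δ>0 makes specialists
interact more strongly, δ<0 favours generalists.  The species strength
``s_i = Σ_{j≠i} W_ij`` is the weighted degree.

Linearizing Holling Type I population dynamics around the stationary state
``x*`` yields the community matrix

    Φ = diag(x*) · W ,

whose off-diagonal entries are nonnegative (so the Perron–Frobenius theorem
applies to the leading mode) and whose diagonal is ``−x*_i d_i < 0``.
Stationary abundances are i.i.d. Gamma with configurable mean and standard
deviation (mean 1 by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .network_io import BipartiteNetwork, to_adjacency

__all__ = [
    "ParamConfig",
    "InteractionMatrix",
    "CommunityMatrix",
    "build_interaction_matrix",
    "sample_abundances",
    "build_community_matrix",
    "parametrize",
]


@dataclass(frozen=True)
class ParamConfig:
    """Parametrization of the community matrix.

    Attributes
    ----------
    gamma0
        Basal mutualistic strength γ0 > 0.
    delta
        Degree trade-off exponent δ (scenarios −0.5, 0, 0.5).
    d
        Intraspecific competition, scalar broadcast or length-S vector, > 0.
    abundance_mean, abundance_sd
        Target mean and sd of the stationary-abundance Gamma distribution.
    seed
        Seed for the abundance draw.
    """

    gamma0: float = 1.0
    delta: float = 0.0
    d: float | np.ndarray = 3.5
    abundance_mean: float = 1.0
    abundance_sd: float = 0.15
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.gamma0 <= 0:
            raise ValueError("gamma0 must be > 0")
        if np.any(np.asarray(self.d) <= 0):
            raise ValueError("d must be > 0")
        if self.abundance_mean <= 0 or self.abundance_sd < 0:
            raise ValueError("abundance_mean > 0 and abundance_sd >= 0 required")

    def with_seed(self, seed: int | None) -> "ParamConfig":
        return replace(self, seed=seed)


@dataclass(frozen=True)
class InteractionMatrix:
    W: np.ndarray
    strengths: np.ndarray  # s_i = off-diagonal row sums


@dataclass(frozen=True)
class CommunityMatrix:
    Phi: np.ndarray
    abundances: np.ndarray


def build_interaction_matrix(net: BipartiteNetwork, cfg: ParamConfig) -> InteractionMatrix:
    """W_ij = γ0·adj_ij / k_i^δ off-diagonal; −d_i on the diagonal."""
    adj = to_adjacency(net).astype(float)
    k = net.degrees().astype(float)
    if (k == 0).any():
        raise ValueError("zero-degree species: weights 1/k^delta undefined")
    W = cfg.gamma0 * adj / (k[:, None] ** cfg.delta)
    s = W.sum(axis=1)  # diagonal still zero here
    d = np.broadcast_to(np.asarray(cfg.d, dtype=float), (net.S,))
    np.fill_diagonal(W, -d)
    return InteractionMatrix(W=W, strengths=s)


def sample_abundances(S: int, cfg: ParamConfig) -> np.ndarray:
    """I.i.d. Gamma stationary abundances with the configured mean and sd.

    Moment matching: shape = mean²/sd², scale = sd²/mean.  ``sd = 0``
    degenerates to the constant vector.
    """
    if cfg.abundance_sd == 0:
        return np.full(S, cfg.abundance_mean)
    shape = cfg.abundance_mean**2 / cfg.abundance_sd**2
    scale = cfg.abundance_sd**2 / cfg.abundance_mean
    rng = np.random.default_rng(cfg.seed)
    return stats.gamma.rvs(shape, scale=scale, size=S, random_state=rng)


def build_community_matrix(W: InteractionMatrix | np.ndarray, x_star: np.ndarray) -> CommunityMatrix:
    """Φ = diag(x*)·W — each row of W scaled by the focal species' abundance."""
    Wm = W.W if isinstance(W, InteractionMatrix) else np.asarray(W, dtype=float)
    x = np.asarray(x_star, dtype=float)
    if x.shape != (Wm.shape[0],):
        raise ValueError("x_star length must match W")
    if (x <= 0).any():
        raise ValueError("stationary abundances must be positive")
    return CommunityMatrix(Phi=x[:, None] * Wm, abundances=x)


def parametrize(
    net: BipartiteNetwork, cfg: ParamConfig, rng: np.random.Generator | None = None
) -> tuple[InteractionMatrix, CommunityMatrix]:
    """Convenience: W, fresh abundance draw, Φ in one call.

    An explicit ``rng`` overrides ``cfg.seed`` (used by null-model ensembles
    to draw fresh abundances per realization).
    """
    W = build_interaction_matrix(net, cfg)
    if rng is not None and cfg.abundance_sd > 0:
        shape = cfg.abundance_mean**2 / cfg.abundance_sd**2
        scale = cfg.abundance_sd**2 / cfg.abundance_mean
        x = stats.gamma.rvs(shape, scale=scale, size=net.S, random_state=rng)
    else:
        x = sample_abundances(net.S, cfg)
    return W, build_community_matrix(W, x)


def warn_if_unstable(lambda1: float) -> None:
    """The framework assumes a stable equilibrium; warn (not error) otherwise,
    since stability is tuned through γ0 and d."""
    if lambda1 >= 0:
        warnings.warn(
            f"leading eigenvalue {lambda1:.4g} >= 0: equilibrium not stable "
            "under this parametrization (tune gamma0/d)"
        )
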