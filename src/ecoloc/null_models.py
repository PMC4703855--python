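"""Randomization ensembles for bipartite networks and relative statistics.

Two null models:

NM1
    the L links are re-assigned at random, keeping the network connected
    (size and connectance preserved, degree heterogeneity destroyed).
NM2
    the links are re-assigned while constraining the full degree sequence
    (k_1 … k_S), via degree-preserving checkerboard swaps.

For a statistic T (an IPR, the leading amplitude, λ1, λ_H) the ensemble
yields the ratio T_obs/⟨T_ran⟩ and an empirical one-sided p-value with the
(r+1)/(n+1) correction.  The relative IPR, rIPR = IPR/⟨IPR_ran⟩, declares a
network *localized* when rIPR > 1 with p < 0.05; the relative amplitude
declares *attenuation* when A1/⟨A1_ran⟩ < 1 with p < 0.05.  Each null
realization re-randomizes the topology and re-parametrizes the community
matrix with a fresh stationary-abundance draw.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .network_io import BipartiteNetwork
from .parametrization import ParamConfig, parametrize
from .synthetic import GeneratorSpec, connected_random_bipartite

__all__ = [
    "NullEnsembleResult",
    "nm1_randomize",
    "nm2_randomize",
    "null_ensemble",
    "ripr",
    "STATISTICS",
]

STATISTICS = ("ipr_v1", "ipr_u1", "ipr_wH", "amplitude_A1", "lambda1", "lambdaH")


@dataclass
class NullEnsembleResult:
    statistic_name: str
    observed: float
    null_values: np.ndarray
    null_mean: float
    null_sd: float
    ratio: float
    p_value: float
    n_realizations: int
    model: str
    seed: int | None
    alternative: str = "greater"

    @property
    def significant(self) -> bool:
        """Localization (ratio > 1) or attenuation (ratio < 1) at p < 0.05,
        depending on the alternative."""
        if self.alternative == "greater":
            return self.ratio > 1 and self.p_value < 0.05
        return self.ratio < 1 and self.p_value < 0.05

    def to_dict(self, include_null: bool = False) -> dict:
        out = {
            "statistic": self.statistic_name,
            "observed": self.observed,
            "null_mean": self.null_mean,
            "null_sd": self.null_sd,
            "ratio": self.ratio,
            "p_value": self.p_value,
            "n": self.n_realizations,
            "model": self.model,
            "alternative": self.alternative,
        }
        if include_null:
            out["null_values"] = self.null_values.tolist()
        return out


def nm1_randomize(net: BipartiteNetwork, seed: int | None = None) -> BipartiteNetwork:
    """Null model 1: same A, P, L; links uniform subject to connectivity."""
    spec = GeneratorSpec(A=net.A, P=net.P, L=net.L, seed=seed)
    out = connected_random_bipartite(spec)
    return BipartiteNetwork(out.incidence, list(net.animal_labels), list(net.plant_labels))


def nm2_randomize(
    net: BipartiteNetwork,
    seed: int | None = None,
    n_swaps: int | None = None,
    require_connected: bool = False,
    max_attempt_factor: int = 100,
) -> BipartiteNetwork:
    """Null model 2: degree-preserving randomization by checkerboard swaps.

    A checkerboard swap picks links (a1,p1) and (a2,p2) with (a1,p2) and
    (a2,p1) absent and exchanges the plant ends; every species degree is
    conserved exactly.  Default mixing length: 10·L accepted swaps.  Returns
    the input with a warning when no swap is possible (e.g. complete graph).
    """
    from .synthetic import checkerboard_mix

    rng = np.random.default_rng(seed)
    target = 10 * net.L if n_swaps is None else n_swaps
    for _ in range(1000):
        mat = net.incidence.copy()
        accepted = checkerboard_mix(mat, rng, target, max_attempt_factor)
        if accepted == 0:
            warnings.warn("no checkerboard swap possible; returning the input network")
            return net
        out = BipartiteNetwork(mat, list(net.animal_labels), list(net.plant_labels))
        if not require_connected or out.is_connected():
            return out
    raise RuntimeError("could not produce a connected NM2 realization")


def _randomize(net: BipartiteNetwork, model: str, seed, **kwargs) -> BipartiteNetwork:
    if model == "NM1":
        return nm1_randomize(net, seed)
    if model == "NM2":
        return nm2_randomize(net, seed, **kwargs)
    raise ValueError(f"unknown null model {model!r}")


def compute_statistics(
    net: BipartiteNetwork,
    cfg: ParamConfig,
    rng: np.random.Generator,
    statistics=STATISTICS,
    zeta: float = 0.1,
    perturbation_kind: str = "all",
    fix_abundances: np.ndarray | None = None,
) -> dict[str, float]:
    """Parametrize the network and evaluate the requested spectral statistics.

    One eigen-analysis serves all statistics; the amplitude statistic draws
    a fresh perturbation from ``rng``.
    """
    from .parametrization import build_community_matrix, build_interaction_matrix
    from .perturbation import leading_amplitude, make_perturbation
    from .spectral import ipr, leading_modes

    if fix_abundances is not None:
        W = build_interaction_matrix(net, cfg)
        Phi = build_community_matrix(W, fix_abundances)
    else:
        _, Phi = parametrize(net, cfg, rng=rng)
    summary = leading_modes(Phi)
    out: dict[str, float] = {}
    for stat in statistics:
        if stat == "ipr_v1":
            out[stat] = ipr(summary.v1)
        elif stat == "ipr_u1":
            out[stat] = ipr(summary.u1)
        elif stat == "ipr_wH":
            out[stat] = ipr(summary.wH)
        elif stat == "lambda1":
            out[stat] = summary.lambda1
        elif stat == "lambdaH":
            out[stat] = summary.lambdaH
        elif stat == "amplitude_A1":
            pert = make_perturbation(
                perturbation_kind, net.S, degrees=net.degrees(), zeta=zeta, rng=rng
            )
            out[stat] = leading_amplitude(summary, pert.xi)
        else:
            raise ValueError(f"unknown statistic {stat!r}")
    return out


def empirical_p_value(null_values: np.ndarray, observed: float, alternative: str) -> float:
    """(r+1)/(n+1) one-sided empirical p-value; never exactly zero."""
    null_values = np.asarray(null_values)
    n = len(null_values)
    if alternative == "greater":
        r = int((null_values >= observed).sum())
    elif alternative == "less":
        r = int((null_values <= observed).sum())
    else:
        raise ValueError("alternative must be 'greater' or 'less'")
    return (1 + r) / (1 + n)


def null_ensemble(
    net: BipartiteNetwork,
    cfg: ParamConfig,
    model: str = "NM1",
    statistic: str = "ipr_v1",
    n: int = 1000,
    seed: int | None = None,
    zeta: float = 0.1,
    perturbation_kind: str = "all",
    alternative: str = "greater",
    fix_abundances: bool = False,
    **null_kwargs,
) -> NullEnsembleResult:
    """Monte-Carlo null ensemble of one statistic against NM1 or NM2.

    ``fix_abundances`` holds the observed abundance draw fixed across null
    realizations to isolate the purely topological effect; by default each
    realization draws fresh abundances (randomization of the full Φ).
    """
    multi = null_ensemble_multi(
        net, cfg, model=model, statistics=(statistic,), n=n, seed=seed, zeta=zeta,
        perturbation_kind=perturbation_kind,
        alternatives={statistic: alternative},
        fix_abundances=fix_abundances, **null_kwargs,
    )
    return multi[statistic]


def null_ensemble_multi(
    net: BipartiteNetwork,
    cfg: ParamConfig,
    model: str = "NM1",
    statistics=STATISTICS,
    n: int = 1000,
    seed: int | None = None,
    zeta: float = 0.1,
    perturbation_kind: str = "all",
    alternatives: dict[str, str] | None = None,
    fix_abundances: bool = False,
    **null_kwargs,
) -> dict[str, NullEnsembleResult]:
    """Evaluate several statistics against one shared null ensemble.

    Each realization re-randomizes the topology once and computes every
    statistic from the same parametrized community matrix, so e.g. the
    localization census and the attenuation census share their nulls.
    """
    if n <= 0:
        raise ValueError("n must be >= 1")
    for stat in statistics:
        if stat not in STATISTICS:
            raise ValueError(f"unknown statistic {stat!r}; choose from {STATISTICS}")
    alternatives = alternatives or {}
    ss = np.random.SeedSequence(seed)
    obs_rng, *child_seqs = ss.spawn(n + 1)

    obs_rng = np.random.default_rng(obs_rng)
    fixed_x = None
    if fix_abundances:
        from .parametrization import sample_abundances

        fixed_x = sample_abundances(net.S, cfg.with_seed(int(ss.generate_state(1)[0] % 2**31)))
    observed = compute_statistics(
        net, cfg, obs_rng, statistics, zeta, perturbation_kind, fix_abundances=fixed_x
    )

    null_rows = {stat: np.empty(n) for stat in statistics}
    for i, child in enumerate(child_seqs):
        rng = np.random.default_rng(child)
        rand_seed = int(rng.integers(2**31))
        rnet = _randomize(net, model, rand_seed, **null_kwargs)
        vals = compute_statistics(
            rnet, cfg, rng, statistics, zeta, perturbation_kind, fix_abundances=fixed_x
        )
        for stat in statistics:
            null_rows[stat][i] = vals[stat]

    out: dict[str, NullEnsembleResult] = {}
    for stat in statistics:
        nv = null_rows[stat]
        alt = alternatives.get(stat, "less" if stat == "amplitude_A1" else "greater")
        mean = float(nv.mean())
        out[stat] = NullEnsembleResult(
            statistic_name=stat,
            observed=float(observed[stat]),
            null_values=nv,
            null_mean=mean,
            null_sd=float(nv.std(ddof=1)) if n > 1 else 0.0,
            ratio=float(observed[stat] / mean),
            p_value=empirical_p_value(nv, observed[stat], alt),
            n_realizations=n,
            model=model,
            seed=seed,
            alternative=alt,
        )
    return out


def ripr(
    net: BipartiteNetwork,
    cfg: ParamConfig,
    model: str = "NM1",
    eigvec: str = "v1",
    n: int = 1000,
    seed: int | None = None,
    **kwargs,
) -> NullEnsembleResult:
    """Relative IPR of a leading eigenvector: IPR/⟨IPR_ran⟩ with p-value.

    rIPR significantly above one (p < 0.05) classifies the network as
    localized with respect to the chosen null model.
    """
    if eigvec not in ("v1", "u1", "wH"):
        raise ValueError("eigvec must be one of v1, u1, wH")
    return null_ensemble(
        net, cfg, model=model, statistic=f"ipr_{eigvec}", n=n, seed=seed,
        alternative="greater", **kwargs,
    )
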