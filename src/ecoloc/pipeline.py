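"""Per-network analysis records, corpus censuses and correlation batteries.

``analyze_network`` chains topology → parametrization → eigen-analysis →
null ensembles → perturbation amplitude into a single ``NetworkRecord``.
``run_corpus`` maps it over a collection of networks and summarizes the
fraction of localized (rIPR > 1, p < 0.05) and attenuated (relative A1 < 1,
p < 0.05) networks per null model, plus Spearman correlations between
localization and topological properties (size, connectance, strength
heterogeneity, resilience).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .network_io import BipartiteNetwork, summarize
from .null_models import NullEnsembleResult, null_ensemble_multi
from .parametrization import ParamConfig, parametrize
from .spectral import leading_modes, localization_report

logger = logging.getLogger(__name__)

__all__ = [
    "NullConfig",
    "NetworkRecord",
    "CorrelationTable",
    "analyze_network",
    "corpus_correlations",
    "node_centrality_correlations",
    "run_corpus",
]

_RIPR_STATS = ("ipr_v1", "ipr_u1", "ipr_wH")


@dataclass(frozen=True)
class NullConfig:
    """Null-ensemble settings shared across a corpus run."""

    models: tuple[str, ...] = ("NM1", "NM2")
    n: int = 1000
    zeta: float = 0.1
    perturbation_kind: str = "all"
    seed: int | None = None


@dataclass
class NetworkRecord:
    """All per-network statistics assembled by :func:`analyze_network`."""

    network_id: str
    S: int
    A: int
    P: int
    L: int
    connectance: float
    sigma_s2: float  # variance of the species strengths
    lambda1: float
    lambdaH: float
    ipr_v1: float
    ipr_u1: float
    ipr_wH: float
    n_localized: dict
    null: dict = field(default_factory=dict)  # model -> stat -> NullEnsembleResult

    def ripr(self, model: str, eigvec: str = "v1") -> NullEnsembleResult:
        return self.null[model][f"ipr_{eigvec}"]

    def rel_amplitude(self, model: str) -> NullEnsembleResult:
        return self.null[model]["amplitude_A1"]

    def to_flat_dict(self) -> dict:
        row = {
            "network_id": self.network_id,
            "S": self.S,
            "A": self.A,
            "P": self.P,
            "L": self.L,
            "connectance": self.connectance,
            "sigma_s2": self.sigma_s2,
            "lambda1": self.lambda1,
            "lambdaH": self.lambdaH,
            "ipr_v1": self.ipr_v1,
            "ipr_u1": self.ipr_u1,
            "ipr_wH": self.ipr_wH,
            "n_localized_v1": self.n_localized["v1"],
            "n_localized_u1": self.n_localized["u1"],
            "n_localized_wH": self.n_localized["wH"],
        }
        for model, res in self.null.items():
            for stat, r in res.items():
                prefix = f"r{stat}" if stat.startswith("ipr") else f"rel_{stat}"
                row[f"{prefix}_{model}"] = r.ratio
                row[f"{prefix}_{model}_p"] = r.p_value
        return row


@dataclass(frozen=True)
class CorrelationTable:
    rows: pd.DataFrame  # columns: x, y, spearman_rho, p_value, n, flagged

    def __iter__(self):
        return iter(self.rows.itertuples(index=False))


def analyze_network(
    net: BipartiteNetwork,
    cfg: ParamConfig,
    null_cfg: NullConfig = NullConfig(),
    network_id: str = "net",
) -> NetworkRecord:
    """Full single-network analysis; deterministic given cfg/null seeds."""
    topo = summarize(net)
    W, Phi = parametrize(net, cfg)
    summary = leading_modes(Phi)
    report = localization_report(summary)
    null: dict[str, dict[str, NullEnsembleResult]] = {}
    stats_wanted = _RIPR_STATS + ("amplitude_A1", "lambda1", "lambdaH")
    for m, model in enumerate(null_cfg.models):
        seed = None if null_cfg.seed is None else int((null_cfg.seed + 7919 * m) % 2**31)
        null[model] = null_ensemble_multi(
            net, cfg, model=model, statistics=stats_wanted, n=null_cfg.n,
            seed=seed, zeta=null_cfg.zeta, perturbation_kind=null_cfg.perturbation_kind,
        )
    return NetworkRecord(
        network_id=network_id,
        S=topo.S,
        A=topo.A,
        P=topo.P,
        L=topo.L,
        connectance=topo.connectance,
        sigma_s2=float(np.var(W.strengths)),
        lambda1=summary.lambda1,
        lambdaH=summary.lambdaH,
        ipr_v1=report.ipr_v1,
        ipr_u1=report.ipr_u1,
        ipr_wH=report.ipr_wH,
        n_localized=report.n_localized,
        null=null,
    )


def _spearman_row(x: np.ndarray, y: np.ndarray, xn: str, yn: str) -> dict:
    flagged = len(np.unique(x)) < 2 or len(np.unique(y)) < 2
    if flagged:
        rho, p = np.nan, np.nan
    else:
        rho, p = stats.spearmanr(x, y)
    return {
        "x": xn, "y": yn, "spearman_rho": rho, "p_value": p,
        "n": len(x), "flagged": flagged,
    }


def corpus_correlations(records: list[NetworkRecord], model: str = "NM1") -> CorrelationTable:
    """Spearman correlations between topology and relative spectral statistics.

    Pairs: network size S, connectance C, resilience λ1 and strength variance
    σ_s² against rIPR (v1, u1, wH) and the relative leading amplitude.
    Constant columns are flagged (ρ undefined) rather than dropped silently.
    """
    if len(records) < 5:
        raise ValueError("need at least 5 network records for corpus correlations")
    df = pd.DataFrame([r.to_flat_dict() for r in records]).sort_values("network_id")
    pairs = []
    for vec in ("v1", "u1", "wH"):
        y = f"ripr_{vec}_{model}"
        pairs += [("S", y), ("connectance", y), ("lambda1", y)]
    pairs += [
        ("sigma_s2", f"ripr_v1_{model}"),
        ("sigma_s2", f"ripr_u1_{model}"),
        ("S", f"rel_amplitude_A1_{model}"),
        ("connectance", f"rel_amplitude_A1_{model}"),
        ("lambda1", f"rel_amplitude_A1_{model}"),
    ]
    rows = [
        _spearman_row(df[x].to_numpy(), df[y].to_numpy(), x, y)
        for x, y in pairs
        if y in df.columns
    ]
    return CorrelationTable(rows=pd.DataFrame(rows))


def node_centrality_correlations(net: BipartiteNetwork, cfg: ParamConfig) -> CorrelationTable:
    """Per-species correlation of |v1|, |u1|, |wH| with four centralities.

    Centralities (degree, strength, eigenvector, PageRank with damping 0.85)
    are computed on the weighted undirected mutualistic graph obtained by
    symmetrizing the off-diagonal of W entrywise with max.
    """
    import networkx as nx

    W, Phi = parametrize(net, cfg)
    summary = leading_modes(Phi)
    k = net.degrees().astype(float)
    s = W.strengths
    Woff = W.W.copy()
    np.fill_diagonal(Woff, 0.0)
    Wsym = np.maximum(Woff, Woff.T)
    G = nx.from_numpy_array(Wsym)
    eig_c = np.array(list(nx.eigenvector_centrality_numpy(G, weight="weight").values()))
    pr = np.array(list(nx.pagerank(G, alpha=0.85, weight="weight").values()))
    rows = []
    for vec_name, vec in (("v1", summary.v1), ("u1", summary.u1), ("wH", summary.wH)):
        for cen_name, cen in (
            ("degree", k), ("strength", s), ("eigenvector_centrality", eig_c), ("pagerank", pr)
        ):
            rows.append(_spearman_row(cen, np.abs(vec), cen_name, f"|{vec_name}|"))
    return CorrelationTable(rows=pd.DataFrame(rows))


def census(records: list[NetworkRecord]) -> dict:
    """Fractions of localized and attenuated networks per null model."""
    out: dict = {}
    models = records[0].null.keys()
    for model in models:
        entry: dict = {}
        for vec in ("v1", "u1", "wH"):
            hits = [r.ripr(model, vec).significant for r in records]
            entry[f"localized_fraction_{vec}"] = float(np.mean(hits))
        amp = [r.rel_amplitude(model).significant for r in records]
        entry["attenuated_fraction"] = float(np.mean(amp))
        entry["n_networks"] = len(records)
        out[model] = entry
    return out


def run_corpus(
    nets: dict[str, BipartiteNetwork],
    cfg: ParamConfig,
    null_cfg: NullConfig = NullConfig(),
    output_dir: str | Path | None = None,
    corpus_seed: int | None = None,
) -> tuple[list[NetworkRecord], CorrelationTable, dict]:
    """Analyze every network, then build the census and correlation table.

    Per-network seeds derive deterministically from ``corpus_seed`` and the
    network index; partial failures are logged and skipped.
    """
    if not nets:
        raise ValueError("empty corpus")
    base = np.random.SeedSequence(corpus_seed)
    records: list[NetworkRecord] = []
    for i, (name, net) in enumerate(nets.items()):
        net_seed = int(base.generate_state(i + 1)[-1] % 2**31)
        ncfg = NullConfig(
            models=null_cfg.models, n=null_cfg.n, zeta=null_cfg.zeta,
            perturbation_kind=null_cfg.perturbation_kind, seed=net_seed,
        )
        try:
            records.append(
                analyze_network(net, cfg.with_seed(net_seed), ncfg, network_id=name)
            )
        except Exception:  # keep going on partial failure
            logger.exception("analysis failed for network %s", name)
    if not records:
        raise RuntimeError("every network in the corpus failed")
    table = corpus_correlations(records) if len(records) >= 5 else None
    cens = census(records)
    if output_dir is not None:
        outdir = Path(output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        pd.DataFrame([r.to_flat_dict() for r in records]).to_csv(
            outdir / "records.csv", index=False
        )
        if table is not None:
            table.rows.to_csv(outdir / "correlations.csv", index=False)
        with open(outdir / "census.json", "w") as fh:
            json.dump(cens, fh, indent=2)
    return records, table, cens
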