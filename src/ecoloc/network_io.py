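"""Reading, validation and basic topology of bipartite mutualistic networks.

A mutualistic community (e.g. pollinators and plants) is encoded as a binary
incidence matrix ``B`` with ``A`` rows (animals) and ``P`` columns (plants);
``B[i, j] = 1`` means animal ``i`` and plant ``j`` interact.  Throughout the
package species are indexed animals-first: indices ``0 … A-1`` are animals,
``A … S-1`` are plants, with ``S = A + P``.  Every per-species vector (degree,
strength, abundance, eigenvector, perturbation) follows this order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "BipartiteNetwork",
    "TopologySummary",
    "read_incidence",
    "write_incidence",
    "read_edge_list",
    "write_edge_list",
    "summarize",
    "to_adjacency",
]


class NetworkValidationError(ValueError):
    """Raised when an incidence matrix violates a structural invariant."""


@dataclass
class BipartiteNetwork:
    """Binary bipartite incidence matrix with species labels.

    Parameters
    ----------
    incidence
        ``(A, P)`` array of 0/1 entries, animals on rows, plants on columns.
    animal_labels, plant_labels
        Species names; generated (``A1…``, ``P1…``) when omitted.
    """

    incidence: np.ndarray
    animal_labels: list[str] = field(default_factory=list)
    plant_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.incidence = np.asarray(self.incidence)
        if self.incidence.ndim != 2 or self.incidence.size == 0:
            raise NetworkValidationError("incidence must be a non-empty 2-D matrix")
        if not self.animal_labels:
            self.animal_labels = [f"A{i + 1}" for i in range(self.incidence.shape[0])]
        if not self.plant_labels:
            self.plant_labels = [f"P{j + 1}" for j in range(self.incidence.shape[1])]
        if len(self.animal_labels) != self.incidence.shape[0]:
            raise NetworkValidationError("animal_labels length mismatch")
        if len(self.plant_labels) != self.incidence.shape[1]:
            raise NetworkValidationError("plant_labels length mismatch")
        self.incidence = self.incidence.astype(np.int8)

    # -- basic dimensions -------------------------------------------------
    @property
    def A(self) -> int:
        return self.incidence.shape[0]

    @property
    def P(self) -> int:
        return self.incidence.shape[1]

    @property
    def S(self) -> int:
        return self.A + self.P

    @property
    def L(self) -> int:
        return int(self.incidence.sum())

    @property
    def species_labels(self) -> list[str]:
        return list(self.animal_labels) + list(self.plant_labels)

    def degrees(self) -> np.ndarray:
        """Per-species degree vector ``k`` (length S, animals first)."""
        return np.concatenate(
            [self.incidence.sum(axis=1), self.incidence.sum(axis=0)]
        ).astype(int)

    def validate(self, relax: bool = False) -> "BipartiteNetwork":
        """Check binarity and (unless *relax*) the absence of isolated species."""
        vals = np.unique(self.incidence)
        if not np.isin(vals, [0, 1]).all():
            raise NetworkValidationError("incidence entries must be 0 or 1")
        if not relax:
            k = self.degrees()
            if (k == 0).any():
                bad = [self.species_labels[i] for i in np.flatnonzero(k == 0)]
                raise NetworkValidationError(f"isolated species: {bad}")
        return self

    def is_connected(self) -> bool:
        adj = to_adjacency(self)
        n_comp = _count_components(adj)
        return n_comp == 1


@dataclass(frozen=True)
class TopologySummary:
    """Species counts, links, degree sequence and connectance of a network."""

    S: int
    A: int
    P: int
    L: int
    degrees: np.ndarray
    connectance: float


def _count_components(adj: np.ndarray) -> int:
    from scipy.sparse.csgraph import connected_components

    n, _ = connected_components(adj, directed=False)
    return int(n)


def read_incidence(
    path,
    dialect: str = "tsv",
    labeled: bool = True,
    coerce: bool = False,
    relax: bool = False,
    largest_component: bool = False,
) -> BipartiteNetwork:
    """Read a labelled incidence matrix (plants on columns, animals on rows).

    With ``labeled`` the first row holds plant labels and the first column
    animal labels (the layout of interaction-web-database pollination
    matrices); otherwise the file is a bare 0/1 grid.  Quantitative entries
    (visit counts) are binarized at ``>0`` only when ``coerce`` is set.
    """
    sep = {"tsv": "\t", "csv": ","}[dialect]
    if labeled:
        df = pd.read_csv(path, sep=sep, index_col=0)
        mat = df.to_numpy(dtype=float)
        animals = [str(x) for x in df.index]
        plants = [str(x) for x in df.columns]
    else:
        df = pd.read_csv(path, sep=sep, header=None)
        mat = df.to_numpy(dtype=float)
        animals, plants = [], []
    if mat.size == 0:
        raise NetworkValidationError("empty matrix")
    if not np.isin(mat, [0, 1]).all():
        if not coerce:
            raise NetworkValidationError(
                "non-binary entries present; pass coerce=True to binarize at >0"
            )
        warnings.warn("binarizing quantitative incidence entries at >0")
        mat = (mat > 0).astype(np.int8)
    net = BipartiteNetwork(mat.astype(np.int8), animals, plants)
    if largest_component:
        net = _largest_component(net)
    return net.validate(relax=relax)


def _largest_component(net: BipartiteNetwork) -> BipartiteNetwork:
    from scipy.sparse.csgraph import connected_components

    adj = to_adjacency(net)
    _, labels = connected_components(adj, directed=False)
    counts = np.bincount(labels)
    keep = labels == counts.argmax()
    rows = np.flatnonzero(keep[: net.A])
    cols = np.flatnonzero(keep[net.A :])
    return BipartiteNetwork(
        net.incidence[np.ix_(rows, cols)],
        [net.animal_labels[i] for i in rows],
        [net.plant_labels[j] for j in cols],
    )


def write_incidence(net: BipartiteNetwork, path, dialect: str = "tsv") -> None:
    sep = {"tsv": "\t", "csv": ","}[dialect]
    df = pd.DataFrame(
        net.incidence, index=net.animal_labels, columns=net.plant_labels
    )
    df.to_csv(path, sep=sep)


def read_edge_list(path, relax: bool = False) -> BipartiteNetwork:
    """Read ``animal<TAB>plant`` pairs; label order follows first appearance.

    Lines starting with ``#`` are ignored; duplicate pairs are collapsed with
    a warning.  A label seen on both sides is an error (the graph would not
    be bipartite).
    """
    animals: dict[str, int] = {}
    plants: dict[str, int] = {}
    pairs: list[tuple[str, str]] = []
    seen = set()
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != 2:
                raise NetworkValidationError(
                    f"line {ln}: expected 2 fields, got {len(fields)}"
                )
            a, p = fields
            if (a, p) in seen:
                warnings.warn(f"duplicate edge ({a}, {p}) ignored")
                continue
            seen.add((a, p))
            pairs.append((a, p))
            animals.setdefault(a, len(animals))
            plants.setdefault(p, len(plants))
    both = set(animals) & set(plants)
    if both:
        raise NetworkValidationError(f"labels on both sides: {sorted(both)}")
    if not pairs:
        raise NetworkValidationError("empty edge list")
    mat = np.zeros((len(animals), len(plants)), dtype=np.int8)
    for a, p in pairs:
        mat[animals[a], plants[p]] = 1
    return BipartiteNetwork(mat, list(animals), list(plants)).validate(relax=relax)


def write_edge_list(net: BipartiteNetwork, path) -> None:
    with open(path, "w") as fh:
        for i, j in zip(*np.nonzero(net.incidence)):
            fh.write(f"{net.animal_labels[i]}\t{net.plant_labels[j]}\n")


def summarize(net: BipartiteNetwork) -> TopologySummary:
    """Topological descriptors: S, A, P, L, degree vector and connectance.

    Connectance uses the unipartite convention ``C = L / (S (S - 1))``, the
    fraction of observed links out of all ordered species pairs.
    """
    k = net.degrees()
    S = net.S
    return TopologySummary(
        S=S,
        A=net.A,
        P=net.P,
        L=net.L,
        degrees=k,
        connectance=net.L / (S * (S - 1)),
    )


def to_adjacency(net: BipartiteNetwork) -> np.ndarray:
    """Symmetric ``S×S`` 0/1 adjacency in block form ``[[0, B], [Bᵀ, 0]]``."""
    A, P = net.A, net.P
    adj = np.zeros((A + P, A + P), dtype=np.int8)
    adj[:A, A:] = net.incidence
    adj[A:, :A] = net.incidence.T
    return adj
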