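"""Synthetic bipartite topologies with controlled size and heterogeneity.

Three families:

``connected_random_bipartite``
    L links placed at random subject only to connectivity — the homogeneous
    randomization that also backs null model 1.
``powerlaw_bipartite``
    animal degrees drawn from a truncated power law ``P(k) ∝ k^(-exponent)``
    on ``1 … P`` — the heterogeneous, core–periphery-like topology typical of
    empirical pollination webs.
``biregular_bipartite``
    every animal has the same degree and every plant has the same degree —
    the fully homogeneous control.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network_io import BipartiteNetwork, NetworkValidationError

__all__ = [
    "GeneratorSpec",
    "connected_random_bipartite",
    "powerlaw_bipartite",
    "biregular_bipartite",
]


@dataclass(frozen=True)
class GeneratorSpec:
    A: int
    P: int
    L: int | None = None
    family: str = "connected_random"
    exponent: float = 2.5
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.A < 1 or self.P < 1:
            raise ValueError("A and P must be >= 1")


def _spanning_structure(A: int, P: int, rng: np.random.Generator) -> set[tuple[int, int]]:
    """Random bipartite spanning tree: S-1 links connecting all species.

    Nodes are attached one at a time in random order, each to a uniformly
    chosen already-placed node of the opposite guild.
    """
    animals = list(rng.permutation(A))
    plants = list(rng.permutation(P))
    edges: set[tuple[int, int]] = set()
    placed_a = [animals.pop()]
    placed_p = [plants.pop()]
    edges.add((placed_a[0], placed_p[0]))
    pending = [("a", a) for a in animals] + [("p", p) for p in plants]
    rng.shuffle(pending)
    for guild, node in pending:
        if guild == "a":
            edges.add((node, placed_p[rng.integers(len(placed_p))]))
            placed_a.append(node)
        else:
            edges.add((placed_a[rng.integers(len(placed_a))], node))
            placed_p.append(node)
    return edges


def connected_random_bipartite(spec: GeneratorSpec) -> BipartiteNetwork:
    """Uniform-ish connected bipartite graph with exactly ``spec.L`` links.

    A random spanning tree over the S species guarantees connectivity; the
    remaining ``L - (S - 1)`` links are drawn uniformly among unused
    animal–plant pairs.
    """
    A, P, L = spec.A, spec.P, spec.L
    S = A + P
    if L is None:
        raise ValueError("L is required")
    if L < S - 1 or L > A * P:
        raise ValueError(f"L={L} infeasible for connected {A}x{P} bipartite graph")
    rng = np.random.default_rng(spec.seed)
    edges = _spanning_structure(A, P, rng)
    free = [(i, j) for i in range(A) for j in range(P) if (i, j) not in edges]
    extra = rng.choice(len(free), size=L - len(edges), replace=False)
    for idx in extra:
        edges.add(free[idx])
    mat = np.zeros((A, P), dtype=np.int8)
    for i, j in edges:
        mat[i, j] = 1
    return BipartiteNetwork(mat).validate()


def _truncated_powerlaw_degrees(
    n: int, kmax: int, exponent: float, rng: np.random.Generator
) -> np.ndarray:
    k = np.arange(1, kmax + 1)
    pmf = k.astype(float) ** (-exponent)
    pmf /= pmf.sum()
    return rng.choice(k, size=n, p=pmf)


def _match_stubs(
    deg_a: np.ndarray, deg_p: np.ndarray, rng: np.random.Generator, max_rounds: int = 200
) -> np.ndarray:
    """Configuration-style bipartite matching with simple-graph repair.

    Animal stubs are matched to shuffled plant stubs; duplicate pairs are
    removed by degree-preserving double-edge swaps.
    """
    from collections import Counter

    A, P = len(deg_a), len(deg_p)
    stubs_a = np.repeat(np.arange(A), deg_a)
    stubs_p = np.repeat(np.arange(P), deg_p)
    assert len(stubs_a) == len(stubs_p)
    L = len(stubs_a)
    for _ in range(max_rounds):
        rng.shuffle(stubs_p)
        pairs = np.stack([stubs_a, stubs_p], axis=1)
        keys = pairs[:, 0] * P + pairs[:, 1]
        count = Counter(keys.tolist())
        # lazy stack of (possibly stale) duplicate-edge indices; each accepted
        # swap moves one multi-edge onto a free animal-plant pair
        stack = [i for i in range(L) if count[keys[i]] > 1]
        attempts = 0
        while stack and attempts < 200 * L:
            i = stack[-1]
            if count[keys[i]] <= 1:
                stack.pop()
                continue
            attempts += 1
            j = int(rng.integers(L))
            a1, p1 = pairs[i]
            a2, p2 = pairs[j]
            if i == j or a1 == a2 or p1 == p2:
                continue
            k1n, k2n = a1 * P + p2, a2 * P + p1
            if count.get(k1n, 0) or count.get(k2n, 0):
                continue
            count[keys[i]] -= 1
            count[keys[j]] -= 1
            pairs[i, 1], pairs[j, 1] = p2, p1
            keys[i], keys[j] = k1n, k2n
            count[k1n] = count[k2n] = 1
        if not stack:
            mat = np.zeros((A, P), dtype=np.int8)
            mat[pairs[:, 0], pairs[:, 1]] = 1
            return mat
    raise NetworkValidationError("could not realize degree sequence as a simple graph")


def checkerboard_mix(
    mat: np.ndarray,
    rng: np.random.Generator,
    target: int,
    max_attempt_factor: int = 100,
) -> int:
    """Run up to *target* accepted degree-preserving checkerboard swaps
    in place; returns the number accepted.

    A swap picks links (a1,p1), (a2,p2) with (a1,p2) and (a2,p1) absent and
    exchanges the plant ends — the standard MCMC move whose stationary
    distribution is uniform over simple bipartite graphs with the given
    degree sequence.
    """
    rows, cols = (a.copy() for a in np.nonzero(mat))
    accepted = attempts = 0
    max_attempts = max_attempt_factor * max(target, 1)
    while accepted < target and attempts < max_attempts:
        attempts += 1
        e1, e2 = rng.integers(len(rows), size=2)
        a1, p1 = rows[e1], cols[e1]
        a2, p2 = rows[e2], cols[e2]
        if a1 == a2 or p1 == p2 or mat[a1, p2] or mat[a2, p1]:
            continue
        mat[a1, p1] = mat[a2, p2] = 0
        mat[a1, p2] = mat[a2, p1] = 1
        cols[e1], cols[e2] = p2, p1
        accepted += 1
    return accepted


def _connect_by_swaps(
    mat: np.ndarray, rng: np.random.Generator, max_iter: int = 10000
) -> np.ndarray:
    """Merge components with degree-preserving cross-component swaps."""
    from scipy.sparse.csgraph import connected_components

    A, P = mat.shape
    for _ in range(max_iter):
        adj = np.zeros((A + P, A + P), dtype=np.int8)
        adj[:A, A:] = mat
        adj[A:, :A] = mat.T
        n_comp, labels = connected_components(adj, directed=False)
        if n_comp == 1:
            return mat
        rows, cols = np.nonzero(mat)
        comp_of_edge = labels[rows]
        c0 = comp_of_edge[0]
        in0 = np.flatnonzero(comp_of_edge == c0)
        out0 = np.flatnonzero(comp_of_edge != c0)
        e1 = int(rng.choice(in0))
        e2 = int(rng.choice(out0))
        a1, p1 = rows[e1], cols[e1]
        a2, p2 = rows[e2], cols[e2]
        # cross pairs are absent (different components), so the swap is valid
        mat[a1, p1] = mat[a2, p2] = 0
        mat[a1, p2] = mat[a2, p1] = 1
    raise NetworkValidationError("failed to connect graph by swaps")


def powerlaw_bipartite(spec: GeneratorSpec) -> BipartiteNetwork:
    """Heterogeneous bipartite network with power-law animal degrees.

    Animal degrees are i.i.d. from ``P(k) ∝ k^(-exponent)`` truncated at
    ``k = P`` (an animal cannot have more partners than there are plants);
    plant degrees take one guaranteed stub each plus a uniform multinomial
    share of the rest.  The result is simple and connected.
    """
    if spec.exponent <= 1:
        raise ValueError("power-law exponent must be > 1")
    if spec.A < 2 or spec.P < 2:
        raise ValueError("need A, P >= 2")
    rng = np.random.default_rng(spec.seed)
    for _ in range(200):
        deg_a = _truncated_powerlaw_degrees(spec.A, spec.P, spec.exponent, rng)
        L = int(deg_a.sum())
        if L < spec.P or L < spec.A + spec.P - 1:
            continue  # too sparse to cover every plant / to connect
        deg_p = np.ones(spec.P, dtype=int) + rng.multinomial(
            L - spec.P, np.full(spec.P, 1 / spec.P)
        )
        if deg_p.max() > spec.A:
            continue
        try:
            mat = _match_stubs(deg_a, deg_p, rng)
        except NetworkValidationError:
            continue
        # mix towards the uniform degree-fixed ensemble, then restore
        # connectivity with degree-preserving cross-component swaps
        checkerboard_mix(mat, rng, 10 * int(mat.sum()))
        mat = _connect_by_swaps(mat, rng)
        return BipartiteNetwork(mat).validate()
    raise NetworkValidationError("failed to draw a realizable power-law degree sequence")


def biregular_bipartite(A: int, P: int, dA: int, seed: int | None = None) -> BipartiteNetwork:
    """Connected bipartite graph with all animal degrees ``dA`` (plants get
    ``A·dA/P`` each); requires ``P | A·dA`` and ``dA ≤ P``."""
    if (A * dA) % P != 0:
        raise ValueError(f"A*dA={A * dA} not divisible by P={P}")
    if dA > P:
        raise ValueError("dA cannot exceed P")
    if dA < 1:
        raise ValueError("dA must be >= 1")
    rng = np.random.default_rng(seed)
    deg_a = np.full(A, dA, dtype=int)
    deg_p = np.full(P, (A * dA) // P, dtype=int)
    mat = _match_stubs(deg_a, deg_p, rng)
    checkerboard_mix(mat, rng, 10 * int(mat.sum()))
    if A * dA >= A + P - 1:  # connectivity only feasible with enough links
        mat = _connect_by_swaps(mat, rng)
    return BipartiteNetwork(mat).validate()


def generate(spec: GeneratorSpec) -> BipartiteNetwork:
    """Dispatch on ``spec.family``."""
    if spec.family == "connected_random":
        return connected_random_bipartite(spec)
    if spec.family == "powerlaw":
        return powerlaw_bipartite(spec)
    if spec.family == "biregular":
        if spec.L is None or spec.L % spec.A:
            raise ValueError("biregular family needs L divisible by A")
        return biregular_bipartite(spec.A, spec.P, spec.L // spec.A, spec.seed)
    raise ValueError(f"unknown family {spec.family!r}")
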