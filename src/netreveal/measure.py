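"""Multifractal network generative model (MFNG).

The generative measure is ``(m, k, P, L)``: every node carries a category
sequence ``c = (c_1, ..., c_k)`` with levels in ``{0, ..., m-1}``, and an
unordered node pair ``(u, v)`` is linked independently with probability

    p(c_u, c_v) = prod_{l=1..k} P[c_u(l), c_v(l)]

where ``P`` is a symmetric ``m x m`` matrix of base link probabilities and
``L`` is the length-``m`` prior over categories at each level.  The model is
a multifractal generalization of stochastic Kronecker graphs: the ``k``-fold
product structure lets a small ``P`` express a rich family of pairwise link
probabilities on the unit square.

Entries of ``P`` are kept inside ``[EPS, 1-EPS]`` so that every log term of
the likelihood stays finite; gradient ascent in the M-step would otherwise
push probabilities onto the boundary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, Hashable, Iterable, Mapping, Sequence, Tuple

import networkx as nx
import numpy as np

__all__ = [
    "EPS",
    "MultifractalMeasure",
    "link_probability",
    "sample_categories",
    "enumerate_categories",
    "default_assignment",
    "sample_network",
    "model_log_likelihood",
    "gradient_log_likelihood",
]

#: Clamp for base link probabilities; keeps all log terms finite.
EPS = 1e-4

CategorySequence = Tuple[int, ...]
Assignment = Dict[Hashable, CategorySequence]


def clamp_probabilities(P: np.ndarray, eps: float = EPS) -> np.ndarray:
    """Project a base probability matrix onto ``[eps, 1-eps]``."""
    return np.clip(P, eps, 1.0 - eps)


@dataclass(frozen=True)
class MultifractalMeasure:
    """Generating measure of the multifractal network model.

    Parameters
    ----------
    m : int
        Number of base categories (>= 2).
    k : int
        Recursion depth; category sequences have length ``k``.
    P : (m, m) ndarray
        Symmetric matrix of base link probabilities, entries in
        ``[EPS, 1-EPS]``.
    L : (m,) ndarray
        Category length measure (prior over categories per level); sums to 1.
    """

    m: int
    k: int
    P: np.ndarray
    L: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.m < 2:
            raise ValueError(f"m must be >= 2, got {self.m}")
        if self.k < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")
        P = np.asarray(self.P, dtype=float)
        if P.shape != (self.m, self.m):
            raise ValueError(f"P must be {self.m}x{self.m}, got {P.shape}")
        if not np.allclose(P, P.T, atol=1e-12):
            raise ValueError("P must be symmetric")
        if np.any(P < EPS) or np.any(P > 1.0 - EPS):
            raise ValueError(f"entries of P must lie in [{EPS}, {1 - EPS}]")
        L = self.L
        if L is None:
            L = np.full(self.m, 1.0 / self.m)
        L = np.asarray(L, dtype=float)
        if L.shape != (self.m,):
            raise ValueError(f"L must have length {self.m}")
        if abs(L.sum() - 1.0) > 1e-9:
            raise ValueError("entries of L must sum to 1")
        if np.any(L < 0):
            raise ValueError("entries of L must be non-negative")
        object.__setattr__(self, "P", P)
        object.__setattr__(self, "L", L)

    # ------------------------------------------------------------------
    # constructors
    # ------------------------------------------------------------------
    @classmethod
    def random(
        cls,
        m: int,
        k: int,
        rng: np.random.Generator,
        mean_degree: float | None = None,
        n_nodes: int | None = None,
    ) -> "MultifractalMeasure":
        """Randomized measure: i.i.d. Uniform(0.1, 0.9) upper triangle,
        symmetrized; uniform length measure.

        When ``mean_degree`` (and ``n_nodes``) are given, the matrix is
        density-calibrated with an elementwise power transform ``P**beta``
        (which preserves entry ordering and keeps probabilities strictly
        inside (0, 1)), solving for ``beta`` so the expected mean degree of
        an ``n_nodes``-node realization under the length measure matches the
        target.  Raw draws at small ``k`` are otherwise so sparse that a
        sustained degree-targeted attack runs out of connected victims.
        """
        P = np.empty((m, m))
        iu = np.triu_indices(m)
        vals = rng.uniform(0.1, 0.9, size=len(iu[0]))
        P[iu] = vals
        P.T[iu] = vals
        L = np.full(m, 1.0 / m)
        if mean_degree is not None:
            if n_nodes is None or n_nodes < 2:
                raise ValueError("density calibration requires n_nodes >= 2")
            q_target = (mean_degree / (n_nodes - 1)) ** (1.0 / k)

            def q(beta: float) -> float:
                return float(L @ (P**beta) @ L)

            lo, hi = 1e-6, 50.0
            for _ in range(200):
                mid = (lo + hi) / 2
                if q(mid) > q_target:
                    lo = mid
                else:
                    hi = mid
            P = (P ** ((lo + hi) / 2) + (P.T ** ((lo + hi) / 2))) / 2
            P = clamp_probabilities(P)
        return cls(m=m, k=k, P=P, L=L)

    def replace_P(self, P: np.ndarray) -> "MultifractalMeasure":
        """Copy of this measure with a new (symmetrized, clamped) ``P``."""
        P = np.asarray(P, dtype=float)
        P = clamp_probabilities((P + P.T) / 2.0)
        return MultifractalMeasure(m=self.m, k=self.k, P=P, L=self.L)

    # ------------------------------------------------------------------
    # serialization: plain JSON {m, k, P (row-major), L}
    # ------------------------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(
            {
                "m": self.m,
                "k": self.k,
                "P": [float(x) for x in self.P.ravel()],
                "L": [float(x) for x in self.L],
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "MultifractalMeasure":
        doc = json.loads(text)
        m = int(doc["m"])
        P = np.asarray(doc["P"], dtype=float).reshape(m, m)
        return cls(m=m, k=int(doc["k"]), P=P, L=np.asarray(doc["L"], dtype=float))

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path) -> "MultifractalMeasure":
        with open(path) as fh:
            return cls.from_json(fh.read())

    # ------------------------------------------------------------------
    # probabilities
    # ------------------------------------------------------------------
    def link_probability(self, ci: Sequence[int], cj: Sequence[int]) -> float:
        return link_probability(self, ci, cj)

    def pairwise_probabilities(self, codes: np.ndarray) -> np.ndarray:
        """Full ``n x n`` link-probability matrix for category code rows.

        ``codes`` is an ``(n, k)`` integer array of category sequences.
        The diagonal is meaningless (no self-loops) and left as the
        product value; callers must ignore it.
        """
        codes = np.asarray(codes)
        if codes.ndim != 2 or codes.shape[1] != self.k:
            raise ValueError(f"codes must be (n, {self.k})")
        p = np.ones((codes.shape[0], codes.shape[0]))
        for l in range(self.k):
            p *= self.P[codes[:, l][:, None], codes[:, l][None, :]]
        return p


def _check_sequence(measure: MultifractalMeasure, c: Sequence[int]) -> Tuple[int, ...]:
    c = tuple(int(x) for x in c)
    if len(c) != measure.k:
        raise ValueError(
            f"category sequence has length {len(c)}, measure expects k={measure.k}"
        )
    if any(x < 0 or x >= measure.m for x in c):
        raise ValueError(f"category levels must lie in [0, {measure.m - 1}]")
    return c


def link_probability(
    measure: MultifractalMeasure, ci: Sequence[int], cj: Sequence[int]
) -> float:
    """Link probability of two nodes given their category sequences.

    Symmetric in ``ci``/``cj``; strictly inside ``(0, 1)`` for a clamped
    measure.
    """
    ci = _check_sequence(measure, ci)
    cj = _check_sequence(measure, cj)
    p = 1.0
    for a, b in zip(ci, cj):
        p *= measure.P[a, b]
    return float(p)


def sample_categories(
    measure: MultifractalMeasure, n: int, rng: np.random.Generator
) -> Assignment:
    """Draw category sequences for ``n`` anonymous nodes, levels i.i.d. ~ L."""
    if n < 1:
        raise ValueError("n must be >= 1")
    draws = rng.choice(measure.m, size=(n, measure.k), p=measure.L)
    return {i: tuple(int(x) for x in draws[i]) for i in range(n)}


def enumerate_categories(measure: MultifractalMeasure) -> list[CategorySequence]:
    """All ``m**k`` category sequences in lexicographic order."""
    seqs: list[CategorySequence] = []
    n = measure.m**measure.k
    for idx in range(n):
        seq = []
        x = idx
        for _ in range(measure.k):
            seq.append(x % measure.m)
            x //= measure.m
        seqs.append(tuple(reversed(seq)))
    return seqs


def default_assignment(
    measure: MultifractalMeasure, n: int, rng: np.random.Generator
) -> Assignment:
    """Category assignment for ``n`` anonymous nodes.

    When ``n == m**k`` every category sequence is used exactly once (the
    Kronecker-style construction); otherwise sequences are drawn i.i.d.
    from the length measure ``L``.
    """
    if n == measure.m**measure.k:
        return {i: seq for i, seq in enumerate(enumerate_categories(measure))}
    return sample_categories(measure, n, rng)


def assignment_codes(
    measure: MultifractalMeasure, assignment: Mapping[Hashable, Sequence[int]],
    nodes: Iterable[Hashable] | None = None,
) -> Tuple[list, np.ndarray]:
    """Order an assignment into a node list and an ``(n, k)`` code array."""
    if nodes is None:
        nodes = list(assignment.keys())
    else:
        nodes = list(nodes)
    codes = np.empty((len(nodes), measure.k), dtype=np.int64)
    for i, u in enumerate(nodes):
        codes[i] = _check_sequence(measure, assignment[u])
    return nodes, codes


def sample_network(
    measure: MultifractalMeasure,
    assignment: Mapping[Hashable, Sequence[int]],
    rng: np.random.Generator,
) -> nx.Graph:
    """Sample an undirected simple graph; pairs linked independently."""
    if not assignment:
        raise ValueError("assignment must be nonempty")
    nodes, codes = assignment_codes(measure, assignment)
    p = measure.pairwise_probabilities(codes)
    n = len(nodes)
    G = nx.Graph()
    G.add_nodes_from(nodes)
    iu, ju = np.triu_indices(n, k=1)
    hit = rng.random(len(iu)) < p[iu, ju]
    G.add_edges_from((nodes[i], nodes[j]) for i, j in zip(iu[hit], ju[hit]))
    return G


def _adjacency(graph: nx.Graph, nodes: list) -> np.ndarray:
    index = {u: i for i, u in enumerate(nodes)}
    A = np.zeros((len(nodes), len(nodes)), dtype=bool)
    for u, v in graph.edges():
        if u == v:
            continue
        A[index[u], index[v]] = True
        A[index[v], index[u]] = True
    return A


def model_log_likelihood(
    measure: MultifractalMeasure,
    graph: nx.Graph,
    assignment: Mapping[Hashable, Sequence[int]],
) -> float:
    """Bernoulli log-likelihood of a graph under the measure.

    ``sum_{(i,j) in E} log p_ij + sum_{(i,j) not in E, i<j} log(1 - p_ij)``
    over unordered pairs of graph nodes.
    """
    nodes = list(graph.nodes())
    missing = [u for u in nodes if u not in assignment]
    if missing:
        raise ValueError(f"assignment missing nodes: {missing[:5]}")
    if len(nodes) < 2:
        return 0.0
    _, codes = assignment_codes(measure, assignment, nodes)
    p = measure.pairwise_probabilities(codes)
    A = _adjacency(graph, nodes)
    iu, ju = np.triu_indices(len(nodes), k=1)
    pe = p[iu, ju]
    ae = A[iu, ju]
    return float(np.sum(np.where(ae, np.log(pe), np.log1p(-pe))))


# ----------------------------------------------------------------------
# Likelihood gradient with respect to the tied symmetric entries of P.
#
# For a pair with link probability p = prod_l P[c_i(l), c_j(l)] and
# n_ab = #{l : {c_i(l), c_j(l)} = {a, b}}, treating P[a,b] == P[b,a] as one
# parameter:
#   d log p / d P[a,b]      =  n_ab / P[a,b]
#   d log(1-p) / d P[a,b]   = -n_ab * p / ((1 - p) * P[a,b])
# The returned matrix stores the tied derivative at both (a,b) and (b,a).
# ----------------------------------------------------------------------


def _class_table(m: int) -> Tuple[np.ndarray, list]:
    """Map (a, b) -> unordered-pair class index; list of (a, b) with a <= b."""
    classes = [(a, b) for a in range(m) for b in range(a, m)]
    table = np.empty((m, m), dtype=np.int64)
    for c, (a, b) in enumerate(classes):
        table[a, b] = c
        table[b, a] = c
    return table, classes


def _profile_keys(codes: np.ndarray, m: int, k: int) -> np.ndarray:
    """Encode, per node pair, the per-class level counts into one integer.

    Key base is ``k+1`` (each class count is at most ``k``), so
    ``key = sum_c count_c * (k+1)**c = sum_l (k+1)**class(l)``.
    """
    table, classes = _class_table(m)
    base = np.int64(k + 1)
    pow_ = base ** np.arange(len(classes), dtype=np.int64)
    n = codes.shape[0]
    keys = np.zeros((n, n), dtype=np.int64)
    for l in range(k):
        cls = table[codes[:, l][:, None], codes[:, l][None, :]]
        keys += pow_[cls]
    return keys


def _decode_counts(keys: np.ndarray, n_classes: int, k: int) -> np.ndarray:
    """(len(keys), n_classes) count matrix from encoded profile keys."""
    base = k + 1
    counts = np.empty((len(keys), n_classes), dtype=np.int64)
    x = keys.astype(np.int64).copy()
    for c in range(n_classes):
        counts[:, c] = x % base
        x //= base
    return counts


def pair_histograms(
    measure: MultifractalMeasure, codes: np.ndarray, adjacency: np.ndarray
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sufficient statistics of the Bernoulli likelihood.

    Returns ``(keys, edge_counts, nonedge_counts)`` where ``keys`` are the
    distinct level-count profiles over unordered node pairs and the counts
    say how many linked / unlinked pairs carry each profile.  The
    log-likelihood and its gradient at *any* ``P`` are functions of these
    alone, which is what makes repeated M-step evaluations cheap.
    """
    keys = _profile_keys(codes, measure.m, measure.k)
    iu, ju = np.triu_indices(codes.shape[0], k=1)
    pk = keys[iu, ju]
    ae = adjacency[iu, ju]
    uniq, inv = np.unique(pk, return_inverse=True)
    e_cnt = np.bincount(inv, weights=ae.astype(float), minlength=len(uniq))
    ne_cnt = np.bincount(inv, weights=(~ae).astype(float), minlength=len(uniq))
    return uniq, e_cnt, ne_cnt


def ll_and_grad_from_histograms(
    measure_m: int,
    measure_k: int,
    P: np.ndarray,
    keys: np.ndarray,
    e_cnt: np.ndarray,
    ne_cnt: np.ndarray,
) -> Tuple[float, np.ndarray]:
    """Log-likelihood and tied-entry gradient from profile histograms."""
    table, classes = _class_table(measure_m)
    counts = _decode_counts(keys, len(classes), measure_k)
    Pc = np.array([P[a, b] for a, b in classes])
    logp = counts @ np.log(Pc)
    p = np.exp(logp)
    p = np.minimum(p, 1.0 - 1e-15)
    ll = float(e_cnt @ logp + ne_cnt @ np.log1p(-p))
    # per-class gradient
    coef = e_cnt - ne_cnt * p / (1.0 - p)
    gc = (counts * coef[:, None]).sum(axis=0) / Pc
    grad = np.zeros_like(P)
    for c, (a, b) in enumerate(classes):
        grad[a, b] = gc[c]
        grad[b, a] = gc[c]
    return ll, grad


def gradient_log_likelihood(
    measure: MultifractalMeasure,
    graph: nx.Graph,
    assignment: Mapping[Hashable, Sequence[int]],
) -> np.ndarray:
    """Gradient of :func:`model_log_likelihood` w.r.t. the entries of P.

    ``P[a, b]`` and ``P[b, a]`` are treated as a single tied parameter; the
    returned symmetric matrix holds the tied derivative in both cells.  It
    matches central finite differences of the log-likelihood in which both
    symmetric cells are perturbed together.
    """
    nodes = list(graph.nodes())
    if len(nodes) < 2:
        return np.zeros_like(measure.P)
    _, codes = assignment_codes(measure, assignment, nodes)
    A = _adjacency(graph, nodes)
    keys, e_cnt, ne_cnt = pair_histograms(measure, codes, A)
    _, grad = ll_and_grad_from_histograms(
        measure.m, measure.k, measure.P, keys, e_cnt, ne_cnt
    )
    return grad
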