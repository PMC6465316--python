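"""Degree-preferential adversarial removal (attack) model.

At each step the attacker removes one node drawn with probability
proportional to ``d_i**alpha`` over the nodes of the *current* residual
graph, together with its incident edges.  ``alpha > 0`` prioritizes hubs,
``alpha < 0`` boundary nodes, and ``alpha = 0`` is a uniformly random
removal.  Because the distribution is recomputed on the residual graph the
removal process is a time-inhomogeneous Markov chain, which is exactly what
makes the surviving network a *biased* (not random) sample of the original.

The module also hosts the social-injection analytics: selecting "injected"
nodes with the same degree-preferential weighting (on the full, unchanged
graph) and measuring how much of the user population they cover.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Hashable, Iterable, List, Set, Tuple

import networkx as nx
import numpy as np

__all__ = [
    "LatentSlot",
    "RemovalEvent",
    "RemovalTrajectory",
    "InterventionModel",
    "attack_distribution",
    "simulate_attack",
    "attack_log_likelihood",
    "select_injected_nodes",
    "injection_sequence",
    "coverage",
    "affected_users",
]


@dataclass(frozen=True, order=True)
class LatentSlot:
    """Anonymous placeholder for the node removed at time ``index``."""

    index: int

    def __repr__(self) -> str:  # compact in tables / serialized output
        return f"slot:{self.index}"


@dataclass(frozen=True)
class RemovalEvent:
    """One removal: the victim, its neighbors and degree at removal time."""

    victim: Hashable
    neighbors: Tuple[Hashable, ...]
    degree: int

    def __post_init__(self) -> None:
        if self.degree != len(self.neighbors):
            raise ValueError("event degree must equal its neighbor count")
        if self.victim in self.neighbors:
            raise ValueError("victim cannot neighbor itself")


@dataclass
class InterventionModel:
    """Attack exponent and likelihood discount.

    ``gamma`` weights the attack term of the complete-data log-likelihood;
    ``gamma = 0`` is the attack-blind baseline.
    """

    alpha: float = 1.0
    gamma: float = 1.0

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")


class RemovalTrajectory:
    """Time-ordered removal events ``s = 0 .. t-1``.

    Applying the events in order to the original graph yields the residual;
    conversely, restoring them (in reverse) onto the residual reconstructs
    the original graph.
    """

    def __init__(self, events: Iterable[RemovalEvent] = ()) -> None:
        self.events: List[RemovalEvent] = list(events)
        victims = [e.victim for e in self.events]
        if len(set(victims)) != len(victims):
            raise ValueError("a node cannot be removed twice")

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def __eq__(self, other) -> bool:
        if not isinstance(other, RemovalTrajectory):
            return NotImplemented
        return [
            (e.victim, frozenset(e.neighbors)) for e in self.events
        ] == [(e.victim, frozenset(e.neighbors)) for e in other.events]

    @property
    def victims(self) -> List[Hashable]:
        return [e.victim for e in self.events]

    # ------------------------------------------------------------------
    def apply_to(self, graph: nx.Graph) -> nx.Graph:
        """Replay the removals on a copy of ``graph``; returns the residual.

        Raises if any event is inconsistent with the evolving graph (wrong
        neighbors or degree), which also verifies the trajectory invariant.
        """
        G = graph.copy()
        for s, ev in enumerate(self.events):
            if ev.victim not in G:
                raise ValueError(f"event {s}: victim {ev.victim!r} not present")
            nbrs = set(G.neighbors(ev.victim))
            if nbrs != set(ev.neighbors):
                raise ValueError(
                    f"event {s}: recorded neighbors disagree with the graph"
                )
            G.remove_node(ev.victim)
        return G

    def restore(self, observed: nx.Graph) -> nx.Graph:
        """Union of the observed residual with all removed subgraphs."""
        G = observed.copy()
        for ev in reversed(self.events):
            if ev.victim in G:
                raise ValueError(f"victim {ev.victim!r} already present")
            G.add_node(ev.victim)
            for u in ev.neighbors:
                if u not in G:
                    raise ValueError(
                        f"neighbor {u!r} of {ev.victim!r} missing from graph"
                    )
                G.add_edge(ev.victim, u)
        return G

    # ------------------------------------------------------------------
    # line-oriented text serialization: "step<TAB>victim<TAB>n1,n2,..."
    # ------------------------------------------------------------------
    @staticmethod
    def _fmt_node(u: Hashable) -> str:
        if isinstance(u, LatentSlot):
            return f"slot:{u.index}"
        return str(u)

    @staticmethod
    def _parse_node(text: str) -> Hashable:
        if text.startswith("slot:"):
            return LatentSlot(int(text[5:]))
        return text

    def to_text(self) -> str:
        lines = []
        for s, ev in enumerate(self.events):
            nbrs = ",".join(self._fmt_node(u) for u in ev.neighbors)
            lines.append(f"{s}\t{self._fmt_node(ev.victim)}\t{nbrs}")
        return "\n".join(lines) + ("\n" if lines else "")

    @classmethod
    def from_text(cls, text: str) -> "RemovalTrajectory":
        events = []
        for line in text.splitlines():
            line = line.strip()
            if not line:
                continue
            step, victim, nbrs = line.split("\t")
            neighbors = tuple(
                cls._parse_node(x) for x in nbrs.split(",") if x != ""
            )
            events.append(
                RemovalEvent(
                    victim=cls._parse_node(victim),
                    neighbors=neighbors,
                    degree=len(neighbors),
                )
            )
        return cls(events)


# ----------------------------------------------------------------------
# attack distribution
# ----------------------------------------------------------------------


def attack_weights(degrees: np.ndarray, alpha: float) -> np.ndarray:
    """Unnormalized removal weights ``d**alpha``.

    Zero-degree nodes get weight 0 unless ``alpha == 0`` (uniform removal,
    where every node is eligible).  ``alpha = +/-inf`` selects uniformly
    among the maximum / minimum positive-degree nodes.
    """
    d = np.asarray(degrees, dtype=float)
    w = np.zeros_like(d)
    pos = d > 0
    if alpha == 0:
        return np.ones_like(d)
    if math.isinf(alpha):
        if not pos.any():
            return w
        target = d[pos].max() if alpha > 0 else d[pos].min()
        w[pos & (d == target)] = 1.0
        return w
    # work in log space so |alpha| ~ 10 cannot overflow for large degrees
    logw = alpha * np.log(d, out=np.full_like(d, -np.inf), where=pos)
    if pos.any():
        logw = logw - logw[pos].max()
    np.exp(logw, out=w, where=pos)
    return w


def attack_distribution(graph: nx.Graph, alpha: float) -> Dict[Hashable, float]:
    """Per-node removal probabilities ``d_i**alpha / sum_j d_j**alpha``."""
    if graph.number_of_nodes() == 0:
        raise ValueError("graph must be nonempty")
    nodes = list(graph.nodes())
    degrees = np.array([graph.degree(u) for u in nodes], dtype=float)
    w = attack_weights(degrees, alpha)
    total = w.sum()
    if total <= 0:
        raise ValueError(
            "no eligible node: all degrees are zero under a degree-weighted attack"
        )
    probs = w / total
    return dict(zip(nodes, probs))


def simulate_attack(
    graph: nx.Graph, alpha: float, T: int, rng: np.random.Generator
) -> Tuple[nx.Graph, RemovalTrajectory]:
    """Remove ``T`` nodes sequentially; victims drawn per the residual graph."""
    if T >= graph.number_of_nodes():
        raise ValueError("T must be smaller than the number of nodes")
    if T < 0:
        raise ValueError("T must be >= 0")
    # adjacency as dict-of-sets: cheap repeated degree updates
    adj: Dict[Hashable, Set[Hashable]] = {
        u: set(graph.neighbors(u)) for u in graph.nodes()
    }
    nodes = list(adj.keys())
    index = {u: i for i, u in enumerate(nodes)}
    alive = np.ones(len(nodes), dtype=bool)
    degrees = np.array([len(adj[u]) for u in nodes], dtype=float)
    events = []
    for _ in range(T):
        w = attack_weights(np.where(alive, degrees, 0.0), alpha)
        w[~alive] = 0.0
        total = w.sum()
        if total <= 0:
            raise ValueError(
                "no eligible node: all degrees are zero under a degree-weighted attack"
            )
        i = rng.choice(len(nodes), p=w / total)
        victim = nodes[i]
        nbrs = tuple(adj[victim])
        events.append(
            RemovalEvent(victim=victim, neighbors=nbrs, degree=len(nbrs))
        )
        for u in nbrs:
            adj[u].discard(victim)
            degrees[index[u]] -= 1
        adj[victim] = set()
        degrees[i] = 0
        alive[i] = False
    trajectory = RemovalTrajectory(events)
    residual = graph.copy()
    residual.remove_nodes_from([e.victim for e in events])
    return residual, trajectory


def attack_log_likelihood(
    trajectory: RemovalTrajectory, observed: nx.Graph, alpha: float
) -> float:
    """Log-probability of the recorded removal sequence.

    The normalizer of the removal distribution depends on every degree of
    the residual graph at each step, so the observed residual is required
    to rebuild the full graph and replay the attack forward.  Returns
    ``-inf`` if any victim has zero removal probability.
    """
    if len(trajectory) == 0:
        return 0.0
    G = trajectory.restore(observed)
    total = 0.0
    for ev in trajectory.events:
        probs = attack_distribution(G, alpha)
        p = probs.get(ev.victim, 0.0)
        if p <= 0:
            return -np.inf
        total += math.log(p)
        G.remove_node(ev.victim)
    return total


# ----------------------------------------------------------------------
# injection / coverage analytics
# ----------------------------------------------------------------------


def injection_sequence(
    graph: nx.Graph, n_pick: int, alpha: float, rng: np.random.Generator
) -> List[Hashable]:
    """Sequentially sample ``n_pick`` distinct nodes with weight ``d**alpha``.

    Weights always come from the original, unchanged graph: injection is a
    labeling process, not a removal process.  The returned order is the
    draw order, so prefixes of one sequence give nested injected sets.
    """
    nodes = list(graph.nodes())
    degrees = np.array([graph.degree(u) for u in nodes], dtype=float)
    w = attack_weights(degrees, alpha).astype(float)
    picked: List[Hashable] = []
    avail = w.copy()
    for _ in range(n_pick):
        total = avail.sum()
        if total <= 0:
            # remaining eligible mass exhausted: fall back to uniform over rest
            rest = np.ones(len(nodes))
            rest[[nodes.index(u) for u in picked]] = 0.0
            avail = rest
            total = avail.sum()
        i = rng.choice(len(nodes), p=avail / total)
        picked.append(nodes[i])
        avail[i] = 0.0
    return picked


def select_injected_nodes(
    graph: nx.Graph, share: float, alpha: float, rng: np.random.Generator
) -> Set[Hashable]:
    """``ceil(share * |V|)`` nodes sampled without replacement, weight d**alpha."""
    if not 0.0 <= share <= 1.0:
        raise ValueError("share must lie in [0, 1]")
    n_pick = math.ceil(share * graph.number_of_nodes())
    return set(injection_sequence(graph, n_pick, alpha, rng))


def coverage(graph: nx.Graph, injected: Set[Hashable]) -> float:
    """Fraction of non-injected nodes with >= 1 injected neighbor.

    By convention the coverage is 1 when every node is injected (no exposed
    user remains uncovered).
    """
    injected = set(injected)
    unknown = injected - set(graph.nodes())
    if unknown:
        raise ValueError(f"injected nodes not in graph: {sorted(map(str, unknown))[:5]}")
    users = [u for u in graph.nodes() if u not in injected]
    if not users:
        return 1.0
    covered = sum(
        1 for u in users if any(v in injected for v in graph.neighbors(u))
    )
    return covered / len(users)


def affected_users(graph: nx.Graph, injected: Set[Hashable]) -> int:
    """Count of non-injected nodes with >= 1 injected neighbor."""
    injected = set(injected)
    return sum(
        1
        for u in graph.nodes()
        if u not in injected and any(v in injected for v in graph.neighbors(u))
    )
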