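"""Monte-Carlo EM engine for attack-aware network reconstruction.

The observed graph ``G_t`` is modelled as the survivor of ``T`` sequential
degree-preferential removals from an unknown original graph ``G_0`` that is
itself a realization of a multifractal generating measure.  The missing
structure is represented by a removal trajectory ``Z_t`` over anonymous
latent slots (slot ``s`` = node removed at attack step ``s``) and a
category assignment ``psi'`` covering observed nodes and slots.  The
complete-data log-likelihood of one latent configuration is::

    log P = log P_model(G_0 | psi', measure) + gamma * log P_attack(Z_t | alpha)

with ``gamma = 0`` the attack-blind baseline and ``gamma = 1`` the full
causal likelihood.

The E-step draws ``(Z_t, psi')`` from their joint posterior by a Gibbs
scheme that alternates (i) a recursive rejection draw of the restoration
path, proposing each slot's links from the model and accepting with the
attack transition probability, (ii) a Metropolis rewiring chain that keeps
``f(G_k; G_{k+1})`` invariant per event, and (iii) a Metropolis swap chain
over category assignments.  The M-step performs batch gradient ascent on
the Monte-Carlo Q-function with respect to the base probability matrix P
(step-halving guards against overshooting; L is held fixed).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field, asdict
from typing import Dict, Hashable, List, Mapping, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import _kernels
from .intervention import (
    InterventionModel,
    LatentSlot,
    RemovalEvent,
    RemovalTrajectory,
    attack_log_likelihood,
)
from .measure import (
    MultifractalMeasure,
    default_assignment,
    ll_and_grad_from_histograms,
    model_log_likelihood,
    pair_histograms,
    _class_table,
)

logger = logging.getLogger(__name__)

__all__ = [
    "EMConfig",
    "PosteriorSample",
    "EMState",
    "complete_log_likelihood",
    "sample_trajectory",
    "refine_trajectory",
    "sample_assignment",
    "draw_posterior_samples",
    "q_function",
    "m_step",
    "run_em",
    "reconstruct_posterior",
    "enumerate_posterior_exact",
    "posterior_sample_key",
    "write_edge_scores",
]


# ----------------------------------------------------------------------
# configuration & sample containers
# ----------------------------------------------------------------------


@dataclass
class EMConfig:
    """Sampler and optimizer sizes for the Monte-Carlo EM loop.

    ``n_samples`` (K) and ``n_burnin`` (B) control the Gibbs pool per EM
    iteration, ``n_grad_steps`` (S) and ``learning_rate`` (sigma) the
    M-step, ``refine_steps`` / ``swap_steps`` the inner chain lengths per
    sweep, and ``traj_attempts`` the per-slot rejection budget of a fresh
    trajectory draw (on exhaustion the sweep falls back to refining the
    previous trajectory; ``init_attempts`` applies to the very first sweep,
    which commits its best-scoring attempt instead of failing).
    """

    n_samples: int = 2000
    n_burnin: int = 500
    n_grad_steps: int = 5
    learning_rate: float = 0.01
    refine_steps: int = 2
    redraw_steps: int = 2
    swap_steps: int = 32
    traj_attempts: int = 30
    init_attempts: int = 500
    tol: float = 1e-3
    max_iter: int = 50
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.n_burnin < 0:
            raise ValueError("n_burnin must be >= 0")
        if self.n_grad_steps < 1:
            raise ValueError("n_grad_steps must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")

    # short aliases matching the field's usual notation
    @property
    def K(self) -> int:
        return self.n_samples

    @property
    def B(self) -> int:
        return self.n_burnin

    @property
    def S(self) -> int:
        return self.n_grad_steps

    @property
    def sigma(self) -> float:
        return self.learning_rate

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "EMConfig":
        return cls(**(yaml.safe_load(text) or {}))


@dataclass
class PosteriorSample:
    """One draw ``(Z_t, psi')`` from the E-step posterior."""

    trajectory: RemovalTrajectory
    assignment: Dict[Hashable, Tuple[int, ...]]
    log_likelihood: float
    attack_ll: float = 0.0


@dataclass
class EMState:
    """Current model estimate and diagnostics of an EM run."""

    measure: MultifractalMeasure
    iteration: int
    trace: List[float] = field(default_factory=list)
    samples: List[PosteriorSample] = field(default_factory=list)
    best_assignment: Dict[Hashable, Tuple[int, ...]] = field(default_factory=dict)


# ----------------------------------------------------------------------
# internal index problem
# ----------------------------------------------------------------------


def _sorted_nodes(graph: nx.Graph) -> list:
    try:
        return sorted(graph.nodes())
    except TypeError:
        return sorted(graph.nodes(), key=str)


class _Problem:
    """Index layout shared with the compiled kernels.

    Observed nodes (sorted) map to ``0 .. n_obs-1``; latent slot ``s`` maps
    to ``n_obs + s``.
    """

    def __init__(
        self,
        measure: Optional[MultifractalMeasure],
        observed: nx.Graph,
        model: InterventionModel,
        T: int,
    ) -> None:
        if T < 0:
            raise ValueError("T must be >= 0")
        self.measure = measure
        self.model = model
        self.T = T
        self.obs_nodes = _sorted_nodes(observed)
        self.slots = [LatentSlot(s) for s in range(T)]
        self.nodes = self.obs_nodes + self.slots
        self.index = {u: i for i, u in enumerate(self.nodes)}
        self.n_obs = len(self.obs_nodes)
        self.n_tot = self.n_obs + T
        A = np.zeros((self.n_obs, self.n_obs), dtype=bool)
        for u, v in observed.edges():
            if u == v:
                continue
            A[self.index[u], self.index[v]] = True
            A[self.index[v], self.index[u]] = True
        self.A_obs = A
        self.deg_obs = A.sum(axis=1).astype(np.int64)

    # -- conversions ----------------------------------------------------
    def codes(self, assignment: Mapping[Hashable, Sequence[int]]) -> np.ndarray:
        C = np.empty((self.n_tot, self.measure.k), dtype=np.int64)
        for u, i in self.index.items():
            if u not in assignment:
                raise ValueError(f"assignment missing {u!r}")
            seq = tuple(assignment[u])
            if len(seq) != self.measure.k:
                raise ValueError("category sequence length mismatch")
            C[i] = seq
        return C

    def assignment(self, C: np.ndarray) -> Dict[Hashable, Tuple[int, ...]]:
        return {u: tuple(int(x) for x in C[i]) for u, i in self.index.items()}

    def lnk(self, trajectory: RemovalTrajectory) -> np.ndarray:
        if len(trajectory) != self.T:
            raise ValueError(f"trajectory must have exactly {self.T} events")
        Lnk = np.zeros((self.T, self.n_tot), dtype=bool)
        for s, ev in enumerate(trajectory.events):
            if ev.victim != LatentSlot(s):
                raise ValueError("trajectory victims must be slots in time order")
            for u in ev.neighbors:
                j = self.index.get(u)
                if j is None:
                    raise ValueError(f"unknown neighbor {u!r}")
                if j >= self.n_obs and (j - self.n_obs) <= s:
                    raise ValueError(
                        f"slot {s} cannot link to {u!r}: not present after step {s}"
                    )
                Lnk[s, j] = True
        return Lnk

    def trajectory(self, Lnk: np.ndarray) -> RemovalTrajectory:
        events = []
        for s in range(self.T):
            nbrs = tuple(self.nodes[j] for j in np.flatnonzero(Lnk[s]))
            events.append(
                RemovalEvent(victim=LatentSlot(s), neighbors=nbrs, degree=len(nbrs))
            )
        return RemovalTrajectory(events)

    def a_full(self, Lnk: np.ndarray) -> np.ndarray:
        A = np.zeros((self.n_tot, self.n_tot), dtype=bool)
        A[: self.n_obs, : self.n_obs] = self.A_obs
        for s in range(self.T):
            A[self.n_obs + s, :] |= Lnk[s]
            A[:, self.n_obs + s] |= Lnk[s]
        return A

    def complete_ll(self, C: np.ndarray, Lnk: np.ndarray) -> Tuple[float, float]:
        """(model term, attack term) via the compiled kernels."""
        mll = _kernels.model_ll_kernel(self.measure.P, C, self.A_obs, Lnk)
        all_ = _kernels.attack_ll_kernel(self.deg_obs, Lnk, float(self.model.alpha))
        return float(mll), float(all_)

    def initial_codes(self, rng: np.random.Generator) -> np.ndarray:
        """Random permutation of the category multiset over all domain elements."""
        base = default_assignment(self.measure, self.n_tot, rng)
        seqs = [base[i] for i in range(self.n_tot)]
        order = rng.permutation(self.n_tot)
        C = np.empty((self.n_tot, self.measure.k), dtype=np.int64)
        for i, j in enumerate(order):
            C[i] = seqs[j]
        return C


def _seed(rng: np.random.Generator) -> int:
    return int(rng.integers(0, 2**31 - 1))


# ----------------------------------------------------------------------
# spec operations (functional surface)
# ----------------------------------------------------------------------


def complete_log_likelihood(
    measure: MultifractalMeasure,
    observed: nx.Graph,
    sample: PosteriorSample,
    model: InterventionModel,
) -> float:
    """Model log-likelihood of the reconstructed graph plus the
    gamma-weighted attack log-likelihood of the removal sequence."""
    G0 = sample.trajectory.restore(observed)
    ll = model_log_likelihood(measure, G0, sample.assignment)
    if model.gamma > 0:
        all_ = attack_log_likelihood(sample.trajectory, observed, model.alpha)
        if not math.isfinite(all_):
            return -np.inf
        ll += model.gamma * all_
    return ll


def sample_trajectory(
    measure: MultifractalMeasure,
    assignment: Mapping[Hashable, Sequence[int]],
    observed: nx.Graph,
    model: InterventionModel,
    T: int,
    rng: np.random.Generator,
    max_attempts: int = 1000,
) -> RemovalTrajectory:
    """Recursive rejection draw of a removal trajectory given psi'."""
    prob = _Problem(measure, observed, model, T)
    C = prob.codes(assignment)
    Lnk = np.zeros((T, prob.n_tot), dtype=bool)
    status = _kernels.traj_sweep(
        _seed(rng), measure.P, C, prob.deg_obs, Lnk,
        float(model.alpha), float(model.gamma), max_attempts, 0,
    )
    if status >= 0:
        raise RuntimeError(
            f"trajectory rejection sampling exhausted {max_attempts} proposals at "
            f"slot {status}; increase the attempt budget or review gamma/alpha"
        )
    return prob.trajectory(Lnk)


def refine_trajectory(
    trajectory: RemovalTrajectory,
    measure: MultifractalMeasure,
    assignment: Mapping[Hashable, Sequence[int]],
    observed: nx.Graph,
    model: InterventionModel,
    n_steps: int,
    rng: np.random.Generator,
) -> RemovalTrajectory:
    """Metropolis rewiring of each removal event; leaves f(G_k;G_{k+1}) invariant."""
    prob = _Problem(measure, observed, model, len(trajectory))
    C = prob.codes(assignment)
    Lnk = prob.lnk(trajectory)
    _kernels.refine_sweep(
        _seed(rng), measure.P, C, prob.deg_obs, Lnk,
        float(model.alpha), float(model.gamma), n_steps, 0, 0,
    )
    return prob.trajectory(Lnk)


def sample_assignment(
    assignment: Mapping[Hashable, Sequence[int]],
    trajectory: RemovalTrajectory,
    measure: MultifractalMeasure,
    observed: nx.Graph,
    model: InterventionModel,
    n_steps: int,
    rng: np.random.Generator,
) -> Dict[Hashable, Tuple[int, ...]]:
    """Metropolis swap chain over category assignments (reversible)."""
    prob = _Problem(measure, observed, model, len(trajectory))
    C = prob.codes(assignment)
    Lnk = prob.lnk(trajectory)
    A_full = prob.a_full(Lnk)
    _kernels.swap_sweep(_seed(rng), measure.P, C, A_full, n_steps)
    return prob.assignment(C)


class _GibbsChain:
    """Alternating (Z_t, psi') sampler over the internal array state."""

    def __init__(
        self,
        measure: MultifractalMeasure,
        observed: nx.Graph,
        model: InterventionModel,
        T: int,
        config: EMConfig,
        rng: np.random.Generator,
        init_assignment: Optional[Mapping[Hashable, Sequence[int]]] = None,
    ) -> None:
        self.prob = _Problem(measure, observed, model, T)
        self.model = model
        self.config = config
        self.rng = rng
        if init_assignment is not None:
            self.C = self.prob.codes(init_assignment)
        else:
            self.C = self.prob.initial_codes(rng)
        self.Lnk = np.zeros((T, self.prob.n_tot), dtype=bool)
        self._tmp = np.zeros_like(self.Lnk)
        self.first = True
        self.fresh_failures = 0

    def set_measure(self, measure: MultifractalMeasure) -> None:
        self.prob.measure = measure

    def sweep(self) -> None:
        cfg = self.config
        prob = self.prob
        P = prob.measure.P
        alpha = float(self.model.alpha)
        gamma = float(self.model.gamma)
        if self.prob.T > 0:
            attempts = cfg.init_attempts if self.first else cfg.traj_attempts
            status = _kernels.traj_sweep(
                _seed(self.rng), P, self.C, prob.deg_obs, self._tmp,
                alpha, gamma, attempts, 1 if self.first else 0,
            )
            if status < 0:
                self.Lnk[:] = self._tmp
            else:
                # budget exhausted: keep the previous trajectory and rely on
                # the rewiring chain for this sweep
                self.fresh_failures += 1
            _kernels.refine_sweep(
                _seed(self.rng), P, self.C, prob.deg_obs, self.Lnk,
                alpha, gamma, cfg.refine_steps, cfg.redraw_steps, 1,
            )
        A_full = prob.a_full(self.Lnk)
        _kernels.swap_sweep(_seed(self.rng), P, self.C, A_full, cfg.swap_steps)
        self.first = False

    def sample(self) -> PosteriorSample:
        mll, all_ = self.prob.complete_ll(self.C, self.Lnk)
        ll = mll + self.model.gamma * all_ if self.model.gamma > 0 else mll
        return PosteriorSample(
            trajectory=self.prob.trajectory(self.Lnk),
            assignment=self.prob.assignment(self.C),
            log_likelihood=ll,
            attack_ll=all_,
        )


def draw_posterior_samples(
    measure: MultifractalMeasure,
    observed: nx.Graph,
    model: InterventionModel,
    T: int,
    config: EMConfig,
    rng: np.random.Generator,
    init_assignment: Optional[Mapping[Hashable, Sequence[int]]] = None,
) -> List[PosteriorSample]:
    """K posterior samples after B burn-in Gibbs sweeps."""
    chain = _GibbsChain(measure, observed, model, T, config, rng, init_assignment)
    out: List[PosteriorSample] = []
    for tau in range(config.K + config.B):
        chain.sweep()
        if tau >= config.B:
            out.append(chain.sample())
    return out


def q_function(
    candidate: MultifractalMeasure,
    samples: Sequence[PosteriorSample],
    observed: nx.Graph,
    model: InterventionModel,
) -> float:
    """Monte-Carlo Q: mean complete log-likelihood under the candidate
    measure with trajectories/assignments held fixed."""
    if not samples:
        raise ValueError("sample list must be nonempty")
    total = 0.0
    for smp in samples:
        G0 = smp.trajectory.restore(observed)
        ll = model_log_likelihood(candidate, G0, smp.assignment)
        if model.gamma > 0:
            ll += model.gamma * smp.attack_ll
        total += ll
    return total / len(samples)


# ----------------------------------------------------------------------
# M-step
# ----------------------------------------------------------------------


def _dense_hist_size(m: int, k: int) -> int:
    n_classes = m * (m + 1) // 2
    return (k + 1) ** n_classes


def _aggregate_histograms(
    prob: _Problem, pool: Sequence[Tuple[np.ndarray, np.ndarray]]
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sum per-profile edge/non-edge counts over the sample pool."""
    m, k = prob.measure.m, prob.measure.k
    size = _dense_hist_size(m, k)
    table, classes = _class_table(m)
    powers = ((k + 1) ** np.arange(len(classes))).astype(np.int64)
    if size <= 5_000_000:
        e_hist = np.zeros(size)
        ne_hist = np.zeros(size)
        for C, Lnk in pool:
            _kernels.hist_kernel(C, prob.a_full(Lnk), table, powers, e_hist, ne_hist)
        keys = np.flatnonzero((e_hist > 0) | (ne_hist > 0)).astype(np.int64)
        return keys, e_hist[keys], ne_hist[keys]
    # sparse fallback for large (m, k)
    agg: Dict[int, List[float]] = {}
    for C, Lnk in pool:
        keys, e_cnt, ne_cnt = pair_histograms(prob.measure, C, prob.a_full(Lnk))
        for key, e, ne in zip(keys, e_cnt, ne_cnt):
            ent = agg.setdefault(int(key), [0.0, 0.0])
            ent[0] += e
            ent[1] += ne
    keys = np.array(sorted(agg), dtype=np.int64)
    e_hist = np.array([agg[int(x)][0] for x in keys])
    ne_hist = np.array([agg[int(x)][1] for x in keys])
    return keys, e_hist, ne_hist


def _ascend(
    measure: MultifractalMeasure,
    keys: np.ndarray,
    e_cnt: np.ndarray,
    ne_cnt: np.ndarray,
    K: int,
    attack_mean: float,
    config: EMConfig,
) -> Tuple[MultifractalMeasure, float]:
    """S gradient-ascent steps on Q with step-halving; returns (measure, q)."""

    def q_of(P: np.ndarray) -> float:
        ll, _ = ll_and_grad_from_histograms(measure.m, measure.k, P, keys, e_cnt, ne_cnt)
        return ll / K + attack_mean

    cur = measure
    q_cur = q_of(cur.P)
    for _ in range(config.S):
        _, grad = ll_and_grad_from_histograms(
            measure.m, measure.k, cur.P, keys, e_cnt, ne_cnt
        )
        step = config.sigma
        accepted = cur
        q_acc = q_cur
        for _halve in range(30):
            cand = cur.replace_P(cur.P + (step / K) * grad)
            q_new = q_of(cand.P)
            if q_new >= q_cur - 1e-12:
                accepted, q_acc = cand, q_new
                break
            step /= 2.0
        cur, q_cur = accepted, q_acc
    return cur, q_cur


def m_step(
    measure: MultifractalMeasure,
    samples: Sequence[PosteriorSample],
    observed: nx.Graph,
    model: InterventionModel,
    config: EMConfig,
) -> MultifractalMeasure:
    """Batch gradient-ascent update of P from a posterior sample pool.

    The attack term does not depend on P, so only the model term drives the
    gradient; after each step P is symmetrized and clamped, and a step that
    would decrease the Q-function is halved.
    """
    if not samples:
        raise ValueError("sample list must be nonempty")
    prob = _Problem(measure, observed, model, len(samples[0].trajectory))
    pool = [(prob.codes(s.assignment), prob.lnk(s.trajectory)) for s in samples]
    keys, e_cnt, ne_cnt = _aggregate_histograms(prob, pool)
    attack_mean = (
        model.gamma * float(np.mean([s.attack_ll for s in samples]))
        if model.gamma > 0
        else 0.0
    )
    new_measure, _ = _ascend(
        measure, keys, e_cnt, ne_cnt, len(samples), attack_mean, config
    )
    return new_measure


# ----------------------------------------------------------------------
# EM driver
# ----------------------------------------------------------------------


def run_em(
    observed: nx.Graph,
    T: int,
    model: InterventionModel,
    config: EMConfig,
    rng: np.random.Generator,
    m: Optional[int] = None,
    k: Optional[int] = None,
    init_measure: Optional[MultifractalMeasure] = None,
) -> Tuple[EMState, pd.DataFrame]:
    """Alternate Monte-Carlo E-steps and gradient M-steps until the
    Q-proxy stabilizes; returns the final state and posterior edge scores.

    The initial measure has symmetric Uniform(0.2, 0.8) entries (unless
    ``init_measure`` is given); ``m`` and ``k`` are then required.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    if init_measure is None:
        if m is None or k is None:
            raise ValueError("provide init_measure or both m and k")
        P = np.empty((m, m))
        iu = np.triu_indices(m)
        vals = rng.uniform(0.2, 0.8, size=len(iu[0]))
        P[iu] = vals
        P.T[iu] = vals
        measure = MultifractalMeasure(m=m, k=k, P=P)
    else:
        measure = init_measure
    logger.info("EM start: %s | model=%s | T=%d", config, model, T)

    chain = _GibbsChain(measure, observed, model, T, config, rng)
    trace: List[float] = []
    final_pool: List[Tuple[np.ndarray, np.ndarray, float, float]] = []
    n_iter = 0
    for j in range(config.max_iter):
        chain.set_measure(measure)
        pool: List[Tuple[np.ndarray, np.ndarray, float, float]] = []
        for tau in range(config.K + config.B):
            chain.sweep()
            if tau >= config.B:
                if model.gamma > 0:
                    all_ = float(
                        _kernels.attack_ll_kernel(
                            chain.prob.deg_obs, chain.Lnk, float(model.alpha)
                        )
                    )
                else:
                    all_ = 0.0
                pool.append((chain.C.copy(), chain.Lnk.copy(), all_, 0.0))
        keys, e_cnt, ne_cnt = _aggregate_histograms(
            chain.prob, [(C, L) for C, L, _, _ in pool]
        )
        attack_mean = (
            model.gamma * float(np.mean([a for _, _, a, _ in pool]))
            if model.gamma > 0
            else 0.0
        )
        measure, q_val = _ascend(
            measure, keys, e_cnt, ne_cnt, len(pool), attack_mean, config
        )
        if not math.isfinite(q_val):
            raise RuntimeError(
                f"non-finite Q at EM iteration {j}: the sampler produced a "
                "zero-probability configuration; review alpha/gamma"
            )
        trace.append(q_val)
        final_pool = pool
        n_iter = j + 1
        logger.info("EM iter %d: Q=%.4f", j, q_val)
        if j > 0 and abs(trace[-1] - trace[-2]) < config.tol * max(1.0, abs(trace[-2])):
            break

    prob = chain.prob
    prob.measure = measure
    samples = []
    best_ll = -np.inf
    best_assignment: Dict[Hashable, Tuple[int, ...]] = {}
    score_sum = np.zeros((T, prob.n_tot))
    for C, Lnk, all_, _ in final_pool:
        mll = float(_kernels.model_ll_kernel(measure.P, C, prob.A_obs, Lnk))
        ll = mll + model.gamma * all_ if model.gamma > 0 else mll
        samples.append(
            PosteriorSample(
                trajectory=prob.trajectory(Lnk),
                assignment=prob.assignment(C),
                log_likelihood=ll,
                attack_ll=all_,
            )
        )
        if ll > best_ll:
            best_ll = ll
            best_assignment = samples[-1].assignment
        score_sum += Lnk
    state = EMState(
        measure=measure,
        iteration=n_iter,
        trace=trace,
        samples=samples,
        best_assignment=best_assignment,
    )
    scores = _score_table(prob, score_sum / len(final_pool))
    return state, scores


def _score_table(prob: _Problem, score: np.ndarray) -> pd.DataFrame:
    rows = []
    for s in range(prob.T):
        for j in range(prob.n_tot):
            if j >= prob.n_obs and (j - prob.n_obs) <= s:
                continue
            rows.append((LatentSlot(s), prob.nodes[j], float(score[s, j])))
    return pd.DataFrame(rows, columns=["u", "v", "score"])


def reconstruct_posterior(
    samples: Sequence[PosteriorSample], observed: nx.Graph, T: int
) -> pd.DataFrame:
    """Edge scores for every latent-incident candidate pair.

    The score of (slot s, v) is the fraction of posterior samples whose
    trajectory links them, slots aligned by removal-time index.
    """
    if not samples:
        raise ValueError("sample list must be nonempty")
    prob = _Problem(None, observed, InterventionModel(), T)
    score_sum = np.zeros((T, prob.n_tot))
    for smp in samples:
        if len(smp.trajectory) != T:
            raise ValueError("all samples must have T events")
        for s, ev in enumerate(smp.trajectory.events):
            for u in ev.neighbors:
                score_sum[s, prob.index[u]] += 1.0
    return _score_table(prob, score_sum / len(samples))


def write_edge_scores(scores: pd.DataFrame, path) -> None:
    """Tab-delimited edge score table (node/slot pair, score)."""
    out = scores.copy()
    out["u"] = out["u"].map(str)
    out["v"] = out["v"].map(str)
    out.to_csv(path, sep="\t", index=False)


# ----------------------------------------------------------------------
# exact enumeration oracle (tiny instances; used by tests and diagnostics)
# ----------------------------------------------------------------------


def posterior_sample_key(
    sample: PosteriorSample, observed: nx.Graph, T: int
) -> Tuple:
    """Canonical hashable key of a posterior sample for distribution tests."""
    nodes = _sorted_nodes(observed) + [LatentSlot(s) for s in range(T)]
    index = {u: i for i, u in enumerate(nodes)}
    traj_key = tuple(
        tuple(sorted(index[u] for u in ev.neighbors))
        for ev in sample.trajectory.events
    )
    assign_key = tuple(tuple(sample.assignment[u]) for u in nodes)
    return traj_key, assign_key


def _count_distinct_permutations(seqs: Sequence[Tuple[int, ...]]) -> int:
    counts = {}
    for s in seqs:
        counts[s] = counts.get(s, 0) + 1
    total = math.factorial(len(seqs))
    for c in counts.values():
        total //= math.factorial(c)
    return total


def _distinct_permutations(seqs: Sequence[Tuple[int, ...]]):
    """Distinct arrangements of a multiset, without enumerating duplicates."""
    pool = sorted(set(seqs))
    counts = {s: 0 for s in pool}
    for s in seqs:
        counts[s] += 1
    n = len(seqs)
    out: List[Tuple[int, ...]] = []

    def rec():
        if len(out) == n:
            yield tuple(out)
            return
        for s in pool:
            if counts[s] > 0:
                counts[s] -= 1
                out.append(s)
                yield from rec()
                out.pop()
                counts[s] += 1

    yield from rec()


def enumerate_posterior_exact(
    measure: MultifractalMeasure,
    observed: nx.Graph,
    model: InterventionModel,
    T: int,
    assignment_multiset: Optional[List[Tuple[int, ...]]] = None,
    max_states: int = 1_000_000,
) -> Dict[Tuple, float]:
    """Exact joint posterior over (trajectory, assignment) by enumeration.

    Assignments range over the distinct arrangements of a fixed category
    multiset (uniform prior over arrangements — the component the swap
    chain explores); trajectories over all restoration paths in which every
    restored node attaches by at least one edge.  Probabilities are
    proportional to ``exp(complete_log_likelihood)``.  Refuses state spaces
    larger than ``max_states``.
    """
    prob = _Problem(measure, observed, model, T)
    if assignment_multiset is None:
        if prob.n_tot != measure.m**measure.k:
            raise ValueError(
                "assignment_multiset is required when the domain size is not m**k"
            )
        from .measure import enumerate_categories

        assignment_multiset = enumerate_categories(measure)
    if len(assignment_multiset) != prob.n_tot:
        raise ValueError("multiset size must equal |V(G_t)| + T")

    multiset = [tuple(s) for s in assignment_multiset]
    n_perms = _count_distinct_permutations(multiset)
    # trajectory space size: prod over s of (2**n_present - 1)
    n_traj = 1
    for s in range(T - 1, -1, -1):
        n_present = prob.n_obs + (T - 1 - s)
        n_traj *= 2**n_present - 1
    if n_traj * n_perms > max_states:
        raise ValueError(
            f"state space too large to enumerate: {n_traj * n_perms} > {max_states}"
        )
    perms = list(_distinct_permutations(multiset))

    # enumerate restoration paths (slot T-1 restored first)
    def paths(s: int, acc: List[Tuple[int, ...]]):
        if s < 0:
            yield list(acc)
            return
        present = [
            j
            for j in range(prob.n_tot)
            if j < prob.n_obs or (j - prob.n_obs) > s
        ]
        for r in range(1, len(present) + 1):
            for combo in itertools.combinations(present, r):
                acc.append(combo)
                yield from paths(s - 1, acc)
                acc.pop()

    states: List[Tuple[Tuple, float]] = []
    lls: List[float] = []
    keys: List[Tuple] = []
    for path in paths(T - 1, []):
        # path[i] holds slot (T-1-i)'s neighbors; reorder by slot index
        by_slot = {T - 1 - i: combo for i, combo in enumerate(path)}
        events = [
            RemovalEvent(
                victim=LatentSlot(s),
                neighbors=tuple(prob.nodes[j] for j in by_slot[s]),
                degree=len(by_slot[s]),
            )
            for s in range(T)
        ]
        traj = RemovalTrajectory(events)
        traj_key = tuple(tuple(sorted(by_slot[s])) for s in range(T))
        for perm in perms:
            assignment = {u: perm[i] for i, u in enumerate(prob.nodes)}
            smp = PosteriorSample(
                trajectory=traj, assignment=assignment, log_likelihood=0.0
            )
            ll = complete_log_likelihood(measure, observed, smp, model)
            if not math.isfinite(ll):
                continue
            keys.append((traj_key, perm))
            lls.append(ll)
    if not lls:
        if T == 0:
            # point mass on the empty trajectory for every assignment
            out = {}
            for perm in perms:
                out[((), perm)] = 1.0 / len(perms)
            return out
        raise ValueError("posterior has empty support")
    arr = np.array(lls)
    w = np.exp(arr - arr.max())
    w /= w.sum()
    return dict(zip(keys, w))
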