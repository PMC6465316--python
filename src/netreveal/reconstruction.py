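"""Estimator interface to the Monte-Carlo EM reconstruction."""

from __future__ import annotations

from typing import Optional

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .inference import EMConfig, run_em
from .intervention import InterventionModel
from .measure import MultifractalMeasure

__all__ = ["NetworkReconstructor"]


class NetworkReconstructor(BaseEstimator):
    """Reconstruct the substructure removed from a network by a
    degree-preferential attack.

    The observed graph is assumed to be the residual of ``n_missing``
    sequential removals with exponent ``alpha`` from an original graph
    generated by a multifractal measure ``(m, k, P, L)``.  Fitting runs a
    Monte-Carlo EM loop: the E-step samples removal trajectories and
    category assignments from their joint posterior, the M-step updates the
    base link-probability matrix by batch gradient ascent.  ``gamma``
    weights the attack term of the complete-data likelihood (``gamma=0``
    reproduces the attack-blind baseline).

    Parameters
    ----------
    n_missing : int
        Number of removed nodes (T); treated as a known hypothesis.
    alpha : float, default 1.0
        Attack exponent (hubs for positive, boundary nodes for negative).
    gamma : float, default 1.0
        Discount weight of the attack log-likelihood term.
    m, k : int
        Multifractal model order (ignored when ``init_measure`` is given).
    n_samples, n_burnin : int
        Retained (K) and burn-in (B) Gibbs sweeps per EM iteration.
    n_grad_steps : int
        Gradient-ascent steps (S) per M-step.
    learning_rate : float
        Ascent step size (sigma) before step-halving.
    refine_steps, redraw_steps, swap_steps : int
        Rewiring moves and link-set redraws per removal event, and
        assignment swaps per sweep.
    traj_attempts, init_attempts : int
        Rejection budgets of the fresh trajectory draw (regular / first sweep).
    tol : float
        Relative Q-change stopping tolerance.
    max_iter : int
        EM iteration cap.
    init_measure : MultifractalMeasure, optional
        Starting measure; random symmetric Uniform(0.2, 0.8) entries if None.
    random_state : int or numpy Generator, optional

    Attributes
    ----------
    measure_ : MultifractalMeasure
        Final estimate of the generating measure.
    edge_scores_ : pandas.DataFrame
        Posterior link scores for every latent-incident candidate pair
        (columns ``u``, ``v``, ``score``).
    trace_ : list of float
        Q-proxy value per EM iteration.
    n_iter_ : int
        EM iterations performed.
    samples_ : list of PosteriorSample
        Final E-step sample pool.
    best_assignment_ : dict
        Highest-likelihood sampled category assignment.

    Examples
    --------
    >>> import numpy as np, networkx as nx
    >>> from netreveal import (MultifractalMeasure, default_assignment,
    ...                        sample_network, simulate_attack)
    >>> rng = np.random.default_rng(0)
    >>> truth = MultifractalMeasure.random(m=2, k=4, rng=rng,
    ...                                    mean_degree=5.0, n_nodes=16)
    >>> g0 = sample_network(truth, default_assignment(truth, 16, rng), rng)
    >>> residual, _ = simulate_attack(g0, alpha=10.0, T=4, rng=rng)
    >>> rec = NetworkReconstructor(n_missing=4, alpha=10.0, m=2, k=4,
    ...                            n_samples=50, n_burnin=20, max_iter=2,
    ...                            random_state=0).fit(residual)
    >>> bool(rec.edge_scores_["score"].between(0, 1).all())
    True
    """

    def __init__(
        self,
        n_missing: int = 1,
        alpha: float = 1.0,
        gamma: float = 1.0,
        m: int = 2,
        k: int = 6,
        n_samples: int = 2000,
        n_burnin: int = 500,
        n_grad_steps: int = 5,
        learning_rate: float = 0.01,
        refine_steps: int = 2,
        redraw_steps: int = 2,
        swap_steps: int = 32,
        traj_attempts: int = 30,
        init_attempts: int = 500,
        tol: float = 1e-3,
        max_iter: int = 50,
        init_measure: Optional[MultifractalMeasure] = None,
        random_state=None,
    ) -> None:
        self.n_missing = n_missing
        self.alpha = alpha
        self.gamma = gamma
        self.m = m
        self.k = k
        self.n_samples = n_samples
        self.n_burnin = n_burnin
        self.n_grad_steps = n_grad_steps
        self.learning_rate = learning_rate
        self.refine_steps = refine_steps
        self.redraw_steps = redraw_steps
        self.swap_steps = swap_steps
        self.traj_attempts = traj_attempts
        self.init_attempts = init_attempts
        self.tol = tol
        self.max_iter = max_iter
        self.init_measure = init_measure
        self.random_state = random_state

    # ------------------------------------------------------------------
    def _config(self) -> EMConfig:
        return EMConfig(
            n_samples=self.n_samples,
            n_burnin=self.n_burnin,
            n_grad_steps=self.n_grad_steps,
            learning_rate=self.learning_rate,
            refine_steps=self.refine_steps,
            redraw_steps=self.redraw_steps,
            swap_steps=self.swap_steps,
            traj_attempts=self.traj_attempts,
            init_attempts=self.init_attempts,
            tol=self.tol,
            max_iter=self.max_iter,
        )

    def _rng(self) -> np.random.Generator:
        if isinstance(self.random_state, np.random.Generator):
            return self.random_state
        return np.random.default_rng(self.random_state)

    def fit(self, X: nx.Graph, y=None) -> "NetworkReconstructor":
        """Run the EM reconstruction on the observed residual graph ``X``."""
        if not isinstance(X, nx.Graph):
            raise TypeError("X must be an undirected networkx Graph")
        if self.n_missing < 1:
            raise ValueError("n_missing must be >= 1")
        model = InterventionModel(alpha=self.alpha, gamma=self.gamma)
        state, scores = run_em(
            observed=X,
            T=self.n_missing,
            model=model,
            config=self._config(),
            rng=self._rng(),
            m=self.m,
            k=self.k,
            init_measure=self.init_measure,
        )
        self.measure_ = state.measure
        self.trace_ = state.trace
        self.n_iter_ = state.iteration
        self.samples_ = state.samples
        self.best_assignment_ = state.best_assignment
        self.edge_scores_ = scores
        return self

    def predict_edges(self, threshold: float = 0.5) -> pd.DataFrame:
        """Candidate latent edges whose posterior score exceeds ``threshold``."""
        if not hasattr(self, "edge_scores_"):
            raise AttributeError("call fit first")
        return self.edge_scores_[self.edge_scores_["score"] >= threshold].reset_index(
            drop=True
        )
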