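"""Quantitative metrics for reconstruction quality.

Covers recovery of the generating measure (permutation-aligned Frobenius
error, sign-carrying divergence of the link-probability distribution),
structural similarity of generated networks (Kolmogorov–Smirnov distance
between degree distributions, model log-likelihood of a reference graph),
link-prediction quality of the posterior edge scores (ROC-AUC / PR-AUC),
and the social-injection analytics (coverage curves, affected users).

Multifractal categories are identifiable only up to a simultaneous
relabeling of rows and columns of P, so measure-level comparisons minimize
over the ``m!`` category permutations first.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, Hashable, List, Mapping, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import ks_2samp
from sklearn.metrics import average_precision_score, roc_auc_score

from .intervention import (
    LatentSlot,
    affected_users,
    coverage,
    injection_sequence,
    select_injected_nodes,
)
from .measure import (
    MultifractalMeasure,
    default_assignment,
    enumerate_categories,
    model_log_likelihood,
    sample_network,
)

__all__ = [
    "MetricReport",
    "frobenius_error",
    "best_category_permutation",
    "signed_kl_divergence",
    "ks_distance",
    "link_auc",
    "model_fit_loglik",
    "coverage_curve",
    "affected_users_estimate",
]


@dataclass
class MetricReport:
    """One reported metric with its replication context."""

    metric: str
    value: float
    dispersion: Optional[float] = None
    n_replicates: int = 1
    config: Dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.n_replicates > 1) != (self.dispersion is not None):
            raise ValueError("dispersion must be present iff n_replicates > 1")


# ----------------------------------------------------------------------
# measure recovery
# ----------------------------------------------------------------------


def best_category_permutation(
    estimated: MultifractalMeasure, truth: MultifractalMeasure
) -> Tuple[Tuple[int, ...], float]:
    """Simultaneous row/column permutation of the estimated P minimizing the
    Frobenius distance to the true P; returns (permutation, error)."""
    if estimated.m != truth.m:
        raise ValueError("measures must share m")
    best_perm: Tuple[int, ...] = tuple(range(truth.m))
    best_err = np.inf
    for perm in itertools.permutations(range(truth.m)):
        perm_arr = np.asarray(perm)
        Pp = estimated.P[np.ix_(perm_arr, perm_arr)]
        err = float(np.linalg.norm(Pp - truth.P))
        if err < best_err:
            best_err = err
            best_perm = perm
    return best_perm, best_err


def frobenius_error(
    estimated: MultifractalMeasure, truth: MultifractalMeasure
) -> float:
    """Permutation-aligned Frobenius norm of the base-matrix difference."""
    _, err = best_category_permutation(estimated, truth)
    return err


def signed_kl_divergence(
    truth: MultifractalMeasure,
    estimated: MultifractalMeasure,
    align: bool = True,
) -> float:
    """Sign-carrying divergence between true and recovered link probabilities.

    ``sum_{ci, cj} w(ci) w(cj) p*(ci,cj) log(p*(ci,cj) / p_hat(ci,cj))``
    over all ordered category-sequence pairs, weighted by the product
    measure of L.  Unlike a full KL over Bernoulli pairs this keeps only
    the link-probability term, so systematic underestimation of p gives a
    positive value and overestimation a negative one.  Categories of the
    estimate are first aligned to the truth (Frobenius-optimal
    permutation) unless ``align=False``.
    """
    if truth.m != estimated.m or truth.k != estimated.k:
        raise ValueError("measures must share m and k")
    est = estimated
    if align:
        perm, _ = best_category_permutation(estimated, truth)
        perm_arr = np.asarray(perm)
        est = MultifractalMeasure(
            m=estimated.m,
            k=estimated.k,
            P=estimated.P[np.ix_(perm_arr, perm_arr)],
            L=estimated.L[perm_arr],
        )
    seqs = enumerate_categories(truth)
    codes = np.array(seqs)
    p_true = np.ones((len(seqs), len(seqs)))
    p_est = np.ones_like(p_true)
    w = np.ones(len(seqs))
    for l in range(truth.k):
        p_true *= truth.P[codes[:, l][:, None], codes[:, l][None, :]]
        p_est *= est.P[codes[:, l][:, None], codes[:, l][None, :]]
        w *= truth.L[codes[:, l]]
    weight = w[:, None] * w[None, :]
    return float(np.sum(weight * p_true * np.log(p_true / p_est)))


# ----------------------------------------------------------------------
# structural similarity
# ----------------------------------------------------------------------


def ks_distance(
    reference: nx.Graph,
    measure: MultifractalMeasure,
    n_samples: int,
    rng: np.random.Generator,
) -> MetricReport:
    """KS distance between the reference degree distribution and degree
    distributions of networks generated from the measure (mean +/- sd)."""
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    ref_deg = np.array([d for _, d in reference.degree()])
    n = reference.number_of_nodes()
    vals = []
    for _ in range(n_samples):
        assignment = default_assignment(measure, n, rng)
        g = sample_network(measure, assignment, rng)
        deg = np.array([d for _, d in g.degree()])
        vals.append(float(ks_2samp(ref_deg, deg).statistic))
    vals = np.asarray(vals)
    return MetricReport(
        metric="ks_distance",
        value=float(vals.mean()),
        dispersion=float(vals.std(ddof=1)) if n_samples > 1 else None,
        n_replicates=n_samples,
        config={"n_samples": n_samples, "n_nodes": n},
    )


def model_fit_loglik(
    measure: MultifractalMeasure,
    reference: nx.Graph,
    assignment: Mapping[Hashable, Sequence[int]],
) -> float:
    """Log-likelihood of the (full) reference graph under the measure."""
    return model_log_likelihood(measure, reference, assignment)


# ----------------------------------------------------------------------
# link prediction
# ----------------------------------------------------------------------


def link_auc(
    scores: pd.DataFrame,
    truth: nx.Graph,
    slot_map: Mapping[LatentSlot, Hashable],
) -> Tuple[float, float]:
    """(ROC-AUC, PR-AUC) of posterior edge scores against the true graph.

    ``slot_map`` aligns latent slot ``s`` with the node actually removed at
    attack step ``s`` (information available only to the evaluation
    harness).  Positives are the candidate pairs that are edges of the true
    graph; raises when there is no positive.
    """

    def resolve(u: Hashable) -> Hashable:
        return slot_map[u] if isinstance(u, LatentSlot) else u

    y_true = []
    y_score = []
    for u, v, score in scores[["u", "v", "score"]].itertuples(index=False):
        y_true.append(truth.has_edge(resolve(u), resolve(v)))
        y_score.append(score)
    y_true = np.asarray(y_true, dtype=int)
    y_score = np.asarray(y_score, dtype=float)
    if y_true.sum() == 0:
        raise ValueError("no positive pair: AUC is undefined")
    if y_true.all():
        raise ValueError("no negative pair: AUC is undefined")
    return float(roc_auc_score(y_true, y_score)), float(
        average_precision_score(y_true, y_score)
    )


# ----------------------------------------------------------------------
# injection analytics
# ----------------------------------------------------------------------


def coverage_curve(
    graph: nx.Graph,
    shares: Sequence[float],
    alpha: float,
    n_trials: int,
    rng: np.random.Generator,
) -> List[MetricReport]:
    """Mean coverage per injected share (paired trials).

    Within a trial all shares use prefixes of one injection sequence, so
    the per-trial coverage is monotone in the share by set inclusion and
    the means inherit the monotonicity exactly.
    """
    shares = list(shares)
    if any(s < 0 or s > 1 for s in shares):
        raise ValueError("shares must lie in [0, 1]")
    n = graph.number_of_nodes()
    n_max = max(int(np.ceil(s * n)) for s in shares) if shares else 0
    vals = {s: [] for s in shares}
    for _ in range(n_trials):
        seq = injection_sequence(graph, n_max, alpha, rng)
        for s in shares:
            injected = set(seq[: int(np.ceil(s * n))])
            vals[s].append(coverage(graph, injected))
    out = []
    for s in shares:
        arr = np.asarray(vals[s])
        out.append(
            MetricReport(
                metric="coverage",
                value=float(arr.mean()),
                dispersion=float(arr.std(ddof=1)) if n_trials > 1 else None,
                n_replicates=n_trials,
                config={"share": s, "alpha": alpha},
            )
        )
    return out


def affected_users_estimate(
    measure: MultifractalMeasure,
    n_total: int,
    share: float,
    alpha: float,
    n_instances: int,
    rng: np.random.Generator,
) -> MetricReport:
    """Mean number of affected users over network instances drawn from the
    measure, each with a fresh degree-preferential injection."""
    if n_instances < 1:
        raise ValueError("n_instances must be >= 1")
    vals = []
    for _ in range(n_instances):
        assignment = default_assignment(measure, n_total, rng)
        g = sample_network(measure, assignment, rng)
        injected = select_injected_nodes(g, share, alpha, rng)
        vals.append(affected_users(g, injected))
    arr = np.asarray(vals, dtype=float)
    return MetricReport(
        metric="affected_users",
        value=float(arr.mean()),
        dispersion=float(arr.std(ddof=1)) if n_instances > 1 else None,
        n_replicates=n_instances,
        config={"share": share, "alpha": alpha, "n_total": n_total},
    )
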