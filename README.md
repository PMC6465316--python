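# netreveal

Reconstruction of the missing substructure of a network that has been
sabotaged by a **degree-preferential adversarial removal process**.

Many partially observed networks — protein-interaction maps attacked by
viral interference, connectomes with damaged hub regions, social graphs
whose injected manipulation accounts have been hidden — are *not* random
subsamples of the full network: the missing part was selected by a process
that prefers (or avoids) highly connected nodes.  Estimators built on the
random-missingness assumption are then systematically biased.  `netreveal`
is for network scientists and systems biologists who want to recover both
the generative model of the original network and a posterior over the
removed nodes and edges while *exploiting*, rather than ignoring, the
statistics of the attack.

## Model

The original network `G₀` is a realization of a multifractal network
generator `𝒢 = (m, k, P, L)`: node `u` carries a category sequence
`c_u ∈ {1..m}^k` (levels i.i.d. from the length measure `L`) and each pair
links independently with probability

    p(c_u, c_v) = ∏_{l=1..k} P[c_u(l), c_v(l)] .

An attacker removes `T` nodes sequentially; at each step the victim is
drawn with probability `A_α(d_i) = d_i^α / Σ_j d_j^α` over the current
residual graph (`α > 0`: hubs; `α < 0`: boundary nodes; `α = 0`: random).
Writing `Z_t` for the time-ordered removed subgraphs and `ψ'` for the
category assignment of observed nodes and latent slots, the complete-data
log-likelihood is

    log P = log P_model(G₀ | ψ', P)  +  γ · log ∏_s A_α(d(z_s), s) ,

and `P` is estimated by Monte-Carlo EM: the E-step samples `(Z_t, ψ')`
from their joint posterior with a Gibbs scheme (recursive rejection draws
of the removal path, Metropolis link-set/rewiring moves per removal event,
and category-swap moves), the M-step performs batch gradient ascent on the
Monte-Carlo Q-function.  `γ = 0` gives the attack-blind baseline;
`γ = 1` the full causal likelihood.  See `docs/methods.md` for the
derivations, sampler details and known limitations.

## Worked example

```python
import numpy as np
from netreveal import (MultifractalMeasure, NetworkReconstructor,
                       default_assignment, sample_network, simulate_attack)
from netreveal.evaluation import frobenius_error, signed_kl_divergence

rng = np.random.default_rng(0)

# ground truth: a 32-node multifractal network (m=2, k=5)
truth = MultifractalMeasure.random(2, 5, rng, mean_degree=6.0, n_nodes=32)
g0 = sample_network(truth, default_assignment(truth, 32, rng), rng)

# hub-prioritized attack removes 8 of 32 nodes
residual, trajectory = simulate_attack(g0, alpha=10.0, T=8, rng=rng)
print(f"original: {g0.number_of_nodes()} nodes / {g0.number_of_edges()} edges; "
      f"residual: {residual.number_of_nodes()} nodes / {residual.number_of_edges()} edges")
print(f"true victim degrees: {[e.degree for e in trajectory.events]}")

for gamma, label in [(0.0, "baseline (attack-blind)"), (1.0, "proposed (attack-aware)")]:
    rec = NetworkReconstructor(
        n_missing=8, alpha=10.0, gamma=gamma, m=2, k=5,
        n_samples=1000, n_burnin=300, max_iter=8, random_state=7,
    ).fit(residual)
    e_f = frobenius_error(rec.measure_, truth)
    kl = signed_kl_divergence(truth, rec.measure_)
    print(f"{label}: e_F = {e_f:.3f}, signed KL = {kl:+.3f}, "
          f"{rec.n_iter_} EM iterations")
```

prints

```
original: 32 nodes / 83 edges; residual: 24 nodes / 29 edges
true victim degrees: [8, 7, 7, 7, 8, 7, 5, 5]
baseline (attack-blind): e_F = 0.289, signed KL = +0.128, 8 EM iterations
proposed (attack-aware): e_F = 0.211, signed KL = +0.046, 3 EM iterations
```

The attack removed the hubs (victim degrees 5–8 against a mean degree of
~5), so the residual graph underrepresents dense structure.  The
attack-blind fit underestimates link probabilities (positive signed
divergence, larger Frobenius error on the recovered base matrix `P`); the
attack-aware fit, which insists that every restored node must also look
like a plausible victim of a hub-seeking attacker, recovers `P` with ~30%
less error and a near-zero divergence.  After fitting,
`rec.edge_scores_` holds posterior link scores for every candidate pair
involving a removed node, and `rec.samples_` the posterior sample pool.

The same machinery is exposed functionally (`run_em`,
`draw_posterior_samples`, `enumerate_posterior_exact`, …) and through a
CLI (`netreveal recover-synthetic`, `recover-real`, `injection`,
`fixtures`) with desk-scale (n=64, K=2000) and paper-scale
(n=1024, K=40000) presets; real-data loaders accept SNAP-style edge lists,
adjacency CSVs and tab-delimited interaction tables.

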