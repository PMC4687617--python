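"""Synthetic trees and Brownian-motion trait data with full ground truth.

Traits evolve by Brownian motion (BM) in log space: the change along a
branch of length ``b`` is drawn from Normal(0, sigma2*b), independently per
branch, and node values are partial sums along root-to-node paths.  The
increment-per-branch construction is distributionally identical to a
multivariate-normal draw over tips but additionally records the true change
on every branch, which is what the downstream bias audits compare against.

Geometric normality is emulated by exponentiating the log-space values at
every node and tip, so the arithmetic-scale traits are log-normal with
variance growing from root to tips.

Seeding: every public entry point takes an integer seed; replicate ``i`` of
a batch uses ``numpy.random.default_rng([seed, i])`` so any single replicate
is reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .trees import Phylogeny

__all__ = [
    "SimulationTruth",
    "PairTruth",
    "simulate_tree",
    "simulate_bm_trait",
    "simulate_correlated_pair",
    "beta_grid",
]


@dataclass(frozen=True)
class SimulationTruth:
    """True node values and per-branch changes for one simulated trait.

    ``log_values`` are indexed by node id and include internal nodes;
    ``arithmetic_values = exp(log_values)``.  ``branch_changes[i]`` is the
    log change on the branch above node ``i`` (NaN at the root), and
    ``standardized_changes`` divides by the square root of branch length.
    """

    tree: Phylogeny
    log_values: np.ndarray
    arithmetic_values: np.ndarray
    branch_changes: np.ndarray
    standardized_changes: np.ndarray
    sigma2: float
    seed: object

    def tip_values(self, space: str = "arithmetic") -> dict[str, float]:
        """Tip-label → value map in 'arithmetic' or 'log' space."""
        vals = self.arithmetic_values if space == "arithmetic" else self.log_values
        return {self.tree.labels[i]: float(vals[i]) for i in self.tree.tips}


@dataclass(frozen=True)
class PairTruth:
    """Two traits simulated under correlated BM on one shared tree.

    ``beta`` is the simulated evolutionary regression coefficient of trait 2
    on trait 1; with unit marginal rates it equals the increment covariance.
    """

    trait1: SimulationTruth
    trait2: SimulationTruth
    beta: float


def simulate_tree(n_tips: int, seed: int) -> Phylogeny:
    """Random rooted binary tree from a pure-birth (Yule) process, rate 1.

    Lineages split at exponential waiting times until ``n_tips`` are extant;
    all pendant branches are then extended to the final time, so the tree is
    ultrametric.  Branch lengths are strictly positive with probability one.
    """
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    rng = np.random.default_rng(seed)
    # grow an edge list over provisional ids; root = 0 splits immediately
    parent_of = {1: 0, 2: 0}
    birth = {1: 0.0, 2: 0.0}  # time each extant lineage began
    active = [1, 2]
    t, next_id = 0.0, 3
    while len(active) < n_tips:
        t += rng.exponential(1.0 / len(active))
        k = int(rng.integers(len(active)))
        node = active.pop(k)
        for _ in range(2):
            parent_of[next_id] = node
            birth[next_id] = t
            active.append(next_id)
            next_id += 1
    t += rng.exponential(1.0 / len(active))  # stem time after last split
    end = {node: t for node in active}  # tips extend to the present
    for node in list(parent_of):
        if node not in end:
            end[node] = birth[min(c for c, p in parent_of.items() if p == node)]
    # dendropy-free conversion to postorder ids
    children: dict[int, list[int]] = {}
    for c, p in parent_of.items():
        children.setdefault(p, []).append(c)
    post: list[int] = []

    def _post(u: int) -> None:
        for c in sorted(children.get(u, [])):
            _post(c)
        post.append(u)

    _post(0)
    index = {u: i for i, u in enumerate(post)}
    parent, lengths, labels = [], [], []
    tip_counter = 0
    for u in post:
        if u == 0:
            parent.append(-1)
            lengths.append(np.nan)
        else:
            p = parent_of[u]
            parent.append(index[p])
            lengths.append(end[u] - birth[u])
        if u in children:
            labels.append(None)
        else:
            tip_counter += 1
            labels.append(f"t{tip_counter}")
    return Phylogeny(parent, lengths, labels)


def _branch_increments(tree: Phylogeny, sigma2: float, rng) -> np.ndarray:
    scale = np.sqrt(sigma2 * np.where(np.isnan(tree.lengths), 0.0, tree.lengths))
    return rng.standard_normal(tree.n_nodes) * scale


def _truth_from_changes(
    tree: Phylogeny, changes: np.ndarray, root_value: float, sigma2: float, seed
) -> SimulationTruth:
    log_values = np.empty(tree.n_nodes)
    log_values[tree.root] = root_value
    changes = changes.copy()
    changes[tree.root] = np.nan
    for i in range(tree.n_nodes - 2, -1, -1):
        log_values[i] = log_values[tree.parent[i]] + changes[i]
    std = changes / np.sqrt(tree.lengths)
    return SimulationTruth(
        tree=tree,
        log_values=log_values,
        arithmetic_values=np.exp(log_values),
        branch_changes=changes,
        standardized_changes=std,
        sigma2=sigma2,
        seed=seed,
    )


def simulate_bm_trait(
    tree: Phylogeny,
    sigma2: float = 1.0,
    root_value: float = 0.0,
    seed: int | list[int] = 0,
) -> SimulationTruth:
    """Simulate one geometrically normal trait: BM in log space, then exp.

    With the defaults (sigma2=1, root 0), every node's expected log value is
    0 and its log-space variance equals its distance from the root.
    """
    if not sigma2 > 0:
        raise ValueError("sigma2 must be positive")
    rng = np.random.default_rng(seed)
    changes = _branch_increments(tree, sigma2, rng)
    return _truth_from_changes(tree, changes, root_value, sigma2, seed)


def simulate_correlated_pair(
    tree: Phylogeny,
    beta: float,
    seed: int | list[int] = 0,
    root_value: float = 0.0,
) -> PairTruth:
    """Simulate two traits under correlated BM with unit marginal rates.

    Per-branch increments are bivariate normal with covariance matrix
    ``[[1, beta], [beta, 1]] * branch_length`` in log space, so ``beta`` is
    both the increment correlation and the evolutionary regression
    coefficient of trait 2 on trait 1.
    """
    if abs(beta) > 1:
        raise ValueError("|beta| must be <= 1 (rate matrix must be PSD)")
    rng = np.random.default_rng(seed)
    z1 = _branch_increments(tree, 1.0, rng)
    z2 = _branch_increments(tree, 1.0, rng)
    c1 = z1
    c2 = beta * z1 + np.sqrt(1.0 - beta * beta) * z2
    return PairTruth(
        trait1=_truth_from_changes(tree, c1, root_value, 1.0, seed),
        trait2=_truth_from_changes(tree, c2, root_value, 1.0, seed),
        beta=float(beta),
    )


def beta_grid(n_pairs: int) -> np.ndarray:
    """Evenly spaced regression coefficients from 0 to 1 inclusive."""
    if n_pairs < 2:
        raise ValueError("n_pairs must be >= 2")
    return np.linspace(0.0, 1.0, n_pairs)
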