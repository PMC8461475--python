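"""Marginal ancestral state reconstruction under the equal-rates Mk model.

A symmetric continuous-time Markov chain over k discrete states (all
off-diagonal rates equal) has the closed-form transition probability

    P(t)_ii = 1/k + (k-1)/k * exp(-k r t)
    P(t)_ij = 1/k - 1/k   * exp(-k r t)   (i != j)

Partial likelihoods are propagated by Felsenstein's pruning algorithm; the
root prior is the stationary (uniform) distribution; marginal posteriors at
internal nodes come from the standard up-down (outside) pass.  The single
rate r is fitted per character set by bounded scalar likelihood
maximisation.

All functions are vectorised over characters: ``tip_states`` maps each tip
name to an integer array of per-character states (-1 = missing data).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .tree import Tree

RATE_BOUNDS = (1e-6, 100.0)


class ASRError(ValueError):
    pass


def er_transition_matrix(k: int, rate: float, t: float) -> np.ndarray:
    """Closed-form transition matrix of the k-state equal-rates model."""
    e = np.exp(-k * rate * t)
    P = np.full((k, k), (1.0 - e) / k)
    np.fill_diagonal(P, 1.0 / k + (k - 1) / k * e)
    return P


def _tip_partials(states: np.ndarray, k: int) -> np.ndarray:
    """(n_chars, k) indicator partials; -1 means missing (all ones)."""
    n = states.shape[0]
    L = np.zeros((n, k))
    miss = states < 0
    L[miss, :] = 1.0
    obs = ~miss
    L[np.nonzero(obs)[0], states[obs]] = 1.0
    return L


def _prepare(tree: Tree, tip_states: dict[str, np.ndarray], k: int):
    nodes = list(tree.postorder())
    index = {node.name: i for i, node in enumerate(nodes)}
    n_chars = None
    for name, st in tip_states.items():
        st = np.atleast_1d(np.asarray(st, dtype=int))
        if n_chars is None:
            n_chars = st.shape[0]
        elif st.shape[0] != n_chars:
            raise ASRError("inconsistent character counts across tips")
        if np.any(st >= k):
            raise ASRError(f"tip {name!r} state outside 0..{k - 1}")
        tip_states[name] = st
    for node in nodes:
        if node.is_leaf and node.name not in tip_states:
            raise ASRError(f"no states for tip {node.name!r}")
    return nodes, index, n_chars


def _down_pass(nodes, tip_states, k, rate):
    """Pruning pass. Returns per-node partials (scaled), per-node log-scale
    accumulators, and the per-branch transition matrices."""
    n_chars = next(iter(tip_states.values())).shape[0]
    partials: list[np.ndarray | None] = [None] * len(nodes)
    log_scale = np.zeros((len(nodes), n_chars))
    P_branch: list[np.ndarray | None] = [None] * len(nodes)
    index = {node.name: i for i, node in enumerate(nodes)}

    for i, node in enumerate(nodes):
        if node.parent is not None:
            P_branch[i] = er_transition_matrix(k, rate, node.length)
        if node.is_leaf:
            partials[i] = _tip_partials(tip_states[node.name], k)
            continue
        L = np.ones((n_chars, k))
        scale = np.zeros(n_chars)
        for child in node.children:
            j = index[child.name]
            L = L * (partials[j] @ P_branch[j].T)
            scale += log_scale[j]
        mx = L.max(axis=1)
        bad = mx <= 0
        if np.any(bad):
            raise ASRError(
                f"zero likelihood below node {node.name!r} "
                f"(characters {np.nonzero(bad)[0][:5].tolist()}...)")
        L = L / mx[:, None]
        partials[i] = L
        log_scale[i] = scale + np.log(mx)
    return partials, log_scale, P_branch


def log_likelihood(tree: Tree, tip_states: dict[str, np.ndarray], k: int,
                   rate: float) -> np.ndarray:
    """Per-character log-likelihood under a uniform root prior."""
    nodes, _, _ = _prepare(tree, dict(tip_states), k)
    partials, log_scale, _ = _down_pass(nodes, dict(tip_states), k, rate)
    root = len(nodes) - 1
    lik = partials[root].mean(axis=1)  # uniform prior 1/k
    return np.log(lik) + log_scale[root]


def fit_rate(tree: Tree, tip_states: dict[str, np.ndarray], k: int,
             bounds: tuple[float, float] = RATE_BOUNDS) -> float:
    """ML estimate of the single equal-rates rate (summed over characters)."""

    def neg_ll(log_rate: float) -> float:
        return -float(np.sum(log_likelihood(tree, tip_states, k,
                                            np.exp(log_rate))))

    res = minimize_scalar(neg_ll, bounds=(np.log(bounds[0]),
                                          np.log(bounds[1])),
                          method="bounded",
                          options={"xatol": 1e-4})
    return float(np.exp(res.x))


@dataclass
class MarginalASR:
    """Marginal posteriors: node name -> (n_chars, k) probability array."""

    posteriors: dict[str, np.ndarray]
    rate: float
    log_lik: float
    k: int

    def node(self, name: str) -> np.ndarray:
        return self.posteriors[name]


def marginal_posteriors(tree: Tree, tip_states: dict[str, np.ndarray],
                        k: int, rate: float | None = None) -> MarginalASR:
    """Marginal posterior state probabilities at every node.

    ``rate=None`` fits the rate by maximum likelihood first.
    """
    tip_states = {name: np.atleast_1d(np.asarray(s, dtype=int))
                  for name, s in tip_states.items()}
    nodes, index, n_chars = _prepare(tree, tip_states, k)
    if rate is None:
        rate = fit_rate(tree, tip_states, k)
    partials, log_scale, P_branch = _down_pass(nodes, tip_states, k, rate)
    root = len(nodes) - 1

    # outside (above-subtree) arrays, preorder
    above: list[np.ndarray | None] = [None] * len(nodes)
    above[root] = np.full((n_chars, k), 1.0 / k)
    for node in reversed(nodes):  # reversed postorder = preorder
        i = index[node.name]
        if above[i] is None:
            continue
        for child in node.children:
            j = index[child.name]
            sib = above[i].copy()
            for other in node.children:
                if other is child:
                    continue
                o = index[other.name]
                sib = sib * (partials[o] @ P_branch[o].T)
            A = sib @ P_branch[j]
            mx = A.max(axis=1)
            mx[mx <= 0] = 1.0
            above[j] = A / mx[:, None]

    posteriors = {}
    for i, node in enumerate(nodes):
        post = partials[i] * above[i]
        total = post.sum(axis=1, keepdims=True)
        if np.any(total <= 0):
            raise ASRError(f"non-finite posterior at node {node.name!r}")
        posteriors[node.name] = post / total

    lik = partials[root].mean(axis=1)
    ll = float(np.sum(np.log(lik) + log_scale[root]))
    return MarginalASR(posteriors=posteriors, rate=rate, log_lik=ll, k=k)
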