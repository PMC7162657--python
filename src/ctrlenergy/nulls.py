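"""Degree- and strength-preserving surrogate networks and real-vs-null tests.

Surrogates randomize the placement of edge weights while preserving, exactly,
the binary degree sequence and the multiset of edge weights, and, closely,
the nodal strength sequence:

1. the binary topology is randomized by degree-preserving double-edge swaps
   (Maslov-Sneppen); for (near-)complete graphs, where no swap changes the
   topology, this step is skipped;
2. the original weights are then re-assigned to the randomized edges by a
   greedy residual-strength rule: weights are placed in descending order on
   the edge whose endpoints currently have the largest residual target
   strength product, choosing at random among the top candidates so that
   different seeds give different surrogates.

This is the standard weighted-network null for tractography-style dense
matrices, where the informative structure lives in the weight placement.
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
from numba import njit
from scipy import stats

from .errors import DegenerateTestError, ValidationError
from .network import Connectome

logger = logging.getLogger(__name__)


@njit(cache=False)
def _place_weights(iu, ju, weights_desc, target_strength, top_k, seed):
    """Greedy residual-strength weight placement (see module docstring)."""
    np.random.seed(seed)
    m = iu.shape[0]
    out = np.empty(m)
    resid = target_strength.copy()
    remaining = np.arange(m)
    nrem = m
    best_idx = np.empty(top_k, dtype=np.int64)
    best_sc = np.empty(top_k)
    for k in range(m):
        t = min(top_k, nrem)
        for j in range(t):
            best_idx[j] = -1
            best_sc[j] = -1.0
        for pos in range(nrem):
            e = remaining[pos]
            ru = resid[iu[e]]
            rv = resid[ju[e]]
            if ru < 0.0:
                ru = 0.0
            if rv < 0.0:
                rv = 0.0
            sc = ru * rv
            if sc > best_sc[t - 1]:
                j = t - 1
                while j > 0 and best_sc[j - 1] < sc:
                    best_sc[j] = best_sc[j - 1]
                    best_idx[j] = best_idx[j - 1]
                    j -= 1
                best_sc[j] = sc
                best_idx[j] = pos
        pick = best_idx[np.random.randint(t)]
        e = remaining[pick]
        w = weights_desc[k]
        out[e] = w
        resid[iu[e]] -= w
        resid[ju[e]] -= w
        remaining[pick] = remaining[nrem - 1]
        nrem -= 1
    return out


@njit(cache=False)
def _refine_weights(iu, ju, w, target_strength, n_nodes, n_attempts, seed):
    """Local search: swap weight pairs whenever that reduces the squared
    strength error; leaves degree and the weight multiset untouched."""
    np.random.seed(seed)
    m = iu.shape[0]
    d = np.zeros(n_nodes)  # current strength minus target
    for e in range(m):
        d[iu[e]] += w[e]
        d[ju[e]] += w[e]
    d -= target_strength
    for _ in range(n_attempts):
        e = np.random.randint(m)
        f = np.random.randint(m)
        if e == f or w[e] == w[f]:
            continue
        nodes = np.empty(4, dtype=np.int64)
        nodes[0], nodes[1], nodes[2], nodes[3] = iu[e], ju[e], iu[f], ju[f]
        dw = w[f] - w[e]
        signs = (dw, dw, -dw, -dw)
        # change in sum of squared deficits if we swap w[e] <-> w[f]
        delta = 0.0
        for t in range(4):
            node = nodes[t]
            dup = False
            for t2 in range(t):
                if nodes[t2] == node:
                    dup = True
            if dup:
                continue
            shift = 0.0
            for t2 in range(4):
                if nodes[t2] == node:
                    shift += signs[t2]
            delta += (d[node] + shift) ** 2 - d[node] ** 2
        if delta < 0.0:
            d[nodes[0]] += dw
            d[nodes[1]] += dw
            d[nodes[2]] -= dw
            d[nodes[3]] -= dw
            tmp = w[e]
            w[e] = w[f]
            w[f] = tmp
    return w


def rewire_preserving_degree_strength(
    connectome: Connectome,
    seed: int,
    n_swap_per_edge: int = 10,
    top_k: int | None = None,
) -> Connectome:
    """One degree- and strength-preserving surrogate of ``connectome``.

    ``top_k`` controls the stochastic choice in the weight-placement step.
    By default it is 1 (deterministic best-match placement) when the topology
    was randomized by swaps, and 10 for complete graphs, where the weight
    placement is the only source of randomness.
    """
    w = connectome.weights
    n = connectome.n_nodes
    iu0, ju0 = np.nonzero(np.triu(w, k=1))
    m = iu0.size
    if m < 4:
        raise ValidationError("rewiring requires at least 4 edges")
    rng = np.random.default_rng(seed)
    complete = m == n * (n - 1) // 2
    if top_k is None:
        top_k = 10 if complete else 1
    if complete:
        # every topology swap is vacuous; only the weight placement randomizes
        iu, ju = iu0, ju0
    else:
        g = nx.Graph(zip(iu0.tolist(), ju0.tolist()))
        try:
            nx.double_edge_swap(
                g,
                nswap=n_swap_per_edge * m,
                max_tries=100 * n_swap_per_edge * m,
                seed=int(rng.integers(2**31)),
            )
        except nx.NetworkXError:
            logger.warning(
                "double-edge swaps infeasible (graph too small/dense); "
                "falling back to weight re-placement on the original topology"
            )
        edges = np.array(sorted(tuple(sorted(e)) for e in g.edges()))
        iu, ju = edges[:, 0], edges[:, 1]
    weights_desc = np.sort(w[iu0, ju0])[::-1].copy()
    target_strength = w.sum(axis=1)
    iu = iu.astype(np.int64)
    ju = ju.astype(np.int64)
    placed = _place_weights(
        iu, ju, weights_desc, target_strength, int(top_k), int(rng.integers(2**31))
    )
    placed = _refine_weights(
        iu,
        ju,
        placed,
        target_strength,
        n,
        50 * m,
        int(rng.integers(2**31)),
    )
    out = np.zeros((n, n))
    out[iu, ju] = placed
    out[ju, iu] = placed
    return Connectome(
        weights=out, node_labels=connectome.node_labels, systems=connectome.systems
    )


class NullEnsemble:
    """A set of surrogate connectomes with seeds and preservation diagnostics."""

    def __init__(self, connectome: Connectome, n_null: int, seed: int, **kwargs):
        rng = np.random.default_rng(seed)
        self.seeds = rng.integers(2**31, size=n_null)
        self.surrogates = [
            rewire_preserving_degree_strength(connectome, int(s), **kwargs)
            for s in self.seeds
        ]
        deg = (connectome.weights > 0).sum(axis=1)
        strength = connectome.weights.sum(axis=1)
        self.degree_match = [
            bool(np.array_equal((s.weights > 0).sum(axis=1), deg))
            for s in self.surrogates
        ]
        self.strength_correlation = [
            float(np.corrcoef(strength, s.weights.sum(axis=1))[0, 1])
            for s in self.surrogates
        ]


def real_vs_null_energy_test(real_energies, null_mean_energies) -> dict:
    """Paired t-test of per-subject null-mean vs real energies.

    The mean difference is reported as ``null - real`` so a positive value
    means null networks are more costly.
    """
    real = np.asarray(real_energies, dtype=float)
    null = np.asarray(null_mean_energies, dtype=float)
    if real.shape != null.shape or real.ndim != 1:
        raise ValidationError("paired vectors of equal length required")
    if real.size < 3:
        raise ValidationError("paired t-test requires n >= 3")
    diff = null - real
    if np.allclose(diff.std(ddof=1), 0.0):
        raise DegenerateTestError("zero-variance differences: paired t undefined")
    t, p = stats.ttest_rel(null, real)
    return {
        "mean_difference": float(diff.mean()),
        "t": float(t),
        "df": real.size - 1,
        "p_value": float(p),
    }


def null_age_effect_test(real_effect: float, null_effects) -> float:
    """One-tailed permutation p for a negative age effect.

    ``p = (k + 1) / (n + 1)`` where ``k`` counts null effects at least as
    negative as the real one.
    """
    null_effects = np.asarray(null_effects, dtype=float)
    if null_effects.size == 0:
        raise ValidationError("at least one null effect is required")
    k = int(np.sum(null_effects <= real_effect))
    return (k + 1) / (null_effects.size + 1)
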