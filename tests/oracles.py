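"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own algorithms: structures are
enumerated explicitly instead of solved by dynamic programming, and tree
likelihoods are summed over every internal-state assignment instead of
pruned.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

ALLOWED = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}


def enumerate_nested_structures(seq: str, min_loop: int = 3):
    """Yield every nested structure (as a frozenset of index pairs)."""

    def rec(i: int, j: int):
        if j - i < min_loop + 1:
            yield frozenset()
            return
        yield from rec(i + 1, j)
        for k in range(i + min_loop + 1, j + 1):
            if (seq[i], seq[k]) in ALLOWED:
                for left in rec(i + 1, k - 1):
                    for right in rec(k + 1, j):
                        yield left | right | {(i, k)}

    yield from rec(0, len(seq) - 1)


def max_pairs_enumeration(seq: str, min_loop: int = 3) -> int:
    return max(len(s) for s in enumerate_nested_structures(seq, min_loop))


def brute_force_log_likelihood(tree, rows, model) -> float:
    """Sum the phylogenetic likelihood over all internal-state assignments."""
    from rnaphylo.phylo_ml.likelihood import _char_vectors

    nodes = list(tree.postorder())
    internals = [n for n in nodes if not n.is_leaf]
    n = model.n_states
    rates = model.gamma_rates()
    vecs = _char_vectors(n)
    n_sites = len(next(iter(rows.values())))
    tipv = {
        label: np.stack([vecs[c] for c in rows[label]], axis=1)
        for label in rows
    }  # (n_states, n_sites)

    site_lik = np.zeros(n_sites)
    for r in rates:
        P = {
            id(nd): model.transition_matrix(nd.length or 0.0, r)
            for nd in nodes
            if nd is not tree.root
        }
        acc = np.zeros(n_sites)
        for assign in itertools.product(range(n), repeat=len(internals)):
            amap = dict(zip((id(x) for x in internals), assign))
            term = np.full(n_sites, model.freqs[amap[id(tree.root)]])
            for nd in nodes:
                if nd is tree.root:
                    continue
                ps = amap[id(nd.parent)]
                if nd.is_leaf:
                    term = term * (P[id(nd)][ps] @ tipv[nd.label])
                else:
                    term = term * P[id(nd)][ps, amap[id(nd)]]
            acc += term
        site_lik += acc / len(rates)
    if model.p_inv > 0:
        prod = np.ones((n, n_sites))
        for label in rows:
            prod *= tipv[label]
        inv = model.freqs @ prod
        site_lik = (1.0 - model.p_inv) * site_lik + model.p_inv * inv
    return float(np.sum(np.log(site_lik)))


def k2p_recount(a: str, b: str):
    """Direct per-pair K2P recount (pairwise deletion)."""
    purine = set("AG")
    plain = set("ACGU")
    ts = tv = n = 0
    for x, y in zip(a, b):
        if x not in plain or y not in plain:
            continue
        n += 1
        if x == y:
            continue
        if (x in purine) == (y in purine):
            ts += 1
        else:
            tv += 1
    P, Q = ts / n, tv / n
    if 1 - 2 * P - Q <= 0 or 1 - 2 * Q <= 0:
        return None
    return -0.5 * math.log(1 - 2 * P - Q) - 0.25 * math.log(1 - 2 * Q)


def random_rooted_tree(labels, rng, max_bl: float = 0.8):
    """A random rooted binary tree with random branch lengths."""
    from rnaphylo.phylo_ml.tree import Node, PhyloTree

    nodes = [Node(label, float(rng.uniform(0.02, max_bl))) for label in labels]
    while len(nodes) > 2:
        i = int(rng.integers(len(nodes)))
        a = nodes.pop(i)
        j = int(rng.integers(len(nodes)))
        b = nodes.pop(j)
        parent = Node(None, float(rng.uniform(0.02, max_bl)))
        parent.add(a)
        parent.add(b)
        nodes.append(parent)
    root = Node()
    for nd in nodes:
        root.add(nd)
    return PhyloTree(root)


def random_model(n_states: int, rng, gamma: bool = True, pinv: bool = True):
    from rnaphylo.phylo_ml.model import SubstitutionModel

    S = rng.uniform(0.3, 3.0, (n_states, n_states))
    S = 0.5 * (S + S.T)
    freqs = rng.dirichlet(np.ones(n_states) * 5.0)
    alpha = float(rng.uniform(0.3, 2.0)) if gamma else None
    p_inv = float(rng.uniform(0.0, 0.4)) if pinv else 0.0
    return SubstitutionModel(n_states, S, freqs, alpha, 4, p_inv)
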