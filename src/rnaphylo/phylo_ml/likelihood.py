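"""Felsenstein pruning likelihood with branch-length and model optimisation.

The engine evaluates partitioned datasets on one shared topology: each
partition carries its own alignment, substitution model and a branch-length
rate multiplier. Site patterns are compressed, gaps and fully-missing
symbols are all-ones partial vectors, ambiguity codes are indicator vectors
over their compatible states, and the +I+Gamma mixture is applied at the
site level (the invariant-site term only contributes for patterns compatible
with a constant site).

Branch lengths are optimised by exact one-dimensional coordinate ascent:
one post-order pass caches the conditional likelihoods below every edge, a
pre-order pass then re-optimises each edge with Brent's method against
"above" partials that are updated on the way down, so the log-likelihood is
monotone across a sweep. NNI candidates are screened the same way: both
alternative arrangements around an internal edge are scored by re-optimising
only the central branch from cached partials.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize_scalar

from ..structure_model import IUPAC
from ..seqstruct_align import LETTERS12, MISSING, GAP, TwelveStateAlignment
from .model import SubstitutionModel, free_exchange_positions, with_updated_exchange
from .tree import Node, PhyloTree

BRANCH_MIN, BRANCH_MAX = 1e-8, 20.0
ALPHA_MIN, ALPHA_MAX = 0.02, 100.0
PINV_MIN, PINV_MAX = 0.0, 0.99
EXCH_MIN, EXCH_MAX = 1e-4, 1e4

NUC_LETTERS = "ACGU"


def _char_vectors(n_states: int) -> dict[str, np.ndarray]:
    """Map alignment characters to state indicator vectors."""
    out: dict[str, np.ndarray] = {}
    if n_states == 4:
        for ch, expansion in IUPAC.items():
            v = np.zeros(4)
            for b in expansion:
                v[NUC_LETTERS.index(b)] = 1.0
            out[ch] = v
        out["T"] = out["U"]
    else:
        for k, ch in enumerate(LETTERS12):
            v = np.zeros(12)
            v[k] = 1.0
            out[ch] = v
        out[MISSING] = np.ones(12)
    out[GAP] = np.ones(n_states)
    out["?"] = np.ones(n_states)
    return out


class _Partition:
    """Pattern-compressed data plus model for one partition."""

    def __init__(self, rows: dict[str, str], model: SubstitutionModel, mult: float = 1.0):
        if mult <= 0:
            raise ValueError("partition rate multiplier must be > 0")
        self.model = model
        self.mult = mult
        self.taxa = sorted(rows)
        vectors = _char_vectors(model.n_states)
        chars = np.array([list(rows[t].upper()) for t in self.taxa])
        patterns, counts = np.unique(chars, axis=1, return_counts=True)
        self.counts = counts.astype(float)
        self.n_sites = chars.shape[1]
        self.n_patterns = patterns.shape[1]
        self.tips: dict[str, np.ndarray] = {}
        for r, taxon in enumerate(self.taxa):
            try:
                tip = np.stack([vectors[c] for c in patterns[r]], axis=1)
            except KeyError as exc:
                raise ValueError(
                    f"invalid character {exc} in row {taxon!r}"
                ) from exc
            self.tips[taxon] = tip  # (n_states, n_patterns)

    def invariant_site_lik(self) -> np.ndarray:
        """Per-pattern probability of the pattern under an invariant site."""
        prod = np.ones((self.model.n_states, self.n_patterns))
        for tip in self.tips.values():
            prod *= tip
        return self.model.freqs @ prod


class LikelihoodEngine:
    """Partitioned pruning likelihood bound to one (mutable) tree."""

    def __init__(self, tree: PhyloTree, partitions: Sequence[_Partition]):
        self.partitions = list(partitions)
        self.set_tree(tree)

    def set_tree(self, tree: PhyloTree) -> None:
        leaves = set(tree.leaf_labels())
        for part in self.partitions:
            missing = sorted(set(part.taxa) - leaves)
            if missing:
                raise ValueError(f"taxa missing from tree: {missing}")
        self.tree = tree

    # -- core passes ---------------------------------------------------------

    def _pmats(self, part: _Partition, t: float) -> np.ndarray:
        return part.model.transition_matrices(max(t, 0.0) * part.mult)

    def _down(self, part: _Partition) -> tuple[dict, dict]:
        """Post-order conditional likelihoods D and per-edge messages M."""
        k = len(part.model.gamma_rates())
        D: dict[int, np.ndarray] = {}
        M: dict[int, np.ndarray] = {}
        for node in self.tree.postorder():
            if node.is_leaf:
                if node.label in part.tips:
                    D[id(node)] = np.broadcast_to(
                        part.tips[node.label],
                        (k,) + part.tips[node.label].shape,
                    )
                else:  # taxon absent from this partition: fully missing
                    D[id(node)] = np.ones(
                        (k, part.model.n_states, part.n_patterns)
                    )
            else:
                prod = None
                for child in node.children:
                    P = self._pmats(part, child.length or 0.0)
                    Mc = np.einsum("kab,kbp->kap", P, D[id(child)])
                    M[id(child)] = Mc
                    prod = Mc if prod is None else prod * Mc
                D[id(node)] = prod
        return D, M

    def _site_liks(self, part: _Partition, percat: np.ndarray) -> np.ndarray:
        """Combine per-category pattern likelihoods with the +I mixture."""
        model = part.model
        site = percat.mean(axis=0)
        if model.p_inv > 0:
            site = (1.0 - model.p_inv) * site + model.p_inv * part.invariant_site_lik()
        return site

    def lnl(self) -> float:
        total = 0.0
        for part in self.partitions:
            D, _ = self._down(part)
            root = D[id(self.tree.root)]
            percat = np.einsum("x,kxp->kp", part.model.freqs, root)
            site = self._site_liks(part, percat)
            total += float(part.counts @ np.log(site))
        return total

    def site_log_likelihoods(self) -> np.ndarray:
        """Per-site log-likelihoods in original site order (single partition)."""
        if len(self.partitions) != 1:
            raise ValueError("per-site values are defined for one partition")
        part = self.partitions[0]
        D, _ = self._down(part)
        root = D[id(self.tree.root)]
        percat = np.einsum("x,kxp->kp", part.model.freqs, root)
        return np.log(self._site_liks(part, percat))

    # -- branch-length optimisation ------------------------------------------

    def _edge_lnl(self, states: list[tuple], t: float) -> float:
        """lnL as a function of one edge length from cached partials.

        ``states`` holds (part, S, D_node, inv) tuples per partition.
        """
        total = 0.0
        for part, S, Dn, inv in states:
            P = np.stack(
                [
                    part.model.transition_matrix(t * part.mult, r)
                    for r in part.model.gamma_rates()
                ]
            )
            PD = np.einsum("kab,kbp->kap", P, Dn)
            percat = np.einsum("kxp,kxp->kp", S, PD)
            site = percat.mean(axis=0)
            if part.model.p_inv > 0:
                site = (1.0 - part.model.p_inv) * site + part.model.p_inv * inv
            total += float(part.counts @ np.log(np.maximum(site, 1e-300)))
        return total

    def _optimize_edge(self, states: list[tuple], t0: float) -> float:
        res = minimize_scalar(
            lambda t: -self._edge_lnl(states, t),
            bounds=(BRANCH_MIN, BRANCH_MAX),
            method="bounded",
            options={"xatol": 1e-8},
        )
        if -res.fun >= self._edge_lnl(states, t0):
            return float(res.x)
        return t0

    def optimize_branch_lengths(
        self, max_sweeps: int = 50, tol: float = 1e-6
    ) -> float:
        """Coordinate-ascent sweeps; returns the final log-likelihood."""
        invs = [p.invariant_site_lik() if p.model.p_inv > 0 else None
                for p in self.partitions]
        prev = self.lnl()
        for _ in range(max_sweeps):
            downs = [self._down(part) for part in self.partitions]

            def visit(node: Node, S_list: list[np.ndarray]) -> None:
                states = [
                    (part, S, downs[pi][0][id(node)], invs[pi])
                    for pi, (part, S) in enumerate(zip(self.partitions, S_list))
                ]
                node.length = self._optimize_edge(states, node.length or 0.0)
                new_m = []
                for pi, part in enumerate(self.partitions):
                    P = self._pmats(part, node.length)
                    Mn = np.einsum("kab,kbp->kap", P, downs[pi][0][id(node)])
                    downs[pi][1][id(node)] = Mn
                    new_m.append(Mn)
                if node.is_leaf:
                    return
                A_list = []
                for pi, part in enumerate(self.partitions):
                    P = self._pmats(part, node.length)
                    A_list.append(np.einsum("kxp,kxy->kyp", S_list[pi], P))
                for child in node.children:
                    S_child = []
                    for pi in range(len(self.partitions)):
                        S = A_list[pi].copy()
                        for other in node.children:
                            if other is not child:
                                S = S * downs[pi][1][id(other)]
                        S_child.append(S)
                    visit(child, S_child)

            root = self.tree.root
            for child in root.children:
                S_list = []
                for pi, part in enumerate(self.partitions):
                    S = np.broadcast_to(
                        part.model.freqs[None, :, None],
                        downs[pi][0][id(root)].shape,
                    ).copy()
                    for other in root.children:
                        if other is not child:
                            S = S * downs[pi][1][id(other)]
                    S_list.append(S)
                visit(child, S_list)

            current = self.lnl()
            if current - prev < tol:
                prev = max(prev, current)
                break
            prev = current
        return prev

    # -- model optimisation ----------------------------------------------------

    def optimize_models(
        self,
        max_sweeps: int = 50,
        tol: float = 1e-6,
        fit_exchange: bool = True,
        exchange_max_sweeps: Optional[int] = None,
    ) -> float:
        """Coordinate-wise optimisation of each partition's model parameters
        (alpha, p_inv when fitted, free exchangeabilities) at fixed tree."""
        prev = self.lnl()
        exch_sweeps_left = (
            exchange_max_sweeps if exchange_max_sweeps is not None else max_sweeps
        )
        current = prev
        for sweep in range(max_sweeps):
            for pi, part in enumerate(self.partitions):

                def try_model(candidate: SubstitutionModel) -> float:
                    old = part.model
                    part.model = candidate
                    val = self.lnl()
                    part.model = old
                    return val

                def accept_best(make_cand, bounds, xatol, maxiter=60):
                    nonlocal current
                    res = minimize_scalar(
                        lambda x: -try_model(make_cand(x)),
                        bounds=bounds,
                        method="bounded",
                        options={"xatol": xatol, "maxiter": maxiter},
                    )
                    if -res.fun >= current:
                        part.model = make_cand(float(res.x))
                        current = -float(res.fun)

                fit_pinv = getattr(part.model, "_fit_pinv", False)

                def preserve_flag(m: SubstitutionModel) -> SubstitutionModel:
                    if fit_pinv:
                        m._fit_pinv = True
                    return m

                if part.model.alpha is not None:
                    accept_best(
                        lambda x: preserve_flag(
                            replace(part.model, alpha=float(np.exp(x)), _eig=None)
                        ),
                        (np.log(ALPHA_MIN), np.log(ALPHA_MAX)),
                        1e-4,
                    )
                if fit_pinv:
                    accept_best(
                        lambda x: preserve_flag(
                            replace(part.model, p_inv=float(x), _eig=None)
                        ),
                        (PINV_MIN, PINV_MAX),
                        1e-4,
                    )
                if fit_exchange and sweep < exch_sweeps_left:
                    for group in free_exchange_positions(part.model):
                        accept_best(
                            lambda x, g=group: preserve_flag(
                                with_updated_exchange(
                                    part.model, g, float(np.exp(x))
                                )
                            ),
                            (np.log(EXCH_MIN), np.log(EXCH_MAX)),
                            1e-3,
                            maxiter=20,
                        )
            if current - prev < tol:
                prev = max(prev, current)
                break
            prev = current
        return prev

    # -- NNI -----------------------------------------------------------------

    def _cached_partials(self):
        """D, M below every edge plus upper partials S/A per node."""
        caches = []
        for part in self.partitions:
            D, M = self._down(part)
            S: dict[int, np.ndarray] = {}
            A: dict[int, np.ndarray] = {}
            root = self.tree.root
            order = [n for n in self.tree.preorder() if n is not root]
            for node in order:
                parent = node.parent
                if parent is root:
                    base = np.broadcast_to(
                        part.model.freqs[None, :, None], D[id(root)].shape
                    ).copy()
                else:
                    base = A[id(parent)].copy()
                for other in parent.children:
                    if other is not node:
                        base = base * M[id(other)]
                S[id(node)] = base
                P = self._pmats(part, node.length or 0.0)
                A[id(node)] = np.einsum("kxp,kxy->kyp", base, P)
            caches.append((part, D, M, S, A))
        return caches

    def nni_candidates(self):
        """Internal edges eligible for NNI: (node, parent) with node internal
        and non-root."""
        out = []
        for node in self.tree.postorder():
            if node.is_leaf or node is self.tree.root:
                continue
            if len(node.children) == 2:
                out.append(node)
        return out

    def nni_moves(self) -> list[tuple[Node, int]]:
        """Deterministic (node, swap) list of all NNI rearrangements; the
        ordering depends only on the tree structure, so indices remain valid
        across tree copies."""
        moves = []
        for v in self.nni_candidates():
            p = v.parent
            if p is self.tree.root:
                if len([c for c in p.children if c is not v]) != 2:
                    continue
            elif len([c for c in p.children if c is not v]) != 1:
                continue
            moves.append((v, 0))
            moves.append((v, 1))
        return moves

    def screen_nnis(self) -> list[tuple[float, int]]:
        """Score every NNI rearrangement by re-optimising only the central
        branch from cached partials; returns (lnL, move_index) aligned with
        :meth:`nni_moves`."""
        caches = self._cached_partials()
        results = []
        move_index = -1
        for v in self.nni_candidates():
            p = v.parent
            c1, c2 = v.children
            if p is self.tree.root:
                others = [c for c in p.children if c is not v]
                if len(others) != 2:
                    continue
                o1, o2 = others
                combos = [((c1, o1), (c2, o2)), ((c1, o2), (c2, o1))]
            else:
                sibs = [c for c in p.children if c is not v]
                if len(sibs) != 1:
                    continue
                s = sibs[0]
                combos = [((c1, s), (c2, None)), ((c2, s), (c1, None))]
            for swap_idx, ((va, vb), (pa, pb)) in enumerate(combos):
                move_index += 1
                edge_states = []
                for part, D, M, S, A in caches:
                    vside = M[id(va)] * M[id(vb)]
                    if p is self.tree.root:
                        pside = (
                            np.broadcast_to(
                                part.model.freqs[None, :, None], vside.shape
                            )
                            * M[id(pa)]
                            * M[id(pb)]
                        )
                    else:
                        # upper partial at p (excludes subtree v and p's
                        # sibling side already folded into A[p]) times the
                        # subtree that stays on the parent side
                        pside = A[id(p)] * M[id(pa)]
                    inv = (
                        part.invariant_site_lik()
                        if part.model.p_inv > 0
                        else None
                    )
                    edge_states.append((part, pside, vside, inv))
                t0 = v.length or 0.1
                t_best = self._optimize_edge(edge_states, t0)
                results.append(
                    (self._edge_lnl(edge_states, t_best), move_index)
                )
        return results

    def apply_nni_index(self, move_index: int) -> None:
        v, swap = self.nni_moves()[move_index]
        self.apply_nni(v, swap)

    def apply_nni(self, v: Node, swap_idx: int) -> None:
        """Perform the NNI around edge (v, parent(v))."""
        p = v.parent
        c1, c2 = v.children
        if p is self.tree.root and len(p.children) >= 3:
            others = [c for c in p.children if c is not v]
            o1, o2 = others[0], others[1]
            # swap 0 puts {c1, o1} below v; swap 1 puts {c1, o2} below v
            moved_up = c2
            moved_down = o1 if swap_idx == 0 else o2
            moved_up.detach()
            moved_down.detach()
            p.add(moved_up)
            v.add(moved_down)
        else:
            sibs = [c for c in p.children if c is not v]
            s = sibs[0]
            moved_up = c2 if swap_idx == 0 else c1
            moved_up.detach()
            s.detach()
            p.add(moved_up)
            v.add(s)


# ---------------------------------------------------------------------------
# Spec-level operations
# ---------------------------------------------------------------------------


def _rows_and_states(alignment) -> tuple[dict[str, str], Optional[int]]:
    if isinstance(alignment, TwelveStateAlignment):
        return alignment.row_map(), 12
    if hasattr(alignment, "row_map"):
        return alignment.row_map(), 4
    if isinstance(alignment, dict):
        return alignment, None  # raw rows: state count taken from the model
    raise TypeError(f"unsupported alignment type {type(alignment)!r}")


def build_engine(
    tree: PhyloTree, alignment, model: SubstitutionModel, mult: float = 1.0
) -> LikelihoodEngine:
    rows, states = _rows_and_states(alignment)
    if states is not None and states != model.n_states:
        raise ValueError(
            f"{states}-state alignment requires a {states}-state model, "
            f"got {model.n_states}-state"
        )
    return LikelihoodEngine(tree, [_Partition(rows, model, mult)])


def log_likelihood(tree: PhyloTree, alignment, model: SubstitutionModel) -> float:
    """Felsenstein pruning log-likelihood of the alignment on the tree."""
    return build_engine(tree, alignment, model).lnl()


def optimize_branch_lengths(
    tree: PhyloTree,
    alignment,
    model: SubstitutionModel,
    max_sweeps: int = 50,
    tol: float = 1e-6,
) -> tuple[PhyloTree, float]:
    """Return a copy of the tree with ML branch lengths and its lnL."""
    work = tree.copy()
    engine = build_engine(work, alignment, model)
    lnl = engine.optimize_branch_lengths(max_sweeps=max_sweeps, tol=tol)
    return work, lnl


def optimize_model(
    tree: PhyloTree,
    alignment,
    model: SubstitutionModel,
    fit_pinv: Optional[bool] = None,
    max_sweeps: int = 50,
    tol: float = 1e-6,
    fit_exchange: bool = True,
    exchange_max_sweeps: Optional[int] = None,
) -> tuple[SubstitutionModel, float]:
    """Optimise substitution parameters on a fixed tree; returns (model, lnL)."""
    if fit_pinv is None:
        fit_pinv = model.p_inv > 0
    if fit_pinv:
        model = replace(model, _eig=None)
        model._fit_pinv = True
    engine = build_engine(tree, alignment, model)
    lnl = engine.optimize_models(
        max_sweeps=max_sweeps,
        tol=tol,
        fit_exchange=fit_exchange,
        exchange_max_sweeps=exchange_max_sweeps,
    )
    return engine.partitions[0].model, lnl
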