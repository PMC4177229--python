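"""Tree search, model selection, bootstrap and consensus.

Maximum-likelihood search follows the global-search recipe: the centre tree
is the neighbour-joining tree with branch lengths (and optionally the model)
optimised; each start is produced by an equidistant random walk of random
nearest-neighbour interchanges (NNIs) from the centre; every start is then
hill-climbed by best-improvement NNI with branch-length re-optimisation
until no rearrangement improves the log-likelihood by more than 1e-6. Nodal
support comes from non-parametric bootstrap over sites, with replicate
searches run at reduced settings; supports are mapped onto the best tree's
bipartitions. Model selection ranks GTR-family candidates by AICc.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .likelihood import (
    LikelihoodEngine,
    _Partition,
    _rows_and_states,
    build_engine,
)
from .model import SubstitutionModel, empirical_freqs, make_model
from .tree import Node, PhyloTree


# ---------------------------------------------------------------------------
# Neighbour joining
# ---------------------------------------------------------------------------


def nj_tree(labels: Sequence[str], matrix: np.ndarray) -> PhyloTree:
    """Canonical neighbour joining with deterministic tie-breaking.

    Ties in the Q criterion resolve to the join whose (sorted) label pair is
    lexicographically smallest; negative branch-length estimates are clamped
    to zero. Returns an unrooted tree (trifurcating root).
    """
    labels = list(labels)
    D = np.asarray(matrix, dtype=float).copy()
    n = len(labels)
    if n < 3:
        raise ValueError("neighbour joining needs at least 3 taxa")
    if D.shape != (n, n) or not np.allclose(D, D.T, equal_nan=True):
        raise ValueError("distance matrix must be square and symmetric")
    if np.isnan(D).any():
        raise ValueError("distance matrix contains undefined entries")

    nodes: list[Node] = [Node(label) for label in labels]
    names: list[str] = list(labels)  # tie-break keys for current clusters
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        best = None
        for a in range(m):
            for b in range(a + 1, m):
                if Q[a, b] <= qmin + 1e-12:
                    key = tuple(sorted((names[active[a]], names[active[b]])))
                    if best is None or key < best[0]:
                        best = (key, a, b)
        _, a, b = best
        i, j = active[a], active[b]
        dij = D[i, j]
        li = 0.5 * dij + (r[a] - r[b]) / (2.0 * (m - 2))
        lj = dij - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        parent = Node()
        nodes[i].length = li
        nodes[j].length = lj
        parent.add(nodes[i])
        parent.add(nodes[j])
        # distances from the new cluster to the rest
        new_row = 0.5 * (D[i, :] + D[j, :] - dij)
        D[i, :] = new_row
        D[:, i] = new_row
        D[i, i] = 0.0
        nodes[i] = parent
        names[i] = min(names[i], names[j])
        active.remove(j)

    i, j, k = active
    # three-point formulas for the final trifurcation
    li = 0.5 * (D[i, j] + D[i, k] - D[j, k])
    lj = 0.5 * (D[i, j] + D[j, k] - D[i, k])
    lk = 0.5 * (D[i, k] + D[j, k] - D[i, j])
    root = Node()
    for idx, length in ((i, li), (j, lj), (k, lk)):
        nodes[idx].length = max(length, 0.0)
        root.add(nodes[idx])
    return PhyloTree(root)


def p_distance_matrix(rows: dict[str, str]) -> tuple[list[str], np.ndarray]:
    """Proportion-different distances (gap/missing columns skipped per pair);
    used to seed starting trees for any state space."""
    labels = sorted(rows)
    n = len(labels)
    mat = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            x, y = rows[labels[a]], rows[labels[b]]
            used = diff = 0
            for cx, cy in zip(x, y):
                if cx in "-N?" or cy in "-N?":
                    continue
                used += 1
                diff += cx != cy
            mat[a, b] = mat[b, a] = diff / used if used else 0.0
    return labels, mat


# ---------------------------------------------------------------------------
# Random NNI walks and hill climbing
# ---------------------------------------------------------------------------


def random_nni_walk(
    engine: LikelihoodEngine, steps: int, rng: np.random.Generator
) -> None:
    for _ in range(steps):
        candidates = engine.nni_candidates()
        if not candidates:
            return
        v = candidates[rng.integers(len(candidates))]
        engine.apply_nni(v, int(rng.integers(2)))


def hill_climb(
    engine: LikelihoodEngine,
    tol: float = 1e-6,
    max_rounds: int = 200,
    branch_sweeps: int = 2,
    verify_top: Optional[int] = None,
) -> float:
    """Best-improvement NNI with branch re-optimisation until stagnation.

    Rearrangements are ranked by the cheap central-branch screen and then
    verified in rank order with full branch-length re-optimisation: the
    screen keeps all other branches at values tuned for the current topology
    and can badly under-rate a neighbour whose improvement is masked by a
    compensatorily stretched branch elsewhere. Verification stops at the
    first candidate that improves, so typical rounds pay for a single full
    re-optimisation; only the final (stagnant) round verifies all
    ``verify_top`` candidates (default: all). The climb stops when no
    verified candidate improves lnL by more than ``tol``.
    """
    current = engine.optimize_branch_lengths(max_sweeps=branch_sweeps, tol=tol)
    for _ in range(max_rounds):
        scored = engine.screen_nnis()
        if not scored:
            break
        scored.sort(key=lambda x: -x[0])
        limit = len(scored) if verify_top is None else verify_top
        base = engine.tree.copy()
        improved = False
        for est, move_idx in scored[:limit]:
            engine.apply_nni_index(move_idx)
            # one cheap sweep decides acceptance; accepted moves get polished
            trial = engine.optimize_branch_lengths(max_sweeps=1, tol=tol)
            if trial > current + tol:
                current = engine.optimize_branch_lengths(
                    max_sweeps=branch_sweeps, tol=tol
                )
                improved = True
                break
            engine.set_tree(base.copy())
        if not improved:
            break
    return current


def ml_search(
    alignment,
    model: SubstitutionModel,
    n_starts: int = 100,
    walk_length: int = 5,
    seed: int = 0,
    optimize_model_first: bool = False,
    branch_sweeps: int = 2,
    tol: float = 1e-6,
) -> tuple[PhyloTree, float]:
    """Multi-start NNI hill-climb from NJ-derived random-walk start trees."""
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    rows, _ = _rows_and_states(alignment)
    labels, pmat = p_distance_matrix(rows)
    centre = nj_tree(labels, pmat)
    engine = build_engine(centre, alignment, model)
    engine.optimize_branch_lengths(max_sweeps=branch_sweeps, tol=tol)
    if optimize_model_first:
        engine.optimize_models(max_sweeps=2, exchange_max_sweeps=1)
    centre = engine.tree.copy()

    best_tree, best_lnl = None, -math.inf
    for start in range(n_starts):
        rng = np.random.default_rng([seed, start])
        work = centre.copy()
        engine.set_tree(work)
        if walk_length > 0:
            random_nni_walk(engine, walk_length, rng)
        lnl = hill_climb(engine, tol=tol, branch_sweeps=branch_sweeps)
        if lnl > best_lnl:
            best_lnl = lnl
            best_tree = engine.tree.copy()
    return best_tree, best_lnl


# ---------------------------------------------------------------------------
# AICc model selection
# ---------------------------------------------------------------------------


@dataclass
class ModelFit:
    name: str
    model: SubstitutionModel
    lnl: float
    k_params: int
    n_sites: int

    @property
    def aicc(self) -> float:
        return aicc(self.lnl, self.k_params, self.n_sites)


def aicc(lnl: float, k_params: int, n_sites: int) -> float:
    """Corrected Akaike information criterion."""
    if n_sites <= k_params + 1:
        return math.inf
    return (
        -2.0 * lnl
        + 2.0 * k_params
        + 2.0 * k_params * (k_params + 1) / (n_sites - k_params - 1)
    )


def model_select_aicc(
    alignment,
    tree: PhyloTree,
    presets: Sequence[str] = ("JC", "K80", "HKY", "TN", "TVM", "GTR"),
    rate_variants: Sequence[str] = ("+G", "+I", "+I+G"),
    n_cats: int = 4,
) -> list[ModelFit]:
    """Fit every preset x rate-variant candidate on a fixed topology and rank
    ascending by AICc. Parameter counts include the substitution-model free
    parameters plus the 2n-3 branch lengths shared by all candidates."""
    rows, states = _rows_and_states(alignment)
    if states == 12:
        raise ValueError("preset-based model selection applies to 4-state data")
    freqs = empirical_freqs(list(rows.values()), "ACGU")
    n_sites = len(next(iter(rows.values())))
    n_branch = 2 * len(rows) - 3
    fits = []
    for preset in presets:
        for variant in rate_variants:
            alpha = 0.5 if "G" in variant else None
            p_inv = 0.1 if "+I" in variant else 0.0
            base = make_model(preset, freqs=freqs, alpha=alpha, p_inv=p_inv,
                              n_cats=n_cats)
            k = base.n_free_params() + n_branch
            if "+I" in variant:
                base._fit_pinv = True
            if n_sites <= k + 1:
                continue  # degenerate: AICc undefined for this candidate
            work, _ = _fit_on_tree(tree, alignment, base)
            name = preset + variant
            fits.append(ModelFit(name, work[0], work[1], k, n_sites))
    fits.sort(key=lambda f: f.aicc)
    return fits


def _fit_on_tree(tree, alignment, model, rounds: int = 2):
    work = tree.copy()
    engine = build_engine(work, alignment, model)
    lnl = -math.inf
    for _ in range(rounds):
        engine.optimize_branch_lengths(max_sweeps=3)
        lnl = engine.optimize_models(max_sweeps=3)
    lnl = engine.optimize_branch_lengths(max_sweeps=3)
    return (engine.partitions[0].model, lnl), work


# ---------------------------------------------------------------------------
# Partitioned (concatenated) analysis
# ---------------------------------------------------------------------------


@dataclass
class PartitionedDataset:
    """Per-gene alignments and models over a shared taxon set."""

    partitions: list[tuple]  # (alignment, model, multiplier)

    def __post_init__(self):
        if not self.partitions:
            raise ValueError("empty partitioned dataset")
        taxa = None
        for aln, model, mult in self.partitions:
            rows, _ = _rows_and_states(aln)
            if taxa is None:
                taxa = set(rows)
            elif set(rows) != taxa:
                raise ValueError("partitions must share an identical taxon set")
            if mult <= 0:
                raise ValueError("multipliers must be > 0")
        mults = [m for _, _, m in self.partitions]
        # normalised so the average rate is 1 (geometric mean, so that a
        # multiplier pair like (2, 0.5) is a pure rate-time reallocation)
        if abs(float(np.exp(np.mean(np.log(mults)))) - 1.0) > 1e-6:
            raise ValueError("multipliers must have (geometric) mean 1")

    def engine(self, tree: PhyloTree) -> LikelihoodEngine:
        parts = []
        for aln, model, mult in self.partitions:
            rows, _ = _rows_and_states(aln)
            parts.append(_Partition(rows, model, mult))
        return LikelihoodEngine(tree, parts)


def concat_likelihood(dataset: PartitionedDataset, tree: PhyloTree) -> float:
    """Total lnL: sum of per-partition lnL on the shared topology with shared
    branch lengths scaled by each partition's rate multiplier."""
    return dataset.engine(tree.copy()).lnl()


def concat_search(
    dataset: PartitionedDataset,
    n_starts: int = 10,
    walk_length: int = 5,
    seed: int = 0,
    branch_sweeps: int = 2,
    tol: float = 1e-6,
) -> tuple[PhyloTree, float]:
    """ML topology search under the partitioned model."""
    rows, _ = _rows_and_states(dataset.partitions[0][0])
    labels, pmat = p_distance_matrix(rows)
    centre = nj_tree(labels, pmat)
    engine = dataset.engine(centre)
    engine.optimize_branch_lengths(max_sweeps=branch_sweeps, tol=tol)
    centre = engine.tree.copy()
    best_tree, best_lnl = None, -math.inf
    for start in range(n_starts):
        rng = np.random.default_rng([seed, start])
        engine.set_tree(centre.copy())
        if walk_length > 0:
            random_nni_walk(engine, walk_length, rng)
        lnl = hill_climb(engine, tol=tol, branch_sweeps=branch_sweeps)
        if lnl > best_lnl:
            best_lnl, best_tree = lnl, engine.tree.copy()
    return best_tree, best_lnl


# ---------------------------------------------------------------------------
# Bootstrap and consensus
# ---------------------------------------------------------------------------


def resample_sites(rows: dict[str, str], rng: np.random.Generator) -> dict[str, str]:
    n = len(next(iter(rows.values())))
    idx = rng.integers(0, n, size=n)
    return {k: "".join(v[i] for i in idx) for k, v in rows.items()}


def bootstrap(
    alignment,
    model: SubstitutionModel,
    reps: int = 1000,
    seed: int = 0,
    n_starts: int = 2,
    walk_length: int = 2,
    best_tree: Optional[PhyloTree] = None,
) -> tuple[PhyloTree, dict[frozenset, float]]:
    """Non-parametric bootstrap: resample sites with replacement, re-run the
    search at reduced settings per replicate, and map bipartition frequencies
    (percent) onto the best tree's internal edges."""
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rows, states = _rows_and_states(alignment)
    if best_tree is None:
        best_tree, _ = ml_search(
            alignment, model, n_starts=n_starts, walk_length=walk_length,
            seed=seed,
        )
    counts: dict[frozenset, int] = {}
    for rep in range(reps):
        rng = np.random.default_rng([seed, 10_000 + rep])
        sampled = resample_sites(rows, rng)
        if states != 12:
            aln = sampled
        else:
            from ..seqstruct_align import TwelveStateAlignment

            ids = sorted(sampled)
            aln = TwelveStateAlignment(ids, [sampled[i] for i in ids])
        rep_tree, _ = ml_search(
            aln, model, n_starts=n_starts, walk_length=walk_length,
            seed=int(rng.integers(2**31)),
        )
        for split in rep_tree.bipartitions():
            counts[split] = counts.get(split, 0) + 1
    supports = {s: 100.0 * c / reps for s, c in counts.items()}
    annotated = best_tree.copy()
    _annotate_supports(annotated, supports)
    return annotated, supports


def _annotate_supports(tree: PhyloTree, supports: dict[frozenset, float]) -> None:
    all_leaves = frozenset(tree.leaf_labels())
    below: dict[int, frozenset] = {}
    for node in tree.postorder():
        if node.is_leaf:
            below[id(node)] = frozenset([node.label])
        else:
            below[id(node)] = frozenset().union(*(below[id(c)] for c in node.children))
    for node in tree.postorder():
        if node.is_leaf or node is tree.root:
            continue
        side = below[id(node)]
        other = all_leaves - side
        if len(side) < 2 or len(other) < 2:
            continue
        canonical = side if (
            len(side) < len(other)
            or (len(side) == len(other) and sorted(side) < sorted(other))
        ) else other
        if canonical in supports:
            node.label = "%g" % round(supports[canonical], 1)


def majority_consensus(
    trees: Sequence[PhyloTree], threshold: float = 0.5
) -> PhyloTree:
    """Majority-rule consensus: exactly the bipartitions with frequency
    strictly above the threshold, supports as percentages on internal nodes."""
    if not trees:
        raise ValueError("no trees to summarise")
    leaf_sets = {frozenset(t.leaf_labels()) for t in trees}
    if len(leaf_sets) != 1:
        raise ValueError("consensus requires a shared leaf set")
    all_leaves = sorted(next(iter(leaf_sets)))
    counts: dict[frozenset, int] = {}
    for t in trees:
        for split in t.bipartitions():
            counts[split] = counts.get(split, 0) + 1
    n = len(trees)
    kept = {s: c / n for s, c in counts.items() if c / n > threshold}

    # grow the consensus tree by inserting splits from largest to smallest
    root = Node()
    leaf_nodes = {}
    for label in all_leaves:
        leaf_nodes[label] = root.add(Node(label, 0.0))
    full = frozenset(all_leaves)
    for split, freq in sorted(
        kept.items(), key=lambda kv: (-len(_small_side(kv[0], full)), sorted(_small_side(kv[0], full)))
    ):
        side = _small_side(split, full)
        # find the node whose children currently cover `side`
        host = root
        placed = False
        while not placed:
            for child in host.children:
                cover = _leafset(child)
                if side < cover:
                    host = child
                    break
            else:
                group = [c for c in host.children if _leafset(c) <= side]
                if frozenset().union(*(_leafset(c) for c in group)) == side:
                    for c in group:
                        c.detach()
                    new = host.add(Node("%g" % round(freq * 100, 1), 0.0))
                    for c in group:
                        new.add(c)
                placed = True
    return PhyloTree(root)


def _small_side(split: frozenset, full: frozenset) -> frozenset:
    other = full - split
    if len(split) < len(other) or (
        len(split) == len(other) and sorted(split) < sorted(other)
    ):
        return split
    return other


def _leafset(node: Node) -> frozenset:
    if node.is_leaf:
        return frozenset([node.label])
    return frozenset().union(*(_leafset(c) for c in node.children))


def robinson_foulds(a: PhyloTree, b: PhyloTree) -> int:
    return a.rf_distance(b)
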