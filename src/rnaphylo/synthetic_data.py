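"""Synthetic trees, co-evolving sequence-structure families and species
complexes, so every pipeline stage is testable without downloads.

The generator emulates the statistical shape of a multi-species, multi-gene
oyster-like dataset: low intraspecific and high interspecific divergence, an
ITS2-like fold of four stem-loop domains with conserved motifs (the CAGAC
processing-site consensus in the DII-DIII spacer, conserved basal helices),
and a clade-diagnostic compensatory base change planted in the DI basal
triplet. Base-pair co-evolution is modelled as instantaneous compensation:
when a substitution hits one partner of a paired column, the other partner
jumps to the Watson-Crick complement with probability ``coevolution``; this
minimal mechanism is sufficient to plant CBCs and exercise the 12-state
encoding without a full 16-state doublet model.

All operations are seed-deterministic; truth records (tree, model,
per-column category, species map) are returned alongside the data so
downstream tests never re-derive ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .io_formats import SequenceRecord
from .seqstruct_align import TwelveStateAlignment, encode_12state
from .structure_model import SecondaryStructure
from .phylo_ml.model import SubstitutionModel, make_gtr12, make_model
from .phylo_ml.tree import Node, PhyloTree

BASES = "ACGU"
WC = {"A": "U", "U": "A", "G": "C", "C": "G"}


@dataclass
class SimulationConfig:
    """Study conditions for the generator.

    ``helix_layout`` lists paired column index pairs (0-based, 5' < 3');
    remaining columns are unpaired. ``coevolution`` is the probability that a
    substitution in a paired column is instantaneously compensated.
    """

    seed: int
    n_taxa: int = 16
    birth_rate: float = 1.0
    n_sites: int = 2000
    helix_layout: list[tuple[int, int]] = field(default_factory=list)
    model: Optional[SubstitutionModel] = None
    coevolution: float = 0.9
    tree_height: Optional[float] = 0.5
    # species-complex structure
    n_species: int = 8
    samples_per_species: int = 3
    intra_scale: float = 0.005
    inter_scale: float = 0.10
    spacer_jitter: int = 0

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not (0.0 <= self.coevolution <= 1.0):
            raise ValueError("coevolution must be in [0, 1]")
        if self.n_taxa < 2 or self.n_sites < 1 or self.birth_rate <= 0:
            raise ValueError("invalid sizes or birth rate")
        flat = [i for pr in self.helix_layout for i in pr]
        if len(flat) != len(set(flat)):
            raise ValueError("paired columns must be disjoint")


# ---------------------------------------------------------------------------
# Yule trees
# ---------------------------------------------------------------------------


def simulate_yule_tree(n_taxa: int, birth_rate: float, seed) -> PhyloTree:
    """Pure-birth tree grown to ``n_taxa`` tips; waiting times are
    exponential with rate (k * birth_rate) for k extant lineages."""
    if n_taxa < 2 or birth_rate <= 0:
        raise ValueError("need n_taxa >= 2 and birth_rate > 0")
    rng = np.random.default_rng(seed)
    root = Node()
    active = [root.add(Node(length=0.0)), root.add(Node(length=0.0))]
    while len(active) < n_taxa:
        wait = rng.exponential(1.0 / (birth_rate * len(active)))
        for leaf in active:
            leaf.length += wait
        k = int(rng.integers(len(active)))
        split = active.pop(k)
        left = split.add(Node(length=0.0))
        right = split.add(Node(length=0.0))
        active.extend([left, right])
    wait = rng.exponential(1.0 / (birth_rate * len(active)))
    for leaf in active:
        leaf.length += wait
    for i, leaf in enumerate(active):
        leaf.label = f"t{i + 1:02d}"
    return PhyloTree(root)


def scale_tree(tree: PhyloTree, factor: float) -> PhyloTree:
    out = tree.copy()
    for node in out.postorder():
        if node.length is not None:
            node.length *= factor
    return out


def clamp_min_branch(tree: PhyloTree, min_length: float) -> PhyloTree:
    """Raise every branch to at least ``min_length``; used by recovery
    experiments so the generating topology is resolvable at finite sites."""
    out = tree.copy()
    for node in out.postorder():
        if node.length is not None and node.length < min_length:
            node.length = min_length
    return out


def tree_height(tree: PhyloTree) -> float:
    depth = {id(tree.root): 0.0}
    best = 0.0
    for node in tree.preorder():
        if node is tree.root:
            continue
        depth[id(node)] = depth[id(node.parent)] + (node.length or 0.0)
        if node.is_leaf:
            best = max(best, depth[id(node)])
    return best


# ---------------------------------------------------------------------------
# Sequence evolution
# ---------------------------------------------------------------------------


def _site_rates(model: SubstitutionModel, n_sites: int, rng) -> np.ndarray:
    """Per-site rate multipliers from the +I+Gamma mixture."""
    rates = np.ones(n_sites)
    gam = model.gamma_rates()
    cats = rng.integers(0, len(gam), size=n_sites)
    rates = gam[cats]
    if model.p_inv > 0:
        inv = rng.random(n_sites) < model.p_inv
        rates[inv] = 0.0
    return rates


def simulate_columns(
    tree: PhyloTree,
    model: SubstitutionModel,
    n_sites: int,
    seed,
    site_rates: Optional[np.ndarray] = None,
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Independent-column CTMC simulation of n-state data along the tree.

    Works for any state count (this is how 12-state data distributed exactly
    as the inference model assumes is generated). Returns per-leaf state-code
    arrays and the per-site rate multipliers used.
    """
    rng = np.random.default_rng(seed)
    n = model.n_states
    if site_rates is None:
        site_rates = _site_rates(model, n_sites, rng)
    unique_rates = np.unique(site_rates)
    states: dict[int, np.ndarray] = {
        id(tree.root): rng.choice(n, size=n_sites, p=model.freqs)
    }
    out: dict[str, np.ndarray] = {}
    for node in tree.preorder():
        if node is tree.root:
            continue
        parent_states = states[id(node.parent)]
        child = parent_states.copy()
        for r in unique_rates:
            mask = site_rates == r
            if r == 0.0 or not mask.any():
                continue
            P = model.transition_matrix((node.length or 0.0), r)
            cum = P.cumsum(axis=1)
            u = rng.random(mask.sum())
            child_states = (
                cum[parent_states[mask]] < u[:, None]
            ).sum(axis=1)
            child[mask] = child_states
        states[id(node)] = child
        if node.is_leaf:
            out[node.label] = child
    return out, site_rates


def _gillespie_pair(
    x: int, y: int, t: float, Q: np.ndarray, c: float, rng
) -> tuple[int, int]:
    """Evolve one paired doublet for time t: independent single-strand
    substitutions, each compensated on the partner with probability c."""
    leave = -np.diag(Q)
    jump = Q - np.diag(np.diag(Q))
    elapsed = 0.0
    while True:
        total = leave[x] + leave[y]
        if total <= 0:
            return x, y
        elapsed += rng.exponential(1.0 / total)
        if elapsed >= t:
            return x, y
        if rng.random() < leave[x] / total:
            x = int(rng.choice(4, p=jump[x] / leave[x]))
            if rng.random() < c:
                y = BASES.index(WC[BASES[x]])
        else:
            y = int(rng.choice(4, p=jump[y] / leave[y]))
            if rng.random() < c:
                x = BASES.index(WC[BASES[y]])


@dataclass
class SimulatedFamily:
    """Gap-free co-evolved family plus its ground truth."""

    records: list[SequenceRecord]
    structures: dict[str, SecondaryStructure]
    twelve_state: TwelveStateAlignment
    tree: PhyloTree
    config: SimulationConfig
    column_category: list[str]  # "paired" | "unpaired" per column

    def truth_config(self) -> dict:
        return {
            "n_taxa": self.config.n_taxa,
            "n_sites": self.config.n_sites,
            "coevolution": self.config.coevolution,
            "seed": self.config.seed,
            "tree": self.tree.to_newick(),
        }


def simulate_alignment(tree: PhyloTree, config: SimulationConfig) -> SimulatedFamily:
    """Evolve a gap-free alignment with co-evolving paired columns.

    Unpaired columns evolve independently under the 4-state model; paired
    column-pairs evolve jointly (substitutions compensated with probability
    ``coevolution``). Root states are drawn from the stationary frequencies,
    paired columns from Watson-Crick-consistent doublets.
    """
    rng = np.random.default_rng(config.seed)
    model = config.model or make_model("HKY", rates={"kappa": 2.0},
                                       freqs=np.array([0.26, 0.24, 0.27, 0.23]))
    if model.n_states != 4:
        raise ValueError("co-evolution simulation uses a 4-state model")
    n_sites = config.n_sites
    paired = config.helix_layout
    paired_cols = {i for pr in paired for i in pr}
    if paired_cols and max(paired_cols) >= n_sites:
        raise ValueError("helix layout exceeds n_sites")
    unpaired_cols = [k for k in range(n_sites) if k not in paired_cols]

    Q = model.rate_matrix()
    site_rates = _site_rates(model, n_sites, rng)

    # unpaired part: fast matrix-exponential sampling
    sub_rates = site_rates[unpaired_cols]
    leaf_states, _ = simulate_columns(
        tree,
        model,
        len(unpaired_cols),
        rng.integers(2**31),
        site_rates=sub_rates,
    )

    # paired part: event-level simulation per doublet
    pair_states: dict[int, list[tuple[int, int]]] = {}
    root_pairs = []
    for i5, i3 in paired:
        x = int(rng.choice(4, p=model.freqs))
        y = BASES.index(WC[BASES[x]])
        root_pairs.append((x, y))
    pair_states[id(tree.root)] = root_pairs
    leaf_pairs: dict[str, list[tuple[int, int]]] = {}
    for node in tree.preorder():
        if node is tree.root:
            continue
        parent_pairs = pair_states[id(node.parent)]
        current = []
        for k, (i5, i3) in enumerate(paired):
            rate = site_rates[i5]
            x, y = parent_pairs[k]
            if rate > 0:
                x, y = _gillespie_pair(
                    x, y, (node.length or 0.0) * rate, Q, config.coevolution, rng
                )
            current.append((x, y))
        pair_states[id(node)] = current
        if node.is_leaf:
            leaf_pairs[node.label] = current

    # assemble rows
    pairs_table: list[Optional[int]] = [None] * n_sites
    for i5, i3 in paired:
        pairs_table[i5], pairs_table[i3] = i3, i5
    records, structures, ids, rows = [], {}, [], []
    category = ["paired" if k in paired_cols else "unpaired" for k in range(n_sites)]
    for label in sorted(leaf_states):
        seq = [""] * n_sites
        for pos, code in zip(unpaired_cols, leaf_states[label]):
            seq[pos] = BASES[code]
        for (i5, i3), (x, y) in zip(paired, leaf_pairs[label]):
            seq[i5], seq[i3] = BASES[x], BASES[y]
        residues = "".join(seq)
        rec = SequenceRecord(id=label, residues=residues, role="other")
        struct = SecondaryStructure(residues, tuple(pairs_table))
        records.append(rec)
        structures[label] = struct
        ids.append(label)
        rows.append(encode_12state(residues, struct))
    aln = TwelveStateAlignment(ids, rows, structures)
    return SimulatedFamily(records, structures, aln, tree, config, category)


# ---------------------------------------------------------------------------
# ITS2-like families with a planted clade-diagnostic CBC
# ---------------------------------------------------------------------------

# Hand-designed ~230 nt four-domain layout. Upper case strands pair reverse-
# complementarily; lower bounds follow the proportions of the oyster ITS2
# consensus (four stem-loop domains, CAGAC in the DII-DIII spacer).
_DI_STEM5 = "CGGAUGCC"   # basal triplet CGG at the start
_DI_LOOP = "GCAA"
_DII_STEM5 = "GGAGCCUAGC"  # upper portion carries AGCC
_DII_LOOP = "UUCG"
_SPACER1 = "AAUACU"
_SPACER2 = "UACAGACAU"   # CAGAC planted single-stranded
_DIII_STEM5 = "GGCAACG"   # apical-stem consensus 5' half
_DIII_LOOP = "GAAA"
_SPACER3 = "AUGUAU"
_DIV_STEM5 = "GCUGAUC"
_DIV_LOOP = "UUUCG"
_LEADER = "ACGAUUCA"
_TAIL = "AUCUAC"


def _revcomp(s: str) -> str:
    return "".join(WC[c] for c in reversed(s))


def _its2_layout() -> tuple[str, list[tuple[int, int]], dict[str, tuple[int, int]]]:
    """Build the ancestral sequence, helix layout and named landmarks."""
    parts = []
    pairs: list[tuple[int, int]] = []
    landmarks: dict[str, tuple[int, int]] = {}

    def add(text: str) -> int:
        start = sum(len(p) for p in parts)
        parts.append(text)
        return start

    def add_stem(stem5: str, loop: str, name: str) -> None:
        s5 = add(stem5)
        add(loop)
        s3 = add(_revcomp(stem5))
        for k in range(len(stem5)):
            pairs.append((s5 + k, s3 + len(stem5) - 1 - k))
        landmarks[name] = (s5, s3 + len(stem5))

    add(_LEADER)
    add_stem(_DI_STEM5, _DI_LOOP, "DI")
    add(_SPACER1)
    add_stem(_DII_STEM5, _DII_LOOP, "DII")
    s2 = add(_SPACER2)
    landmarks["CAGAC"] = (s2 + _SPACER2.index("CAGAC"),
                          s2 + _SPACER2.index("CAGAC") + 5)
    add_stem(_DIII_STEM5, _DIII_LOOP, "DIII")
    add(_SPACER3)
    add_stem(_DIV_STEM5, _DIV_LOOP, "DIV")
    add(_TAIL)
    return "".join(parts), pairs, landmarks


@dataclass
class Its2Family:
    records: list[SequenceRecord]
    structures: dict[str, SecondaryStructure]
    tree: PhyloTree
    clades: dict[str, str]  # leaf -> "A" | "B"
    landmarks: dict[str, tuple[int, int]]
    conserved: set


def make_its2_family(config: SimulationConfig) -> Its2Family:
    """Simulate an ITS2-like family of four-domain folds.

    Every record keeps the conserved landmarks (CAGAC spacer motif, basal
    helices); one clade carries a planted full CBC in the DI basal triplet
    (CGG/CCG -> CGA/UCG), mirroring the family-diagnostic landmark logic.
    """
    ancestor, pairs, landmarks = _its2_layout()
    n_sites = len(ancestor)
    # conserved columns: all landmark helices' basal parts + CAGAC + apical 5'
    conserved: set[int] = set()
    for name in ("CAGAC",):
        s, e = landmarks[name]
        conserved |= set(range(s, e))
    for name in ("DI", "DII", "DIII", "DIV"):
        s, e = landmarks[name]
        conserved |= {s, s + 1, s + 2, e - 3, e - 2, e - 1}  # basal triplets

    rng = np.random.default_rng(config.seed)
    tree = simulate_yule_tree(config.n_taxa, config.birth_rate, rng.integers(2**31))
    if config.tree_height:
        tree = scale_tree(tree, config.tree_height / max(tree_height(tree), 1e-9))

    model = config.model or make_model("HKY", rates={"kappa": 2.0},
                                       freqs=np.array([0.26, 0.24, 0.27, 0.23]))
    pair_table: list[Optional[int]] = [None] * n_sites
    for i, j in pairs:
        pair_table[i], pair_table[j] = j, i

    # evolve variable columns only; conserved columns stay ancestral
    Q = model.rate_matrix()
    site_rates = np.ones(n_sites)
    for k in conserved:
        site_rates[k] = 0.0

    paired_var = [
        (i, j) for i, j in pairs if i not in conserved and j not in conserved
    ]
    unpaired_var = [
        k
        for k in range(n_sites)
        if pair_table[k] is None and k not in conserved
    ]

    anc_codes = np.array([BASES.index(c) for c in ancestor])
    # unpaired variable columns via CTMC sampling conditioned on the ancestor
    leaf_cols: dict[str, np.ndarray] = {
        leaf: anc_codes.copy() for leaf in tree.leaf_labels()
    }
    states = {id(tree.root): anc_codes[unpaired_var].copy()}
    for node in tree.preorder():
        if node is tree.root:
            continue
        parent = states[id(node.parent)]
        P = model.transition_matrix(node.length or 0.0)
        cum = P.cumsum(axis=1)
        u = rng.random(len(parent))
        child = (cum[parent] < u[:, None]).sum(axis=1)
        states[id(node)] = child
        if node.is_leaf:
            leaf_cols[node.label][unpaired_var] = child

    # paired variable columns with compensation
    pair_states = {
        id(tree.root): [
            (int(anc_codes[i]), int(anc_codes[j])) for i, j in paired_var
        ]
    }
    for node in tree.preorder():
        if node is tree.root:
            continue
        parent_pairs = pair_states[id(node.parent)]
        current = []
        for (i, j), (x, y) in zip(paired_var, parent_pairs):
            x, y = _gillespie_pair(
                x, y, node.length or 0.0, Q, config.coevolution, rng
            )
            current.append((x, y))
        pair_states[id(node)] = current
        if node.is_leaf:
            for (i, j), (x, y) in zip(paired_var, current):
                leaf_cols[node.label][i] = x
                leaf_cols[node.label][j] = y

    # clades: the two subtrees of the root; clade B gets the planted CBC
    clade_of: dict[str, str] = {}
    first = tree.root.children[0]
    in_first = {n.label for n in PhyloTree(first).postorder() if n.is_leaf}
    for leaf in tree.leaf_labels():
        clade_of[leaf] = "A" if leaf in in_first else "B"
    di5, di3_end = landmarks["DI"]
    # DI basal triplet pairs: (di5+k, partner); plant CGG/CCG -> CGA/UCG at
    # triplet position 3 (5' G->A compensated by 3' C->U)
    plant_pos5 = di5 + 2
    plant_pos3 = pair_table[plant_pos5]
    for leaf, codes in leaf_cols.items():
        if clade_of[leaf] == "B":
            codes[plant_pos5] = BASES.index("A")
            codes[plant_pos3] = BASES.index("U")

    records, structures = [], {}
    for leaf in sorted(leaf_cols):
        residues = "".join(BASES[c] for c in leaf_cols[leaf])
        rec = SequenceRecord(
            id=leaf,
            residues=residues,
            role="ITS2",
            description=f"clade={clade_of[leaf]}",
        )
        struct = SecondaryStructure(residues, tuple(pair_table))
        if config.spacer_jitter:
            rec, struct = _jitter_spacers(
                rec, struct, landmarks, config.spacer_jitter, rng
            )
        records.append(rec)
        structures[leaf] = struct
    return Its2Family(records, structures, tree, clade_of, landmarks, conserved)


def _jitter_spacers(rec, struct, landmarks, jitter, rng):
    """Insert up to ``jitter`` random unpaired residues in the 3' tail so the
    family has length variation for the alignment stage."""
    extra = int(rng.integers(0, jitter + 1))
    if extra == 0:
        return rec, struct
    tail = "".join(rng.choice(list("ACGU")) for _ in range(extra))
    residues = rec.residues + tail
    pairs = tuple(list(struct.pairs) + [None] * extra)
    rec2 = SequenceRecord(
        id=rec.id, residues=residues, role=rec.role, description=rec.description
    )
    return rec2, SecondaryStructure(residues, pairs)


# ---------------------------------------------------------------------------
# Species complexes for barcoding
# ---------------------------------------------------------------------------


@dataclass
class SpeciesComplex:
    records: list[SequenceRecord]
    species_map: dict[str, str]
    species_tree: PhyloTree
    full_tree: PhyloTree


def make_species_complex(config: SimulationConfig) -> SpeciesComplex:
    """Species-level Yule tree (rescaled so the minimum between-species tip
    path equals 2 x inter_scale) with within-species star subtrees of radius
    intra_scale; expected K2P distances: intra ~ 2 x intra_scale, inter >=
    2 x inter_scale."""
    if config.n_species < 2 or config.samples_per_species < 2:
        raise ValueError("need >= 2 species and >= 2 samples per species")
    rng = np.random.default_rng(config.seed)
    sp_tree = simulate_yule_tree(
        config.n_species, config.birth_rate, rng.integers(2**31)
    )
    # rescale the species tree so the minimum tip-to-tip path equals
    # 2*(inter - intra); sample branches add 2*intra, so the expected
    # minimum interspecific distance is 2*inter_scale. Equal scales collapse
    # the species tree, making intra/inter ranges overlap.
    min_path = _min_tip_path(sp_tree)
    target = max(2.0 * (config.inter_scale - config.intra_scale), 0.0)
    sp_tree = scale_tree(sp_tree, target / max(min_path, 1e-12))

    full = sp_tree.copy()
    species_map: dict[str, str] = {}
    for leaf in list(full.leaves()):
        species = f"sp{leaf.label[1:]}"
        leaf.label = None
        for s in range(config.samples_per_species):
            sid = f"{species}_{s + 1}"
            leaf.add(Node(sid, config.intra_scale))
            species_map[sid] = species

    model = config.model or make_model("HKY", rates={"kappa": 2.0},
                                       freqs=np.array([0.26, 0.24, 0.27, 0.23]))
    leaf_states, _ = simulate_columns(
        full, model, config.n_sites, rng.integers(2**31)
    )
    records = [
        SequenceRecord(
            id=label,
            residues="".join(BASES[c] for c in leaf_states[label]),
            role="COI",
            species=species_map[label],
        )
        for label in sorted(leaf_states)
    ]
    return SpeciesComplex(records, species_map, sp_tree, full)


def _min_tip_path(tree: PhyloTree) -> float:
    labels = tree.leaf_labels()
    depth: dict[int, float] = {id(tree.root): 0.0}
    node_of: dict[str, Node] = {}
    parent_chain: dict[str, list] = {}
    for node in tree.preorder():
        if node is not tree.root:
            depth[id(node)] = depth[id(node.parent)] + (node.length or 0.0)
        if node.is_leaf:
            node_of[node.label] = node
            chain = []
            cur = node
            while cur is not None:
                chain.append(id(cur))
                cur = cur.parent
            parent_chain[node.label] = chain
    best = np.inf
    for a in range(len(labels)):
        for b in range(a + 1, len(labels)):
            ca, cb = parent_chain[labels[a]], parent_chain[labels[b]]
            sa = set(ca)
            lca = next(x for x in cb if x in sa)
            d = (
                depth[id(node_of[labels[a]])]
                + depth[id(node_of[labels[b]])]
                - 2.0 * depth[lca]
            )
            best = min(best, d)
    return float(best)
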