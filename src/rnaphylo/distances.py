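"""Kimura 2-parameter distances and DNA-barcoding-gap analysis.

The K2P distance separates transition (P) and transversion (Q) proportions:

    d = -1/2 * ln(1 - 2P - Q) - 1/4 * ln(1 - 2Q)

Gaps are handled either by complete deletion (every column containing a gap
or ambiguity code in ANY row is removed before all comparisons) or pairwise
deletion (per pair). Ambiguity codes count as gaps for deletion. Pairs whose
log arguments are non-positive are flagged saturated (distance undefined)
rather than crashing, and are excluded from barcoding summaries.

Distances are substitutions/site; reports also carry percentages (x100) for
direct comparison with the percent values conventional in barcoding studies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Optional, Sequence

import numpy as np

from .io_formats import Alignment

PURINES = {"A", "G"}
PYRIMIDINES = {"C", "U"}
_PLAIN = {"A", "C", "G", "U"}


@dataclass(frozen=True)
class PairwiseDistance:
    P: float  # transition proportion
    Q: float  # transversion proportion
    d: Optional[float]  # substitutions/site; None when saturated
    n_sites_used: int

    @property
    def saturated(self) -> bool:
        return self.d is None

    @property
    def percent(self) -> Optional[float]:
        return None if self.d is None else 100.0 * self.d


def k2p_from_counts(transitions: int, transversions: int, n: int) -> PairwiseDistance:
    if n <= 0:
        raise ValueError("no usable sites")
    P, Q = transitions / n, transversions / n
    a1, a2 = 1.0 - 2.0 * P - Q, 1.0 - 2.0 * Q
    if a1 <= 0.0 or a2 <= 0.0:
        return PairwiseDistance(P, Q, None, n)
    return PairwiseDistance(P, Q, -0.5 * math.log(a1) - 0.25 * math.log(a2), n)


def k2p_pair(a: str, b: str) -> PairwiseDistance:
    """K2P distance between two equal-length rows, pairwise deletion."""
    if len(a) != len(b):
        raise ValueError("rows differ in length")
    ts = tv = n = 0
    for x, y in zip(a.upper().replace("T", "U"), b.upper().replace("T", "U")):
        if x not in _PLAIN or y not in _PLAIN:
            continue
        n += 1
        if x == y:
            continue
        if (x in PURINES) == (y in PURINES):
            ts += 1
        else:
            tv += 1
    if n == 0:
        raise ValueError("zero usable columns for pair")
    return k2p_from_counts(ts, tv, n)


@dataclass
class DistanceMatrix:
    labels: list[str]
    matrix: np.ndarray  # d values; NaN marks saturated pairs
    deletion: str
    saturated_pairs: list[tuple[str, str]] = field(default_factory=list)
    details: dict = field(default_factory=dict)  # (i, j) -> PairwiseDistance

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.labels)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        with np.errstate(invalid="ignore"):
            if np.nanmax(np.abs(self.matrix - self.matrix.T), initial=0.0) > 1e-12:
                raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.matrix) != 0):
            raise ValueError("diagonal must be zero")

    def get(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.matrix[i, j])


def k2p_matrix(alignment: Alignment, deletion: str = "complete") -> DistanceMatrix:
    """All-pairs K2P distances under complete or pairwise deletion."""
    if deletion not in ("complete", "pairwise"):
        raise ValueError(f"unknown deletion mode {deletion!r}")
    labels = alignment.ids
    rows = [r.residues.upper().replace("T", "U") for r in alignment.rows]
    if deletion == "complete":
        keep = [
            k
            for k in range(alignment.n_sites)
            if all(row[k] in _PLAIN for row in rows)
        ]
        rows = ["".join(row[k] for k in keep) for row in rows]
    n = len(labels)
    mat = np.zeros((n, n))
    saturated, details = [], {}
    for i, j in combinations(range(n), 2):
        try:
            pd = k2p_pair(rows[i], rows[j])
        except ValueError as exc:
            raise ValueError(
                f"pair ({labels[i]}, {labels[j]}): {exc}"
            ) from exc
        details[(i, j)] = pd
        if pd.saturated:
            mat[i, j] = mat[j, i] = np.nan
            saturated.append((labels[i], labels[j]))
        else:
            mat[i, j] = mat[j, i] = pd.d
    return DistanceMatrix(labels, mat, deletion, saturated, details)


# ---------------------------------------------------------------------------
# Barcoding-gap analysis
# ---------------------------------------------------------------------------


@dataclass
class BarcodingReport:
    """Intra/interspecific K2P summary for one marker.

    ``gap`` = global minimum interspecific d minus global maximum
    intraspecific d; ``overlaps`` lists species pairs with at least one
    interspecific distance below the global maximum intraspecific distance.
    Distances are substitutions/site; ``*_percent`` views multiply by 100.
    """

    per_species_max_intra: dict[str, float]
    max_intra: float
    min_inter: float
    gap: float
    overlaps: list[tuple[str, str, float]]
    synonym_sets_applied: list[frozenset]
    saturated_excluded: list[tuple[str, str]]

    @property
    def max_intra_percent(self) -> float:
        return 100.0 * self.max_intra

    @property
    def min_inter_percent(self) -> float:
        return 100.0 * self.min_inter

    @property
    def gap_percent(self) -> float:
        return 100.0 * self.gap

    @property
    def has_gap(self) -> bool:
        return self.gap > 0

    def to_table(self) -> str:
        lines = ["metric\tvalue_subst_per_site\tvalue_percent"]
        lines.append(f"max_intraspecific\t{self.max_intra:.6f}\t{self.max_intra_percent:.4f}")
        lines.append(f"min_interspecific\t{self.min_inter:.6f}\t{self.min_inter_percent:.4f}")
        lines.append(f"barcoding_gap\t{self.gap:.6f}\t{self.gap_percent:.4f}")
        for sp, v in sorted(self.per_species_max_intra.items()):
            lines.append(f"max_intra[{sp}]\t{v:.6f}\t{100 * v:.4f}")
        for a, b, v in self.overlaps:
            lines.append(f"overlap[{a}|{b}]\t{v:.6f}\t{100 * v:.4f}")
        return "\n".join(lines) + "\n"


def merge_synonyms(
    species_map: dict[str, str], synonym_sets: Iterable[frozenset]
) -> dict[str, str]:
    """Collapse synonymised species to a canonical (sorted-first) name."""
    canon: dict[str, str] = {}
    for group in synonym_sets:
        name = sorted(group)[0]
        for sp in group:
            canon[sp] = name
    return {sid: canon.get(sp, sp) for sid, sp in species_map.items()}


def barcoding_analysis(
    matrix: DistanceMatrix,
    species_map: dict[str, str],
    synonym_sets: Sequence[frozenset] = (),
) -> BarcodingReport:
    """Classify pairwise distances as intra- vs interspecific and report the
    barcoding gap. Synonym sets merge species before classification; species
    with fewer than 2 sequences simply contribute no intraspecific values."""
    missing = [t for t in matrix.labels if t not in species_map]
    if missing:
        raise ValueError(f"taxa without species assignment: {missing}")
    merged = merge_synonyms(species_map, synonym_sets)
    labels = matrix.labels
    per_species: dict[str, float] = {}
    inter: list[tuple[str, str, float]] = []
    saturated = list(matrix.saturated_pairs)
    for i, j in combinations(range(len(labels)), 2):
        d = matrix.matrix[i, j]
        if np.isnan(d):
            continue
        si, sj = merged[labels[i]], merged[labels[j]]
        if si == sj:
            per_species[si] = max(per_species.get(si, 0.0), float(d))
        else:
            inter.append((si, sj, float(d)))
    if not inter:
        raise ValueError("no interspecific pairs: need at least 2 species")
    max_intra = max(per_species.values()) if per_species else 0.0
    min_inter = min(v for _, _, v in inter)
    overlap_pairs: dict[tuple[str, str], float] = {}
    for a, b, v in inter:
        if v < max_intra:
            key = tuple(sorted((a, b)))
            overlap_pairs[key] = min(overlap_pairs.get(key, np.inf), v)
    overlaps = [(a, b, v) for (a, b), v in sorted(overlap_pairs.items())]
    return BarcodingReport(
        per_species_max_intra=per_species,
        max_intra=max_intra,
        min_inter=min_inter,
        gap=min_inter - max_intra,
        overlaps=overlaps,
        synonym_sets_applied=list(synonym_sets),
        saturated_excluded=saturated,
    )
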