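"""RNA secondary-structure modelling, ITS2 domain annotation and CBC detection.

The folding engine is Nussinov-style base-pair maximisation over nested
structures with a minimum hairpin span and a canonical + wobble pair set
{AU, UA, GC, CG, GU, UG}. It is deterministic (documented traceback
tie-breaks) and serves the downstream pipeline, which only requires a valid
nested structure; a seam to an external thermodynamic folder (ViennaRNA) is
provided for users who want free-energy models instead.

Coordinates are 0-based half-open internally; every user-facing report and
error message is 1-based inclusive.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Optional, Sequence

ALLOWED_PAIRS = frozenset(
    [("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")]
)

#: IUPAC nucleotide degeneracy (RNA alphabet; T accepted as U on input).
IUPAC = {
    "A": "A", "C": "C", "G": "G", "U": "U",
    "R": "AG", "Y": "CU", "S": "CG", "W": "AU", "K": "GU", "M": "AC",
    "B": "CGU", "D": "AGU", "H": "ACU", "V": "ACG", "N": "ACGU",
}


def pairs_from_dotbracket(db: str) -> list[Optional[int]]:
    """Parse a dot-bracket string into a partner-index table (0-based).

    Raises ValueError with the 1-based column of the first violation when
    brackets are unbalanced.
    """
    pairs: list[Optional[int]] = [None] * len(db)
    stack: list[int] = []
    for i, ch in enumerate(db):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise ValueError(f"unbalanced bracket at column {i + 1}")
            j = stack.pop()
            pairs[j], pairs[i] = i, j
        elif ch != ".":
            raise ValueError(f"invalid structure character {ch!r} at column {i + 1}")
    if stack:
        raise ValueError(f"unbalanced bracket at column {stack[0] + 1}")
    return pairs


@dataclass
class SecondaryStructure:
    """A sequence plus a nested base-pair table (dot-bracket equivalent)."""

    sequence: str
    pairs: tuple[Optional[int], ...]
    min_loop: int = 3

    def __post_init__(self):
        self.sequence = normalize_rna(self.sequence)
        self.pairs = tuple(self.pairs)
        if len(self.pairs) != len(self.sequence):
            raise ValueError("pair table length must equal sequence length")

    @classmethod
    def from_dotbracket(cls, sequence: str, db: str, min_loop: int = 3):
        if len(sequence) != len(db):
            raise ValueError(
                f"sequence length {len(sequence)} != structure length {len(db)}"
            )
        return cls(sequence, tuple(pairs_from_dotbracket(db)), min_loop)

    @property
    def dot_bracket(self) -> str:
        out = []
        for i, j in enumerate(self.pairs):
            out.append("." if j is None else ("(" if j > i else ")"))
        return "".join(out)

    @property
    def pair_set(self) -> frozenset:
        return frozenset(
            (i, j) for i, j in enumerate(self.pairs) if j is not None and i < j
        )

    @property
    def n_pairs(self) -> int:
        return len(self.pair_set)

    def validate(self, strict_pairs: bool = True) -> None:
        """Check the structural invariants; raise ValueError on violation."""
        n = len(self.pairs)
        for i, j in enumerate(self.pairs):
            if j is None:
                continue
            if j == i:
                raise ValueError(f"self-pairing at position {i + 1}")
            if not (0 <= j < n) or self.pairs[j] != i:
                raise ValueError(f"pair table is not an involution at {i + 1}")
        for i, j in self.pair_set:
            # hairpin span: a pair with no enclosed pair must span >= min_loop
            if j - i - 1 < self.min_loop:
                raise ValueError(
                    f"hairpin between {i + 1} and {j + 1} spans "
                    f"{j - i - 1} < {self.min_loop}"
                )
            if strict_pairs:
                pair = (self.sequence[i], self.sequence[j])
                if pair not in ALLOWED_PAIRS:
                    raise ValueError(
                        f"disallowed pair {pair[0]}-{pair[1]} at "
                        f"({i + 1},{j + 1})"
                    )
        # nesting: matched-bracket construction guarantees it; verify anyway
        open_stack = []
        for i, j in enumerate(self.pairs):
            if j is None:
                continue
            if j > i:
                open_stack.append(j)
            else:
                if not open_stack or open_stack[-1] != i:
                    raise ValueError(f"pseudoknot crossing at position {i + 1}")
                open_stack.pop()


def normalize_rna(seq: str) -> str:
    """Uppercase, map DNA T to RNA U, and validate the alphabet."""
    out = seq.upper().replace("T", "U")
    bad = set(out) - set(IUPAC) - {"-"}
    if bad:
        raise ValueError(f"invalid residue(s) {sorted(bad)} in sequence")
    return out


# ---------------------------------------------------------------------------
# Folding: base-pair maximisation
# ---------------------------------------------------------------------------


def _can_pair(a: str, b: str) -> bool:
    return (a, b) in ALLOWED_PAIRS


def fold_max_pairs(
    sequence: str,
    min_loop: int = 3,
    allowed_pairs: frozenset = ALLOWED_PAIRS,
) -> SecondaryStructure:
    """Maximise the number of nested base pairs (Nussinov dynamic program).

    Deterministic traceback: when several choices achieve the optimum, pairing
    position i is preferred over leaving it unpaired, and the smallest
    admissible partner j is taken (this fixes the bifurcation point as well).
    """
    seq = normalize_rna(sequence)
    if "-" in seq:
        raise ValueError("gapped input: remove gaps before folding")
    n = len(seq)
    if n == 0:
        raise ValueError("empty sequence")
    pairable = lambda a, b: (a, b) in allowed_pairs  # noqa: E731

    N = [[0] * n for _ in range(n)]
    for span in range(min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            best = N[i + 1][j]
            for k in range(i + min_loop + 1, j + 1):
                if pairable(seq[i], seq[k]):
                    inner = N[i + 1][k - 1] if k - 1 > i + 1 else 0
                    right = N[k + 1][j] if k + 1 <= j else 0
                    best = max(best, inner + 1 + right)
            N[i][j] = best

    pairs: list[Optional[int]] = [None] * n
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if i >= j:
            continue
        target = N[i][j]
        chosen = None
        for k in range(i + min_loop + 1, j + 1):
            if pairable(seq[i], seq[k]):
                inner = N[i + 1][k - 1] if k - 1 > i + 1 else 0
                right = N[k + 1][j] if k + 1 <= j else 0
                if inner + 1 + right == target:
                    chosen = k
                    break
        if chosen is not None:
            pairs[i], pairs[chosen] = chosen, i
            stack.append((i + 1, chosen - 1))
            stack.append((chosen + 1, j))
        else:
            stack.append((i + 1, j))
    return SecondaryStructure(seq, tuple(pairs), min_loop)


def enumerate_suboptimal(
    sequence: str,
    within_delta_pairs: int = 0,
    max_candidates: int = 50,
    min_loop: int = 3,
    allowed_pairs: frozenset = ALLOWED_PAIRS,
) -> list[SecondaryStructure]:
    """All nested structures whose pair count is within ``within_delta_pairs``
    of the maximum, ordered by pair count (descending) then lexicographic
    dot-bracket, truncated to ``max_candidates``."""
    if within_delta_pairs < 0:
        raise ValueError("within_delta_pairs must be >= 0")
    if max_candidates <= 0:
        raise ValueError("max_candidates must be >= 1")
    seq = normalize_rna(sequence)
    if "-" in seq:
        raise ValueError("gapped input: remove gaps before folding")
    n = len(seq)
    pairable = lambda a, b: (a, b) in allowed_pairs  # noqa: E731

    @lru_cache(maxsize=None)
    def nmax(i: int, j: int) -> int:
        if j - i < min_loop + 1:
            return 0
        best = nmax(i + 1, j)
        for k in range(i + min_loop + 1, j + 1):
            if pairable(seq[i], seq[k]):
                best = max(best, nmax(i + 1, k - 1) + 1 + nmax(k + 1, j))
        return best

    def gen(i: int, j: int, slack: int) -> set[frozenset]:
        """Pair sets on [i, j] with count >= nmax(i, j) - slack."""
        if j - i < min_loop + 1:
            return {frozenset()}
        out: set[frozenset] = set()
        here = nmax(i, j)
        loss = here - nmax(i + 1, j)
        if loss <= slack:
            out |= gen(i + 1, j, slack - loss)
        for k in range(i + min_loop + 1, j + 1):
            if not pairable(seq[i], seq[k]):
                continue
            gain = nmax(i + 1, k - 1) + 1 + nmax(k + 1, j)
            loss = here - gain
            if loss > slack:
                continue
            budget = slack - loss
            for left in gen(i + 1, k - 1, budget):
                d1 = nmax(i + 1, k - 1) - len(left)
                if d1 > budget:
                    continue
                for right in gen(k + 1, j, budget - d1):
                    out.add(left | right | {(i, k)})
        return out

    structures = []
    for pair_set in gen(0, n - 1, within_delta_pairs):
        pairs: list[Optional[int]] = [None] * n
        for a, b in pair_set:
            pairs[a], pairs[b] = b, a
        structures.append(SecondaryStructure(seq, tuple(pairs), min_loop))
    structures.sort(key=lambda s: (-s.n_pairs, s.dot_bracket))
    return structures[:max_candidates]


def fold_thermodynamic(sequence: str) -> SecondaryStructure:
    """Optional seam to the ViennaRNA minimum-free-energy folder.

    Requires the ``RNA`` Python bindings; raises ImportError otherwise.
    """
    try:
        import RNA
    except ImportError as exc:  # pragma: no cover
        raise ImportError(
            "ViennaRNA bindings not available; install the 'RNA' module or "
            "use fold_max_pairs"
        ) from exc
    seq = normalize_rna(sequence)
    db, _ = RNA.fold(seq)
    return SecondaryStructure.from_dotbracket(seq, db)


def select_by_template(
    candidates: Sequence[SecondaryStructure],
    template_pairs: frozenset,
) -> tuple[SecondaryStructure, float]:
    """Pick the candidate whose pair set best agrees (F1) with a template.

    Ties broken by more pairs, then by candidate order. The template is the
    role previously published structure models play when contrasting
    alternative low-energy foldings.
    """
    if not candidates:
        raise ValueError("no candidate structures supplied")
    template = frozenset(template_pairs)
    if not template:
        raise ValueError("template must contain at least one pair")

    def f1(cand: SecondaryStructure) -> float:
        inter = len(cand.pair_set & template)
        denom = len(cand.pair_set) + len(template)
        return 2.0 * inter / denom if denom else 0.0

    best_idx = max(
        range(len(candidates)),
        key=lambda i: (f1(candidates[i]), candidates[i].n_pairs, -i),
    )
    return candidates[best_idx], f1(candidates[best_idx])


# ---------------------------------------------------------------------------
# Domain annotation
# ---------------------------------------------------------------------------


@dataclass
class DomainAnnotation:
    """Stem-loop domains DI.. rooted in the exterior loop, 5'->3'.

    ``domains`` holds (label, start, end) with 0-based half-open coordinates;
    ``single_strands`` the inter-domain unpaired segments, same convention.
    """

    domains: list[tuple[str, int, int]] = field(default_factory=list)
    single_strands: list[tuple[int, int]] = field(default_factory=list)

    def to_table(self) -> str:
        """Tab-separated report with 1-based inclusive coordinates."""
        lines = ["label\tstart\tend"]
        for label, s, e in self.domains:
            lines.append(f"{label}\t{s + 1}\t{e}")
        for s, e in self.single_strands:
            lines.append(f"ss\t{s + 1}\t{e}")
        return "\n".join(lines) + "\n"


_ROMAN = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X"]


def annotate_domains(structure: SecondaryStructure) -> DomainAnnotation:
    """One domain per stem rooted in the exterior loop, labelled DI, DII, ...

    Each domain interval runs from the 5' to the 3' side of its basal pair.
    """
    ann = DomainAnnotation()
    n = len(structure.pairs)
    i = 0
    ss_start = 0
    count = 0
    while i < n:
        j = structure.pairs[i]
        if j is not None and j > i:
            if i > ss_start:
                ann.single_strands.append((ss_start, i))
            label = "D" + (_ROMAN[count] if count < len(_ROMAN) else str(count + 1))
            ann.domains.append((label, i, j + 1))
            count += 1
            i = j + 1
            ss_start = i
        else:
            i += 1
    if n > ss_start:
        ann.single_strands.append((ss_start, n))
    return ann


# ---------------------------------------------------------------------------
# Motif search
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MotifMatch:
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    text: str


def iupac_regex(pattern: str) -> str:
    parts = []
    for ch in pattern.upper().replace("T", "U"):
        if ch not in IUPAC:
            raise ValueError(f"invalid IUPAC symbol {ch!r} in pattern")
        exp = IUPAC[ch]
        parts.append(exp if len(exp) == 1 else "[" + exp + "]")
    return "".join(parts)


def find_motif(
    sequence: str,
    iupac_pattern: str,
    region: Optional[tuple[int, int]] = None,
    context: Optional[str] = None,
    structure: Optional[SecondaryStructure] = None,
) -> list[MotifMatch]:
    """All (possibly overlapping) matches of an IUPAC pattern, 1-based.

    ``region`` is a 1-based inclusive interval restriction. ``context``
    restricts matches to lie wholly in single-stranded or helical positions
    of ``structure`` ("single-stranded" | "helix").
    """
    seq = normalize_rna(sequence)
    rx = re.compile("(?=(" + iupac_regex(iupac_pattern) + "))")
    if context is not None:
        if structure is None:
            raise ValueError("structural context requires a structure")
        if context not in ("single-stranded", "helix"):
            raise ValueError(f"unknown context {context!r}")
    matches = []
    for m in rx.finditer(seq):
        s = m.start(1)
        e = s + len(m.group(1))
        if region is not None and not (region[0] - 1 <= s and e <= region[1]):
            continue
        if context is not None:
            paired = [structure.pairs[k] is not None for k in range(s, e)]
            if context == "single-stranded" and any(paired):
                continue
            if context == "helix" and not all(paired):
                continue
        matches.append(MotifMatch(s + 1, e, m.group(1)))
    return matches


# ---------------------------------------------------------------------------
# Compensatory base changes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HelixMotif:
    """A double-helix motif: both strands written 5'->3'.

    Position i of strand5 pairs position (length-1-i) of strand3.
    """

    strand5: str
    strand3: str

    def __post_init__(self):
        object.__setattr__(self, "strand5", normalize_rna(self.strand5))
        object.__setattr__(self, "strand3", normalize_rna(self.strand3))
        if len(self.strand5) != len(self.strand3) or not self.strand5:
            raise ValueError("helix strands must have equal non-zero length")

    @property
    def length(self) -> int:
        return len(self.strand5)

    def pair(self, i: int) -> tuple[str, str]:
        return self.strand5[i], self.strand3[self.length - 1 - i]


@dataclass
class CBCReport:
    """Per-position comparison of two positionally homologous helices."""

    categories: list[str]  # unchanged | hemi-CBC | CBC | pairing-lost

    @property
    def counts(self) -> dict[str, int]:
        out = {"unchanged": 0, "hemi-CBC": 0, "CBC": 0, "pairing-lost": 0}
        for c in self.categories:
            out[c] += 1
        return out

    @property
    def n_cbc(self) -> int:
        return self.counts["CBC"]

    def to_table(self, helix_a: HelixMotif, helix_b: HelixMotif) -> str:
        lines = ["position\tstateA\tstateB\tcategory"]
        for i, cat in enumerate(self.categories):
            a5, a3 = helix_a.pair(i)
            b5, b3 = helix_b.pair(i)
            lines.append(f"{i + 1}\t{a5}-{a3}\t{b5}-{b3}\t{cat}")
        return "\n".join(lines) + "\n"


def detect_cbc(helix_a: HelixMotif, helix_b: HelixMotif) -> CBCReport:
    """Categorise each pair position of two homologous helices.

    unchanged: both partners identical. CBC: both partners substituted and
    the new pair still pairs. hemi-CBC: exactly one partner substituted,
    pairing preserved. pairing-lost: the resulting duplex position cannot
    pair. Hemi-CBCs are never added to the CBC count.
    """
    if helix_a.length != helix_b.length:
        raise ValueError(
            f"helix lengths differ: {helix_a.length} vs {helix_b.length}"
        )
    cats = []
    for i in range(helix_a.length):
        a5, a3 = helix_a.pair(i)
        b5, b3 = helix_b.pair(i)
        changed5, changed3 = a5 != b5, a3 != b3
        pairs_b = (b5, b3) in ALLOWED_PAIRS
        if not changed5 and not changed3:
            cats.append("unchanged")
        elif not pairs_b:
            cats.append("pairing-lost")
        elif changed5 and changed3:
            cats.append("CBC")
        else:
            cats.append("hemi-CBC")
    return CBCReport(cats)


# ---------------------------------------------------------------------------
# ITS2 delimitation
# ---------------------------------------------------------------------------


def delimit_its2(record, flank5_motif: str, flank3_motif: str):
    """Trim a record to the region between its 5.8S tail and 28S head motifs.

    Returns a copy spanning strictly between the 3' end of the FIRST flank5
    match and the 5' start of the LAST flank3 match; the cut coordinates
    (1-based) are appended to the description. No default motifs are shipped:
    flank choice follows the annotation conventions of the sequences at hand.
    """
    from .io_formats import SequenceRecord  # local import to avoid a cycle

    seq = normalize_rna(record.residues)
    m5 = find_motif(seq, flank5_motif)
    if not m5:
        raise ValueError("5′ flank not found")
    m3 = find_motif(seq, flank3_motif)
    if not m3:
        raise ValueError("3′ flank not found")
    start = m5[0].end  # 1-based inclusive end of flank5 == 0-based start
    end = m3[-1].start - 1  # 0-based exclusive end
    if end < start:
        raise ValueError("flank motifs overlap")
    if end == start:
        raise ValueError("zero-length ITS2 region between flanks")
    return SequenceRecord(
        id=record.id,
        description=(record.description + f" its2={start + 1}..{end}").strip(),
        residues=seq[start:end],
        role="ITS2",
        species=record.species,
    )
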