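"""The 12-letter sequence-structure alphabet and structure-aware alignment.

Each residue of a folded RNA is encoded as one of 12 states: the cross
product of the 4 nucleotides {A, C, G, U} with 3 structural states
{unpaired ".", paired-left "(", paired-right ")"}. The gap is a distinct
13th alignment symbol; IUPAC ambiguity codes encode as a missing symbol (N)
that scores zero against everything.

Export letter table (FASTA-safe, one letter per state)::

    base   unpaired   paired-left   paired-right
    A      A          B             D
    C      C          E             F
    G      G          H             I
    U      U          V             W

Alignment is global with affine gaps (Gotoh), pairwise and progressive with
an NJ guide tree, mirroring Clustal-style progressive alignment over a
sequence+structure scoring scheme. The same machinery aligns plain 4-state
nucleotide data (COI, 28S) with a 4x4 scheme.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .structure_model import IUPAC, SecondaryStructure, normalize_rna

BASES = "ACGU"
STRUCTS = ".()"

#: letter for state code 3*base + struct
LETTERS12 = "ABDCEFGHIUVW"
MISSING = "N"
GAP = "-"

_LETTER_TO_CODE = {c: i for i, c in enumerate(LETTERS12)}


def state_code(base: str, struct: str) -> int:
    return 3 * BASES.index(base) + STRUCTS.index(struct)


def state_letter(base: str, struct: str) -> str:
    return LETTERS12[state_code(base, struct)]


def letter_to_base_struct(letter: str) -> tuple[str, str]:
    code = _LETTER_TO_CODE[letter]
    return BASES[code // 3], STRUCTS[code % 3]


def encode_12state(sequence: str, structure: SecondaryStructure) -> str:
    """Position-wise pairing of base with structural state; invertible.

    Ambiguity codes encode as the missing symbol N (scored 0 in alignment,
    treated as fully missing in likelihoods).
    """
    seq = normalize_rna(sequence)
    if len(seq) != len(structure.pairs):
        raise ValueError(
            f"sequence length {len(seq)} != structure length {len(structure.pairs)}"
        )
    db = structure.dot_bracket
    out = []
    for base, st in zip(seq, db):
        if base in BASES:
            out.append(state_letter(base, st))
        elif base == "-":
            raise ValueError("gapped sequence cannot be encoded")
        else:  # IUPAC ambiguity
            out.append(MISSING)
    return "".join(out)


def decode_12state(encoded: str) -> tuple[str, str]:
    """Invert :func:`encode_12state` (N decodes to N with unpaired state)."""
    seq, db = [], []
    for ch in encoded:
        if ch == MISSING:
            seq.append("N")
            db.append(".")
        elif ch in _LETTER_TO_CODE:
            b, s = letter_to_base_struct(ch)
            seq.append(b)
            db.append(s)
        else:
            raise ValueError(f"invalid 12-state letter {ch!r}")
    return "".join(seq), "".join(db)


# ---------------------------------------------------------------------------
# Scoring schemes
# ---------------------------------------------------------------------------


@dataclass
class ScoringScheme:
    """Symmetric substitution scores over an alphabet plus affine gap costs.

    A single-residue gap costs ``gap_open``; each further residue of the same
    gap costs ``gap_extend``. The missing symbol N scores 0 against
    everything and never pays mismatch penalties.
    """

    letters: str
    matrix: np.ndarray
    gap_open: float = -5.0
    gap_extend: float = -1.0

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.letters)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape must match alphabet size")
        if not np.allclose(self.matrix, self.matrix.T):
            raise ValueError("scoring matrix must be symmetric")
        row_means = self.matrix.mean(axis=1)
        if np.any(np.diag(self.matrix) < row_means):
            raise ValueError("each diagonal score must be >= its row mean")
        if self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("gap penalties must be <= 0")
        if abs(self.gap_extend) > abs(self.gap_open):
            raise ValueError("|gap_extend| must be <= |gap_open|")
        self._index = {c: i for i, c in enumerate(self.letters)}

    def score(self, a: str, b: str) -> float:
        if a == MISSING or b == MISSING:
            return 0.0
        return self.matrix[self._index[a], self._index[b]]

    def to_tsv(self) -> str:
        lines = ["\t" + "\t".join(self.letters)]
        for i, c in enumerate(self.letters):
            lines.append(c + "\t" + "\t".join("%g" % v for v in self.matrix[i]))
        return "\n".join(lines) + "\n"

    @classmethod
    def from_tsv(cls, text: str, gap_open: float = -5.0, gap_extend: float = -1.0):
        lines = [ln for ln in text.splitlines() if ln.strip()]
        letters = "".join(lines[0].split())
        matrix = [[float(x) for x in ln.split()[1:]] for ln in lines[1:]]
        return cls(letters, np.asarray(matrix), gap_open, gap_extend)


def default_scheme_12() -> ScoringScheme:
    """Sum of a nucleotide component (+2 match / -1 mismatch) and a
    structural component (+1 match / -1 mismatch)."""
    n = len(LETTERS12)
    mat = np.zeros((n, n))
    for i, a in enumerate(LETTERS12):
        ab, ast = letter_to_base_struct(a)
        for j, b in enumerate(LETTERS12):
            bb, bst = letter_to_base_struct(b)
            mat[i, j] = (2.0 if ab == bb else -1.0) + (1.0 if ast == bst else -1.0)
    return ScoringScheme(LETTERS12, mat)


def default_scheme_4() -> ScoringScheme:
    mat = np.full((4, 4), -1.0)
    np.fill_diagonal(mat, 2.0)
    return ScoringScheme(BASES, mat)


# ---------------------------------------------------------------------------
# Pairwise global alignment (Gotoh, affine gaps)
# ---------------------------------------------------------------------------


def align_pairwise(
    a: str, b: str, scheme: Optional[ScoringScheme] = None
) -> tuple[str, str, float]:
    """Global alignment of two encoded strings maximising the scheme score.

    Deterministic traceback: prefer diagonal, then up (gap in b), then left.
    """
    if scheme is None:
        scheme = default_scheme_12()
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    pa = _Profile([a], ["a"])
    pb = _Profile([b], ["b"])
    merged, score = _align_profiles(pa, pb, scheme)
    return merged.rows[0], merged.rows[1], score


class _Profile:
    """A set of already-aligned rows treated as a column profile."""

    def __init__(self, rows: list[str], ids: list[str]):
        self.rows = rows
        self.ids = ids
        self.length = len(rows[0])

    def column(self, k: int) -> str:
        return "".join(r[k] for r in self.rows)

    def with_gaps(self, keep: list[Optional[int]]) -> list[str]:
        out = []
        for r in self.rows:
            out.append("".join(r[k] if k is not None else GAP for k in keep))
        return out


def _column_score(col_a: str, col_b: str, scheme: ScoringScheme) -> float:
    """Mean pairwise score between two profile columns (gaps score 0)."""
    total, count = 0.0, 0
    for x in col_a:
        for y in col_b:
            count += 1
            if x != GAP and y != GAP:
                total += scheme.score(x, y)
    return total / count


def _align_profiles(
    pa: _Profile, pb: _Profile, scheme: ScoringScheme
) -> tuple[_Profile, float]:
    n, m = pa.length, pb.length
    go, ge = scheme.gap_open, scheme.gap_extend
    NEG = -np.inf
    sub = np.empty((n, m))
    for i in range(n):
        ca = pa.column(i)
        for j in range(m):
            sub[i, j] = _column_score(ca, pb.column(j), scheme)

    # state indices: 0 = M (diagonal), 1 = X (gap in pb), 2 = Y (gap in pa);
    # ties everywhere resolve by this order (prefer diagonal, then up, then left)
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)
    Y = np.full((n + 1, m + 1), NEG)
    ptr = np.zeros((3, n + 1, m + 1), dtype=np.int8)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = go + ge * (i - 1)
        ptr[1, i, 0] = 0 if i == 1 else 1
    for j in range(1, m + 1):
        Y[0, j] = go + ge * (j - 1)
        ptr[2, 0, j] = 0 if j == 1 else 2

    def _argmax3(a: float, b: float, c: float) -> int:
        if a >= b and a >= c:
            return 0
        return 1 if b >= c else 2

    for i in range(1, n + 1):
        for j in range(1, m + 1):
            k = _argmax3(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            M[i, j] = (M, X, Y)[k][i - 1, j - 1] + sub[i - 1, j - 1]
            ptr[0, i, j] = k
            k = _argmax3(M[i - 1, j] + go, X[i - 1, j] + ge, Y[i - 1, j] + go)
            X[i, j] = (M[i - 1, j] + go, X[i - 1, j] + ge, Y[i - 1, j] + go)[k]
            ptr[1, i, j] = k
            k = _argmax3(M[i, j - 1] + go, X[i, j - 1] + go, Y[i, j - 1] + ge)
            Y[i, j] = (M[i, j - 1] + go, X[i, j - 1] + go, Y[i, j - 1] + ge)[k]
            ptr[2, i, j] = k

    keep_a: list[Optional[int]] = []
    keep_b: list[Optional[int]] = []
    i, j = n, m
    state = _argmax3(M[n, m], X[n, m], Y[n, m])
    score = (M[n, m], X[n, m], Y[n, m])[state]
    while i > 0 or j > 0:
        prev = ptr[state, i, j]
        if state == 0:
            keep_a.append(i - 1)
            keep_b.append(j - 1)
            i, j = i - 1, j - 1
        elif state == 1:
            keep_a.append(i - 1)
            keep_b.append(None)
            i -= 1
        else:
            keep_a.append(None)
            keep_b.append(j - 1)
            j -= 1
        state = int(prev)
    keep_a.reverse()
    keep_b.reverse()
    rows = pa.with_gaps(keep_a) + pb.with_gaps(keep_b)
    return _Profile(rows, pa.ids + pb.ids), float(score)


# ---------------------------------------------------------------------------
# Progressive multiple alignment
# ---------------------------------------------------------------------------


@dataclass
class TwelveStateAlignment:
    """Aligned rows over the 12-letter alphabet (+ gap, + missing)."""

    ids: list[str]
    rows: list[str]
    sources: dict[str, SecondaryStructure] = field(default_factory=dict)

    def __post_init__(self):
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("ragged 12-state alignment")
        if len(self.ids) != len(self.rows):
            raise ValueError("ids/rows length mismatch")

    @property
    def n_sites(self) -> int:
        return len(self.rows[0])

    def row_map(self) -> dict[str, str]:
        return dict(zip(self.ids, self.rows))

    def validate(self) -> None:
        for sid, row in zip(self.ids, self.rows):
            degapped = row.replace(GAP, "")
            seq, db = decode_12state(degapped)
            if MISSING not in degapped:
                # balanced structure string after gap removal
                depth = 0
                for ch in db:
                    depth += ch == "("
                    depth -= ch == ")"
                    if depth < 0:
                        raise ValueError(f"row {sid!r}: unbalanced structure state")
                if depth != 0:
                    raise ValueError(f"row {sid!r}: unbalanced structure state")
            src = self.sources.get(sid)
            if src is not None and any(
                d != s
                for d, s, ch in zip(db, src.dot_bracket, degapped)
                if ch != MISSING
            ):
                raise ValueError(f"row {sid!r} disagrees with source structure")

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for sid, row in zip(self.ids, self.rows):
                fh.write(f">{sid}\n{row}\n")


def p_distance(a: str, b: str) -> float:
    """Proportion of differing, jointly non-gap, non-missing columns."""
    used = diff = 0
    for x, y in zip(a, b):
        if GAP in (x, y) or MISSING in (x, y):
            continue
        used += 1
        diff += x != y
    return diff / used if used else 1.0


def align_progressive(
    items: Sequence[tuple], scheme: Optional[ScoringScheme] = None
) -> TwelveStateAlignment:
    """Progressive sequence-structure alignment with an NJ guide tree.

    ``items`` are (SequenceRecord, SecondaryStructure) pairs. A first pass of
    all-vs-all pairwise alignments yields p-distances, an NJ guide tree is
    built on them, and profiles are merged in guide-tree postorder.
    Deterministic given input order and scheme.
    """
    from .phylo_ml.search import nj_tree

    if scheme is None:
        scheme = default_scheme_12()
    if len(items) < 2:
        raise ValueError("progressive alignment needs at least 2 records")
    ids = [rec.id for rec, _ in items]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate record ids")
    encoded = {rec.id: encode_12state(rec.residues, st) for rec, st in items}
    sources = {rec.id: st for rec, st in items}

    if len(items) == 2:
        ra, rb, _ = align_pairwise(encoded[ids[0]], encoded[ids[1]], scheme)
        return TwelveStateAlignment(ids, [ra, rb], sources)

    n = len(ids)
    dmat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ra, rb, _ = align_pairwise(encoded[ids[i]], encoded[ids[j]], scheme)
            dmat[i, j] = dmat[j, i] = p_distance(ra, rb)
    guide = nj_tree(ids, dmat)

    profiles: dict[int, _Profile] = {}
    for node in guide.postorder():
        if node.is_leaf:
            profiles[id(node)] = _Profile([encoded[node.label]], [node.label])
        else:
            prof = profiles[id(node.children[0])]
            for child in node.children[1:]:
                prof, _ = _align_profiles(prof, profiles[id(child)], scheme)
            profiles[id(node)] = prof
    final = profiles[id(guide.root)]
    order = {sid: k for k, sid in enumerate(final.ids)}
    rows = [final.rows[order[sid]] for sid in ids]
    aln = TwelveStateAlignment(ids, rows, sources)
    aln.validate()
    return aln


def align_progressive_nucleotide(
    records: Sequence, scheme: Optional[ScoringScheme] = None
):
    """Plain 4-state progressive alignment (COI/28S path) via the same
    machinery; returns an :class:`rnaphylo.io_formats.Alignment`."""
    from .io_formats import Alignment, SequenceRecord

    if scheme is None:
        scheme = default_scheme_4()
    fake = []
    for rec in records:
        seq = rec.degapped()
        st = SecondaryStructure(seq, tuple([None] * len(seq)))
        fake.append((rec, st))
    # encode nucleotides directly: unpaired states map onto their own letters
    aln12 = align_progressive(fake, _lift_scheme_to_12(scheme))
    rows = []
    by_id = {r.id: r for r in records}
    for sid, row in zip(aln12.ids, aln12.rows):
        seq, _ = decode_12state(row.replace(GAP, ""))
        aligned = []
        k = 0
        for ch in row:
            if ch == GAP:
                aligned.append(GAP)
            else:
                aligned.append(seq[k])
                k += 1
        src = by_id[sid]
        rows.append(
            SequenceRecord(
                id=sid,
                residues="".join(aligned),
                description=src.description,
                role=src.role,
                species=src.species,
            )
        )
    return Alignment(rows)


def _lift_scheme_to_12(scheme4: ScoringScheme) -> ScoringScheme:
    """Embed a 4x4 nucleotide scheme into the 12-letter alphabet (structure
    component zero), so unpaired-only data aligns as plain nucleotides."""
    n = len(LETTERS12)
    mat = np.zeros((n, n))
    for i, a in enumerate(LETTERS12):
        ab, _ = letter_to_base_struct(a)
        for j, b in enumerate(LETTERS12):
            bb, _ = letter_to_base_struct(b)
            mat[i, j] = scheme4.score(ab, bb)
    return ScoringScheme(LETTERS12, mat, scheme4.gap_open, scheme4.gap_extend)
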