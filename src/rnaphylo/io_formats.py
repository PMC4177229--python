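"""Readers/writers for every external representation the pipeline touches.

FASTA goes through Biopython; Newick through the tree module (dendropy
backed); Vienna dot-bracket triplets, square PHYLIP distance matrices and the
flat key-value config format are simple line formats parsed here. All readers
reject malformed input rather than silently repairing it. Error messages use
1-based inclusive coordinates.

DNA input is accepted and normalised to the RNA alphabet on ingest (T -> U),
with the original molecule noted in the record description; writers can map
back to DNA with ``alphabet="DNA"``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

from .structure_model import SecondaryStructure, normalize_rna
from .phylo_ml.tree import PhyloTree, read_newick, write_newick  # noqa: F401

ROLES = {"ITS2", "16S", "COI", "28S", "other"}


@dataclass
class SequenceRecord:
    """One sequence with its provenance metadata.

    ``residues`` are RNA-alphabet (plus IUPAC ambiguity codes and '-').
    """

    id: str
    residues: str
    description: str = ""
    role: str = "other"
    species: Optional[str] = None

    def __post_init__(self):
        if not self.id:
            raise ValueError("record id must be non-empty")
        if not self.residues:
            raise ValueError(f"empty sequence for record {self.id!r}")
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}")
        self.residues = normalize_rna(self.residues)

    def __len__(self) -> int:
        return len(self.residues)

    def degapped(self) -> str:
        return self.residues.replace("-", "")


@dataclass
class Alignment:
    """Equal-length rows of SequenceRecords."""

    rows: list[SequenceRecord]

    def __post_init__(self):
        if len(self.rows) < 2:
            raise ValueError("alignment needs at least 2 rows")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise ValueError(f"ragged alignment: row lengths {sorted(lengths)}")
        _check_unique_ids(r.id for r in self.rows)

    @property
    def n_sites(self) -> int:
        return len(self.rows[0])

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.rows]

    def row_map(self) -> dict[str, str]:
        return {r.id: r.residues for r in self.rows}


def _check_unique_ids(ids: Iterable[str]) -> None:
    seen = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate sequence id {i!r}")
        seen.add(i)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path, role: str = "other") -> list[SequenceRecord]:
    """Read a multi-FASTA file; T is normalised to U, noted in description."""
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        raw = str(rec.seq)
        desc = rec.description[len(rec.id):].strip()
        if "T" in raw.upper() and "molecule=" not in desc:
            desc = (desc + " molecule=DNA").strip()
        records.append(
            SequenceRecord(id=rec.id, residues=raw, description=desc, role=role)
        )
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    _check_unique_ids(r.id for r in records)
    return records


def write_fasta(
    records: Iterable[SequenceRecord],
    path,
    line_width: int = 70,
    alphabet: str = "RNA",
) -> None:
    records = list(records)
    if not records:
        raise ValueError("refusing to write an empty FASTA file")
    _check_unique_ids(r.id for r in records)
    with open(path, "w") as fh:
        for r in records:
            seq = r.residues if alphabet == "RNA" else r.residues.replace("U", "T")
            header = f">{r.id}" + (f" {r.description}" if r.description else "")
            fh.write(header + "\n")
            for i in range(0, len(seq), line_width):
                fh.write(seq[i : i + line_width] + "\n")


# ---------------------------------------------------------------------------
# Vienna dot-bracket triplets
# ---------------------------------------------------------------------------


def read_vienna(path) -> list[tuple[SequenceRecord, SecondaryStructure]]:
    """Read (header, sequence, dot-bracket) triplets."""
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if len(lines) % 3 != 0:
        raise ValueError(
            f"{path}: expected header/sequence/structure triplets, "
            f"got {len(lines)} non-empty lines"
        )
    out = []
    for k in range(0, len(lines), 3):
        header, seq, db = lines[k], lines[k + 1], lines[k + 2]
        if not header.startswith(">"):
            raise ValueError(f"{path}: line {k + 1}: expected '>' header")
        parts = header[1:].split(None, 1)
        rec = SequenceRecord(
            id=parts[0], residues=seq, description=parts[1] if len(parts) > 1 else ""
        )
        if len(db) != len(seq):
            raise ValueError(
                f"{path}: {rec.id}: structure length {len(db)} != "
                f"sequence length {len(seq)}"
            )
        struct = SecondaryStructure.from_dotbracket(rec.residues, db)
        out.append((rec, struct))
    if not out:
        raise ValueError(f"no Vienna entries found in {path}")
    _check_unique_ids(r.id for r, _ in out)
    return out


def write_vienna(
    entries: Iterable[tuple[SequenceRecord, SecondaryStructure]], path
) -> None:
    entries = list(entries)
    if not entries:
        raise ValueError("refusing to write an empty Vienna file")
    with open(path, "w") as fh:
        for rec, struct in entries:
            header = f">{rec.id}" + (f" {rec.description}" if rec.description else "")
            fh.write(f"{header}\n{rec.residues}\n{struct.dot_bracket}\n")


# ---------------------------------------------------------------------------
# Square PHYLIP distance matrix
# ---------------------------------------------------------------------------


def read_phylip_matrix(path) -> tuple[list[str], np.ndarray]:
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    try:
        n = int(lines[0])
    except (IndexError, ValueError) as exc:
        raise ValueError(f"{path}: first line must be the taxon count") from exc
    if len(lines) != n + 1:
        raise ValueError(f"{path}: expected {n} matrix rows, got {len(lines) - 1}")
    labels, matrix = [], []
    for ln in lines[1:]:
        parts = ln.split()
        if len(parts) != n + 1:
            raise ValueError(f"{path}: row {parts[0]!r} has {len(parts) - 1} values")
        labels.append(parts[0])
        matrix.append([float(x) for x in parts[1:]])
    mat = np.asarray(matrix)
    if not np.allclose(mat, mat.T, atol=1e-9):
        raise ValueError(f"{path}: matrix is not symmetric")
    return labels, mat


def write_phylip_matrix(labels: list[str], matrix: np.ndarray, path) -> None:
    matrix = np.asarray(matrix)
    n = len(labels)
    if matrix.shape != (n, n):
        raise ValueError("matrix shape does not match label count")
    with open(path, "w") as fh:
        fh.write(f"{n}\n")
        for i, label in enumerate(labels):
            vals = "  ".join("%.8f" % v for v in matrix[i])
            fh.write(f"{label:<12s}  {vals}\n")


# ---------------------------------------------------------------------------
# Species maps, synonym sets, flat key-value config
# ---------------------------------------------------------------------------


def read_species_map(path) -> dict[str, str]:
    """Two-column TSV: sequence_id<TAB>species."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for ln_no, ln in enumerate(fh, 1):
            if not ln.strip() or ln.startswith("#"):
                continue
            parts = ln.rstrip("\n").split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}: line {ln_no}: expected 2 columns")
            if parts[0] in out:
                raise ValueError(f"{path}: duplicate sequence id {parts[0]!r}")
            out[parts[0]] = parts[1]
    if not out:
        raise ValueError(f"{path}: empty species map")
    return out


def write_species_map(species_map: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for sid, sp in species_map.items():
            fh.write(f"{sid}\t{sp}\n")


def read_synonym_sets(path) -> list[frozenset]:
    """One synonym set per line, species names comma-joined."""
    out = []
    with open(path) as fh:
        for ln in fh:
            if not ln.strip() or ln.startswith("#"):
                continue
            names = frozenset(x.strip() for x in ln.split(",") if x.strip())
            if len(names) >= 2:
                out.append(names)
    return out


def read_config(path) -> dict[str, str]:
    """Flat ``key = value`` settings file; '#' starts a comment."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for ln_no, ln in enumerate(fh, 1):
            stripped = ln.split("#", 1)[0].strip()
            if not stripped:
                continue
            if "=" not in stripped:
                raise ValueError(f"{path}: line {ln_no}: expected 'key = value'")
            key, value = stripped.split("=", 1)
            out[key.strip()] = value.strip()
    return out


def write_config(settings: dict, path) -> None:
    with open(path, "w") as fh:
        for k, v in settings.items():
            fh.write(f"{k} = {v}\n")


# ---------------------------------------------------------------------------
# Biopython bridge (used by callers that want Bio.SeqRecord objects)
# ---------------------------------------------------------------------------


def to_biopython(record: SequenceRecord) -> BioSeqRecord:
    return BioSeqRecord(
        Seq(record.residues), id=record.id, description=record.description
    )
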