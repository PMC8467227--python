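"""Sequence and tree I/O for the GH13 CSR pipeline.

Reads and writes plain/aligned FASTA, Clustal alignments and Newick trees,
and implements the record-id convention used throughout the pipeline:
the first underscore-delimited token of a FASTA header is the database
accession, the remainder (underscores turned into spaces) is the binomial
organism name, and a trailing parenthetical such as ``(saliva)`` is kept
as a free-text note, e.g. ``AAA85446_Paenibacillus_polymyxa``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

from Bio import AlignIO, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: 'X' is accepted on input but never satisfies any site rule downstream.
VALID_RESIDUES = frozenset(AMINO_ACIDS + "X")
GAP = "-"

SUBFAMILIES = ("GH13_1", "GH13_5", "GH13_15", "GH13_24", "GH13_32", "GH13_42")
TAXON_DOMAINS = ("Procarya", "Eucarya")

_NOTE_RE = re.compile(r"\s*\(([^()]*)\)\s*$")


@dataclass(frozen=True)
class SequenceRecord:
    """One ungapped protein sequence with its provenance labels.

    ``subfamily`` is one of the six GH13 subfamilies handled by the
    pipeline (or ``"unknown"``); ``taxon_domain`` distinguishes
    prokaryotic (``Procarya``) from eukaryotic (``Eucarya``) origin.
    """

    accession: str
    residues: str
    organism: str = ""
    subfamily: str = "unknown"
    taxon_domain: str = "unknown"
    note: str = ""

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValueError("accession must be non-empty")
        if not self.residues:
            raise ValueError(f"record {self.accession}: residues must be non-empty")
        bad = set(self.residues) - VALID_RESIDUES
        if bad:
            raise ValueError(
                f"record {self.accession}: invalid residue characters {sorted(bad)}"
            )
        if self.subfamily != "unknown" and self.subfamily not in SUBFAMILIES:
            raise ValueError(f"record {self.accession}: unknown subfamily {self.subfamily!r}")
        if self.taxon_domain != "unknown" and self.taxon_domain not in TAXON_DOMAINS:
            raise ValueError(
                f"record {self.accession}: unknown taxon domain {self.taxon_domain!r}"
            )

    def __len__(self) -> int:
        return len(self.residues)


def parse_record_id(text: str) -> tuple[str, str, str]:
    """Split a header into ``(accession, organism, note)``.

    The first underscore-delimited token is the accession; the rest,
    with underscores replaced by spaces, is the organism.  A trailing
    parenthetical (tissue or strain qualifier) becomes the note.
    """
    text = text.strip()
    if not text:
        raise ValueError("empty record id")
    note = ""
    m = _NOTE_RE.search(text)
    if m:
        note = m.group(1).strip()
        text = text[: m.start()].strip()
    accession, _, rest = text.partition("_")
    organism = rest.replace("_", " ").strip()
    return accession, organism, note


def compose_record_id(record: SequenceRecord) -> str:
    """Inverse of :func:`parse_record_id` for a record's labels."""
    parts = [record.accession]
    if record.organism:
        parts.append(record.organism.replace(" ", "_"))
    rid = "_".join(parts)
    if record.note:
        rid += f" ({record.note})"
    return rid


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read ungapped protein records from a FASTA file.

    Residues are upper-cased and a terminal ``*`` stop is stripped.
    Raises if the file holds no records or a sequence contains
    characters outside the 20 amino-acid letters plus ``X``.
    """
    records = []
    for entry in SeqIO.parse(str(path), "fasta"):
        accession, organism, note = parse_record_id(entry.description)
        residues = str(entry.seq).upper().rstrip("*")
        records.append(
            SequenceRecord(
                accession=accession, residues=residues, organism=organism, note=note
            )
        )
    if not records:
        raise ValueError(f"no records in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    entries = [
        _BioSeqRecord(Seq(r.residues), id=compose_record_id(r), description="")
        for r in records
    ]
    with open(path, "w", newline="\n") as fh:
        SeqIO.write(entries, fh, "fasta")


@dataclass
class Msa:
    """A rectangular gapped alignment; columns are addressed 1-based."""

    row_ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.row_ids) != len(self.rows):
            raise ValueError("row_ids and rows differ in length")
        if len(set(self.row_ids)) != len(self.row_ids):
            raise ValueError("row ids are not unique")
        if self.rows:
            width = len(self.rows[0])
            for rid, row in zip(self.row_ids, self.rows):
                if len(row) != width:
                    raise ValueError(
                        f"row {rid!r} has length {len(row)}, expected {width}"
                    )

    @property
    def width(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def __len__(self) -> int:
        return len(self.rows)

    def index(self, row_id: str) -> int:
        try:
            return self.row_ids.index(row_id)
        except ValueError:
            raise KeyError(f"row {row_id!r} not in alignment") from None

    def row(self, row_id: str) -> str:
        return self.rows[self.index(row_id)]

    def degapped(self, row_id: str) -> str:
        return self.row(row_id).replace(GAP, "")

    def column(self, j: int) -> str:
        """Residues of 1-based column ``j``, top to bottom."""
        if not 1 <= j <= self.width:
            raise IndexError(f"column {j} outside 1..{self.width}")
        return "".join(row[j - 1] for row in self.rows)

    def select_columns(self, columns: Iterable[int]) -> "Msa":
        """New alignment keeping only the given 1-based columns, in order."""
        cols = list(columns)
        rows = ["".join(row[c - 1] for c in cols) for row in self.rows]
        return Msa(list(self.row_ids), rows)


def _normalize_gap(seq: str) -> str:
    # '.' is a common alternative gap character on input; normalized here.
    return seq.upper().replace(".", GAP)


def read_msa(path: str | Path, dialect: str = "aligned_fasta") -> Msa:
    """Read an alignment in aligned-FASTA or Clustal format.

    Ragged aligned-FASTA input raises an error naming the offending row.
    """
    if dialect == "aligned_fasta":
        ids, rows = [], []
        for entry in SeqIO.parse(str(path), "fasta"):
            accession, _, _ = parse_record_id(entry.description)
            ids.append(accession)
            rows.append(_normalize_gap(str(entry.seq)))
        if not ids:
            raise ValueError(f"no alignment rows in {path}")
        width = len(rows[0])
        for rid, row in zip(ids, rows):
            if len(row) != width:
                raise ValueError(f"ragged alignment: row {rid!r} has length {len(row)}")
        return Msa(ids, rows)
    if dialect == "clustal":
        aln = AlignIO.read(str(path), "clustal")
        ids = [parse_record_id(rec.id)[0] for rec in aln]
        rows = [_normalize_gap(str(rec.seq)) for rec in aln]
        return Msa(ids, rows)
    raise ValueError(f"unknown alignment dialect {dialect!r}")


def write_msa(msa: Msa, path: str | Path) -> None:
    """Write an alignment as aligned FASTA (LF line endings)."""
    with open(path, "w", newline="\n") as fh:
        for rid, row in zip(msa.row_ids, msa.rows):
            fh.write(f">{rid}\n{row}\n")


def write_phylip(msa: Msa, path: str | Path) -> None:
    """Relaxed sequential PHYLIP export, for external tree programs."""
    with open(path, "w", newline="\n") as fh:
        fh.write(f" {len(msa)} {msa.width}\n")
        for rid, row in zip(msa.row_ids, msa.rows):
            fh.write(f"{rid:<12s}{row}\n")


def write_newick(tree, path: str | Path) -> None:
    """Write a scikit-bio ``TreeNode`` as Newick.

    Branch lengths are kept; integer bootstrap supports, when present,
    travel as internal-node labels.
    """
    with open(path, "w", newline="\n") as fh:
        tree.write(fh, format="newick")


def read_newick(path: str | Path):
    from skbio import TreeNode

    return TreeNode.read(str(path), format="newick")
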