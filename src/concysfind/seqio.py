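"""Reading and writing of every external format the pipeline touches.

Covers FASTA proteomes and queries, the two-column tab-separated query
list, substitution matrices (BLOSUM62 bundled via Biopython), the
tab-separated results table and the plain-text alignment dump.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Mapping, Sequence, TextIO

import numpy as np
from Bio import SeqIO
from Bio.Align import substitution_matrices

#: The residue alphabet accepted everywhere: the 20 standard amino acids
#: plus X (unknown).  ``*`` is tolerated only as a terminal stop and
#: stripped on input; ``-`` never appears inside stored residues.
ALPHABET = "ACDEFGHIKLMNPQRSTVWYX"
_ALPHABET_SET = frozenset(ALPHABET)

GAP = "-"


class ConCysFindError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(ConCysFindError):
    """Malformed input data."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SequenceRecord:
    """One protein sequence from one species."""

    id: str
    description: str
    species: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record id must be non-empty")
        if not self.residues:
            raise ValueError(f"record {self.id!r}: empty sequence")


@dataclass(frozen=True)
class QueryEntry:
    """A query protein: identifier, optional description, sequence."""

    id: str
    description: str
    sequence: str


@dataclass(frozen=True)
class SubstitutionMatrix:
    """Symmetric integer substitution matrix over :data:`ALPHABET`.

    ``scores`` is indexed by letter position in ``alphabet``; use
    :meth:`score` for letter lookup and :meth:`encode` to map a sequence
    to integer indices for vectorised scoring.
    """

    alphabet: str
    scores: np.ndarray  # square, int, symmetric
    name: str
    _index: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        n = len(self.alphabet)
        if self.scores.shape != (n, n):
            raise ValueError("substitution matrix is not square over its alphabet")
        if not np.array_equal(self.scores, self.scores.T):
            raise ParseError(f"substitution matrix {self.name!r} is asymmetric")
        object.__setattr__(self, "_index", {c: i for i, c in enumerate(self.alphabet)})

    def score(self, a: str, b: str) -> int:
        return int(self.scores[self._index[a], self._index[b]])

    def encode(self, seq: str) -> np.ndarray:
        try:
            return np.fromiter((self._index[c] for c in seq), dtype=np.intp, count=len(seq))
        except KeyError as exc:
            raise ParseError(f"residue {exc.args[0]!r} not in matrix alphabet") from None


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def _validate_residues(seq: str, record_id: str) -> None:
    for pos, ch in enumerate(seq, start=1):
        if ch not in _ALPHABET_SET:
            raise ParseError(
                f"record {record_id!r}: illegal residue {ch!r} at position {pos}"
            )


def parse_fasta(stream: TextIO | str, species: str = "") -> list[SequenceRecord]:
    """Parse FASTA text into :class:`SequenceRecord` objects.

    Multi-line sequences are concatenated, residues uppercased, and a
    single terminal ``*`` (stop) stripped.  ``species`` labels every
    record (one file = one species).

    Raises :class:`ParseError` on an empty file, a duplicate id, or an
    illegal residue (named with record and 1-based position).
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(stream, "fasta"):
        if rec.id in seen:
            raise ParseError(f"duplicate accession {rec.id!r} in species {species!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if seq.endswith("*"):
            seq = seq[:-1]
        if not seq:
            raise ParseError(f"record {rec.id!r}: empty sequence")
        _validate_residues(seq, rec.id)
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(SequenceRecord(id=rec.id, description=desc, species=species, residues=seq))
    if not records:
        raise ParseError("no sequences found in FASTA input")
    return records


def write_fasta(records: Iterable[SequenceRecord], stream: TextIO, width: int = 60) -> None:
    """Serialize records to FASTA (round-trips through :func:`parse_fasta`)."""
    for rec in records:
        header = f">{rec.id} {rec.description}".rstrip()
        stream.write(header + "\n")
        for i in range(0, len(rec.residues), width):
            stream.write(rec.residues[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# Query table
# ---------------------------------------------------------------------------


def parse_query_table(stream: TextIO | str, sequences: Mapping[str, str]) -> list[QueryEntry]:
    """Parse the two-column (id, optional description) query list.

    Every id must resolve in ``sequences`` (an id -> residue-string map,
    typically from a companion FASTA).
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    entries: list[QueryEntry] = []
    seen: set[str] = set()
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n").rstrip("\r")
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) > 2:
            raise ParseError(f"line {lineno}: expected 1 or 2 tab-separated fields")
        qid = parts[0].strip()
        desc = parts[1].strip() if len(parts) == 2 else ""
        if qid in seen:
            raise ParseError(f"duplicate query id {qid!r} at line {lineno}")
        seen.add(qid)
        if qid not in sequences:
            raise ParseError(f"unknown query id {qid!r}: no sequence supplied for it")
        entries.append(QueryEntry(id=qid, description=desc, sequence=sequences[qid]))
    return entries


# ---------------------------------------------------------------------------
# Substitution matrices
# ---------------------------------------------------------------------------


def load_substitution_matrix(name: str = "BLOSUM62") -> SubstitutionMatrix:
    """Load a substitution matrix by name (``"BLOSUM62"`` bundled) or
    from an NCBI-format matrix file path.

    The returned matrix is restricted to the 21-letter alphabet
    (20 amino acids + X) and checked for symmetry.
    """
    if name == "BLOSUM62":
        raw = substitution_matrices.load("BLOSUM62")
    else:
        try:
            raw = substitution_matrices.read(name)
        except FileNotFoundError:
            raise ConCysFindError(f"unknown substitution matrix {name!r}") from None
    missing = [c for c in ALPHABET if c not in raw.alphabet]
    if missing:
        raise ParseError(f"matrix {name!r} lacks letters {missing}")
    n = len(ALPHABET)
    scores = np.zeros((n, n), dtype=np.int64)
    for i, a in enumerate(ALPHABET):
        for j, b in enumerate(ALPHABET):
            v = raw[a, b]
            if v != int(v):
                raise ParseError(f"matrix {name!r} entry [{a},{b}] is not integral")
            scores[i, j] = int(v)
    label = "BLOSUM62" if name == "BLOSUM62" else name
    return SubstitutionMatrix(alphabet=ALPHABET, scores=scores, name=label)


# ---------------------------------------------------------------------------
# Results table and alignment dump
# ---------------------------------------------------------------------------

RESULTS_HEADER = (
    "name\tid\thomologs\tputatively_conserved\ttarget_aa\tposition\tscore\tp_value\tconserved"
)


def format_score(k: int, n: int) -> str:
    """Render k/n with exactly two decimals, round-half-up."""
    return str((Decimal(k) / Decimal(n)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def format_pvalue(p: float) -> str:
    """Scientific notation with three significant digits (e.g. 1.13e-13)."""
    return f"{p:.2e}".replace("e-0", "e-").replace("e+0", "e+")


def write_results_table(reports: Sequence, stream: TextIO) -> None:
    """Write the per-protein / per-residue results as tab-separated text.

    Layout per protein: one summary row (homolog-species count and a
    ``k of m`` conserved tally), then one row per analyzed residue with
    position, score (2 decimals, half-up) and p-value (3 significant
    digits).  Proteins appear in input order.
    """
    if not reports:
        raise ConCysFindError("no reports to write")
    stream.write(RESULTS_HEADER + "\n")
    for rep in reports:
        name = rep.query.description or rep.query.id
        stream.write(
            f"{name}\t{rep.query.id}\t{rep.n_homolog_species}\t"
            f"{rep.conserved_count} of {rep.total_count}\t\t\t\t\t\n"
        )
        for res in rep.residues:
            if res.n == 0:
                stream.write(
                    f"{name}\t{rep.query.id}\t\t\t{res.target_aa}\t{res.position}\t"
                    "NA\tNA\tERROR:no_homologs\n"
                )
                continue
            stream.write(
                f"{name}\t{rep.query.id}\t\t\t{res.target_aa}\t{res.position}\t"
                f"{format_score(res.k, res.n)}\t{format_pvalue(res.p_value)}\t"
                f"{'yes' if res.conserved else 'no'}\n"
            )


def write_alignment_dump(blocks: Iterable[tuple[str, Sequence[tuple[str, str]]]],
                         stream: TextIO) -> None:
    """Write alignment blocks: a ``# title`` line then ``label<TAB>row`` lines."""
    for title, rows in blocks:
        stream.write(f"# {title}\n")
        for label, gapped in rows:
            stream.write(f"{label}\t{gapped}\n")
        stream.write("\n")
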