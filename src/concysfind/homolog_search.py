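"""Per-species homolog search: exact local alignment, e-value statistics,
and the relative-score / max-9-candidate selection rule.

The search engine is a built-in exact Smith-Waterman with affine gaps
(default open 11, extend 1, BLOSUM62), so runs are deterministic and
need no external binary.  Candidate selection is the part that matters
downstream: per species, hits above the e-value cutoff are dropped,
survivors scoring below ``rel_score_cutoff`` x the species' best hit are
dropped, and at most ``max_hits`` (default 9) candidates are kept,
best-first.  An adapter accepts standard 12-column tabular search output
in place of the built-in aligner for large databases.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, TextIO

import numpy as np

from .proteome_db import ProteomeDatabase
from .seqio import ConCysFindError, ParseError, QueryEntry, SequenceRecord, SubstitutionMatrix


@dataclass(frozen=True)
class PairwiseAlignment:
    """A scored local alignment with 1-based inclusive coordinates."""

    raw_score: float
    bit_score: float
    e_value: float
    query_aligned: str
    subject_aligned: str
    query_start: int
    query_end: int
    subject_start: int
    subject_end: int
    identity: float


@dataclass
class SpeciesHitList:
    """Ranked homolog candidates for one species (possibly empty)."""

    species: str
    hits: list[tuple[SequenceRecord, PairwiseAlignment]]

    @property
    def best_score(self) -> float:
        return self.hits[0][1].raw_score if self.hits else 0.0

    def __len__(self) -> int:
        return len(self.hits)

    def __bool__(self) -> bool:
        return bool(self.hits)


@dataclass
class SearchParams:
    """Tunable knobs of the search and selection step.

    lambda_gapped / k_gapped are the Karlin-Altschul statistics used to
    turn raw scores into bit scores and e-values; the defaults are the
    standard published values for gapped BLOSUM62 (open 11, extend 1).
    """

    gap_open: int = 11
    gap_extend: int = 1
    evalue_cutoff: float = 1e-5
    max_hits: int = 9
    rel_score_cutoff: float = 0.8
    lambda_gapped: float = 0.267
    k_gapped: float = 0.041
    alpha: float = 0.01

    def __post_init__(self) -> None:
        if self.max_hits < 1:
            raise ConCysFindError("max_hits must be >= 1")
        if not (0.0 < self.rel_score_cutoff <= 1.0):
            raise ConCysFindError("rel_score_cutoff must be in (0, 1]")


# ---------------------------------------------------------------------------
# Smith-Waterman, affine gaps
# ---------------------------------------------------------------------------

_NEG = -1 << 40  # effectively -infinity for integer DP


def sw_score(qi: np.ndarray, si: np.ndarray, matrix: SubstitutionMatrix,
             gap_open: int, gap_extend: int) -> int:
    """Optimal local-alignment score only (vectorised per row).

    The horizontal-gap recursion is collapsed into a running prefix
    maximum, which makes each row a handful of numpy operations.
    """
    sub = matrix.scores[qi][:, si]  # (m, n) substitution scores
    m, n = sub.shape
    ext = gap_extend
    idx_ext = np.arange(n, dtype=np.int64) * ext
    H_prev = np.zeros(n + 1, dtype=np.int64)
    F = np.full(n, _NEG, dtype=np.int64)
    best = 0
    for i in range(m):
        F = np.maximum(H_prev[1:] - gap_open, F - ext)
        G = np.maximum(np.maximum(sub[i] + H_prev[:-1], F), 0)
        # horizontal gaps: E[j] = max_{j'<j}(G[j'] + j'*ext) - open - (j-1)*ext
        run = np.maximum.accumulate(G + idx_ext)
        H = G.copy()
        if n > 1:
            E = run[:-1] - gap_open - idx_ext[1:] + ext
            np.maximum(H[1:], E, out=H[1:])
        row_best = int(H.max())
        if row_best > best:
            best = row_best
        H_prev = np.concatenate(([0], H))
    return best


def smith_waterman(query: str, subject: str, matrix: SubstitutionMatrix,
                   gap_open: int = 11, gap_extend: int = 1,
                   params: SearchParams | None = None,
                   db_residues: int | None = None) -> PairwiseAlignment:
    """Optimal local alignment with affine gaps and full traceback.

    Gap of length L costs ``gap_open + (L-1)*gap_extend``.  Traceback is
    deterministic: ties resolve diagonal > up (gap in subject) > left
    (gap in query); among equal-scoring end cells the smallest query
    index, then smallest subject index, wins.
    """
    if not query or not subject:
        raise ConCysFindError("smith_waterman requires non-empty sequences")
    qi = matrix.encode(query)
    si = matrix.encode(subject)
    sub = matrix.scores[qi][:, si]
    m, n = len(query), len(subject)
    H = np.zeros((m + 1, n + 1), dtype=np.int64)
    E = np.full((m + 1, n + 1), _NEG, dtype=np.int64)  # gap in query (left)
    F = np.full((m + 1, n + 1), _NEG, dtype=np.int64)  # gap in subject (up)
    for i in range(1, m + 1):
        Hi, Hi1 = H[i], H[i - 1]
        Ei, Fi, Fi1 = E[i], F[i], F[i - 1]
        row = sub[i - 1]
        for j in range(1, n + 1):
            e = max(Hi[j - 1] - gap_open, Ei[j - 1] - gap_extend)
            f = max(Hi1[j] - gap_open, Fi1[j] - gap_extend)
            Ei[j] = e
            Fi[j] = f
            h = Hi1[j - 1] + row[j - 1]
            if f > h:
                h = f
            if e > h:
                h = e
            Hi[j] = h if h > 0 else 0
    best = int(H.max())
    if best == 0:
        bit, ev = (0.0, math.inf)
        if params is not None:
            bit, ev = evalue_from_score(0, m, db_residues or n, params)
        return PairwiseAlignment(0, bit, ev, "", "", 0, 0, 0, 0, 0.0)
    end_i, end_j = np.unravel_index(int(np.argmax(H)), H.shape)  # row-major: smallest i, then j
    # traceback
    qa: list[str] = []
    sa: list[str] = []
    i, j = int(end_i), int(end_j)
    state = "H"
    while True:
        if state == "H":
            if H[i, j] == 0:
                break
            if H[i, j] == H[i - 1, j - 1] + sub[i - 1, j - 1]:
                qa.append(query[i - 1])
                sa.append(subject[j - 1])
                i -= 1
                j -= 1
            elif H[i, j] == F[i, j]:
                state = "F"
            else:
                state = "E"
        elif state == "F":  # gap in subject, consume query residue
            qa.append(query[i - 1])
            sa.append("-")
            opened = F[i, j] == H[i - 1, j] - gap_open
            i -= 1
            if opened:
                state = "H"
        else:  # E: gap in query, consume subject residue
            qa.append("-")
            sa.append(subject[j - 1])
            opened = E[i, j] == H[i, j - 1] - gap_open
            j -= 1
            if opened:
                state = "H"
    qa.reverse()
    sa.reverse()
    q_aln, s_aln = "".join(qa), "".join(sa)
    ncols = len(q_aln)
    matches = sum(1 for a, b in zip(q_aln, s_aln) if a == b and a != "-")
    bit, ev = (float(best), 0.0)
    if params is not None:
        bit, ev = evalue_from_score(best, m, db_residues or n, params)
    return PairwiseAlignment(
        raw_score=float(best), bit_score=bit, e_value=ev,
        query_aligned=q_aln, subject_aligned=s_aln,
        query_start=i + 1, query_end=int(end_i),
        subject_start=j + 1, subject_end=int(end_j),
        identity=matches / ncols if ncols else 0.0,
    )


def evalue_from_score(raw_score: float, query_len: int, db_residues: int,
                      params: SearchParams) -> tuple[float, float]:
    """Karlin-Altschul closed form: E = K*m*n*exp(-lambda*S),
    bits = (lambda*S - ln K) / ln 2."""
    lam, K = params.lambda_gapped, params.k_gapped
    bits = (lam * raw_score - math.log(K)) / math.log(2.0)
    e_value = K * query_len * db_residues * math.exp(-lam * raw_score)
    return bits, e_value


# ---------------------------------------------------------------------------
# Per-species search and selection
# ---------------------------------------------------------------------------


def _select(scored: list[tuple[SequenceRecord, PairwiseAlignment]],
            params: SearchParams) -> list[tuple[SequenceRecord, PairwiseAlignment]]:
    """Apply e-value cutoff, the relative-score 0.8 rule, and max_hits."""
    survivors = [(r, a) for r, a in scored if a.e_value <= params.evalue_cutoff]
    if not survivors:
        return []
    survivors.sort(key=lambda ra: (-ra[1].raw_score, ra[1].e_value, ra[0].id))
    best = survivors[0][1].raw_score
    floor = params.rel_score_cutoff * best
    survivors = [(r, a) for r, a in survivors if a.raw_score >= floor]
    return survivors[: params.max_hits]


def search_species(query: QueryEntry, db: ProteomeDatabase, species: str,
                   params: SearchParams, matrix: SubstitutionMatrix) -> SpeciesHitList:
    """Align the query against every subject of one species and keep the
    selected candidates, best-first.  An empty list is a valid outcome
    (the species has no detectable homolog)."""
    if species not in db.panel.species:
        raise ConCysFindError(f"species {species!r} not in panel")
    qi = matrix.encode(query.sequence)
    m = len(query.sequence)
    db_res = db.total_residues
    scored: list[tuple[SequenceRecord, PairwiseAlignment]] = []
    for rec in db.records[species]:
        s = sw_score(qi, matrix.encode(rec.residues), matrix,
                     params.gap_open, params.gap_extend)
        _, ev = evalue_from_score(s, m, db_res, params)
        if ev > params.evalue_cutoff:
            continue
        aln = smith_waterman(query.sequence, rec.residues, matrix,
                             params.gap_open, params.gap_extend,
                             params=params, db_residues=db_res)
        scored.append((rec, aln))
    return SpeciesHitList(species=species, hits=_select(scored, params))


def search_all_species(query: QueryEntry, db: ProteomeDatabase,
                       params: SearchParams,
                       matrix: SubstitutionMatrix) -> dict[str, SpeciesHitList]:
    """Run :func:`search_species` for every panel species, in panel order."""
    return {sp: search_species(query, db, sp, params, matrix)
            for sp in db.panel.species}


# ---------------------------------------------------------------------------
# External tabular-search adapter (12-column outfmt-6 dialect)
# ---------------------------------------------------------------------------

_TAB_COLS = 12


def external_search_adapter(stream: TextIO | str, db: ProteomeDatabase,
                            params: SearchParams) -> dict[str, SpeciesHitList]:
    """Build hit lists from 12-column tabular search output
    (qseqid sseqid pident length mismatch gapopen qstart qend sstart send
    evalue bitscore), applying the same selection rules as
    :func:`search_species`.  Species absent from the stream map to empty
    lists."""
    if isinstance(stream, str):
        lines = stream.splitlines()
    else:
        lines = stream.read().splitlines()
    by_acc: dict[str, tuple[str, SequenceRecord]] = {}
    for sp, recs in db:
        for r in recs:
            by_acc[r.id] = (sp, r)
    per_species: dict[str, list[tuple[SequenceRecord, PairwiseAlignment]]] = {
        sp: [] for sp in db.panel.species
    }
    for lineno, line in enumerate(lines, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != _TAB_COLS:
            raise ParseError(f"tabular search line {lineno}: expected {_TAB_COLS} columns, "
                             f"got {len(parts)}")
        try:
            sseqid = parts[1]
            pident = float(parts[2]) / 100.0
            qstart, qend, sstart, send = (int(parts[i]) for i in (6, 7, 8, 9))
            evalue = float(parts[10])
            bitscore = float(parts[11])
        except ValueError as exc:
            raise ParseError(f"tabular search line {lineno}: {exc}") from None
        if sseqid not in by_acc:
            raise ParseError(f"tabular search line {lineno}: accession {sseqid!r} "
                             "not present in the database")
        sp, rec = by_acc[sseqid]
        aln = PairwiseAlignment(
            raw_score=bitscore, bit_score=bitscore, e_value=evalue,
            query_aligned="", subject_aligned="",
            query_start=qstart, query_end=qend,
            subject_start=sstart, subject_end=send, identity=pident,
        )
        per_species[sp].append((rec, aln))
    return {sp: SpeciesHitList(species=sp, hits=_select(scored, params))
            for sp, scored in per_species.items()}
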