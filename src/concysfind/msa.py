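"""Query-anchored greedy progressive multiple alignment.

The query seeds a single-row profile; each homolog representative is
folded in by a global profile-to-sequence alignment, in order of
descending similarity to the query.  Gaps already in the profile are
never removed ("once a gap, always a gap").  Column scores are the mean
substitution score of the incoming residue against the column's
residues (gaps contribute 0); the DP is run on integer scores scaled by
the row count, so traceback comparisons are exact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .seqio import ConCysFindError, GAP, QueryEntry, SequenceRecord, SubstitutionMatrix


@dataclass
class MultipleAlignment:
    """Rows of (label, gapped string); row 0 is always the query."""

    rows: list[tuple[str, str]]
    query_row: int = 0

    def __post_init__(self) -> None:
        if not self.rows:
            raise ConCysFindError("alignment must have at least one row")
        length = len(self.rows[0][1])
        if any(len(r) != length for _, r in self.rows):
            raise ConCysFindError("alignment rows differ in length")

    @property
    def length(self) -> int:
        return len(self.rows[0][1])

    def ungapped(self, row: int) -> str:
        return self.rows[row][1].replace(GAP, "")


def _column_counts(profile: MultipleAlignment, matrix: SubstitutionMatrix) -> np.ndarray:
    """(length, alphabet) residue counts per column; gaps not counted."""
    counts = np.zeros((profile.length, len(matrix.alphabet)), dtype=np.int64)
    for _, gapped in profile.rows:
        for col, ch in enumerate(gapped):
            if ch != GAP:
                counts[col, matrix._index[ch]] += 1
    return counts


def needleman_wunsch_profile(profile: MultipleAlignment, seq: str,
                             matrix: SubstitutionMatrix,
                             gap_open: int = 11, gap_extend: int = 1,
                             label: str = "seq") -> MultipleAlignment:
    """Global (end-to-end, affine-gap) alignment of ``seq`` against the
    profile; returns a new alignment with ``seq`` appended as the last
    row.  Terminal gaps are penalized like internal ones.  Traceback
    ties resolve diagonal > up (consume profile column) > left (insert a
    gap column).  Previously introduced profile gaps are preserved.
    """
    if not seq:
        raise ConCysFindError("cannot align an empty sequence")
    nrows = len(profile.rows)
    counts = _column_counts(profile, matrix)
    si = matrix.encode(seq)
    # integer scores scaled by nrows: sub[i, j] = sum_rows score(col_i, seq_j)
    sub = counts @ matrix.scores[:, si]
    Lp, Ls = profile.length, len(seq)
    opn, ext = gap_open * nrows, gap_extend * nrows
    NEG = -1 << 40
    H = np.full((Lp + 1, Ls + 1), NEG, dtype=np.int64)
    E = np.full((Lp + 1, Ls + 1), NEG, dtype=np.int64)  # gap column inserted (left)
    F = np.full((Lp + 1, Ls + 1), NEG, dtype=np.int64)  # gap in new row (up)
    H[0, 0] = 0
    for j in range(1, Ls + 1):
        E[0, j] = -(opn + (j - 1) * ext)
        H[0, j] = E[0, j]
    for i in range(1, Lp + 1):
        F[i, 0] = -(opn + (i - 1) * ext)
        H[i, 0] = F[i, 0]
        Hi, Hi1, Ei, Fi, Fi1 = H[i], H[i - 1], E[i], F[i], F[i - 1]
        row = sub[i - 1]
        for j in range(1, Ls + 1):
            e = max(Hi[j - 1] - opn, Ei[j - 1] - ext)
            f = max(Hi1[j] - opn, Fi1[j] - ext)
            Ei[j] = e
            Fi[j] = f
            h = Hi1[j - 1] + row[j - 1]
            if f > h:
                h = f
            if e > h:
                h = e
            Hi[j] = h
    # traceback from (Lp, Ls)
    i, j = Lp, Ls
    state = "H"
    ops: list[str] = []  # 'D' diagonal, 'U' consume column, 'L' insert gap column
    while i > 0 or j > 0:
        if state == "H":
            if i > 0 and j > 0 and H[i, j] == H[i - 1, j - 1] + sub[i - 1, j - 1]:
                ops.append("D")
                i -= 1
                j -= 1
            elif i > 0 and H[i, j] == F[i, j]:
                state = "F"
            else:
                state = "E"
        elif state == "F":
            ops.append("U")
            opened = F[i, j] == H[i - 1, j] - opn
            i -= 1
            if opened or i == 0:
                state = "H"
        else:
            ops.append("L")
            opened = E[i, j] == H[i, j - 1] - opn
            j -= 1
            if opened or j == 0:
                state = "H"
    ops.reverse()
    new_old = []  # per output column: profile column index or None (gap column)
    new_row = []
    pi = sj = 0
    for op in ops:
        if op == "D":
            new_old.append(pi)
            new_row.append(seq[sj])
            pi += 1
            sj += 1
        elif op == "U":
            new_old.append(pi)
            new_row.append(GAP)
            pi += 1
        else:
            new_old.append(None)
            new_row.append(seq[sj])
            sj += 1
    rows = []
    for lab, gapped in profile.rows:
        rows.append((lab, "".join(GAP if c is None else gapped[c] for c in new_old)))
    rows.append((label, "".join(new_row)))
    return MultipleAlignment(rows=rows, query_row=profile.query_row)


def greedy_msa(query: QueryEntry,
               representatives: list[tuple[str, SequenceRecord, float]],
               matrix: SubstitutionMatrix,
               gap_open: int = 11, gap_extend: int = 1) -> MultipleAlignment:
    """Progressive alignment of the query plus one representative per
    species, inserted in descending order of raw score to the query
    (ties keep the supplied — panel — order; the sort is stable).

    An empty representative list yields a single-row (query-only)
    alignment.
    """
    msa = MultipleAlignment(rows=[(f"query|{query.id}", query.sequence)])
    ordered = sorted(representatives, key=lambda t: -t[2])
    for species, rec, _score in ordered:
        msa = needleman_wunsch_profile(msa, rec.residues, matrix,
                                       gap_open, gap_extend,
                                       label=f"{species}|{rec.id}")
    return msa


def pairwise_global(a: str, b: str, matrix: SubstitutionMatrix,
                    gap_open: int = 11, gap_extend: int = 1) -> tuple[str, str]:
    """Global pairwise alignment (affine gaps); returns the two gapped rows."""
    msa = needleman_wunsch_profile(
        MultipleAlignment(rows=[("a", a)]), b, matrix, gap_open, gap_extend, label="b")
    return msa.rows[0][1], msa.rows[1][1]


def map_query_position(msa: MultipleAlignment, pos: int) -> int:
    """Column (1-based) holding the ``pos``-th residue of the query row."""
    gapped = msa.rows[msa.query_row][1]
    if pos < 1:
        raise ConCysFindError(f"query position {pos} out of range")
    count = 0
    for col, ch in enumerate(gapped, start=1):
        if ch != GAP:
            count += 1
            if count == pos:
                return col
    raise ConCysFindError(f"query position {pos} out of range (query has {count} residues)")


def identity_to_query(msa: MultipleAlignment, row: int) -> float:
    """Fraction of query-residue columns where ``row`` carries the
    identical residue (gaps and mismatches count against)."""
    if row == msa.query_row:
        raise ConCysFindError("identity_to_query requires a non-query row")
    q = msa.rows[msa.query_row][1]
    r = msa.rows[row][1]
    denom = matches = 0
    for a, b in zip(q, r):
        if a != GAP:
            denom += 1
            if a == b:
                matches += 1
    return matches / denom if denom else 0.0
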