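"""Conservation scoring of target residues across a species panel.

For each occurrence of the target amino acid in the query, each species'
candidate homologs are tried best-first (up to the kept 9): a candidate
"detects" the residue if a global pairwise alignment to the query places
the target amino acid opposite the query position.  The first detecting
candidate becomes the species' representative — this iteration guards
against paralogs that lost the residue after gene duplication.  If no
candidate detects it, the best-scoring candidate represents the species
and the species counts as non-conserving.

The conservation score is k/n: conserving species over species with an
accepted homolog.  Significance is the upper tail of a Poisson-binomial
distribution — under the null, species s shows the target residue at the
position with probability q_s = 1 - (its overall identity to the query),
so observing k or more matches by chance has probability P(X >= k) with
X a sum of independent Bernoulli(q_s).  A residue is called putatively
conserved when p <= alpha (default 0.01).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .homolog_search import SearchParams, SpeciesHitList
from .msa import (GAP, MultipleAlignment, greedy_msa, identity_to_query,
                  map_query_position, pairwise_global)
from .seqio import ConCysFindError, QueryEntry, SequenceRecord, SubstitutionMatrix

#: Clamp bounds for per-species null probabilities.
Q_MIN = 1e-6
Q_MAX = 1.0 - 1e-6


@dataclass
class ResidueAlignmentSet:
    """Chosen representatives and their multiple alignment for one
    target-residue position."""

    position: int  # 1-based query index
    target_aa: str
    representatives: dict[str, SequenceRecord]  # species -> chosen record
    msa: MultipleAlignment
    column: int  # 1-based alignment column of `position`


@dataclass
class ResidueConservationResult:
    position: int
    target_aa: str
    presence: dict[str, bool]
    k: int
    n: int
    score: float
    p_value: float
    conserved: bool
    chance_probs: dict[str, float] = field(default_factory=dict)


@dataclass
class ProteinReport:
    query: QueryEntry
    n_homolog_species: int
    residues: list[ResidueConservationResult]

    @property
    def conserved_count(self) -> int:
        return sum(1 for r in self.residues if r.conserved)

    @property
    def total_count(self) -> int:
        return len(self.residues)


# ---------------------------------------------------------------------------
# Target positions
# ---------------------------------------------------------------------------


def find_target_positions(seq: str, target_aa: str | set[str]) -> list[int]:
    """Ascending 1-based positions of every target-letter occurrence."""
    targets = {target_aa} if isinstance(target_aa, str) and len(target_aa) == 1 \
        else set(target_aa)
    return [i for i, ch in enumerate(seq, start=1) if ch in targets]


# ---------------------------------------------------------------------------
# Representative selection (the up-to-9 iteration) and MSA assembly
# ---------------------------------------------------------------------------


def _detects(query: str, position: int, candidate: str, target_aa: str,
             matrix: SubstitutionMatrix, gap_open: int, gap_extend: int,
             aln_cache: dict | None = None) -> bool:
    """True if a global alignment of candidate to query puts target_aa
    opposite the query position."""
    key = (query, candidate)
    if aln_cache is not None and key in aln_cache:
        q_row, c_row = aln_cache[key]
    else:
        q_row, c_row = pairwise_global(query, candidate, matrix, gap_open, gap_extend)
        if aln_cache is not None:
            aln_cache[key] = (q_row, c_row)
    count = 0
    for qc, cc in zip(q_row, c_row):
        if qc != GAP:
            count += 1
            if count == position:
                return cc == target_aa
    return False


def assess_position(query: QueryEntry, position: int,
                    hits: dict[str, SpeciesHitList],
                    params: SearchParams, matrix: SubstitutionMatrix,
                    target_aa: str = "C",
                    aln_cache: dict | None = None,
                    msa_cache: dict | None = None) -> ResidueAlignmentSet:
    """Pick one representative per species for a target-residue position
    and build the multiple alignment over them.

    Candidates are tried best-first; the first one whose pairwise
    alignment carries the target residue opposite the query position is
    chosen.  If none does, the best-scoring candidate stands in (the
    species will count as non-conserving).  Species with empty hit lists
    are excluded from the analysis entirely.
    """
    if query.sequence[position - 1] != target_aa:
        raise ConCysFindError(
            f"query {query.id!r} position {position} is "
            f"{query.sequence[position - 1]!r}, not {target_aa!r}")
    reps: dict[str, SequenceRecord] = {}
    rep_scores: dict[str, float] = {}
    for species, hit_list in hits.items():
        if not hit_list:
            continue
        chosen = None
        for rec, aln in hit_list.hits:
            if _detects(query.sequence, position, rec.residues, target_aa,
                        matrix, params.gap_open, params.gap_extend, aln_cache):
                chosen = (rec, aln)
                break
        if chosen is None:
            chosen = hit_list.hits[0]
        reps[species] = chosen[0]
        rep_scores[species] = chosen[1].raw_score
    key = tuple((sp, reps[sp].id) for sp in reps)
    if msa_cache is not None and key in msa_cache:
        msa = msa_cache[key]
    else:
        msa = greedy_msa(query,
                         [(sp, reps[sp], rep_scores[sp]) for sp in reps],
                         matrix, params.gap_open, params.gap_extend)
        if msa_cache is not None:
            msa_cache[key] = msa
    column = map_query_position(msa, position)
    return ResidueAlignmentSet(position=position, target_aa=target_aa,
                               representatives=reps, msa=msa, column=column)


def presence_flags(ras: ResidueAlignmentSet) -> dict[str, bool]:
    """Per species: does its representative row carry the target residue
    exactly at the query's alignment column?  The final multiple
    alignment is authoritative, overriding the pairwise detection used
    during candidate selection."""
    flags: dict[str, bool] = {}
    row_by_label = {label: gapped for label, gapped in ras.msa.rows}
    for species, rec in ras.representatives.items():
        gapped = row_by_label[f"{species}|{rec.id}"]
        flags[species] = gapped[ras.column - 1] == ras.target_aa
    return flags


# ---------------------------------------------------------------------------
# Score and significance
# ---------------------------------------------------------------------------


def conservation_score(k: int, n: int) -> float:
    """k/n at full precision; the output layer rounds to 2 decimals."""
    if n == 0:
        raise ConCysFindError("conservation score undefined: no homolog species")
    if not (0 <= k <= n):
        raise ConCysFindError(f"invalid counts k={k}, n={n}")
    return k / n


def chance_probabilities(ras: ResidueAlignmentSet) -> dict[str, float]:
    """Per-species null probability q_s = 1 - identity_to_query, clamped
    away from 0 and 1."""
    probs: dict[str, float] = {}
    row_index = {label: i for i, (label, _) in enumerate(ras.msa.rows)}
    for species, rec in ras.representatives.items():
        row = row_index[f"{species}|{rec.id}"]
        ident = identity_to_query(ras.msa, row)
        probs[species] = min(max(1.0 - ident, Q_MIN), Q_MAX)
    return probs


def poisson_binomial_pmf(probs: list[float]) -> np.ndarray:
    """Exact pmf of a sum of independent Bernoulli(p_i), by O(n^2)
    dynamic-programming convolution."""
    pmf = np.array([1.0])
    for p in probs:
        nxt = np.zeros(len(pmf) + 1)
        nxt[:-1] += pmf * (1.0 - p)
        nxt[1:] += pmf * p
        pmf = nxt
    return pmf


def p_value(k: int, chance_probs: list[float]) -> float:
    """Upper-tail Poisson-binomial probability P(X >= k)."""
    n = len(chance_probs)
    if not (0 <= k <= n):
        raise ConCysFindError(f"invalid k={k} for n={n}")
    if k == 0:
        return 1.0
    pmf = poisson_binomial_pmf(chance_probs)
    tail = float(pmf[k:].sum())
    return min(max(tail, 5e-324), 1.0)


def classify_conserved(p: float, alpha: float = 0.01) -> bool:
    """Putatively conserved iff p <= alpha (boundary inclusive)."""
    return p <= alpha


def analyze_residue(ras: ResidueAlignmentSet, alpha: float = 0.01) -> ResidueConservationResult:
    """Presence flags -> (k, n) -> score, Poisson-binomial p, verdict."""
    flags = presence_flags(ras)
    n = len(flags)
    k = sum(flags.values())
    probs = chance_probabilities(ras)
    if n == 0:
        return ResidueConservationResult(
            position=ras.position, target_aa=ras.target_aa, presence={},
            k=0, n=0, score=float("nan"), p_value=1.0, conserved=False)
    p = p_value(k, [probs[sp] for sp in flags])
    return ResidueConservationResult(
        position=ras.position, target_aa=ras.target_aa, presence=flags,
        k=k, n=n, score=conservation_score(k, n), p_value=p,
        conserved=classify_conserved(p, alpha), chance_probs=probs)


def summarize_protein(query: QueryEntry, hits: dict[str, SpeciesHitList],
                      residues: list[ResidueConservationResult]) -> ProteinReport:
    """Per-protein roll-up; the homolog count is the number of species
    with at least one accepted hit (residue-independent)."""
    n_homolog_species = sum(1 for hl in hits.values() if hl)
    return ProteinReport(query=query, n_homolog_species=n_homolog_species,
                         residues=residues)
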