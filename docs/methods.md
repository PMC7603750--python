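# Methods

## Problem and overall procedure

`concysfind` asks, for every occurrence of a target amino acid (cysteine
by default) in a query protein, whether that residue is evolutionarily
conserved across a panel of species — the working hypothesis being that
residues held fixed across large evolutionary distances are candidates
for functional post-translational modification (for cysteine: disulfide
formation, S-nitrosylation, glutathionylation and other redox states).

The pipeline runs in five stages per query:

1. **Homolog search.** The query is aligned locally against every
   sequence of every panel species (exact Smith–Waterman, affine gaps,
   BLOSUM62). Per species, hits above the e-value cutoff are discarded,
   survivors scoring below 0.8 × the species' best raw score are
   discarded, and at most 9 candidates are kept, best-first.
2. **Candidate iteration.** For each target-residue position, each
   species' candidates are tried best-first: a candidate *detects* the
   residue if a global pairwise alignment to the query places the target
   amino acid opposite the query position. The first detecting candidate
   becomes the species' representative; if none detects, the best-scoring
   candidate stands in and the species will count as non-conserving.
   This iteration exists because the top hit may be a paralog that lost
   the residue after gene duplication while a slightly lower-scoring
   ortholog retains it.
3. **Multiple alignment.** The query seeds a single-row profile; each
   representative is folded in by a global profile-to-sequence alignment
   in order of descending similarity to the query ("once a gap, always a
   gap"). Presence is then re-read from the final alignment column of
   the query position — the multiple alignment is authoritative.
4. **Score and significance.** With n = species that have an accepted
   homolog and k = species whose representative carries the identical
   target residue at the column, the conservation score is k/n. The
   p-value is the upper tail P(X ≥ k) of a Poisson-binomial variable,
   X = Σ Bernoulli(q_s), with per-species null probability
   q_s = 1 − (overall identity of the representative to the query),
   clamped to [1e-6, 1−1e-6]. A residue is *putatively conserved* when
   p ≤ α (default 0.01, boundary inclusive).
5. **Trees.** Per residue, a neighbour-joining tree is built from
   uncorrected p-distances between all alignment rows; leaves are
   annotated `species|accession|C126+` / `…-` and written as Newick.

## Model choices and their rationale

**Search engine.** The homolog search is an in-package exact
Smith–Waterman (affine gaps: a gap of length L costs open + (L−1)·ext;
defaults 11/1) rather than a heuristic seeded search: panel proteomes at
desk scale are small enough that exactness is affordable, and the
selection rule — not the engine — is what the downstream statistic
depends on. A vectorised score-only pass filters the database; the full
traceback runs only for surviving hits, and both paths are cross-checked
against each other and against brute-force recursion in the tests. For
genome-scale databases, 12-column tabular output of any standard protein
search tool can be substituted via `--hits-from`; the same selection
rules are applied to it.

**E-values.** The Karlin–Altschul closed form E = K·m·n·e^(−λS) with the
standard published gapped-BLOSUM62 constants λ = 0.267, K = 0.041
(configurable). Default cutoff 1e-5; at desk scale this admits clear
homologs and rejects the score-0 noise floor by many orders of
magnitude.

**The 0.8 rule.** The relative reading — keep hits scoring at least 80 %
of the species' best hit — is used, because the rule's purpose is to
delimit the *within-species* candidate set the iteration walks through.

**Greedy progressive alignment.** Insertion order is descending raw
score to the query (ties keep panel order; the sort is stable). Column
scores are the mean substitution score of the incoming residue against
the column's residues, gaps contributing 0; the DP runs on integer
scores scaled by the row count so traceback tie comparisons
(diagonal > up > left) are exact, with no floating-point ambiguity. At
two sequences this reduces exactly to optimal global pairwise alignment,
which the tests verify against an independent recursion oracle.
Terminal gaps are penalized like internal ones: representatives were
pre-filtered for high similarity, so end-to-end alignment is the honest
model.

**Significance model.** Only the two ingredients of the p-value are
fixed by the tool's stated design — the per-position occurrence pattern
and the overall conservation of each homolog. The Poisson-binomial tail
with q_s = 1 − identity is the simplest model consistent with both, and
it reproduces the qualitative signatures of published output: residues
of one protein with equal k share an identical p-value, p is
non-increasing in k, and a fully conserved residue in a family of ~80 %
identity lands around (0.2)^n. Exact reproduction of any particular
published p-value digit-for-digit is **not** claimed; the classification
boundary (α = 0.01) and the score arithmetic are reproduced exactly.
No multiple-testing correction is applied across residues or proteins.

**Presence is identity.** Only the identical letter at the aligned
column counts; conservative substitutions (serine for cysteine) count
as absent, because the question is chemical identity of a modifiable
side chain, not structural equivalence.

**Trees.** Distances are p-distances over mutually ungapped column
pairs; a pair of rows with no shared residue columns is a hard error.
Neighbour joining is the classic Q-criterion algorithm with the
Studier–Keppler update; the joined pair is deterministic (smallest Q,
ties by lexicographically smallest min-leaf-label pair), negative branch
estimates are clamped to 0 with a warning, and the final two subtrees
share the last edge evenly. On additive matrices the output reproduces
every pairwise distance to 1e-9 (tested on random 4–8 leaf trees).
Trees are per-residue because the representative set can differ between
residues of one protein when the candidate iteration picks different
paralogs.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `gap_open` / `gap_extend` | 11 / 1 | affine gap cost (matrix units), shared by search and alignment |
| `evalue_cutoff` | 1e-5 | per-hit admission threshold |
| `max_hits` | 9 | candidates kept per species |
| `rel_score_cutoff` | 0.8 | fraction of the species' best raw score a candidate must reach |
| `lambda_gapped`, `k_gapped` | 0.267, 0.041 | Karlin–Altschul statistics for gapped BLOSUM62 |
| `alpha` | 0.01 | significance threshold for "putatively conserved" |
| `target_aa` | `C` | target letter(s); any subset of the 20 amino acids |

Scores print with exactly two decimals, round-half-up (so 16/18 prints
0.89, not 0.88); p-values print with three significant digits. The
pipeline itself contains no randomness: identical inputs give
byte-identical outputs.

## The synthetic-family generator

`concysfind.fixtures` emulates a species panel with exact ground truth:
a random query (uniform over the 20 amino acids, seeded), one ortholog
per species produced by i.i.d. per-site substitution at that species'
divergence rate (default 0.2, a typical mid-range protein-family
distance), chosen positions pinned to the target residue, chosen
species' copies knocked out to a non-target residue, and optional decoy
paralogs at a scaled divergence (default 2×; a scale below 1 creates
decoys that outrank the true ortholog — the hard case the candidate
iteration exists for). An optional deletion rate exercises gap handling.

What it deliberately does **not** model: tree-structured evolution,
rate heterogeneity across sites, insertions, compositional bias, and
domain-level rearrangement. Passing the recovery tests therefore shows
that the pipeline's bookkeeping (selection, iteration, column mapping,
counting) is exact under controlled substitution noise — not that the
statistic is well calibrated on real proteomes with correlated
evolution.

Problem sizes used by the test suite and the acceptance script — panels
of 5–21 species, sequences of 120–150 residues, 10–20 seeded replicates
per condition — are the package's chosen desk-scale study conditions;
they complete in well under a minute per condition.

## Numerical notes and degenerate inputs

- All alignment DPs are integer-valued; there are no floating-point
  traceback ties anywhere.
- The Poisson-binomial tail is an O(n²) exact convolution; the result is
  floored at the smallest positive double so downstream logs never see 0.
- Null probabilities are clamped to [1e-6, 1−1e-6] so a representative
  identical to the query still yields a finite, non-zero p-value.
- A species with an empty hit list is excluded from n entirely; a query
  whose every species comes up empty gets its residues reported with an
  explicit error marker and the run continues.
- `X` is accepted in input and scored by the bundled matrix's X row;
  `*` is tolerated only as a terminal stop and stripped.

## Known limitations

- Under decoy-stress conditions the true ortholog occasionally falls
  below the 0.8 relative-score band by chance; the species then counts
  as non-conserving even though its proteome contains the residue. This
  is inherent to a relative cutoff, not a defect of the iteration, and
  shows up as a recovery rate slightly below 1 in stressed replicates.
- The greedy progressive alignment is exact only at two sequences; with
  more rows it is a heuristic (as intended) and can be suboptimal in
  low-identity corners the homolog filter is designed to exclude.
- p-values are model-based significance statements, not calibrated
  error rates on real data, and are reported without multiple-testing
  correction.
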