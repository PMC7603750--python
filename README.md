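# concysfind

Find evolutionarily conserved target residues — cysteines by default —
in query proteins across a panel of species proteomes.

Reversible cysteine modifications (disulfide formation,
S-nitrosylation, S-glutathionylation, sulfenic-acid states) regulate
protein function, and functionally modified cysteines tend to be held
fixed across large evolutionary distances. `concysfind` turns that
observation into a screen: given query proteins and one proteome FASTA
per species, it finds each species' closest homologs, iterates through
up to 9 candidates per species to avoid being fooled by paralogs that
lost the residue, builds a query-anchored progressive multiple
alignment, and reports for every target-residue occurrence

- a **conservation score** k/n — species carrying the identical residue
  at the aligned column, over species with an accepted homolog;
- a **p-value** — the upper tail P(X ≥ k) of a Poisson-binomial
  variable with per-species null probability
  q_s = 1 − identity(homolog_s, query), i.e. the chance of seeing k or
  more matches at a neutrally evolving position;
- a **verdict** — putatively conserved iff p ≤ α (default 0.01);
- a **neighbour-joining tree** per residue (p-distance,
  Newick-serialized) with presence-annotated leaves such as
  `sp03|sp03_orth|C75-`.

The homolog search is an exact Smith–Waterman with affine gaps and
BLOSUM62; per species, hits are filtered by e-value (Karlin–Altschul,
default cutoff 1e-5) and by a relative score band (keep hits ≥ 0.8 ×
the species' best), and at most 9 candidates are kept. Tabular output
of an external search tool can be substituted for the built-in aligner
(`--hits-from`). See `docs/methods.md` for the full model description
and its assumptions.

## Worked example

The package ships a synthetic-family generator with exact ground truth,
so the whole pipeline can be exercised without downloading proteomes:

```python
from concysfind import FamilySpec, generate_family, write_family

spec = FamilySpec(seed=42, n_species=8, seq_length=120, divergence=0.2,
                  conserved_positions=(30, 75),
                  loss_map={"sp03": (75,), "sp06": (75,)})
db, query, truth = generate_family(spec)
write_family(db, query, "demo_family")
```

This builds 8 species proteomes in which position 30 of the query is a
cysteine held in all 8 species and position 75 is a cysteine knocked
out in sp03 and sp06 (truth: 8/8 and 6/8). Then:

```sh
concysfind run --query demo_family/query.fasta \
               --panel demo_family/panel.tsv --out demo_out
```

prints

```
queries: 1
residues analyzed: 10
residues conserved: 9
species misses: 0
output: demo_out
```

and `demo_out/results.tsv` contains (excerpt):

```
name             id      homologs  putatively_conserved  target_aa  position  score  p_value  conserved
synthetic query  query1  8         9 of 10
synthetic query  query1                                  C          30        1.00   2.94e-6  yes
synthetic query  query1                                  C          75        0.75   1.42e-3  yes
synthetic query  query1                                  C          10        0.38   2.21e-1  no
```

Position 30 scores 1.00 (present in all 8 species; p = 2.9e-6 — seeing
8/8 by chance at ~80 % family identity is essentially impossible) and
position 75 scores 0.75 = 6/8, exactly the engineered truth. Position
10 is one of the query's incidental cysteines: only 3 of 8 species
happen to share it, p = 0.22, not conserved. The per-residue tree
`demo_out/trees/query1_C75.nwk` marks exactly sp03 and sp06 with
`C75-`:

```
(sp08|sp08_orth|C75+:0.0706,(sp05|sp05_orth|C75+:0.1337,(query|query1|C75+:0.0155,
((sp04|sp04_orth|C75+:0.1274,sp06|sp06_orth|C75-:0.2226):0.0268,...
```

Real proteomes are used the same way: one FASTA per species, listed in
a `panel.tsv` (`species<TAB>path` per line), queries as FASTA with an
optional two-column TSV (`id<TAB>description`) to select and label
them.

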