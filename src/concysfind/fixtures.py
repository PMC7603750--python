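"""Synthetic protein families with known conservation ground truth.

The generator emulates a species panel: each species carries one
ortholog of a random query protein, diverged by i.i.d. per-site
substitutions at a per-species rate, with chosen positions held fixed
at a target amino acid (conserved) and optionally knocked out in chosen
species (lost).  Decoy paralogs — duplicates at a scaled divergence,
with or without the target residue — stress the candidate-iteration
logic.  No tree-structured evolution and no rate heterogeneity: the
goal is controlled truth, not realism.  All randomness is confined to
this module; the pipeline itself is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .proteome_db import ProteomeDatabase, SpeciesPanel, database_from_records
from .seqio import ConCysFindError, QueryEntry, SequenceRecord, write_fasta

#: Residues the generator draws from (the 20 standard amino acids).
AA20 = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class ParalogSpec:
    """Decoy duplicates per species: how many, whether they carry the
    target residue at conserved positions, and their divergence relative
    to the ortholog (2.0 = classic distant paralog; values < 1 create
    decoys that outrank the ortholog, the hard case the candidate
    iteration exists for)."""

    count: int = 0
    carry_target: bool = False
    divergence_scale: float = 2.0


@dataclass(frozen=True)
class FamilySpec:
    seed: int
    n_species: int
    seq_length: int
    divergence: float | dict[str, float] = 0.2
    conserved_positions: tuple[int, ...] = ()
    loss_map: dict[str, tuple[int, ...]] = field(default_factory=dict)
    paralogs: ParalogSpec = ParalogSpec()
    target_aa: str = "C"
    indel_rate: float = 0.0

    def species_labels(self) -> list[str]:
        return [f"sp{i + 1:02d}" for i in range(self.n_species)]

    def divergence_of(self, species: str) -> float:
        if isinstance(self.divergence, dict):
            return self.divergence[species]
        return float(self.divergence)


@dataclass
class FamilyTruth:
    """Per conserved position: expected k, n and the presence map."""

    per_position: dict[int, tuple[int, int, dict[str, bool]]]

    def expected(self, position: int) -> tuple[int, int]:
        if position not in self.per_position:
            raise ConCysFindError(f"position {position} not in truth table")
        k, n, _ = self.per_position[position]
        return k, n


def expected_score(truth: FamilyTruth, position: int) -> float:
    k, n = truth.expected(position)
    return k / n


def _substitute(rng: np.random.Generator, seq: list[str], rate: float,
                frozen: set[int]) -> list[str]:
    """i.i.d. substitution at ``rate`` per site, uniform over the 19
    non-identical residues; 0-based ``frozen`` sites untouched."""
    out = list(seq)
    mask = rng.random(len(seq)) < rate
    for i in np.nonzero(mask)[0]:
        if int(i) in frozen:
            continue
        choices = [c for c in AA20 if c != out[i]]
        out[i] = choices[rng.integers(len(choices))]
    return out


def generate_family(spec: FamilySpec) -> tuple[ProteomeDatabase, QueryEntry, FamilyTruth]:
    """Build a seeded synthetic family: a query, one ortholog per
    species (plus optional decoy paralogs), and the truth table.

    Conserved positions hold the target residue in every species unless
    listed in the species' loss map, where it is substituted to a
    non-target residue.  Deterministic given the seed.
    """
    for sp, positions in spec.loss_map.items():
        bad = set(positions) - set(spec.conserved_positions)
        if bad:
            raise ConCysFindError(
                f"loss positions {sorted(bad)} for {sp!r} are not conserved positions")
    if any(p < 1 or p > spec.seq_length for p in spec.conserved_positions):
        raise ConCysFindError("conserved positions outside sequence length")
    rng = np.random.default_rng(spec.seed)
    query = [AA20[i] for i in rng.integers(len(AA20), size=spec.seq_length)]
    conserved0 = {p - 1 for p in spec.conserved_positions}
    for i in conserved0:
        query[i] = spec.target_aa
    species = spec.species_labels()
    non_target = [c for c in AA20 if c != spec.target_aa]
    records: dict[str, list[SequenceRecord]] = {}
    presence: dict[int, dict[str, bool]] = {p: {} for p in spec.conserved_positions}
    for sp in species:
        rate = spec.divergence_of(sp)
        lost = set(spec.loss_map.get(sp, ()))
        orth = _substitute(rng, query, rate, conserved0)
        for p in spec.conserved_positions:
            if p in lost:
                orth[p - 1] = non_target[rng.integers(len(non_target))]
            presence[p][sp] = p not in lost
        if spec.indel_rate > 0:
            keep = rng.random(len(orth)) >= spec.indel_rate
            orth = [c for i, c in enumerate(orth) if keep[i] or i in conserved0]
        recs = [SequenceRecord(id=f"{sp}_orth", description="ortholog",
                               species=sp, residues="".join(orth))]
        for t in range(spec.paralogs.count):
            para = _substitute(rng, query, rate * spec.paralogs.divergence_scale,
                               conserved0)
            for p in spec.conserved_positions:
                if not spec.paralogs.carry_target:
                    para[p - 1] = non_target[rng.integers(len(non_target))]
            recs.append(SequenceRecord(id=f"{sp}_para{t + 1}", description="paralog",
                                       species=sp, residues="".join(para)))
        records[sp] = recs
    panel = SpeciesPanel(species=tuple(species),
                         source_files={sp: f"{sp}.fasta" for sp in species})
    db = database_from_records(panel, records)
    truth = FamilyTruth(per_position={
        p: (sum(presence[p].values()), spec.n_species, presence[p])
        for p in spec.conserved_positions
    })
    qentry = QueryEntry(id="query1", description="synthetic query",
                        sequence="".join(query))
    return db, qentry, truth


def write_family(db: ProteomeDatabase, query: QueryEntry,
                 out_dir: str | Path) -> tuple[Path, Path]:
    """Materialize a generated family as FASTA files plus a panel config
    so fixtures can be driven through the command-line interface.
    Returns (panel config path, query FASTA path)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    panel_path = out / "panel.tsv"
    with open(panel_path, "w") as fh:
        for sp in db.panel.species:
            fasta = out / f"{sp}.fasta"
            with open(fasta, "w") as sf:
                write_fasta(db.records[sp], sf)
            fh.write(f"{sp}\t{fasta.name}\n")
    query_path = out / "query.fasta"
    with open(query_path, "w") as fh:
        fh.write(f">{query.id} {query.description}\n{query.sequence}\n")
    return panel_path, query_path
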