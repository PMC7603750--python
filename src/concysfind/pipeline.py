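"""End-to-end orchestration: queries -> per-species search -> per-residue
assessment -> score / p-value / classification -> per-residue trees.

Outputs, under the configured directory: ``results.tsv`` (scores and
p-values), ``alignments.txt`` (one block per analyzed residue),
``trees/<queryid>_<AA><position>.nwk`` and ``run.log``.  The pipeline
contains no randomness: identical inputs produce identical bytes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import conservation as cons
from .homolog_search import SearchParams, external_search_adapter, search_all_species
from .msa import MultipleAlignment
from .phylo import annotate_and_serialize, neighbor_joining, p_distance_matrix
from .proteome_db import build_database, parse_panel_config
from .seqio import (ConCysFindError, QueryEntry, load_substitution_matrix,
                    parse_fasta, parse_query_table, write_alignment_dump,
                    write_results_table)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything one run needs; flags override config files override
    these defaults."""

    query_fastas: list[str] = field(default_factory=list)
    query_table: str | None = None
    panel_path: str = ""
    target_aa: str = "C"  # one or more target letters, e.g. "CWSTYM"
    params: SearchParams = field(default_factory=SearchParams)
    alpha: float = 0.01
    out_dir: str = "concysfind_out"
    matrix_name: str = "BLOSUM62"
    hits_from: str | None = None  # optional tabular search output
    log_level: str = "INFO"


def load_queries(config: RunConfig) -> list[QueryEntry]:
    sequences: dict[str, str] = {}
    order: list[str] = []
    descriptions: dict[str, str] = {}
    for path in config.query_fastas:
        with open(path) as fh:
            for rec in parse_fasta(fh, species="query"):
                if rec.id in sequences:
                    raise ConCysFindError(f"duplicate query id {rec.id!r}")
                sequences[rec.id] = rec.residues
                descriptions[rec.id] = rec.description
                order.append(rec.id)
    if config.query_table:
        with open(config.query_table) as fh:
            return parse_query_table(fh, sequences)
    return [QueryEntry(id=q, description=descriptions[q], sequence=sequences[q])
            for q in order]


def run_pipeline(config: RunConfig) -> dict:
    """Run the whole pipeline; returns a summary of counts."""
    out = Path(config.out_dir)
    trees_dir = out / "trees"
    trees_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    pkg_logger = logging.getLogger("concysfind")
    pkg_logger.addHandler(handler)
    pkg_logger.setLevel(config.log_level)
    try:
        return _run(config, out, trees_dir)
    finally:
        pkg_logger.removeHandler(handler)
        handler.close()


def _run(config: RunConfig, out: Path, trees_dir: Path) -> dict:
    matrix = load_substitution_matrix(config.matrix_name)
    with open(config.panel_path) as fh:
        panel = parse_panel_config(fh, base_dir=Path(config.panel_path).parent)
    db = build_database(panel)
    queries = load_queries(config)
    if not queries:
        raise ConCysFindError("no queries supplied")
    targets = set(config.target_aa)

    precomputed_hits = None
    if config.hits_from:
        with open(config.hits_from) as fh:
            precomputed_hits = external_search_adapter(fh, db, config.params)

    reports = []
    blocks = []
    residues_analyzed = residues_conserved = species_misses = 0
    for query in queries:
        logger.info("query %s: searching %d species", query.id, len(panel.species))
        hits = precomputed_hits if precomputed_hits is not None else \
            search_all_species(query, db, config.params, matrix)
        misses = [sp for sp, hl in hits.items() if not hl]
        species_misses += len(misses)
        if misses:
            logger.info("query %s: no homolog in %s", query.id, ", ".join(misses))
        aln_cache: dict = {}
        msa_cache: dict = {}
        results = []
        for aa in sorted(targets):
            for pos in cons.find_target_positions(query.sequence, aa):
                ras = cons.assess_position(query, pos, hits, config.params, matrix,
                                           target_aa=aa, aln_cache=aln_cache,
                                           msa_cache=msa_cache)
                res = cons.analyze_residue(ras, alpha=config.alpha)
                results.append(res)
                residues_analyzed += 1
                if res.conserved:
                    residues_conserved += 1
                blocks.append((f"{query.id} {aa}{pos}", ras.msa.rows))
                if res.n >= 1:
                    tree = neighbor_joining(p_distance_matrix(ras.msa))
                    newick = annotate_and_serialize(tree, res.presence, pos, aa)
                    (trees_dir / f"{query.id}_{aa}{pos}.nwk").write_text(newick + "\n")
                else:
                    logger.warning("query %s %s%d: no homolog species, no tree",
                                   query.id, aa, pos)
        reports.append(cons.summarize_protein(query, hits, results))
    with open(out / "results.tsv", "w") as fh:
        write_results_table(reports, fh)
    with open(out / "alignments.txt", "w") as fh:
        write_alignment_dump(blocks, fh)
    summary = {
        "queries": len(queries),
        "residues_analyzed": residues_analyzed,
        "residues_conserved": residues_conserved,
        "species_misses": species_misses,
        "reports": reports,
    }
    logger.info("done: %d queries, %d residues analyzed, %d conserved, %d species misses",
                len(queries), residues_analyzed, residues_conserved, species_misses)
    return summary
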