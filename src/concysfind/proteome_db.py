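"""Per-species proteome collections and the species panel definition.

A panel is an ordered list of species labels, each backed by one FASTA
file; panel order fixes every downstream output ordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, TextIO

from .seqio import ConCysFindError, ParseError, SequenceRecord, parse_fasta


@dataclass(frozen=True)
class SpeciesPanel:
    """Ordered species labels with their proteome FASTA paths."""

    species: tuple[str, ...]
    source_files: Mapping[str, str]

    def __post_init__(self) -> None:
        if len(set(self.species)) != len(self.species):
            raise ConCysFindError("species labels in a panel must be unique")


@dataclass
class ProteomeDatabase:
    """Sequence records grouped by species, iterated in panel order."""

    panel: SpeciesPanel
    records: dict[str, list[SequenceRecord]]
    stats: dict[str, tuple[int, int]] = field(default_factory=dict)  # (n_records, n_residues)

    def __post_init__(self) -> None:
        for sp in self.panel.species:
            self.records.setdefault(sp, [])
        if not self.stats:
            self.stats = {
                sp: (len(recs), sum(len(r.residues) for r in recs))
                for sp, recs in ((s, self.records[s]) for s in self.panel.species)
            }

    @property
    def total_residues(self) -> int:
        return sum(n for _, n in self.stats.values())

    def __iter__(self) -> Iterator[tuple[str, list[SequenceRecord]]]:
        for sp in self.panel.species:
            yield sp, self.records[sp]


def parse_panel_config(stream: TextIO | str, base_dir: str | Path = ".") -> SpeciesPanel:
    """Read a panel config: one ``label<TAB>fasta-path`` line per species,
    ``#`` comments and blank lines allowed.  Relative paths resolve
    against ``base_dir``."""
    if isinstance(stream, str):
        lines = stream.splitlines()
    else:
        lines = stream.read().splitlines()
    base = Path(base_dir)
    species: list[str] = []
    files: dict[str, str] = {}
    for lineno, line in enumerate(lines, start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ParseError(f"panel config line {lineno}: expected 'label<TAB>path'")
        label, path = parts[0].strip(), parts[1].strip()
        if label in files:
            raise ParseError(f"panel config line {lineno}: duplicate species {label!r}")
        species.append(label)
        p = Path(path)
        files[label] = str(p if p.is_absolute() else base / p)
    if not species:
        raise ParseError("panel config defines no species")
    return SpeciesPanel(species=tuple(species), source_files=files)


def build_database(panel: SpeciesPanel) -> ProteomeDatabase:
    """Load every panel species' FASTA into a :class:`ProteomeDatabase`.

    Raises naming the species if a file is missing, and naming the
    accession if one occurs twice within a species.
    """
    records: dict[str, list[SequenceRecord]] = {}
    for sp in panel.species:
        path = Path(panel.source_files[sp])
        if not path.exists():
            raise ConCysFindError(f"proteome file for species {sp!r} not found: {path}")
        with open(path) as fh:
            try:
                records[sp] = parse_fasta(fh, species=sp)
            except ParseError as exc:
                raise ParseError(f"species {sp!r}: {exc}") from exc
    return ProteomeDatabase(panel=panel, records=records)


def database_from_records(panel: SpeciesPanel,
                          records: Mapping[str, list[SequenceRecord]]) -> ProteomeDatabase:
    """Build a database directly from in-memory records (used by the
    synthetic-family generator and tests)."""
    recs: dict[str, list[SequenceRecord]] = {}
    for sp in panel.species:
        rs = list(records.get(sp, []))
        seen: set[str] = set()
        for r in rs:
            if r.id in seen:
                raise ConCysFindError(f"duplicate accession {r.id!r} in species {sp!r}")
            seen.add(r.id)
        recs[sp] = rs
    return ProteomeDatabase(panel=panel, records=recs)
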