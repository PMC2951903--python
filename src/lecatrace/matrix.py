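"""Presence/absence matrices, taxon metadata, and their tab-separated formats.

The central object of the pipeline is a binary components-by-genomes
:class:`PresenceMatrix`.  A cell is 1 when at least one accepted homolog of
the component was found in the genome.  Matrices are stored as plain
tab-separated text: the first row carries genome codes, the first column
component names, and a cell holds a mark character (``x`` by default, case
insensitive) for presence or is empty for absence.  An optional second
column may carry a per-component annotation such as the NPC subcomplex or
coatomer complex the component belongs to.

:class:`TaxonomyMap` assigns each genome code to a taxonomic class and one
of the eukaryote supergroups (by default Opisthokonts, Amoebozoa, Plantae,
Chromalveolates and Excavates).  Genome codes are scoped per matrix: two
matrices may reuse a code for different species, each carrying its own
taxonomy block.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_SUPERGROUPS",
    "MatrixFormatError",
    "TaxonomyError",
    "PresenceMatrix",
    "TaxonEntry",
    "TaxonomyMap",
    "ControlRecord",
    "ControlReference",
    "PhenotypeMap",
    "read_presence_matrix",
    "write_presence_matrix",
    "read_taxonomy",
    "read_phenotypes",
    "read_control_reference",
    "presence_by_supergroup",
    "supergroup_counts",
]

#: The five-supergroup universe used throughout unless a caller overrides it.
DEFAULT_SUPERGROUPS: tuple[str, ...] = (
    "Opisthokonts",
    "Amoebozoa",
    "Plantae",
    "Chromalveolates",
    "Excavates",
)

#: Sentinel cell value for an explicit "unknown" mark (excluded from OR-collapse).
UNKNOWN = -1


class MatrixFormatError(ValueError):
    """Raised when a presence/absence table violates the format contract."""


class TaxonomyError(KeyError):
    """Raised when a genome lacks a taxonomy entry or a supergroup is unknown."""


@dataclass(frozen=True)
class PresenceMatrix:
    """Binary components-by-genomes indicator matrix.

    ``states`` has shape ``(len(components), len(genomes))`` with entries in
    {0, 1} (plus ``-1`` for an explicit unknown mark, which behaves as
    absence in every collapse).
    """

    components: tuple[str, ...]
    genomes: tuple[str, ...]
    states: np.ndarray
    annotation: Mapping[str, str] | None = None
    provenance: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "components", tuple(self.components))
        object.__setattr__(self, "genomes", tuple(self.genomes))
        states = np.asarray(self.states, dtype=np.int8)
        object.__setattr__(self, "states", states)
        self.validate()

    def validate(self) -> None:
        _check_unique("component", self.components)
        _check_unique("genome", self.genomes)
        if self.states.shape != (len(self.components), len(self.genomes)):
            raise MatrixFormatError(
                f"states shape {self.states.shape} does not match "
                f"{len(self.components)} components x {len(self.genomes)} genomes"
            )
        bad = ~np.isin(self.states, (0, 1, UNKNOWN))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise MatrixFormatError(
                f"invalid state {self.states[i, j]} at component "
                f"{self.components[i]!r}, genome {self.genomes[j]!r}"
            )
        if self.annotation is not None:
            unknown = set(self.annotation) - set(self.components)
            if unknown:
                raise MatrixFormatError(f"annotation for unknown components: {sorted(unknown)}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.states.shape

    def state(self, component: str, genome: str) -> int:
        return int(self.states[self.components.index(component), self.genomes.index(genome)])

    def row(self, component: str) -> np.ndarray:
        return self.states[self.components.index(component)]

    def present_genomes(self, component: str) -> tuple[str, ...]:
        r = self.row(component)
        return tuple(g for g, s in zip(self.genomes, r) if s == 1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.states.copy(), index=list(self.components), columns=list(self.genomes))

    def with_states(self, states: np.ndarray) -> "PresenceMatrix":
        return replace(self, states=np.asarray(states, dtype=np.int8))


def _check_unique(kind: str, names: Iterable[str]) -> None:
    seen: set[str] = set()
    for n in names:
        if not n:
            raise MatrixFormatError(f"empty {kind} name")
        if n in seen:
            raise MatrixFormatError(f"duplicate {kind} name {n!r}")
        seen.add(n)


@dataclass(frozen=True)
class TaxonEntry:
    species: str
    clade_class: str
    supergroup: str


@dataclass(frozen=True)
class TaxonomyMap:
    """Genome code -> (species, taxonomic class, supergroup) assignments."""

    entries: Mapping[str, TaxonEntry]
    supergroups: tuple[str, ...] = DEFAULT_SUPERGROUPS

    def __post_init__(self) -> None:
        object.__setattr__(self, "entries", dict(self.entries))
        object.__setattr__(self, "supergroups", tuple(self.supergroups))
        for g, e in self.entries.items():
            if e.supergroup not in self.supergroups:
                raise TaxonomyError(
                    f"genome {g!r} assigned to unknown supergroup {e.supergroup!r}; "
                    f"declared universe: {self.supergroups}"
                )

    def supergroup_of(self, genome: str) -> str:
        try:
            return self.entries[genome].supergroup
        except KeyError:
            raise TaxonomyError(f"no taxonomy entry for genome {genome!r}") from None

    def genomes_in(self, supergroup: str) -> tuple[str, ...]:
        if supergroup not in self.supergroups:
            raise TaxonomyError(f"unknown supergroup {supergroup!r}")
        return tuple(g for g, e in self.entries.items() if e.supergroup == supergroup)

    def check_covers(self, matrix: PresenceMatrix) -> None:
        missing = [g for g in matrix.genomes if g not in self.entries]
        if missing:
            raise TaxonomyError(f"genomes without taxonomy entries: {missing}")


# ---------------------------------------------------------------------------
# Screen-control records (concordance against an external experimental set)
# ---------------------------------------------------------------------------

_OUTCOMES = ("identified", "excluded", "not_detected")


@dataclass(frozen=True)
class ControlRecord:
    """One externally characterised protein and how the screen treated it."""

    protein_id: str
    orthology_established: bool
    outcome: str  # identified | excluded | not_detected
    fg_repeat_note: bool = False
    component: str | None = None

    def __post_init__(self) -> None:
        if self.outcome not in _OUTCOMES:
            raise ValueError(f"outcome must be one of {_OUTCOMES}, got {self.outcome!r}")
        if self.fg_repeat_note and self.component:
            raise ValueError(
                f"{self.protein_id}: FG-repeat note is only valid on records "
                "without an assigned component"
            )


@dataclass(frozen=True)
class ControlReference:
    records: tuple[ControlRecord, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        _check_unique("control protein", [r.protein_id for r in self.records])

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def implied_calls(self) -> dict[str, str]:
        """Accepted (protein id -> component) calls encoded by the control flags."""
        return {
            r.protein_id: r.component
            for r in self.records
            if r.outcome == "identified" and r.component
        }


@dataclass(frozen=True)
class PhenotypeMap:
    """Genome code -> phenotype label (e.g. 'open'/'closed' mitosis)."""

    labels: Mapping[str, str]
    vocabulary: tuple[str, ...] = ("closed", "open", "unknown")

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", dict(self.labels))
        bad = {g: p for g, p in self.labels.items() if p not in self.vocabulary}
        if bad:
            raise ValueError(f"phenotype labels outside vocabulary {self.vocabulary}: {bad}")

    def __getitem__(self, genome: str) -> str:
        return self.labels.get(genome, "unknown")


# ---------------------------------------------------------------------------
# Tab-separated I/O
# ---------------------------------------------------------------------------


def _read_table(path) -> tuple[list[list[str]], str]:
    """Read a '#'-commented UTF-8 TSV into rows of cells, plus the provenance note."""
    if hasattr(path, "read"):
        text = path.read()
    else:
        text = Path(path).read_text(encoding="utf-8")
    provenance: list[str] = []
    rows: list[list[str]] = []
    for line in text.split("\n"):
        if line.startswith("#"):
            provenance.append(line.lstrip("# ").rstrip())
        elif line:
            rows.append(line.split("\t"))
    return rows, "; ".join(provenance)


def read_presence_matrix(path, mark: str = "x", unknown_mark: str | None = None) -> PresenceMatrix:
    """Parse a presence/absence TSV into a validated :class:`PresenceMatrix`.

    The mark is matched case-insensitively.  Any other non-empty cell token is
    a format error reported with its row and column.
    """
    rows, provenance = _read_table(path)
    if not rows:
        raise MatrixFormatError(f"{path}: empty file")
    header = rows[0]
    has_annotation = len(header) > 1 and header[1].strip().lower() == "annotation"
    first_genome_col = 2 if has_annotation else 1
    genomes = [c.strip() for c in header[first_genome_col:]]
    components: list[str] = []
    annotation: dict[str, str] = {}
    states = np.zeros((len(rows) - 1, len(genomes)), dtype=np.int8)
    mark = mark.lower()
    for i, row in enumerate(rows[1:]):
        row = row + [""] * (len(header) - len(row))
        if len(row) > len(header):
            raise MatrixFormatError(
                f"row {row[0]!r} has {len(row)} cells but the header declares {len(header)}"
            )
        name = row[0].strip()
        components.append(name)
        if has_annotation and row[1].strip():
            annotation[name] = row[1].strip()
        for j, cell in enumerate(row[first_genome_col:]):
            token = cell.strip().lower()
            if token == mark:
                states[i, j] = 1
            elif unknown_mark is not None and token == unknown_mark.lower():
                states[i, j] = UNKNOWN
            elif token:
                raise MatrixFormatError(
                    f"unknown cell token {cell!r} at component {name!r}, genome {genomes[j]!r}"
                )
    return PresenceMatrix(
        components=tuple(components),
        genomes=tuple(genomes),
        states=states,
        annotation=annotation or None,
        provenance=provenance,
    )


def write_presence_matrix(matrix: PresenceMatrix, path, mark: str = "x") -> None:
    """Write ``matrix`` as deterministic TSV (byte-identical for equal input)."""
    matrix.validate()
    lines: list[str] = []
    if matrix.provenance:
        lines.append(f"# {matrix.provenance}")
    has_annotation = matrix.annotation is not None
    header = ["component"] + (["annotation"] if has_annotation else []) + list(matrix.genomes)
    lines.append("\t".join(header))
    for i, comp in enumerate(matrix.components):
        cells = [comp]
        if has_annotation:
            cells.append(matrix.annotation.get(comp, ""))
        cells.extend(
            mark if s == 1 else ("?" if s == UNKNOWN else "") for s in matrix.states[i]
        )
        lines.append("\t".join(cells))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_taxonomy(path, supergroups: tuple[str, ...] = DEFAULT_SUPERGROUPS) -> TaxonomyMap:
    """Read a taxonomy TSV.

    Accepts three columns (genome, class, supergroup) or four
    (genome, species, class, supergroup); a header row is detected by its
    first cell reading ``genome``.
    """
    rows, _ = _read_table(path)
    entries: dict[str, TaxonEntry] = {}
    for row in rows:
        cells = [c.strip() for c in row]
        if not cells or not cells[0] or cells[0].lower() == "genome":
            continue
        if len(cells) == 3:
            genome, species, cls, sg = cells[0], "", cells[1], cells[2]
        elif len(cells) >= 4:
            genome, species, cls, sg = cells[:4]
        else:
            raise MatrixFormatError(f"taxonomy row needs 3 or 4 columns: {row!r}")
        if genome in entries:
            raise MatrixFormatError(f"duplicate taxonomy entry for {genome!r}")
        entries[genome] = TaxonEntry(species=species, clade_class=cls, supergroup=sg)
    return TaxonomyMap(entries=entries, supergroups=supergroups)


def read_phenotypes(path, vocabulary: tuple[str, ...] = ("closed", "open", "unknown")) -> PhenotypeMap:
    rows, _ = _read_table(path)
    labels: dict[str, str] = {}
    for row in rows:
        cells = [c.strip() for c in row]
        if not cells or not cells[0] or cells[0].lower() == "genome":
            continue
        labels[cells[0]] = cells[1]
    return PhenotypeMap(labels=labels, vocabulary=vocabulary)


def read_control_reference(path) -> ControlReference:
    rows, _ = _read_table(path)
    records: list[ControlRecord] = []
    for row in rows:
        cells = [c.strip() for c in row] + [""] * (5 - len(row))
        if not cells[0] or cells[0] == "protein_id":
            continue
        records.append(
            ControlRecord(
                protein_id=cells[0],
                orthology_established=cells[1] == "1",
                outcome=cells[2],
                fg_repeat_note=cells[3] == "1",
                component=cells[4] or None,
            )
        )
    return ControlReference(records=tuple(records))


# ---------------------------------------------------------------------------
# Supergroup profiling
# ---------------------------------------------------------------------------


def presence_by_supergroup(
    matrix: PresenceMatrix, taxonomy: TaxonomyMap
) -> dict[str, frozenset[str]]:
    """Map each component to the set of supergroups with at least one presence."""
    taxonomy.check_covers(matrix)
    sg_of = [taxonomy.supergroup_of(g) for g in matrix.genomes]
    profile: dict[str, frozenset[str]] = {}
    for i, comp in enumerate(matrix.components):
        profile[comp] = frozenset(
            sg for sg, s in zip(sg_of, matrix.states[i]) if s == 1
        )
    return profile


def supergroup_counts(matrix: PresenceMatrix, taxonomy: TaxonomyMap) -> dict[str, int]:
    """Per supergroup, the number of components present in >=1 of its genomes."""
    profile = presence_by_supergroup(matrix, taxonomy)
    return {
        sg: sum(1 for comp in matrix.components if sg in profile[comp])
        for sg in taxonomy.supergroups
    }
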