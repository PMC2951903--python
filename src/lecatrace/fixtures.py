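"""Bundled table fixtures transcribed from the published comparative survey.

The fixtures are plain tab-separated files shipped with the package:

``nup_table2`` / ``taxonomy_table2``
    Nucleoporin presence/absence across 51 eukaryote genomes spanning the
    five supergroups, with the genome -> class -> supergroup assignments.
``tbrucei_table1``
    The *Trypanosoma brucei* concordance control: the proteomically
    characterised NPC protein set with, per protein, whether orthology was
    established, how the profile screen treated it, and FG-repeat notes.
``fungi_table4`` / ``taxonomy_table4`` / ``mitosis_phenotypes``
    Anchoring nucleoporins (Ndc1, Pom152, Pom34) across 19 fungal genomes,
    with the closed (ascomycete) / open (basidiomycete + zygomycete)
    mitosis phenotype labels.
``coatomer_table5`` / ``taxonomy_table5``
    COPI / COPII / clathrin-adaptin component presence across 46 genomes.

Transcription notes: the presence mark is normalized case-insensitively
(the nucleoporin table contains a single upper-case cell); genome codes are
scoped per fixture (the two matrices' panels differ); the chlorophyte
printed 'Ot' keeps that code although the source footnote spells the
species out under 'Ol'.
"""

from __future__ import annotations

from importlib import resources

from .matrix import (
    ControlReference,
    PhenotypeMap,
    PresenceMatrix,
    TaxonomyMap,
    read_control_reference,
    read_phenotypes,
    read_presence_matrix,
    read_taxonomy,
)

__all__ = ["FIXTURE_NAMES", "load_fixture", "fixture_path"]

_FILES = {
    "nup_table2": ("nup_table2.tsv", "matrix"),
    "taxonomy_table2": ("taxonomy_table2.tsv", "taxonomy"),
    "tbrucei_table1": ("tbrucei_table1.tsv", "control"),
    "fungi_table4": ("fungi_table4.tsv", "matrix"),
    "taxonomy_table4": ("taxonomy_table4.tsv", "taxonomy"),
    "mitosis_phenotypes": ("mitosis_phenotypes.tsv", "phenotypes"),
    "coatomer_table5": ("coatomer_table5.tsv", "matrix"),
    "taxonomy_table5": ("taxonomy_table5.tsv", "taxonomy"),
}

FIXTURE_NAMES = tuple(_FILES)


def fixture_path(name: str):
    """Filesystem path of a bundled fixture (context-free; files ship as text)."""
    if name not in _FILES:
        raise KeyError(f"unknown fixture {name!r}; available: {FIXTURE_NAMES}")
    return resources.files("lecatrace") / "fixtures" / _FILES[name][0]


def load_fixture(
    name: str,
) -> PresenceMatrix | TaxonomyMap | ControlReference | PhenotypeMap:
    """Load a bundled fixture by name into its validated domain object."""
    path = fixture_path(name)
    kind = _FILES[name][1]
    with resources.as_file(path) as p:
        if kind == "matrix":
            return read_presence_matrix(p)
        if kind == "taxonomy":
            return read_taxonomy(p)
        if kind == "control":
            return read_control_reference(p)
        return read_phenotypes(p)
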