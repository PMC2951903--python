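"""Derived comparative analyses over presence/absence matrices.

Covers the phenotype-association test (does a component's distribution track
open versus closed mitosis across fungi?), whole-supergroup absence reports
for the coatomer complexes, side-by-side comparison of supergroup profiles
from different screens, and a deterministic rendered summary.

The phenotype association is quantified with Fisher's exact test (the exact
conditional hypergeometric null over all margin-preserving 2x2 tables).
This statistic is an addition of this package, not part of the original
comparative analysis, and the rendered output says so.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd
from scipy import stats

from .matrix import (
    PhenotypeMap,
    PresenceMatrix,
    TaxonomyMap,
    presence_by_supergroup,
    supergroup_counts,
)

__all__ = [
    "ContingencyTable",
    "MitosisAssociation",
    "DifferenceReport",
    "StudyComparison",
    "mitosis_association",
    "coatomer_supergroup_differences",
    "study_comparison",
    "render_summary",
]


class DegenerateInputError(ValueError):
    """Raised when a contingency analysis has an empty phenotype class."""


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts: phenotype class (rows) x component present/absent (cols)."""

    phenotype_a: str
    phenotype_b: str
    a_present: int
    a_absent: int
    b_present: int
    b_absent: int

    def __post_init__(self) -> None:
        if min(self.a_present, self.a_absent, self.b_present, self.b_absent) < 0:
            raise ValueError("contingency counts must be nonnegative")

    @property
    def counts(self) -> tuple[int, int, int, int]:
        return (self.a_present, self.a_absent, self.b_present, self.b_absent)

    @property
    def row_margins(self) -> tuple[int, int]:
        return (self.a_present + self.a_absent, self.b_present + self.b_absent)

    @property
    def col_margins(self) -> tuple[int, int]:
        return (self.a_present + self.b_present, self.a_absent + self.b_absent)

    @property
    def total(self) -> int:
        return sum(self.counts)


@dataclass(frozen=True)
class MitosisAssociation:
    component: str
    table: ContingencyTable
    perfect_association: bool
    p_value: float


def mitosis_association(
    matrix: PresenceMatrix,
    phenotypes: PhenotypeMap,
    component: str,
    classes: tuple[str, str] = ("closed", "open"),
) -> MitosisAssociation:
    """Exact 2x2 association between a component and a binary phenotype.

    Genomes with an unknown phenotype are dropped.  The association is
    *perfect* when both off-diagonal cells are zero, i.e. presence exactly
    coincides with one phenotype class.  The two-sided p-value comes from
    Fisher's exact test.
    """
    pa, pb = classes
    cells = {(pa, 1): 0, (pa, 0): 0, (pb, 1): 0, (pb, 0): 0}
    row = matrix.row(component)
    for genome, state in zip(matrix.genomes, row):
        label = phenotypes[genome]
        if label not in classes:
            continue
        cells[(label, 1 if state == 1 else 0)] += 1
    table = ContingencyTable(
        phenotype_a=pa,
        phenotype_b=pb,
        a_present=cells[(pa, 1)],
        a_absent=cells[(pa, 0)],
        b_present=cells[(pb, 1)],
        b_absent=cells[(pb, 0)],
    )
    if table.row_margins[0] == 0 or table.row_margins[1] == 0:
        raise DegenerateInputError(
            f"phenotype class without genomes after dropping unknowns: {table}"
        )
    perfect = (table.a_absent == 0 and table.b_present == 0) or (
        table.a_present == 0 and table.b_absent == 0
    )
    p = float(
        stats.fisher_exact(
            [[table.a_present, table.a_absent], [table.b_present, table.b_absent]],
            alternative="two-sided",
        ).pvalue
    )
    return MitosisAssociation(
        component=component, table=table, perfect_association=perfect, p_value=p
    )


@dataclass(frozen=True)
class DifferenceReport:
    """Components (or paralog groups) entirely absent from >=1 supergroup."""

    entries: tuple[tuple[str, tuple[str, ...]], ...]  # (name, absent supergroups)

    def absent_supergroups(self, name: str) -> tuple[str, ...]:
        for n, sgs in self.entries:
            if n == name:
                return sgs
        raise KeyError(name)

    def __len__(self) -> int:
        return len(self.entries)


def coatomer_supergroup_differences(
    matrix: PresenceMatrix,
    taxonomy: TaxonomyMap,
    paralog_groups: Sequence[set[str]] = ({"apl1", "apl2"},),
) -> DifferenceReport:
    """Whole-supergroup absences, after OR-collapsing paralog groups.

    Paralogous components that arose by duplication (by default the two
    clathrin-adaptor β-chains apl1/apl2) are merged before absence testing,
    since either copy covers the ancestral function.  Groups must be
    disjoint sets of known components.
    """
    known = set(matrix.components)
    seen: set[str] = set()
    for group in paralog_groups:
        unknown = set(group) - known
        if unknown:
            raise KeyError(f"paralog group references unknown components: {sorted(unknown)}")
        if seen & set(group):
            raise ValueError("paralog groups must be disjoint")
        seen |= set(group)
    profile = presence_by_supergroup(matrix, taxonomy)
    merged: dict[str, frozenset[str]] = {}
    for comp in matrix.components:
        if comp in seen:
            continue
        merged[comp] = profile[comp]
    for group in paralog_groups:
        name = "/".join(sorted(group))
        merged[name] = frozenset().union(*(profile[c] for c in group))
    entries = []
    for name in sorted(merged):
        absent = tuple(sg for sg in taxonomy.supergroups if sg not in merged[name])
        if absent:
            entries.append((name, absent))
    return DifferenceReport(entries=tuple(entries))


@dataclass(frozen=True)
class StudyComparison:
    counts: pd.DataFrame  # supergroups x studies
    grid: pd.DataFrame  # (component, supergroup) x studies booleans


def study_comparison(
    profiles: Mapping[str, Mapping[str, frozenset[str]]],
    supergroups: Sequence[str],
) -> StudyComparison:
    """Compare per-supergroup component counts across named screens.

    ``profiles`` maps study name -> (component -> supergroups with >=1
    presence).  Studies with differing component universes produce a
    reconciliation warning listing the symmetric difference; counting then
    proceeds on each study's own universe.
    """
    names = list(profiles)
    universes = {s: set(profiles[s]) for s in names}
    union = set().union(*universes.values()) if names else set()
    for s in names:
        diff = union ^ universes[s]
        if diff:
            warnings.warn(
                f"study {s!r} component universe differs: {sorted(diff)}",
                stacklevel=2,
            )
    counts = pd.DataFrame(
        {
            s: [sum(1 for c in profiles[s] if sg in profiles[s][c]) for sg in supergroups]
            for s in names
        },
        index=list(supergroups),
    )
    rows = []
    for comp in sorted(union):
        for sg in supergroups:
            rows.append(
                [comp, sg] + [sg in profiles[s].get(comp, frozenset()) for s in names]
            )
    grid = pd.DataFrame(rows, columns=["component", "supergroup"] + names)
    return StudyComparison(counts=counts, grid=grid)


def render_summary(
    matrix: PresenceMatrix,
    taxonomy: TaxonomyMap,
    leca: frozenset[str] | set[str] | None = None,
    associations: Sequence[MitosisAssociation] = (),
) -> tuple[str, dict[str, pd.DataFrame]]:
    """Deterministic human-readable summary plus machine-readable tables.

    Components present in every supergroup are marked with ``*``; components
    are grouped by their annotation (subcomplex / complex) when present.
    """
    profile = presence_by_supergroup(matrix, taxonomy)
    counts = supergroup_counts(matrix, taxonomy)
    universe = set(taxonomy.supergroups)
    universal = [c for c in matrix.components if profile[c] >= universe]
    lines: list[str] = []
    lines.append(f"Components: {len(matrix.components)}  Genomes: {len(matrix.genomes)}")
    lines.append(
        "Per-supergroup component counts: "
        + "  ".join(f"{sg}={counts[sg]}" for sg in taxonomy.supergroups)
    )
    lines.append(
        f"Universal components (present in all {len(taxonomy.supergroups)} "
        f"supergroups): {len(universal)}"
    )
    annotation = matrix.annotation or {}
    groups: dict[str, list[str]] = {}
    for comp in matrix.components:
        groups.setdefault(annotation.get(comp, "unannotated"), []).append(comp)
    for group, comps in groups.items():
        marked = ", ".join(c + ("*" if c in universal else "") for c in comps)
        lines.append(f"  [{group}] {marked}")
    if leca is not None:
        lines.append(f"Root (LECA) complement: {len(leca)} components")
        lines.append("  " + ", ".join(sorted(leca)))
    for assoc in associations:
        t = assoc.table
        lines.append(
            f"Phenotype association for {assoc.component}: "
            f"{t.phenotype_a}&present={t.a_present} {t.phenotype_a}&absent={t.a_absent} "
            f"{t.phenotype_b}&present={t.b_present} {t.phenotype_b}&absent={t.b_absent} "
            f"perfect={assoc.perfect_association} "
            f"exact-p={assoc.p_value:.3g} (test added by this package)"
        )
    tables = {
        "profile": pd.DataFrame(
            [
                [c] + [sg in profile[c] for sg in taxonomy.supergroups]
                for c in matrix.components
            ],
            columns=["component", *taxonomy.supergroups],
        ),
        "counts": pd.DataFrame(
            {"supergroup": list(taxonomy.supergroups), "components": [counts[sg] for sg in taxonomy.supergroups]}
        ),
    }
    return "\n".join(lines) + "\n", tables
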