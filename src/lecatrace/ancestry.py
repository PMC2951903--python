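"""Ancestral complex composition by parsimony on rooted supergroup trees.

Each component of a complex is treated as a binary character (present/absent
per genome or supergroup).  Reconstruction follows Dollo parsimony: a
component arises exactly once — on the edge above the last common ancestor
of all taxa that carry it — and may then be lost independently in any number
of lineages.  The cost of a component's history is 1 (the gain) plus the
number of maximal all-absent subtrees below the gain.

The root (LECA, when the tree spans the eukaryote supergroups) carries a
component exactly when the gain maps to the root edge, i.e. when the
component is present on at least two child subtrees of the root.  Because
that statement depends only on the root bipartition, the LECA complement is
insensitive to how each side of the root is internally arranged.

An unrestricted-parsimony pass (gains and losses both at unit cost) sets an
ambiguity flag whenever the opposite root state can be realised at no extra
cost — the classic "one gain or one loss, equally parsimonious" situation.

Two named rootings of the eukaryote tree are built in: ``excavate_basal``
(Excavates as the outgroup to everything else) and ``unikont_bikont`` (root
between {Opisthokonts, Amoebozoa} and {Plantae, Chromalveolates,
Excavates}).  A ``star`` rooting treats the supergroup relationships as
fully unresolved and yields only bounds on the ancestral complement.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .matrix import (
    DEFAULT_SUPERGROUPS,
    PresenceMatrix,
    TaxonomyMap,
    presence_by_supergroup,
    supergroup_counts,
)
from .trees import ROOT_EDGE, Clade, clade, from_newick

__all__ = [
    "RootingSpec",
    "ComponentEvents",
    "DolloResult",
    "EventSummary",
    "StarBounds",
    "rooting_topology",
    "collapse_to_supergroups",
    "universal_components",
    "dollo_reconstruct",
    "mark_ambiguous",
    "leca_complement",
    "star_tree_bounds",
    "gain_loss_summary",
]

_PRESETS = ("excavate_basal", "unikont_bikont", "star", "custom")


@dataclass(frozen=True)
class RootingSpec:
    """Which root of the eukaryote tree to reconstruct under."""

    preset: str = "unikont_bikont"
    newick: str | None = None

    def __post_init__(self) -> None:
        if self.preset not in _PRESETS:
            raise ValueError(f"preset must be one of {_PRESETS}, got {self.preset!r}")
        if self.preset == "custom" and not self.newick:
            raise ValueError("custom rooting needs a newick topology")


def rooting_topology(
    rooting: RootingSpec | str, supergroups: tuple[str, ...] = DEFAULT_SUPERGROUPS
) -> Clade:
    """Materialise a rooting preset as a rooted supergroup topology.

    The within-side arrangement for the binary presets follows the default
    ((Plantae,(Chromalveolates,Excavates)),(Opisthokonts,Amoebozoa)) shape;
    root-level conclusions do not depend on it.
    """
    if isinstance(rooting, str):
        rooting = RootingSpec(preset=rooting)
    o, a, p, c, e = supergroups
    if rooting.preset == "unikont_bikont":
        top = clade(clade(o, a), clade(p, clade(c, e)))
    elif rooting.preset == "excavate_basal":
        top = clade(e, clade(clade(o, a), clade(p, c)))
    elif rooting.preset == "star":
        top = clade(*supergroups)
    else:
        top = from_newick(rooting.newick)
    top.validate()
    missing = set(supergroups) - set(top.leaf_names)
    if missing and rooting.preset == "custom":
        raise ValueError(f"custom rooting lacks supergroups: {sorted(missing)}")
    return top


@dataclass(frozen=True)
class ComponentEvents:
    """Dollo event mapping for a single component."""

    component: str
    gain_edge: str | None  # signature of the gain edge; ROOT_EDGE for the root
    loss_edges: tuple[str, ...]
    root_state: bool
    cost: int
    ambiguous: bool | None = None  # None until mark_ambiguous has run


@dataclass(frozen=True)
class DolloResult:
    by_component: Mapping[str, ComponentEvents]

    def __post_init__(self) -> None:
        object.__setattr__(self, "by_component", dict(self.by_component))

    def __getitem__(self, component: str) -> ComponentEvents:
        return self.by_component[component]

    def __iter__(self):
        return iter(self.by_component.values())

    def root_present(self) -> set[str]:
        return {c.component for c in self if c.root_state}


@dataclass(frozen=True)
class EventSummary:
    """Per-lineage gains/losses plus the ancestral (root) complement."""

    gained: Mapping[str, tuple[str, ...]]  # edge signature -> components gained there
    lost: Mapping[str, tuple[str, ...]]
    ambiguous: tuple[str, ...]
    leca: frozenset[str]


@dataclass(frozen=True)
class StarBounds:
    """Bounds on the root complement under a fully unresolved supergroup tree."""

    lower: int
    upper: int
    witness_supergroup: str
    universal: frozenset[str]

    def as_tuple(self) -> tuple[int, int]:
        return (self.lower, self.upper)


# ---------------------------------------------------------------------------


def collapse_to_supergroups(matrix: PresenceMatrix, taxonomy: TaxonomyMap) -> PresenceMatrix:
    """OR-collapse genome columns into one column per supergroup."""
    taxonomy.check_covers(matrix)
    cols = []
    for sg in taxonomy.supergroups:
        members = [j for j, g in enumerate(matrix.genomes) if taxonomy.supergroup_of(g) == sg]
        col = (matrix.states[:, members] == 1).any(axis=1).astype(np.int8)
        cols.append(col)
    return PresenceMatrix(
        components=matrix.components,
        genomes=taxonomy.supergroups,
        states=np.column_stack(cols),
        annotation=matrix.annotation,
        provenance=matrix.provenance,
    )


def universal_components(matrix: PresenceMatrix, taxonomy: TaxonomyMap) -> list[str]:
    """Components present in at least one genome of every supergroup."""
    profile = presence_by_supergroup(matrix, taxonomy)
    universe = set(taxonomy.supergroups)
    return [c for c in matrix.components if profile[c] >= universe]


def dollo_reconstruct(
    topology: Clade, tip_states: Mapping[str, Mapping[str, int]]
) -> DolloResult:
    """Single-gain/multiple-loss event mapping per component.

    ``tip_states`` maps component -> leaf label -> 0/1.  Every leaf of the
    topology must have a state; a component absent from all leaves gets a
    no-event result (no gain, root absent).
    """
    topology.validate()
    leaves = topology.leaf_names
    results: dict[str, ComponentEvents] = {}
    for comp, states in tip_states.items():
        missing = [l for l in leaves if l not in states]
        if missing:
            raise KeyError(f"component {comp!r}: missing states for leaves {missing}")
        present = {l for l in leaves if states[l] == 1}
        if not present:
            results[comp] = ComponentEvents(comp, None, (), False, 0)
            continue
        gain_node = topology.find_lca(present)
        losses = _maximal_absent_subtrees(gain_node, present)
        is_root = gain_node is topology
        results[comp] = ComponentEvents(
            component=comp,
            gain_edge=ROOT_EDGE if is_root else gain_node.signature,
            loss_edges=tuple(sorted(n.signature for n in losses)),
            root_state=is_root,
            cost=1 + len(losses),
        )
    return DolloResult(by_component=results)


def _maximal_absent_subtrees(node: Clade, present: set[str]) -> list[Clade]:
    losses: list[Clade] = []
    for child in node.children:
        if present & set(child.leaf_names):
            losses.extend(_maximal_absent_subtrees(child, present))
        else:
            losses.append(child)
    return losses


def _min_changes(node: Clade, states: Mapping[str, int]) -> tuple[int, int]:
    """Sankoff pass: minimal edge-change counts for (root absent, root present)."""
    if node.is_leaf:
        s = states[node.label]
        return (0 if s == 0 else _INF, 0 if s == 1 else _INF)
    c0 = c1 = 0
    for child in node.children:
        k0, k1 = _min_changes(child, states)
        c0 += min(k0, k1 + 1)
        c1 += min(k1, k0 + 1)
    return (c0, c1)


_INF = 10**9


def mark_ambiguous(
    topology: Clade, tip_states: Mapping[str, Mapping[str, int]], dollo: DolloResult
) -> DolloResult:
    """Flag components whose root state is not forced at minimal unrestricted cost.

    A component is ambiguous when an unrestricted binary-parsimony mapping
    (any number of gains and losses, unit cost each, root state free) with
    the opposite root state costs no more than the Dollo mapping.
    """
    flagged: dict[str, ComponentEvents] = {}
    for comp, events in dollo.by_component.items():
        if events.gain_edge is None:
            flagged[comp] = ComponentEvents(
                comp, None, (), False, 0, ambiguous=False
            )
            continue
        c0, c1 = _min_changes(topology, tip_states[comp])
        alternative = c0 if events.root_state else c1
        flagged[comp] = ComponentEvents(
            component=events.component,
            gain_edge=events.gain_edge,
            loss_edges=events.loss_edges,
            root_state=events.root_state,
            cost=events.cost,
            ambiguous=bool(alternative <= events.cost),
        )
    return DolloResult(by_component=flagged)


def _supergroup_tip_states(
    matrix: PresenceMatrix, taxonomy: TaxonomyMap
) -> dict[str, dict[str, int]]:
    collapsed = collapse_to_supergroups(matrix, taxonomy)
    return {
        comp: {sg: int(collapsed.states[i, j]) for j, sg in enumerate(collapsed.genomes)}
        for i, comp in enumerate(collapsed.components)
    }


def leca_complement(
    matrix: PresenceMatrix,
    taxonomy: TaxonomyMap,
    rooting: RootingSpec | str = "unikont_bikont",
) -> set[str] | StarBounds:
    """Components assigned to the root under a rooting.

    For binary-rooted presets this is the set of components present on both
    sides of the root bipartition (equivalently, with Dollo root state
    present).  For the ``star`` preset the reconstruction is only bounded:
    the :class:`StarBounds` pair is returned instead.
    """
    if isinstance(rooting, str):
        rooting = RootingSpec(preset=rooting)
    if rooting.preset == "star":
        return star_tree_bounds(matrix, taxonomy)
    topology = rooting_topology(rooting, taxonomy.supergroups)
    tip_states = _supergroup_tip_states(matrix, taxonomy)
    dollo = dollo_reconstruct(topology, tip_states)
    return dollo.root_present()


def star_tree_bounds(matrix: PresenceMatrix, taxonomy: TaxonomyMap) -> StarBounds:
    """(lower, upper) bounds on the root complement for an unresolved tree.

    The lower bound counts components present in every supergroup; the upper
    bound is the smallest per-supergroup component count, reported with the
    supergroup attaining it.
    """
    universal = universal_components(matrix, taxonomy)
    counts = supergroup_counts(matrix, taxonomy)
    witness = min(taxonomy.supergroups, key=lambda sg: counts[sg])
    return StarBounds(
        lower=len(universal),
        upper=counts[witness],
        witness_supergroup=witness,
        universal=frozenset(universal),
    )


def gain_loss_summary(dollo: DolloResult, topology: Clade) -> EventSummary:
    """Group gains and losses by the lineage (edge) they map to."""
    gained: dict[str, list[str]] = {}
    lost: dict[str, list[str]] = {}
    ambiguous: list[str] = []
    leca: set[str] = set()
    for events in dollo:
        if events.gain_edge is None:
            continue
        if events.root_state:
            leca.add(events.component)
        else:
            gained.setdefault(events.gain_edge, []).append(events.component)
        for edge in events.loss_edges:
            lost.setdefault(edge, []).append(events.component)
        if events.ambiguous:
            ambiguous.append(events.component)
    order = {n.signature: k for k, n in enumerate(topology.postorder())}
    return EventSummary(
        gained={e: tuple(sorted(v)) for e, v in sorted(gained.items(), key=lambda kv: order.get(kv[0], -1))},
        lost={e: tuple(sorted(v)) for e, v in sorted(lost.items(), key=lambda kv: order.get(kv[0], -1))},
        ambiguous=tuple(sorted(ambiguous)),
        leca=frozenset(leca),
    )
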