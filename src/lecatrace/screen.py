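"""Proteome screening with profile scoring and homology-vetting rules.

The screen mirrors the decision structure of a profile-based comparative
survey: score every protein of a proteome against every component profile,
keep hits above a threshold, then vet them.  Vetting encodes two classes of
evidence that are *insufficient* on their own:

* FG repeats — phenylalanine–glycine dipeptide repeats typical of transport
  channel components occur in many unrelated proteins, so a hit whose
  matched positions fall (almost) entirely inside FG-repeat windows is
  rejected unless a component-specific motif is found outside them.
* WD repeats — the ~40-residue β-propeller repeat is ancient and ubiquitous
  across all domains of life; similarity confined to WD-repeat windows is
  likewise rejected without an independent motif (such as the SIEGR motif
  that distinguishes Rae1 among WD-repeat proteins).

Surviving candidates are validated reciprocally: the candidate's best
pairwise match in a labelled reference proteome must belong to the same
component family, otherwise the hit is discarded.  For genomes where the
primary profile screen finds nothing, a rescue search re-screens the
proteome with profiles built from individual sequences of related genomes
at a permissive threshold; rescued hits re-enter vetting and reciprocal
validation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .matrix import ControlReference
from .profiles import (
    HitRecord,
    ProteinRecord,
    ScoringProfile,
    SeedAlignment,
    build_profile,
    score_sequence,
)

__all__ = [
    "DecoyQuantileThreshold",
    "ScreenDecision",
    "LabeledProtein",
    "ConcordanceReport",
    "screen_proteome",
    "repeat_windows",
    "detect_repeat_coverage",
    "apply_vetting",
    "reciprocal_validate",
    "rescue_search",
    "concordance_report",
    "REPEAT_FRACTION_CUTOFF",
    "REPEAT_FRACTION_WARN",
]

#: Hits with at least this fraction of matched positions inside repeat
#: windows (and no rescuing motif) are rejected as repeat-only similarity.
REPEAT_FRACTION_CUTOFF = 0.9
#: Above this fraction a decision carries a caution flag even when accepted.
REPEAT_FRACTION_WARN = 0.75

_FG_PATTERN = re.compile(r"FG")
_FG_FLANK = 2
_WD_PATTERN = re.compile(r"(?=([LIV].{6,12}WD))")
_WD_WINDOW = 40


class ThresholdError(ValueError):
    """Raised when a screen threshold specification cannot be resolved."""


@dataclass(frozen=True)
class DecoyQuantileThreshold:
    """Threshold given as a quantile of an empirical decoy score set."""

    quantile: float
    decoy_scores: Mapping[str, Sequence[float]] | Sequence[float]

    def resolve(self, component: str) -> float:
        scores = self.decoy_scores
        if isinstance(scores, Mapping):
            if component not in scores:
                raise ThresholdError(f"no decoy scores supplied for component {component!r}")
            scores = scores[component]
        arr = np.asarray(list(scores), dtype=float)
        if arr.size == 0:
            raise ThresholdError("decoy score set is empty")
        return float(np.quantile(arr, self.quantile))


def _resolve_threshold(threshold, component: str) -> float:
    if isinstance(threshold, DecoyQuantileThreshold):
        return threshold.resolve(component)
    try:
        return float(threshold)
    except (TypeError, ValueError):
        raise ThresholdError(f"unresolvable threshold spec: {threshold!r}") from None


@dataclass(frozen=True)
class ScreenDecision:
    """Vetting verdict for one hit."""

    hit: HitRecord
    status: str  # accepted | rejected
    reason: str = "none"  # none | below_threshold | repeat_only_similarity |
    #                       reciprocal_failed | motif_absent
    repeat_class: str | None = None  # FG | WD when reason is repeat_only_similarity
    repeat_warning: bool = False

    def __post_init__(self) -> None:
        if (self.status == "accepted") != (self.reason == "none"):
            raise ValueError("accepted decisions must (only) have reason 'none'")


@dataclass(frozen=True)
class LabeledProtein:
    """Reference protein annotated with its component family."""

    protein: ProteinRecord
    component: str


def screen_proteome(
    profiles: Iterable[ScoringProfile],
    proteome: Iterable[ProteinRecord],
    threshold,
) -> dict[str, list[HitRecord]]:
    """Score every protein against every profile; keep hits at/above threshold.

    Returns, per component, hits sorted by score (descending) then protein id;
    the output is independent of the input iteration order.
    """
    proteins = sorted(proteome, key=lambda p: p.id)
    out: dict[str, list[HitRecord]] = {}
    for prof in sorted(profiles, key=lambda p: p.component):
        cutoff = _resolve_threshold(threshold, prof.component)
        hits = [score_sequence(prof, p) for p in proteins]
        kept = [h for h in hits if h.score >= cutoff]
        kept.sort(key=lambda h: (-h.score, h.protein_id))
        out[prof.component] = kept
    return out


def repeat_windows(sequence: str, repeat_class: str) -> list[tuple[int, int]]:
    """Half-open repeat windows of the given class ('FG' or 'WD').

    FG windows are FG dipeptide occurrences (which covers the GLFG / FxFG
    contexts) expanded by two residues on each side; WD windows extend up to
    40 residues upstream from the end of each [LIV]-x(6,12)-W-D match.
    Overlapping windows are merged.
    """
    sequence = sequence.upper()
    raw: list[tuple[int, int]] = []
    if repeat_class == "FG":
        for m in _FG_PATTERN.finditer(sequence):
            raw.append((max(0, m.start() - _FG_FLANK), min(len(sequence), m.start() + 2 + _FG_FLANK)))
    elif repeat_class == "WD":
        for m in _WD_PATTERN.finditer(sequence):
            end = m.start() + len(m.group(1))
            raw.append((max(0, end - _WD_WINDOW), end))
    else:
        raise ValueError(f"unknown repeat class {repeat_class!r}")
    raw.sort()
    merged: list[tuple[int, int]] = []
    for a, b in raw:
        if merged and a <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], b))
        else:
            merged.append((a, b))
    return merged


def detect_repeat_coverage(hit: HitRecord, sequence: str, repeat_class: str) -> float:
    """Fraction of the hit's matched positions lying inside repeat windows."""
    positions = hit.matched_sequence_positions
    if not positions:
        return 0.0
    if max(positions) >= len(sequence) or hit.interval[1] > len(sequence):
        raise ValueError(
            f"hit interval {hit.interval} outside sequence of length {len(sequence)}"
        )
    windows = repeat_windows(sequence, repeat_class)
    covered = sum(1 for p in positions if any(a <= p < b for a, b in windows))
    return covered / len(positions)


def _motif_outside_windows(sequence: str, motifs: Sequence[str], windows) -> bool:
    for motif in motifs:
        for m in re.finditer(re.escape(motif.upper()), sequence.upper()):
            inside = any(a <= m.start() and m.end() <= b for a, b in windows)
            if not inside:
                return True
    return False


def apply_vetting(
    hits: Iterable[HitRecord],
    sequences: Mapping[str, str],
    repeat_fraction_cutoff: float = REPEAT_FRACTION_CUTOFF,
    required_motifs: Mapping[str, Sequence[str]] | None = None,
    warn_cutoff: float = REPEAT_FRACTION_WARN,
) -> list[ScreenDecision]:
    """Apply the repeat-only-similarity and required-motif rules to hits.

    A hit is rejected with ``repeat_only_similarity`` when its matched
    positions are covered by FG or WD repeat windows at or above the cutoff
    and no required motif of its component occurs outside those windows.  A
    hit whose component has required motifs that are absent from the protein
    altogether is rejected with ``motif_absent``.  Everything else is
    accepted (pending reciprocal validation), with a caution flag when
    repeat coverage exceeds the warn tier.
    """
    if not 0.0 <= repeat_fraction_cutoff <= 1.0:
        raise ValueError("repeat_fraction_cutoff must be within [0, 1]")
    required_motifs = required_motifs or {}
    decisions: list[ScreenDecision] = []
    for hit in hits:
        seq = sequences[hit.protein_id]
        motifs = list(required_motifs.get(hit.component, ()))
        if motifs and not any(re.search(re.escape(m.upper()), seq.upper()) for m in motifs):
            decisions.append(ScreenDecision(hit, "rejected", "motif_absent"))
            continue
        coverage = {rc: detect_repeat_coverage(hit, seq, rc) for rc in ("FG", "WD")}
        repeat_class = max(coverage, key=lambda rc: (coverage[rc], rc == "FG"))
        frac = coverage[repeat_class]
        if frac >= repeat_fraction_cutoff:
            windows = repeat_windows(seq, repeat_class)
            if not _motif_outside_windows(seq, motifs, windows):
                decisions.append(
                    ScreenDecision(
                        hit, "rejected", "repeat_only_similarity", repeat_class=repeat_class
                    )
                )
                continue
        decisions.append(
            ScreenDecision(hit, "accepted", "none", repeat_warning=frac >= warn_cutoff)
        )
    return decisions


def _pairwise_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    aligner.mode = "local"
    return aligner


def pairwise_score(a: str, b: str) -> float:
    """Symmetric substitution-matrix local alignment score (BLOSUM62)."""
    aligner = _pairwise_aligner()
    return float(aligner.score(a.replace("X", "A"), b.replace("X", "A")))


def reciprocal_validate(
    candidate: ProteinRecord,
    component: str,
    reference: Sequence[LabeledProtein],
) -> bool:
    """Best-hit-back test against a labelled reference proteome.

    Passes iff the candidate's best-scoring reference protein (pairwise
    local alignment, ties broken by reference id) carries the candidate's
    component label.
    """
    if not reference:
        raise ValueError("reference proteome is empty")
    scored = [
        (pairwise_score(candidate.sequence, ref.protein.sequence), ref)
        for ref in reference
    ]
    scored.sort(key=lambda t: (-t[0], t[1].protein.id))
    return scored[0][1].component == component


def rescue_search(
    component: str,
    donors: Sequence[ProteinRecord],
    target_proteome: Iterable[ProteinRecord],
    permissive_threshold: float,
) -> list[HitRecord]:
    """Re-screen a proteome with donor-seeded profiles at a permissive cutoff.

    Each donor sequence from a related genome becomes a single-sequence
    profile — scoring against it is a pairwise log-odds alignment — and the
    best donor score per protein is kept.  Hits at or above the permissive
    threshold are returned and are expected to re-enter
    :func:`apply_vetting` and :func:`reciprocal_validate`.
    """
    if not donors:
        raise ValueError(f"rescue for {component!r} needs at least one donor sequence")
    best: dict[str, HitRecord] = {}
    for donor in sorted(donors, key=lambda d: d.id):
        profile = build_profile(
            SeedAlignment(component=component, sequences=(donor.sequence,)), mode="local"
        )
        for hits in screen_proteome([profile], target_proteome, permissive_threshold).values():
            for hit in hits:
                prev = best.get(hit.protein_id)
                if prev is None or hit.score > prev.score:
                    best[hit.protein_id] = hit
    out = list(best.values())
    out.sort(key=lambda h: (-h.score, h.protein_id))
    return out


# ---------------------------------------------------------------------------
# Concordance against an external control set
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConcordanceReport:
    """Reconciliation of screen calls against an external control set."""

    established_total: int
    established_recovered: int
    extra_calls: tuple[str, ...]  # called ids whose orthology was not established
    additional_proteins: int  # control records with no assigned component
    fg_flagged: int  # ... of which carry an FG-repeat note
    excluded_after_hit: int
    not_detected: int
    lines: tuple[str, ...] = field(default=(), compare=False)


def concordance_report(
    screen_calls: Mapping[str, str],
    control: ControlReference,
) -> ConcordanceReport:
    """Tally screen calls (protein id -> component) against a control set."""
    established = [r for r in control if r.orthology_established and r.component]
    recovered = [r for r in established if r.protein_id in screen_calls]
    unassigned = [r for r in control if not r.component]
    extras = tuple(
        sorted(pid for pid in screen_calls if pid not in {r.protein_id for r in established})
    )
    lines = []
    for r in control:
        called = r.protein_id in screen_calls
        label = screen_calls.get(r.protein_id, "-")
        lines.append(
            f"{r.protein_id}\t{'established' if r.orthology_established else 'unassigned'}"
            f"\t{r.outcome}\t{'FG' if r.fg_repeat_note else '-'}"
            f"\t{'called:' + label if called else 'not-called'}"
        )
    return ConcordanceReport(
        established_total=len(established),
        established_recovered=len(recovered),
        extra_calls=extras,
        additional_proteins=len(unassigned),
        fg_flagged=sum(1 for r in unassigned if r.fg_repeat_note),
        excluded_after_hit=sum(1 for r in control if r.outcome == "excluded"),
        not_detected=sum(1 for r in control if r.outcome == "not_detected"),
        lines=tuple(lines),
    )
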