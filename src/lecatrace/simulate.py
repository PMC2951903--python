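"""Synthetic data: trees, single-gain/multiple-loss character evolution,
detection noise, and proteomes with planted homologs and repeat decoys.

The generator mirrors the assumptions behind the parsimony reconstruction:
each component originates once (on a gain edge), is lost independently on
descendant branches with a fixed per-branch probability (loss is
absorbing), and is then observed imperfectly — a true presence is missed
with probability ``q`` (the "missing data versus genuine loss" problem) and
a true absence spuriously called with probability ``r``.

Sequence-level simulation plants, for each component, a diverged homolog of
the component's seed consensus into a proteome otherwise made of decoys:
composition-shuffled random proteins, FG-repeat-only sequences, and
WD-repeat-window-only sequences.  These exercise the screen's vetting rules
without attempting realistic protein evolution.

All randomness flows from a master seed through stable labelled substreams,
so e.g. adding decoys does not perturb tree simulation.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .ancestry import dollo_reconstruct, mark_ambiguous
from .matrix import PresenceMatrix
from .profiles import AMINO_ACIDS, ProteinRecord, SeedAlignment, build_profile
from .screen import DecoyQuantileThreshold, apply_vetting, screen_proteome
from .trees import Clade, clade, leaf, ROOT_EDGE

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "ProteomeTruth",
    "ScenarioResult",
    "substream",
    "simulate_tree",
    "balanced_tree",
    "simulate_dollo_evolution",
    "apply_detection_noise",
    "states_to_matrix",
    "simulate_seed_alignment",
    "simulate_proteome",
    "end_to_end_scenario",
]


def substream(seed: int, label: str) -> np.random.Generator:
    """Independent reproducible random stream for (master seed, label)."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(label.encode())])
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic study.

    The defaults describe a survey-sized instance: a handful of genomes per
    lineage collapsed to 16 tips, a few hundred binary characters, a 10%
    per-branch loss rate and noise-free detection; sequence simulation
    plants homologs at 30% substitution divergence among a few decoys of
    each class.
    """

    seed: int = 0
    n_leaves: int = 16
    n_components: int = 200
    p_loss: float = 0.1
    gain_distribution: str = "uniform"  # uniform over edges | root
    q: float = 0.0  # detection false-negative rate
    r: float = 0.0  # detection false-positive rate
    simulate_sequences: bool = False
    sequence_length: int = 120
    substitution_fraction: float = 0.3
    indel_rate: float = 0.01
    n_decoy_random: int = 10
    n_decoy_fg: int = 5
    n_decoy_wd: int = 5

    def __post_init__(self) -> None:
        for name in ("p_loss", "q", "r"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be within [0, 1], got {v}")
        if not 0.0 <= self.substitution_fraction <= 1.0:
            raise ValueError("substitution_fraction must be within [0, 1]")
        if self.gain_distribution not in ("uniform", "root"):
            raise ValueError("gain_distribution must be 'uniform' or 'root'")

    @classmethod
    def from_file(cls, path) -> "SimulationConfig":
        """Read a flat ``key = value`` text config."""
        kwargs = {}
        booleans = {"simulate_sequences"}
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.split("#")[0].strip()
                if not line:
                    continue
                key, _, value = line.partition("=")
                key, value = key.strip(), value.strip()
                f = cls.__dataclass_fields__.get(key)
                if f is None:
                    raise KeyError(f"unknown simulation option {key!r}")
                if key in booleans:
                    kwargs[key] = value.lower() in ("1", "true", "yes")
                elif f.type == "int" or isinstance(f.default, int) and not isinstance(f.default, bool):
                    kwargs[key] = int(value)
                elif isinstance(f.default, float):
                    kwargs[key] = float(value)
                else:
                    kwargs[key] = value
        return cls(**kwargs)


@dataclass(frozen=True)
class ComponentTruth:
    component: str
    gain_edge: str  # signature of the planted gain edge (ROOT_EDGE at root)
    loss_edges: tuple[str, ...]  # branches on which the realized losses occurred
    n_events: int  # 1 gain + realized losses


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted character histories and the resulting tip states."""

    topology: Clade
    components: tuple[ComponentTruth, ...]
    true_states: Mapping[str, Mapping[str, int]]
    observed_states: Mapping[str, Mapping[str, int]] | None = None

    def truth_for(self, component: str) -> ComponentTruth:
        for c in self.components:
            if c.component == component:
                return c
        raise KeyError(component)

    def root_present_components(self) -> set[str]:
        return {c.component for c in self.components if c.gain_edge == ROOT_EDGE}


def simulate_tree(n_leaves: int, seed: int) -> Clade:
    """Random rooted binary topology by uniform sequential attachment."""
    if n_leaves < 2:
        raise ValueError("a rooted topology needs at least 2 leaves")
    rng = substream(seed, "tree")
    width = len(str(n_leaves))
    labels = [f"L{i + 1:0{width}d}" for i in range(n_leaves)]

    # grow by splitting a uniformly chosen current tip into a cherry
    def split(node, target, new_leaf):
        if isinstance(node, str):
            return [node, new_leaf] if node == target else node
        return [split(c, target, new_leaf) for c in node]

    tips = [labels[0]]
    tree: object = labels[0]
    for lab in labels[1:]:
        target = tips[int(rng.integers(len(tips)))]
        tree = split(tree, target, lab) if not isinstance(tree, str) else [tree, lab]
        tips.append(lab)

    def build(node) -> Clade:
        if isinstance(node, str):
            return leaf(node)
        return Clade(children=tuple(build(c) for c in node))

    out = build(tree)
    out.validate()
    return out


def balanced_tree(depth: int, prefix: str = "L") -> Clade:
    """Complete binary tree with 2**depth leaves (all tips at depth ``depth``)."""
    counter = [0]

    def build(d: int) -> Clade:
        if d == 0:
            counter[0] += 1
            return leaf(f"{prefix}{counter[0]:04d}")
        return clade(build(d - 1), build(d - 1))

    return build(depth)


def simulate_dollo_evolution(topology: Clade, config: SimulationConfig) -> SyntheticTruth:
    """Plant a single gain per component and propagate absorbing losses."""
    topology.validate()
    rng = substream(config.seed, "dollo")
    nodes = list(topology.postorder())
    components: list[ComponentTruth] = []
    true_states: dict[str, dict[str, int]] = {}
    width = len(str(max(config.n_components, 1)))
    for k in range(config.n_components):
        name = f"C{k + 1:0{width}d}"
        if config.gain_distribution == "root":
            gain = topology
        else:
            gain = nodes[rng.integers(len(nodes))]
        states: dict[str, int] = {l: 0 for l in topology.leaf_names}
        losses: list[str] = []

        def descend(node: Clade, present: bool) -> None:
            if node.is_leaf:
                states[node.label] = 1 if present else 0
                return
            for child in node.children:
                child_present = present
                if present and rng.random() < config.p_loss:
                    child_present = False
                    losses.append(child.signature)
                descend(child, child_present)

        if gain.is_leaf:
            states[gain.label] = 1
        else:
            descend(gain, True)
        components.append(
            ComponentTruth(
                component=name,
                gain_edge=ROOT_EDGE if gain is topology else gain.signature,
                loss_edges=tuple(losses),
                n_events=1 + len(losses),
            )
        )
        true_states[name] = states
    return SyntheticTruth(
        topology=topology, components=tuple(components), true_states=true_states
    )


def apply_detection_noise(
    truth: SyntheticTruth, q: float, r: float, seed: int
) -> SyntheticTruth:
    """Flip true presences with probability ``q``, absences with ``r``."""
    if not (0.0 <= q <= 1.0 and 0.0 <= r <= 1.0):
        raise ValueError("noise rates must be within [0, 1]")
    rng = substream(seed, "noise")
    observed: dict[str, dict[str, int]] = {}
    for truth_c in truth.components:
        comp = truth_c.component
        row = {}
        for leaf_name in truth.topology.leaf_names:
            s = truth.true_states[comp][leaf_name]
            flip = rng.random() < (q if s == 1 else r)
            row[leaf_name] = (1 - s) if flip else s
        observed[comp] = row
    return replace(truth, observed_states=observed)


def states_to_matrix(
    states: Mapping[str, Mapping[str, int]], genomes: Sequence[str], provenance: str = "simulated"
) -> PresenceMatrix:
    comps = sorted(states)
    arr = np.array([[states[c][g] for g in genomes] for c in comps], dtype=np.int8)
    return PresenceMatrix(
        components=tuple(comps), genomes=tuple(genomes), states=arr, provenance=provenance
    )


# ---------------------------------------------------------------------------
# Sequence-level simulation
# ---------------------------------------------------------------------------

_AA = np.array(list(AMINO_ACIDS))


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_AA, size=length))


def simulate_seed_alignment(
    component: str,
    length: int,
    n_sequences: int,
    divergence: float,
    seed: int,
) -> SeedAlignment:
    """Synthetic ungapped family: an ancestral sequence plus diverged copies."""
    rng = substream(seed, f"seed-family:{component}")
    ancestor = _random_sequence(rng, length)
    seqs = []
    for _ in range(n_sequences):
        chars = list(ancestor)
        n_mut = int(round(divergence * length))
        for pos in rng.choice(length, size=n_mut, replace=False):
            chars[pos] = str(rng.choice(_AA))
        seqs.append("".join(chars))
    return SeedAlignment(component=component, sequences=tuple(seqs))


def mutate_sequence(
    sequence: str, substitution_fraction: float, indel_rate: float, rng: np.random.Generator
) -> str:
    """Substitute a fixed fraction of residues and add geometric(mean 2) indels."""
    chars = list(sequence)
    n_mut = int(round(substitution_fraction * len(chars)))
    if n_mut:
        for pos in rng.choice(len(chars), size=n_mut, replace=False):
            chars[pos] = str(rng.choice(_AA))
    out: list[str] = []
    i = 0
    while i < len(chars):
        if indel_rate and rng.random() < indel_rate:
            if rng.random() < 0.5:  # deletion of a geometric-length run
                i += int(rng.geometric(0.5))
                continue
            out.append("".join(rng.choice(_AA, size=int(rng.geometric(0.5)))))
        out.append(chars[i])
        i += 1
    mutated = "".join(out)
    return mutated if mutated else sequence[:1]


def _fg_decoy(rng: np.random.Generator, length: int) -> str:
    """FG-repeat-only sequence: >=30% FG dipeptide density, no homology."""
    blocks = []
    n = 0
    while n < length:
        kind = rng.random()
        if kind < 0.6:
            block = rng.choice(["FG", "FSFG", "GLFG", "FGFG"])
        else:
            block = "".join(rng.choice(np.array(list("STNQAP")), size=rng.integers(2, 5)))
        blocks.append(str(block))
        n += len(str(block))
    return "".join(blocks)[:length]


def _wd_decoy(rng: np.random.Generator, length: int, n_windows: int = 6) -> str:
    """Sequence whose only structure is planted WD-repeat windows."""
    window_len = max(20, length // max(n_windows, 1))
    parts = []
    for _ in range(n_windows):
        spacer_len = int(rng.integers(6, 13))
        core = (
            str(rng.choice(np.array(list("LIV"))))
            + _random_sequence(rng, spacer_len)
            + "WD"
        )
        pad = _random_sequence(rng, max(0, window_len - len(core)))
        parts.append(core + pad)
    return "".join(parts)[:length]


@dataclass(frozen=True)
class ProteomeTruth:
    """Identity of every simulated protein (planted homolog or decoy class)."""

    origins: Mapping[str, str]  # protein id -> component name | decoy class

    def planted(self) -> dict[str, str]:
        return {
            pid: origin
            for pid, origin in self.origins.items()
            if not origin.startswith("decoy")
        }


def simulate_proteome(
    seeds: Sequence[SeedAlignment],
    config: SimulationConfig,
    genome: str = "synthetic",
    present_components: set[str] | None = None,
) -> tuple[list[ProteinRecord], ProteomeTruth]:
    """One synthetic proteome: planted homologs plus three decoy classes."""
    rng = substream(config.seed, f"proteome:{genome}")
    records: list[ProteinRecord] = []
    origins: dict[str, str] = {}
    for seed_aln in seeds:
        if present_components is not None and seed_aln.component not in present_components:
            continue
        consensus = build_profile(seed_aln).consensus
        mutated = mutate_sequence(
            consensus, config.substitution_fraction, config.indel_rate, rng
        )
        pid = f"{genome}|planted|{seed_aln.component}"
        records.append(ProteinRecord(id=pid, genome=genome, sequence=mutated))
        origins[pid] = seed_aln.component
    pooled = "".join(build_profile(s).consensus for s in seeds) or "A"
    pool = np.array(list(pooled))
    for k in range(config.n_decoy_random):
        pid = f"{genome}|decoy_rand|{k + 1}"
        seq = "".join(rng.choice(pool, size=config.sequence_length))
        records.append(ProteinRecord(id=pid, genome=genome, sequence=seq))
        origins[pid] = "decoy_random"
    for k in range(config.n_decoy_fg):
        pid = f"{genome}|decoy_fg|{k + 1}"
        records.append(
            ProteinRecord(id=pid, genome=genome, sequence=_fg_decoy(rng, config.sequence_length))
        )
        origins[pid] = "decoy_fg"
    for k in range(config.n_decoy_wd):
        pid = f"{genome}|decoy_wd|{k + 1}"
        records.append(
            ProteinRecord(id=pid, genome=genome, sequence=_wd_decoy(rng, config.sequence_length))
        )
        origins[pid] = "decoy_wd"
    return records, ProteomeTruth(origins=origins)


@dataclass(frozen=True)
class ScreenBenchmark:
    """Planted-truth screen benchmark outcome."""

    n_planted: int
    n_decoys: int
    accepted_true: int
    accepted_false: int
    false_discovery_proportion: float
    threshold_bits: float


def screen_benchmark(
    seed: int,
    n_planted: int = 100,
    n_decoys_random: int = 300,
    n_decoys_fg: int = 100,
    n_decoys_wd: int = 100,
    profile_length: int = 100,
    substitutions: Sequence[float] = (0.2, 0.3, 0.4, 0.5),
    decoy_quantile: float = 0.99,
) -> ScreenBenchmark:
    """Screen planted homologs among decoys at a decoy-quantile threshold.

    One component family is simulated; ``n_planted`` homologs of its
    consensus are planted at the given substitution fractions (cycled),
    among composition-shuffled, FG-repeat-only and WD-repeat-only decoys.
    The threshold is the ``decoy_quantile`` of the decoys' own score
    distribution, and decisions then pass the repeat-vetting rules.  The
    false-discovery proportion is the fraction of accepted calls that are
    decoys.
    """
    rng = substream(seed, "benchmark")
    family = simulate_seed_alignment("bench", profile_length, 5, 0.1, seed)
    profile = build_profile(family)
    consensus = profile.consensus
    proteins: list[ProteinRecord] = []
    truth: dict[str, bool] = {}
    for k in range(n_planted):
        sub = substitutions[k % len(substitutions)]
        seq = mutate_sequence(consensus, sub, 0.01, rng)
        pid = f"planted|{k + 1}"
        proteins.append(ProteinRecord(id=pid, genome="bench", sequence=seq))
        truth[pid] = True
    pool = np.array(list(consensus))
    decoy_len = profile_length * 2
    for k in range(n_decoys_random):
        pid = f"decoy_rand|{k + 1}"
        proteins.append(
            ProteinRecord(id=pid, genome="bench", sequence="".join(rng.choice(pool, size=decoy_len)))
        )
        truth[pid] = False
    for k in range(n_decoys_fg):
        pid = f"decoy_fg|{k + 1}"
        proteins.append(ProteinRecord(id=pid, genome="bench", sequence=_fg_decoy(rng, decoy_len)))
        truth[pid] = False
    for k in range(n_decoys_wd):
        pid = f"decoy_wd|{k + 1}"
        proteins.append(ProteinRecord(id=pid, genome="bench", sequence=_wd_decoy(rng, decoy_len)))
        truth[pid] = False
    all_hits = screen_proteome([profile], proteins, -1e9)["bench"]
    decoy_scores = [h.score for h in all_hits if not truth[h.protein_id]]
    threshold = DecoyQuantileThreshold(decoy_quantile, decoy_scores).resolve("bench")
    kept = [h for h in all_hits if h.score >= threshold]
    sequences = {p.id: p.sequence for p in proteins}
    decisions = apply_vetting(kept, sequences)
    accepted = [d.hit.protein_id for d in decisions if d.status == "accepted"]
    true_calls = sum(1 for pid in accepted if truth[pid])
    false_calls = len(accepted) - true_calls
    fdp = false_calls / len(accepted) if accepted else 0.0
    return ScreenBenchmark(
        n_planted=n_planted,
        n_decoys=n_decoys_random + n_decoys_fg + n_decoys_wd,
        accepted_true=true_calls,
        accepted_false=false_calls,
        false_discovery_proportion=fdp,
        threshold_bits=threshold,
    )


# ---------------------------------------------------------------------------
# End-to-end scenario
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScenarioResult:
    config: SimulationConfig
    truth: SyntheticTruth
    observed_matrix: PresenceMatrix
    scorecard: Mapping[str, float] = field(default_factory=dict)

    def scorecard_text(self) -> str:
        return "\n".join(f"{k}\t{v:.6g}" for k, v in sorted(self.scorecard.items())) + "\n"


def end_to_end_scenario(config: SimulationConfig) -> ScenarioResult:
    """Simulate, reconstruct, and score the full pipeline against truth.

    When ``simulate_sequences`` is on, presence calls come from actually
    screening per-tip synthetic proteomes (planted homolog per truly present
    component plus decoys) with profiles built from the seed families;
    otherwise the observed matrix is the truth with detection noise applied.
    """
    topology = simulate_tree(config.n_leaves, config.seed)
    truth = simulate_dollo_evolution(topology, config)
    truth = apply_detection_noise(truth, config.q, config.r, config.seed)
    genomes = topology.leaf_names

    if config.simulate_sequences:
        comp_names = [c.component for c in truth.components]
        seeds = [
            simulate_seed_alignment(c, config.sequence_length, 5, 0.1, config.seed)
            for c in comp_names
        ]
        profiles = [build_profile(s) for s in seeds]
        decoy_rng = substream(config.seed, "threshold-decoys")
        pool = np.array(list("".join(p.consensus for p in profiles)))
        decoys = [
            ProteinRecord(
                id=f"null|{k}",
                genome="null",
                sequence="".join(decoy_rng.choice(pool, size=config.sequence_length)),
            )
            for k in range(100)
        ]
        decoy_scores = {
            p.component: [h.score for hits in screen_proteome([p], decoys, -1e9).values() for h in hits]
            for p in profiles
        }
        threshold = DecoyQuantileThreshold(0.99, decoy_scores)
        states: dict[str, dict[str, int]] = {c: {} for c in comp_names}
        for genome in genomes:
            present = {
                c.component
                for c in truth.components
                if truth.true_states[c.component][genome] == 1
            }
            proteome, _ = simulate_proteome(seeds, config, genome=genome, present_components=present)
            hits_by_comp = screen_proteome(profiles, proteome, threshold)
            sequences = {p.id: p.sequence for p in proteome}
            for comp in comp_names:
                decisions = apply_vetting(hits_by_comp[comp], sequences)
                states[comp][genome] = int(any(d.status == "accepted" for d in decisions))
        observed = states
    else:
        observed = {c: dict(s) for c, s in truth.observed_states.items()}

    matrix = states_to_matrix(observed, genomes)
    dollo = dollo_reconstruct(topology, observed)
    dollo = mark_ambiguous(topology, observed, dollo)

    true_leca = truth.root_present_components()
    inferred_leca = dollo.root_present()
    tp = len(true_leca & inferred_leca)
    recovered = 0
    eligible = 0
    cost_ok = 0
    for c in truth.components:
        ev = dollo[c.component]
        if ev.gain_edge is not None:
            eligible += 1
            if ev.gain_edge == c.gain_edge:
                recovered += 1
        if ev.cost <= c.n_events:
            cost_ok += 1
    scorecard = {
        "leca_true": float(len(true_leca)),
        "leca_inferred": float(len(inferred_leca)),
        "leca_recall": tp / len(true_leca) if true_leca else 1.0,
        "leca_precision": tp / len(inferred_leca) if inferred_leca else 1.0,
        "gain_edge_recovery": recovered / eligible if eligible else 1.0,
        "parsimony_cost_within_truth": cost_ok / len(truth.components),
    }
    return ScenarioResult(
        config=config, truth=truth, observed_matrix=matrix, scorecard=scorecard
    )
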