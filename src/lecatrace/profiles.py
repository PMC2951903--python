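"""Position-specific scoring profiles built from seed alignments.

A profile summarises a vetted seed alignment of a component family as one
log-odds score vector (in bits, against background amino-acid frequencies)
per match column.  Columns with more than 50% gap characters are treated as
insert columns and excluded from the match states.  Scoring a protein
aligns the profile to it with affine gap penalties, either over the
best-scoring local segment (``local`` mode) or requiring the full profile
to be consumed while the protein may be entered and left freely (``global``
mode).  Scores are directly comparable across proteins for a fixed profile;
they are not calibrated E-values.

The ambiguity code ``X`` scores zero bits (background) in every column.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import SeqIO

__all__ = [
    "AMINO_ACIDS",
    "BACKGROUND_FREQUENCIES",
    "SeedAlignment",
    "ScoringProfile",
    "ProteinRecord",
    "HitRecord",
    "DegenerateProfileError",
    "build_profile",
    "score_sequence",
    "read_seed_alignment",
    "read_fasta_proteome",
    "write_fasta",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
GAP = "-"

# Robinson & Robinson amino-acid background frequencies, ordered as AMINO_ACIDS.
BACKGROUND_FREQUENCIES = np.array(
    [
        0.07805, 0.01925, 0.05364, 0.06295, 0.03856, 0.07377, 0.02199,
        0.05142, 0.05744, 0.09019, 0.02243, 0.04487, 0.05203, 0.04264,
        0.05129, 0.07120, 0.05841, 0.06441, 0.01330, 0.03216,
    ]
)
BACKGROUND_FREQUENCIES = BACKGROUND_FREQUENCIES / BACKGROUND_FREQUENCIES.sum()


class DegenerateProfileError(ValueError):
    """Raised when an alignment yields no usable match columns."""


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence from an annotated proteome."""

    id: str
    genome: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.id!r}: empty sequence")
        bad = set(self.sequence.upper()) - set(AMINO_ACIDS) - {"X"}
        if bad:
            raise ValueError(f"protein {self.id!r}: invalid residues {sorted(bad)}")
        object.__setattr__(self, "sequence", self.sequence.upper())


@dataclass(frozen=True)
class SeedAlignment:
    """Aligned (equal-length, '-' gapped) seed sequences for one component."""

    component: str
    sequences: tuple[str, ...]
    sources: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        seqs = tuple(s.upper() for s in self.sequences)
        object.__setattr__(self, "sequences", seqs)
        object.__setattr__(self, "sources", tuple(self.sources) or ("",) * len(seqs))
        if not seqs:
            raise ValueError(f"{self.component}: seed alignment needs >=1 sequence")
        if len({len(s) for s in seqs}) != 1:
            raise ValueError(f"{self.component}: aligned rows differ in length")
        alphabet = set(AMINO_ACIDS) | {GAP, "X"}
        for s in seqs:
            bad = set(s) - alphabet
            if bad:
                raise ValueError(f"{self.component}: invalid alignment symbols {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.sequences[0])


@dataclass(frozen=True)
class ScoringProfile:
    """Log-odds scoring model over the match columns of a seed alignment."""

    component: str
    match_scores: np.ndarray  # (n_match_columns, 20) bits
    gap_open: np.ndarray  # (n_match_columns,) bits
    gap_extend: np.ndarray  # (n_match_columns,) bits
    background: np.ndarray  # (20,) probabilities
    mode: str = "local"
    match_columns: tuple[int, ...] = ()  # original alignment column indices
    consensus: str = ""

    def __post_init__(self) -> None:
        if self.mode not in ("local", "global"):
            raise ValueError(f"mode must be 'local' or 'global', got {self.mode!r}")
        if abs(float(self.background.sum()) - 1.0) > 1e-9:
            raise ValueError("background frequencies must sum to 1")
        if not np.isfinite(self.match_scores).all():
            raise ValueError("profile scores must be finite")

    @property
    def length(self) -> int:
        return self.match_scores.shape[0]

    def max_score(self) -> float:
        """Best achievable (gap-free) score: sum of per-column maxima."""
        return float(self.match_scores.max(axis=1).sum())


@dataclass(frozen=True)
class HitRecord:
    """Best-scoring placement of a profile on a protein."""

    protein_id: str
    component: str
    score: float  # bits
    interval: tuple[int, int]  # 0-based half-open on the protein
    match_positions: tuple[tuple[int, int], ...] = ()  # (profile column, seq position)

    def __post_init__(self) -> None:
        if not np.isfinite(self.score):
            raise ValueError("hit score must be finite")
        if self.interval[0] > self.interval[1] or self.interval[0] < 0:
            raise ValueError(f"invalid interval {self.interval}")

    @property
    def matched_sequence_positions(self) -> tuple[int, ...]:
        return tuple(p for _, p in self.match_positions)


def build_profile(
    seed: SeedAlignment,
    mode: str = "local",
    pseudocount_weight: float = 1.0,
    gap_open: float = 4.0,
    gap_extend: float = 0.5,
) -> ScoringProfile:
    """Turn a seed alignment into a position-specific log-odds profile.

    Column residue frequencies are mixed with the background using a fixed
    pseudocount weight (default 1.0 background-distributed observation per
    column), which keeps every log-odds score finite.  Gap penalties are
    uniform across columns and expressed in bits.
    """
    if pseudocount_weight < 0:
        raise ValueError("pseudocount_weight must be nonnegative")
    columns = []
    kept = []
    n = len(seed.sequences)
    for j in range(seed.length):
        col = [s[j] for s in seed.sequences]
        if col.count(GAP) / n > 0.5:
            continue  # insert column
        counts = np.zeros(20)
        for r in col:
            if r in _AA_INDEX:
                counts[_AA_INDEX[r]] += 1.0
            elif r == "X":  # spread an ambiguous residue over the background
                counts += BACKGROUND_FREQUENCIES
        total = counts.sum()
        freqs = (counts + pseudocount_weight * BACKGROUND_FREQUENCIES) / (
            total + pseudocount_weight
        )
        columns.append(np.log2(freqs / BACKGROUND_FREQUENCIES))
        kept.append(j)
    if not columns:
        raise DegenerateProfileError(
            f"{seed.component}: no match columns (every column >50% gaps)"
        )
    match_scores = np.array(columns)
    consensus = "".join(AMINO_ACIDS[k] for k in match_scores.argmax(axis=1))
    L = len(kept)
    return ScoringProfile(
        component=seed.component,
        match_scores=match_scores,
        gap_open=np.full(L, float(gap_open)),
        gap_extend=np.full(L, float(gap_extend)),
        background=BACKGROUND_FREQUENCIES.copy(),
        mode=mode,
        match_columns=tuple(kept),
        consensus=consensus,
    )


def _residue_scores(profile: ScoringProfile, sequence: str) -> np.ndarray:
    """(len(sequence), L) match scores; 'X' scores 0 in every column."""
    L = profile.length
    out = np.zeros((len(sequence), L))
    for i, r in enumerate(sequence):
        if r in _AA_INDEX:
            out[i] = profile.match_scores[:, _AA_INDEX[r]]
    return out


_NEG = -1e30
_TOL = 1e-9


def score_sequence(profile: ScoringProfile, protein: ProteinRecord) -> HitRecord:
    """Align ``profile`` to ``protein`` and return the best-scoring placement.

    Alignments are canonical: they start and end on a match state (in global
    mode, flanking profile columns may additionally be skipped at gap cost),
    and an insertion is never adjacent to a deletion.  Local mode maximises
    over all segments and returns an empty zero-score hit when no segment
    scores positive; global mode requires every profile column to be
    consumed.  Ties are broken toward the leftmost interval start, then the
    shortest interval.
    """
    seq = protein.sequence
    N, L = len(seq), profile.length
    S = _residue_scores(profile, seq)
    open_, ext = float(profile.gap_open[0]), float(profile.gap_extend[0])
    local = profile.mode == "local"

    # M[i, j]: best alignment ending with residue i matched to column j.
    # Ix[i, j]: ending with residue i inserted after column j was consumed.
    # Iy[i, j]: ending with column j deleted, residue i consumed last.
    # St*: leftmost interval start achieving the state's best score.
    M = np.full((N, L), _NEG)
    Ix = np.full((N, L), _NEG)
    Iy = np.full((N, L), _NEG)
    StM = np.zeros((N, L), dtype=np.int32)
    StIx = np.zeros((N, L), dtype=np.int32)
    StIy = np.zeros((N, L), dtype=np.int32)

    # Entry score for starting a fresh alignment at column j (before scoring
    # the matched residue).  Local alignments may begin at any column free of
    # charge; global alignments pay for skipping columns 0..j-1.
    if local:
        entry = np.zeros(L)
    else:
        entry = np.concatenate(([0.0], -(open_ + ext * np.arange(L - 1))))

    for i in range(N):
        # match state: best of continuing from (i-1, j-1) or starting fresh
        val = entry.copy()
        start = np.full(L, i, dtype=np.int32)
        if i > 0:
            for prev, st in ((M, StM), (Ix, StIx), (Iy, StIy)):
                pv = np.full(L, _NEG)
                ps = np.zeros(L, dtype=np.int32)
                pv[1:] = prev[i - 1, :-1]
                ps[1:] = st[i - 1, :-1]
                better = pv > val + _TOL
                tie = np.abs(pv - val) <= _TOL
                start = np.where(better | (tie & (ps < start)), ps, start)
                val = np.maximum(val, pv)
        M[i] = S[i] + val
        StM[i] = start

        # insertion state (gap in profile): extends M or Ix from row i-1
        if i > 0:
            from_m = M[i - 1] - open_
            from_ix = Ix[i - 1] - ext
            Ix[i] = np.maximum(from_m, from_ix)
            StIx[i] = np.where(
                (from_m > from_ix + _TOL)
                | ((np.abs(from_m - from_ix) <= _TOL) & (StM[i - 1] <= StIx[i - 1])),
                StM[i - 1],
                StIx[i - 1],
            )

        # deletion state (gap in sequence): within-row scan over columns
        best = _NEG
        bstart = 0
        for j in range(1, L):
            opened = M[i, j - 1] - open_
            extended = best - ext
            if opened > extended + _TOL or (
                abs(opened - extended) <= _TOL and StM[i, j - 1] < bstart
            ):
                best, bstart = opened, StM[i, j - 1]
            else:
                best = extended
            Iy[i, j] = best
            StIy[i, j] = bstart

    if local:
        best_score = float(M.max()) if M.size else 0.0
        if best_score <= _TOL:
            return HitRecord(protein.id, profile.component, 0.0, (0, 0), ())
        final = M
        ends = np.argwhere(final >= best_score - _TOL)
        starts = StM
    else:
        # trailing deletion cost for ending the match phase at column j
        trail = np.concatenate((-(open_ + ext * np.arange(L - 1))[::-1], [0.0]))
        final = M + trail
        best_score = float(final.max())
        ends = np.argwhere(final >= best_score - _TOL)
        starts = StM

    # leftmost start, then shortest interval
    cells = sorted(
        ((int(starts[i, j]), int(i), int(j)) for i, j in ends),
        key=lambda c: (c[0], c[1]),
    )
    _, ei, ej = cells[0]
    matches = _traceback(ei, ej, M, Ix, Iy, S, entry, open_, ext)
    start_pos = matches[0][1]
    return HitRecord(
        protein_id=protein.id,
        component=profile.component,
        score=round(best_score, 9),
        interval=(start_pos, ei + 1),
        match_positions=tuple(matches),
    )


def _traceback(i, j, M, Ix, Iy, S, entry, open_, ext):
    """Recover the matched (column, residue) pairs ending at M[i, j]."""
    matches: list[tuple[int, int]] = []
    state = "M"
    while True:
        if state == "M":
            matches.append((j, i))
            base = M[i, j] - S[i, j]
            if i > 0 and j > 0 and abs(base - M[i - 1, j - 1]) <= _TOL:
                i, j = i - 1, j - 1
            elif i > 0 and j > 0 and abs(base - Iy[i - 1, j - 1]) <= _TOL:
                i, j, state = i - 1, j - 1, "Iy"
            elif i > 0 and j > 0 and abs(base - Ix[i - 1, j - 1]) <= _TOL:
                i, j, state = i - 1, j - 1, "Ix"
            else:  # fresh start (entry[j] by construction)
                break
        elif state == "Ix":
            if abs(Ix[i, j] - (M[i - 1, j] - open_)) <= _TOL:
                i, state = i - 1, "M"
            else:
                i, state = i - 1, "Ix"
        else:  # Iy
            if abs(Iy[i, j] - (M[i, j - 1] - open_)) <= _TOL:
                j, state = j - 1, "M"
            else:
                j = j - 1
    matches.reverse()
    return matches


# ---------------------------------------------------------------------------
# FASTA plumbing
# ---------------------------------------------------------------------------


def read_seed_alignment(path, component: str | None = None) -> SeedAlignment:
    """Read an aligned FASTA file as a seed alignment.

    The component name defaults to the file stem; per-sequence source
    genomes are taken from the description after the id when present.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no sequences")
    return SeedAlignment(
        component=component or path.stem,
        sequences=tuple(str(r.seq) for r in records),
        sources=tuple(r.description.split()[1] if len(r.description.split()) > 1 else "" for r in records),
    )


def read_fasta_proteome(path, genome: str | None = None) -> list[ProteinRecord]:
    path = Path(path)
    genome = genome or path.stem
    return [
        ProteinRecord(id=r.id, genome=genome, sequence=str(r.seq))
        for r in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(records, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for r in records:
            fh.write(f">{r.id} {r.genome}\n")
            seq = r.sequence
            for k in range(0, len(seq), 60):
                fh.write(seq[k : k + 60] + "\n")
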