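"""Independent brute-force oracles used by the test suite.

These deliberately avoid the implementation's algorithms: alignment scoring
enumerates gap *runs* top-down instead of running a three-state Gotoh
recursion, and parsimony enumerates every internal-state assignment instead
of dynamic programming on the tree.
"""

from functools import lru_cache
from itertools import product


# ---------------------------------------------------------------------------
# Alignment-path oracle
# ---------------------------------------------------------------------------


def best_alignment_score(S, gap_open, gap_extend, mode="local"):
    """Best canonical alignment score of a profile (columns) to a sequence.

    ``S[i][j]`` is the score of matching residue ``i`` to profile column
    ``j``.  Canonical alignments start and end on a match; a run of ``c``
    gaps costs ``gap_open + gap_extend * (c - 1)``; insertions are never
    adjacent to deletions.  Local mode scores the best segment (>= 0 via
    the empty alignment); global mode charges for skipped profile columns
    at both ends.
    """
    N = len(S)
    L = len(S[0]) if N else 0

    def gap(c):
        return gap_open + gap_extend * (c - 1)

    @lru_cache(maxsize=None)
    def after(i, j):
        """Best continuation after a match at (i, j), excluding its score."""
        if mode == "local":
            best = 0.0
        else:
            c = L - 1 - j
            best = 0.0 if c == 0 else -gap(c)
        if i + 1 < N and j + 1 < L:
            best = max(best, S[i + 1][j + 1] + after(i + 1, j + 1))
        for c in range(1, N - 1 - i):  # insertion run, then a match
            ii = i + c + 1
            if ii < N and j + 1 < L:
                best = max(best, -gap(c) + S[ii][j + 1] + after(ii, j + 1))
        for c in range(1, L - 1 - j):  # deletion run, then a match
            jj = j + c + 1
            if i + 1 < N and jj < L:
                best = max(best, -gap(c) + S[i + 1][jj] + after(i + 1, jj))
        return best

    best = 0.0 if mode == "local" else float("-inf")
    for i in range(N):
        for j in range(L):
            if mode == "local":
                entry = 0.0
            else:
                entry = 0.0 if j == 0 else -gap(j)
            best = max(best, entry + S[i][j] + after(i, j))
    return best


# ---------------------------------------------------------------------------
# Binary-character parsimony oracles
# ---------------------------------------------------------------------------


def _assignments(tree, tip_states):
    """Yield dicts node-id -> state over all internal assignments."""
    nodes = list(tree.postorder())
    internals = [n for n in nodes if not n.is_leaf]
    base = {id(n): tip_states[n.label] for n in nodes if n.is_leaf}
    for bits in product((0, 1), repeat=len(internals)):
        assign = dict(base)
        for n, b in zip(internals, bits):
            assign[id(n)] = b
        yield assign


def _count_events(tree, assign):
    """(root state, gains-on-tree-edges, losses) for one assignment."""
    gains = losses = 0
    for node in tree.postorder():
        for child in node.children:
            a, b = assign[id(node)], assign[id(child)]
            if a == 0 and b == 1:
                gains += 1
            elif a == 1 and b == 0:
                losses += 1
    return assign[id(tree)], gains, losses


def dollo_min_cost(tree, tip_states):
    """Minimal cost over single-origin mappings: 1 gain (root birth counts
    as the gain) plus losses."""
    best = None
    for assign in _assignments(tree, tip_states):
        root, gains, losses = _count_events(tree, assign)
        total_gains = gains + (1 if root == 1 else 0)
        if total_gains != 1:
            continue
        cost = 1 + losses
        if best is None or cost < best:
            best = cost
    return best


def unrestricted_min_changes(tree, tip_states, root_state):
    """Minimal number of edge state-changes with the root state fixed."""
    best = None
    for assign in _assignments(tree, tip_states):
        root, gains, losses = _count_events(tree, assign)
        if root != root_state:
            continue
        cost = gains + losses
        if best is None or cost < best:
            best = cost
    return best


# ---------------------------------------------------------------------------
# Exact 2x2 conditional test oracle
# ---------------------------------------------------------------------------


def exact_two_sided_p(a, b, c, d):
    """Sum of margin-preserving table probabilities <= the observed one."""
    from math import comb

    n = a + b + c + d
    r1, c1 = a + b, a + c

    def prob(x):
        if x < 0 or x > c1 or r1 - x < 0 or r1 - x > n - c1:
            return 0.0
        return comb(c1, x) * comb(n - c1, r1 - x) / comb(n, r1)

    p_obs = prob(a)
    return sum(prob(x) for x in range(0, min(r1, c1) + 1) if prob(x) <= p_obs * (1 + 1e-9))
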