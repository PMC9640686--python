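"""Independent brute-force oracles used to verify the implementation.

These are deliberately naive reference implementations (full-matrix
dynamic programming, DFS, exhaustive enumeration, textbook formulas)
kept free of any code from the package under test.
"""

from __future__ import annotations

import itertools
from collections import defaultdict

import numpy as np
from Bio.Align import substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")
NEG_INF = float("-inf")


def sw_gotoh(
    a: str, b: str, open_gap: float = -11.0, extend_gap: float = -1.0
) -> tuple[float, float, float, float, int] | None:
    """Full-matrix Smith-Waterman with affine gaps (Gotoh), with traceback.

    ``open_gap`` is the score of the first gap column, ``extend_gap``
    of each subsequent one.  Returns (score, percent_identity,
    a_coverage, b_coverage, alignment_length) of one optimal local
    alignment, identity over all alignment columns including gaps, or
    None when no positive-scoring alignment exists.
    """
    a = a.upper().translate(str.maketrans("UOJ", "XXX"))
    b = b.upper().translate(str.maketrans("UOJ", "XXX"))
    n, m = len(a), len(b)
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG_INF] * (m + 1) for _ in range(n + 1)]  # gap in a (consumes b)
    F = [[NEG_INF] * (m + 1) for _ in range(n + 1)]  # gap in b (consumes a)
    best, bi, bj = 0.0, 0, 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] + open_gap, E[i][j - 1] + extend_gap)
            F[i][j] = max(H[i - 1][j] + open_gap, F[i - 1][j] + extend_gap)
            sub = _BLOSUM62[a[i - 1], b[j - 1]]
            H[i][j] = max(0.0, H[i - 1][j - 1] + sub, E[i][j], F[i][j])
            if H[i][j] > best:
                best, bi, bj = H[i][j], i, j
    if best <= 0:
        return None
    # traceback
    i, j, state = bi, bj, "H"
    matches = columns = 0
    end_i, end_j = bi, bj
    while True:
        if state == "H":
            if H[i][j] == 0:
                break
            sub = _BLOSUM62[a[i - 1], b[j - 1]]
            if H[i][j] == H[i - 1][j - 1] + sub:
                columns += 1
                if a[i - 1] == b[j - 1]:
                    matches += 1
                i, j = i - 1, j - 1
            elif H[i][j] == E[i][j]:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            columns += 1
            if E[i][j] == H[i][j - 1] + open_gap:
                state = "H"
            j -= 1
        else:
            columns += 1
            if F[i][j] == H[i - 1][j] + open_gap:
                state = "H"
            i -= 1
    a_span, b_span = end_i - i, end_j - j
    return (
        best,
        100.0 * matches / columns,
        a_span / n,
        b_span / m,
        columns,
    )


def pairwise_identity(a: str, b: str) -> float:
    """Identity of the DP-oracle optimal local alignment, as a fraction."""
    result = sw_gotoh(a, b)
    if result is None:
        return 0.0
    return result[1] / 100.0


def dfs_components(nodes, edges) -> list[frozenset]:
    """Connected components by explicit depth-first search."""
    adjacency = defaultdict(set)
    for u, v in edges:
        adjacency[u].add(v)
        adjacency[v].add(u)
    seen: set = set()
    components = []
    for start in nodes:
        if start in seen:
            continue
        stack, comp = [start], set()
        while stack:
            node = stack.pop()
            if node in comp:
                continue
            comp.add(node)
            stack.extend(adjacency[node] - comp)
        seen |= comp
        components.append(frozenset(comp))
    return components


def exhaustive_accumulation(presence: dict[str, set[str]], soft_fraction: float = 0.95):
    """Accumulation statistics over *all* genome orderings.

    ``presence`` maps genome id -> set of group ids it holds.  Returns
    {ordering: [(pan_k, strict_k, soft_k) for k=1..N]}.
    """
    genomes = sorted(presence)
    out = {}
    for ordering in itertools.permutations(genomes):
        counts: dict[str, int] = defaultdict(int)
        row = []
        for k, genome in enumerate(ordering, start=1):
            for group in presence[genome]:
                counts[group] += 1
            pan = len(counts)
            strict = sum(1 for c in counts.values() if c == k)
            soft = sum(1 for c in counts.values() if c / k >= soft_fraction)
            row.append((pan, strict, soft))
        out[ordering] = row
    return out


def spearman_rho(x, y) -> float:
    """Spearman correlation via the rank formula (average ranks for ties)."""

    def ranks(values):
        order = np.argsort(values, kind="stable")
        r = np.empty(len(values), dtype=float)
        i = 0
        sorted_vals = np.asarray(values)[order]
        while i < len(values):
            j = i
            while j + 1 < len(values) and sorted_vals[j + 1] == sorted_vals[i]:
                j += 1
            avg = (i + j) / 2 + 1
            for k in range(i, j + 1):
                r[order[k]] = avg
            i = j + 1
        return r

    rx, ry = ranks(x), ranks(y)
    rx -= rx.mean()
    ry -= ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx**2).sum() * (ry**2).sum()))


def tally_profile(protein_labels, protein_bin) -> dict[str, dict[int, int]]:
    """Brute-force label -> bin -> protein-count tally."""
    out: dict[str, dict[int, int]] = {}
    for protein_id, label in protein_labels:
        b = protein_bin[protein_id]
        out.setdefault(label, {}).setdefault(b, 0)
        out[label][b] += 1
    return out
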