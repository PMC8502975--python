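"""Independent reference implementations used only to check the package.

These deliberately avoid the package's own code paths: the alignment
oracle is a plain full-matrix dynamic program, the curve oracle enumerates
orderings with Python sets, and the tree oracle scores all topologies by
least squares.
"""

from __future__ import annotations

from itertools import permutations

import numpy as np
from scipy.optimize import nnls


def naive_local_affine_score(a: str, b: str, score, gap_open: float,
                             gap_extend: float) -> float:
    """Smith-Waterman with affine gaps, full O(nm) matrices, no shortcuts.

    ``score(x, y)`` is the substitution score; a gap of length L costs
    gap_open + L * gap_extend. Returns the optimal local alignment score
    (0 if no positive-scoring alignment exists).
    """
    n, m = len(a), len(b)
    neg = float("-inf")
    open_cost = gap_open + gap_extend
    h_prev = [0.0] * (m + 1)
    e_prev = [neg] * (m + 1)
    best = 0.0
    for i in range(1, n + 1):
        h_cur = [0.0] * (m + 1)
        e_cur = [neg] * (m + 1)
        f = neg
        ai = a[i - 1]
        for j in range(1, m + 1):
            e_cur[j] = max(h_prev[j] - open_cost, e_prev[j] - gap_extend)
            f = max(h_cur[j - 1] - open_cost, f - gap_extend)
            h = max(0.0, h_prev[j - 1] + score(ai, b[j - 1]), e_cur[j], f)
            h_cur[j] = h
            if h > best:
                best = h
        h_prev, e_prev = h_cur, e_cur
    return best


def naive_curve_medians(presence_rows: list[list[bool]]):
    """Exhaustive pan/core/new medians over all strain orderings.

    ``presence_rows`` is families x strains booleans. Returns three lists
    of per-depth medians computed with Python sets and statistics.median.
    """
    import statistics

    n_strains = len(presence_rows[0])
    fam_strains = [
        {s for s in range(n_strains) if row[s]} for row in presence_rows
    ]
    pan_vals = [[] for _ in range(n_strains)]
    core_vals = [[] for _ in range(n_strains)]
    new_vals = [[] for _ in range(n_strains)]
    for order in permutations(range(n_strains)):
        seen_prefix = set()
        prev_pan = 0
        for depth in range(n_strains):
            seen_prefix.add(order[depth])
            pan = sum(1 for fs in fam_strains if fs & seen_prefix)
            core = sum(1 for fs in fam_strains if seen_prefix <= fs)
            pan_vals[depth].append(pan)
            core_vals[depth].append(core)
            new_vals[depth].append(pan - prev_pan)
            prev_pan = pan
    med = statistics.median
    return ([med(v) for v in pan_vals], [med(v) for v in core_vals],
            [med(v) for v in new_vals])


_QUARTET_TOPOLOGIES = [
    ((0, 1), (2, 3)),
    ((0, 2), (1, 3)),
    ((0, 3), (1, 2)),
]


def best_quartet_by_least_squares(d: np.ndarray):
    """Fit all three 4-taxon topologies by non-negative least squares.

    Edge order: four terminal branches then the internal branch. Returns
    (topology as pair of cherries, branch lengths, rss) for the best fit.
    """
    pairs = [(i, j) for i in range(4) for j in range(i + 1, 4)]
    y = np.array([d[i, j] for i, j in pairs])
    best = None
    for topo in _QUARTET_TOPOLOGIES:
        (a, b), (c, e) = topo
        rows = []
        for i, j in pairs:
            row = [0.0] * 5
            row[i] += 1.0
            row[j] += 1.0
            # internal branch used iff i and j are in different cherries
            same_cherry = ({i, j} == {a, b}) or ({i, j} == {c, e})
            if not same_cherry:
                row[4] = 1.0
            rows.append(row)
        design = np.array(rows)
        lengths, _ = nnls(design, y)
        rss = float(np.sum((design @ lengths - y) ** 2))
        if best is None or rss < best[2]:
            best = (topo, lengths, rss)
    return best
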