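"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the package's own code paths: chord
extraction uses ``itertools.groupby`` per line, clustering uses an O(n^2)
pure-python union-find, and the exact-test oracle enumerates label
assignments literally.  They exist to check the vectorized implementations
against first principles on small inputs.
"""

from itertools import combinations, groupby

import numpy as np
import pytest


def groupby_chords(line, pixel_size_um, min_chord_um):
    """Air-chord lengths (um) of one boolean tissue line, via groupby.

    Runs touching either end of the line are discarded, then runs shorter
    than ``min_chord_um`` are discarded.
    """
    lengths = []
    pos = 0
    runs = [(k, sum(1 for _ in g)) for k, g in groupby(bool(v) for v in line)]
    for i, (is_tissue, n) in enumerate(runs):
        if not is_tissue and 0 < i < len(runs) - 1:
            lengths.append(n * pixel_size_um)
        pos += n
    return [v for v in lengths if v >= min_chord_um]


def oracle_chord_multiset(mask, pixel_size_um, orientation="horizontal",
                          spacing_px=1, min_chord_um=10.0):
    """All chords of a mask at the given line spacing, one line at a time."""
    mask = np.asarray(mask, dtype=bool)
    if orientation == "vertical":
        mask = mask.T
    out = []
    for r in range(spacing_px // 2, mask.shape[0], spacing_px):
        out.extend(groupby_chords(mask[r], pixel_size_um, min_chord_um))
    return sorted(out)


class UnionFind:
    def __init__(self, n):
        self.parent = list(range(n))

    def find(self, i):
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i, j):
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def brute_force_clusters(points, radius):
    """All-pairs single-linkage components as frozensets of point indices."""
    points = np.asarray(points, dtype=float)
    n = len(points)
    uf = UnionFind(n)
    for i in range(n):
        for j in range(i + 1, n):
            if np.hypot(*(points[i] - points[j])) <= radius:
                uf.union(i, j)
    comps = {}
    for i in range(n):
        comps.setdefault(uf.find(i), set()).add(i)
    return {frozenset(c) for c in comps.values()}


def mann_whitney_oracle_p(x, y):
    """Two-sided exact Mann-Whitney p by literal label-assignment counting.

    U is computed by pairwise comparison counting (ties count 1/2), with no
    rank arithmetic, over every split of the pooled values.
    """
    x, y = list(x), list(y)
    pooled = x + y
    n1, n = len(x), len(x) + len(y)

    def u_stat(ix):
        ix = set(ix)
        xs = [pooled[i] for i in ix]
        ys = [pooled[i] for i in range(n) if i not in ix]
        return sum(1.0 if a > b else 0.5 if a == b else 0.0
                   for a in xs for b in ys)

    u_obs = u_stat(range(n1))
    us = [u_stat(c) for c in combinations(range(n), n1)]
    lo = sum(u <= u_obs + 1e-9 for u in us) / len(us)
    hi = sum(u >= u_obs - 1e-9 for u in us) / len(us)
    return min(1.0, 2.0 * min(lo, hi))


@pytest.fixture(scope="session")
def foam_section():
    """One medium foam phantom shared across tests (expensive to build)."""
    from emphyquant.synthetic import generate_alveolar_section

    section, truth = generate_alveolar_section(
        "voronoi_foam", size_px=1024, pixel_size_um=2.0, seed=42)
    return section, truth
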