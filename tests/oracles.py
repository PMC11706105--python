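"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library's own code paths: the scoring oracle
is a plain loop over dictionaries, and the clustering oracle is a naive
agglomerator that rescans every pair distance at each step using the
Lance-Williams Ward update on squared distances.
"""

from __future__ import annotations

import itertools

import numpy as np


def brute_force_rs(profile: dict[str, float], drug: dict[str, float]) -> float:
    denom = sum(abs(v) for v in profile.values())
    rs = 0.0
    for gene, p in profile.items():
        if gene in drug and drug[gene] * p < 0:
            rs += abs(drug[gene] - p) * abs(p) / denom
    return rs


def brute_force_oc(profile: dict[str, float], drug: dict[str, float]) -> tuple[float, int, int]:
    a = sum(1 for gene, p in profile.items() if gene in drug and drug[gene] * p < 0)
    g = len(profile)
    return a / g, a, g


def brute_force_ward(D: np.ndarray, k: int) -> tuple[list[float], list[set[int]]]:
    """Naive Ward agglomeration from a condensed-to-square distance matrix.

    Maintains squared inter-cluster distances and, at each step, rescans all
    pairs for the minimum, merging with the Lance-Williams Ward update:

        d(i+j, h)^2 = ((n_i+n_h) d(i,h)^2 + (n_j+n_h) d(j,h)^2
                       - n_h d(i,j)^2) / (n_i + n_j + n_h)

    Returns the sequence of merge heights (sqrt of the merged squared
    distance) and the partition (as sets of original column indices) after
    cutting at k clusters.
    """
    n = D.shape[0]
    clusters: dict[int, set[int]] = {i: {i} for i in range(n)}
    d2 = {(i, j): float(D[i, j]) ** 2 for i, j in itertools.combinations(range(n), 2)}
    heights: list[float] = []
    partition_at_k: list[set[int]] | None = None
    next_id = n
    while len(clusters) > 1:
        if len(clusters) == k:
            partition_at_k = [set(m) for m in clusters.values()]
        (i, j), best = min(d2.items(), key=lambda kv: (kv[1], kv[0]))
        heights.append(float(np.sqrt(best)))
        ni, nj = len(clusters[i]), len(clusters[j])
        merged = clusters.pop(i) | clusters.pop(j)
        new_d2 = {}
        for h, members in clusters.items():
            nh = len(members)
            dih = d2[(min(i, h), max(i, h))]
            djh = d2[(min(j, h), max(j, h))]
            new_d2[(h, next_id)] = ((ni + nh) * dih + (nj + nh) * djh - nh * best) / (ni + nj + nh)
        d2 = {p: v for p, v in d2.items() if i not in p and j not in p}
        d2.update(new_d2)
        clusters[next_id] = merged
        next_id += 1
    if partition_at_k is None:  # k == 1
        partition_at_k = [set(m) for m in clusters.values()]
    return heights, partition_at_k


def partitions_equal(p1: list[set[int]], p2: list[set[int]]) -> bool:
    return sorted(map(sorted, p1)) == sorted(map(sorted, p2))
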