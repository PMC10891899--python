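"""Independent brute-force oracles shared by the test modules."""

import itertools

import numpy as np


def exhaustive_ward(D):
    """Dictionary-based Lance-Williams agglomeration for tiny instances.

    Tracks every pairwise squared distance explicitly and merges the closest
    pair until one cluster remains; no index bookkeeping shared with the
    implementation under test.
    """
    D = D.astype(float) ** 2
    clusters = {i: 1 for i in range(D.shape[0])}
    dist = {frozenset((i, j)): D[i, j] for i, j in itertools.combinations(range(D.shape[0]), 2)}
    merges = []
    next_id = D.shape[0]
    while len(clusters) > 1:
        pair = min(dist, key=lambda p: (dist[p], tuple(sorted(p))))
        i, j = sorted(pair)
        h = float(np.sqrt(dist[pair]))
        ni, nj = clusters[i], clusters[j]
        merges.append((i, j, h, ni + nj))
        new_dist = {}
        for k in clusters:
            if k in (i, j):
                continue
            nk = clusters[k]
            dik = dist[frozenset((i, k))]
            djk = dist[frozenset((j, k))]
            new_dist[k] = ((ni + nk) * dik + (nj + nk) * djk - nk * dist[pair]) / (ni + nj + nk)
        del clusters[i], clusters[j]
        dist = {p: v for p, v in dist.items() if not (p & {i, j})}
        for k, v in new_dist.items():
            dist[frozenset((next_id, k))] = v
        clusters[next_id] = ni + nj
        next_id += 1
    return merges


def random_distance_matrix(rng, n, dim=3):
    """Euclidean distance matrix of n random points."""
    pts = rng.normal(size=(n, dim))
    return np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
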