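"""Independent, deliberately naive re-implementations used as test oracles.

These follow the published greedy atomize/agglomerate rule step by step
with plain Python loops and recompute every quantity from scratch at each
step.  They share no code with the package so that agreement between the
two is informative.
"""

import numpy as np


def pearson(a, b):
    a = a - np.mean(a)
    b = b - np.mean(b)
    return float(np.sum(a * b) / np.sqrt(np.sum(a * a) * np.sum(b * b)))


def principal_centroid(member_maps, first_member):
    """Dominant eigenvector of sum of outer products, oriented to the first
    member, unit-norm and mean-free."""
    S = np.zeros((member_maps.shape[1], member_maps.shape[1]))
    for v in member_maps:
        S += np.outer(v, v)
    vals, vecs = np.linalg.eigh(S)
    w = vecs[:, np.argmax(vals)]
    w = w - np.mean(w)
    w = w / np.linalg.norm(w)
    if pearson(w, first_member) < 0:
        w = -w
    return w


def aahc_oracle(maps, K):
    """Greedy AAHC replayed naively; returns (assignment, centroids, gev).

    assignment[i] is the cluster id of map i, with clusters renumbered by
    descending GEV contribution (ties by lowest member index) to match the
    package's presentation order.
    """
    maps = np.asarray(maps, dtype=float)
    n = len(maps)
    gfps = np.array([np.std(m) for m in maps])
    denom = float(np.sum(gfps ** 2))

    clusters = [[i] for i in range(n)]

    def centroid_of(idx):
        idx = sorted(idx)
        if len(idx) == 1:
            m = maps[idx[0]] - np.mean(maps[idx[0]])
            return m / np.linalg.norm(m)
        first = maps[idx[0]] - np.mean(maps[idx[0]])
        first = first / np.linalg.norm(first)
        return principal_centroid(maps[idx], first)

    def contribution_of(idx):
        w = centroid_of(idx)
        total = 0.0
        for i in idx:
            total += (gfps[i] * abs(pearson(maps[i], w))) ** 2
        return total

    while len(clusters) > K:
        contribs = [contribution_of(c) for c in clusters]
        worst = int(np.argmin(contribs))
        orphans = clusters.pop(worst)
        survivors_w = [centroid_of(c) for c in clusters]
        for o in orphans:
            rs = [abs(pearson(maps[o], w)) for w in survivors_w]
            clusters[int(np.argmax(rs))].append(o)
        clusters = [sorted(c) for c in clusters]

    contribs = [contribution_of(c) for c in clusters]
    order = sorted(range(len(clusters)), key=lambda c: (-contribs[c], clusters[c][0]))
    assignment = np.empty(n, dtype=int)
    centroids = []
    for new_id, c in enumerate(order):
        for i in clusters[c]:
            assignment[i] = new_id
        centroids.append(centroid_of(clusters[c]))
    gev = float(sum(contribs)) / denom
    return assignment, np.array(centroids), gev


def tanova_between_oracle(maps_a, maps_b):
    """Exhaustive between-subject TANOVA by explicit enumeration."""
    from itertools import combinations

    X = np.vstack([maps_a, maps_b])
    n1 = len(maps_a)

    def stat(idx_a):
        idx_a = set(idx_a)
        A = np.array([X[i] for i in sorted(idx_a)])
        B = np.array([X[i] for i in range(len(X)) if i not in idx_a])
        ma, mb = A.mean(axis=0), B.mean(axis=0)
        ua = (ma - ma.mean()) / ma.std()
        ub = (mb - mb.mean()) / mb.std()
        return float(np.sqrt(np.mean((ua - ub) ** 2)))

    observed = stat(range(n1))
    stats = [stat(c) for c in combinations(range(len(X)), n1)]
    p = np.mean([s >= observed - 1e-15 for s in stats])
    return observed, float(p), len(stats)
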