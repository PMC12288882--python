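"""Independent brute-force oracles shared across test modules."""

import numpy as np

NOISE = -1


def brute_wcss(expr, labels):
    total = 0.0
    for lab in set(labels):
        members = [i for i, l in enumerate(labels) if l == lab]
        mu = expr[members].mean(axis=0)
        for i in members:
            total += float(((expr[i] - mu) ** 2).sum())
    return total


def brute_dbscan(points, eps, min_pts):
    """Textbook neighbourhood-expansion DBSCAN."""
    n = len(points)
    dist = np.linalg.norm(points[:, None] - points[None, :], axis=2)
    nbrs = [set(np.flatnonzero(dist[i] <= eps)) for i in range(n)]
    core = [len(nbrs[i]) >= min_pts for i in range(n)]
    labels = [None] * n
    cid = -1
    for i in range(n):
        if labels[i] is not None or not core[i]:
            continue
        cid += 1
        stack = [i]
        labels[i] = cid
        while stack:
            j = stack.pop()
            if not core[j]:
                continue
            for q in nbrs[j]:
                if labels[q] is None:
                    labels[q] = cid
                    stack.append(q)
    return np.array([l if l is not None else NOISE for l in labels])
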