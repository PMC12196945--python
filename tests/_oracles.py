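"""Independent brute-force reference implementations used only by tests.

Deliberately written as plain nested loops over definitions, sharing no code
path with the package, so agreement between the two is meaningful.
"""

from __future__ import annotations

import math


def brute_distance_matrix(X):
    n = len(X)
    D = [[0.0] * n for _ in range(n)]
    for a in range(n):
        for b in range(n):
            D[a][b] = math.sqrt(sum((X[a][j] - X[b][j]) ** 2 for j in range(len(X[a]))))
    return D


def brute_knn(D, a, k):
    """k nearest neighbors of a by (distance, index), self excluded."""
    others = sorted((D[a][b], b) for b in range(len(D)) if b != a)
    return [b for _, b in others[:k]]


def brute_dpc(X, k=8, m=2.0):
    """Full clustering pipeline from the definitions; returns a dict of stages."""
    n = len(X)
    D = brute_distance_matrix(X)
    sigma = max(D[a][b] for a in range(n) for b in range(n))
    knn = [brute_knn(D, a, k) for a in range(n)]

    rho = [1.0 - sum(D[a][b] for b in knn[a]) / (k * sigma) for a in range(n)]
    rho = [min(max(r, 0.0), 1.0) for r in rho]

    rho_max = max(rho)
    delta = []
    for a in range(n):
        if rho[a] >= rho_max:
            delta.append(max(D[a][b] for b in range(n)))
        else:
            hd = [e for e in range(n) if rho[e] > rho[a]]
            knnp = knn[a] + [a]
            delta.append(min(D[b][e] for b in knnp for e in hd))

    gamma = [(rho[a] * delta[a]) ** m for a in range(n)]

    rho_mean = sum(rho) / n
    delta_mean = sum(delta) / n
    cand = [a for a in range(n) if rho[a] > rho_mean and delta[a] > delta_mean]
    cand.sort(key=lambda a: (-gamma[a], a))
    if not cand:
        return {"rho": rho, "delta": delta, "gamma": gamma, "centers": [], "K": 0,
                "labels": None}
    if len(cand) == 1:
        K = 1
    else:
        gaps = [gamma[cand[i]] - gamma[cand[i + 1]] for i in range(len(cand) - 1)]
        gbar = sum(gaps) / len(gaps)
        above = [i + 1 for i, g in enumerate(gaps) if g > gbar]
        K = above[-1] if above else len(cand)  # boundary (last above-mean) gap
    centers = cand[:K]

    labels = [-1] * n
    for j, c in enumerate(centers):
        labels[c] = j
    order = sorted(range(n), key=lambda a: (-rho[a], a))
    for a in order:
        if labels[a] >= 0:
            continue
        denser = [b for b in range(n) if rho[b] > rho[a]]
        if denser:
            target = min(denser, key=lambda b: (D[a][b], b))
        else:
            target = min(centers, key=lambda c: (D[a][c], c))
        labels[a] = labels[target]
    return {"rho": rho, "delta": delta, "gamma": gamma, "centers": centers,
            "K": K, "labels": labels}


def brute_contingency(u, v):
    rows = sorted(set(u))
    cols = sorted(set(v))
    table = [[0] * len(cols) for _ in rows]
    for a, b in zip(u, v):
        table[rows.index(a)][cols.index(b)] += 1
    return table


def brute_ari_pairs(u, v):
    """ARI from explicit enumeration of all point pairs."""
    n = len(u)
    ss = sd = ds = dd = 0  # same/diff in u x same/diff in v
    for a in range(n):
        for b in range(a + 1, n):
            su = u[a] == u[b]
            sv = v[a] == v[b]
            if su and sv:
                ss += 1
            elif su:
                sd += 1
            elif sv:
                ds += 1
            else:
                dd += 1
    total = ss + sd + ds + dd
    sum_a = ss + sd  # pairs together in u
    sum_b = ss + ds  # pairs together in v
    expected = sum_a * sum_b / total
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == expected:
        return 1.0 if ss == sum_a == sum_b else 0.0
    return (ss - expected) / (max_index - expected)


def brute_nmi(u, v):
    """NMI from the probability definitions, natural log."""
    n = len(u)
    table = brute_contingency(u, v)
    pi = [sum(row) / n for row in table]
    pj = [sum(col) / n for col in zip(*table)]
    mi = 0.0
    for i, row in enumerate(table):
        for j, nij in enumerate(row):
            if nij:
                p = nij / n
                mi += p * math.log(p / (pi[i] * pj[j]))
    hu = -sum(p * math.log(p) for p in pi if p)
    hv = -sum(p * math.log(p) for p in pj if p)
    if hu + hv == 0:
        return 1.0
    return 2.0 * mi / (hu + hv)
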