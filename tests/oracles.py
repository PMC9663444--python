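"""Independent brute-force reference implementations used to check the
package against a second route.  Everything here is deliberately naive:
double loops, exhaustive enumeration, textbook formulas."""

from itertools import combinations

import numpy as np


def union_find_components(n_nodes, edges):
    """Connected components via union-find (no DFS)."""
    parent = list(range(n_nodes))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i, j in edges:
        ri, rj = find(int(i)), find(int(j))
        if ri != rj:
            parent[ri] = rj
    groups = {}
    for node in range(n_nodes):
        groups.setdefault(find(node), []).append(node)
    return [sorted(g) for g in groups.values()]


def pearson(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xm, ym = x - x.mean(), y - y.mean()
    return float((xm * ym).sum() / np.sqrt((xm ** 2).sum() * (ym ** 2).sum()))


def objective_double_loop(labels, pcs, sigma, isolated_label=-1):
    """All-pairs intra/inter similarity objective, one pair at a time."""
    labels = np.asarray(labels)
    region_ids = sorted(set(labels[labels != isolated_label]))
    if not region_ids:
        return -np.inf
    intra = []
    for rid in region_ids:
        members = np.flatnonzero(labels == rid)
        sims = [pearson(pcs[i], pcs[j]) for i, j in combinations(members, 2)]
        intra.append(np.mean(sims) if sims else 0.0)
    inter = []
    for a_pos in range(len(region_ids)):
        for b_pos in range(a_pos + 1, len(region_ids)):
            ma = np.flatnonzero(labels == region_ids[a_pos])
            mb = np.flatnonzero(labels == region_ids[b_pos])
            inter.append(np.mean([pearson(pcs[i], pcs[j]) for i in ma for j in mb]))
    inter_term = np.mean(inter) if inter else 0.0
    coverage = (labels != isolated_label).sum() / labels.size
    return float(np.mean(intra) - inter_term + sigma * coverage)


def silhouette_double_loop(x, labels):
    """O(n^2) Euclidean silhouette score."""
    x = np.asarray(x, dtype=float)
    labels = np.asarray(labels)
    n = x.shape[0]
    dist = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(-1))
    scores = []
    for i in range(n):
        same = (labels == labels[i]) & (np.arange(n) != i)
        if not same.any():
            scores.append(0.0)
            continue
        a = dist[i, same].mean()
        b = min(
            dist[i, labels == other].mean()
            for other in set(labels)
            if other != labels[i]
        )
        scores.append((b - a) / max(a, b))
    return float(np.mean(scores))


def ari_pair_counting(labels_a, labels_b):
    """Adjusted Rand index from the explicit contingency-table formula."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    n = a.size

    def comb2(x):
        return x * (x - 1) / 2.0

    cats_a, cats_b = sorted(set(a.tolist())), sorted(set(b.tolist()))
    table = np.array(
        [[np.sum((a == ca) & (b == cb)) for cb in cats_b] for ca in cats_a],
        dtype=float,
    )
    sum_ij = comb2(table).sum()
    sum_a = comb2(table.sum(axis=1)).sum()
    sum_b = comb2(table.sum(axis=0)).sum()
    expected = sum_a * sum_b / comb2(n)
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == expected:
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))


def rank_sum_u(x, y):
    """Mann-Whitney U of sample x (ties counted half) by double loop."""
    u = 0.0
    for xi in x:
        for yj in y:
            if xi > yj:
                u += 1.0
            elif xi == yj:
                u += 0.5
    return u


def rank_sum_exact_p(x, y):
    """Exact two-sided p-value of the rank-sum statistic by enumerating
    every assignment of the pooled sample (n <= 10 per group)."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    observed = rank_sum_u(x, y)
    n = len(pooled)
    total = 0
    extreme = 0
    mean_u = n1 * (n - n1) / 2.0
    for idx in combinations(range(n), n1):
        xs = pooled[list(idx)]
        ys = pooled[[i for i in range(n) if i not in idx]]
        u = rank_sum_u(xs, ys)
        total += 1
        if abs(u - mean_u) >= abs(observed - mean_u) - 1e-12:
            extreme += 1
    return extreme / total


def spknn_double_loop(counts, coords, neighbor_fn):
    """Neighbour-average baseline, entry by entry."""
    counts = np.asarray(counts, dtype=float)
    m, n = counts.shape
    index = {tuple(c): i for i, c in enumerate(np.asarray(coords).tolist())}
    out = counts.copy()
    for s in range(m):
        nbs = [index[c] for c in neighbor_fn(coords[s]) if tuple(c) in index]
        for g in range(n):
            if counts[s, g] == 0 and nbs:
                out[s, g] = np.mean([counts[t, g] for t in nbs])
    return out


def qc_filter_by_hand(counts, gene_ids, min_spots, min_umi, max_mito, prefixes):
    """Single-pass QC re-implemented entry-by-entry: genes first, spots second."""
    counts = np.asarray(counts, dtype=float)
    gene_keep = []
    for g in range(counts.shape[1]):
        observed_in = sum(1 for s in range(counts.shape[0]) if counts[s, g] > 0)
        gene_keep.append(observed_in >= min_spots)
    kept_genes = [g for g in range(counts.shape[1]) if gene_keep[g]]
    spot_keep = []
    for s in range(counts.shape[0]):
        total = sum(counts[s, g] for g in kept_genes)
        mito = sum(
            counts[s, g]
            for g in kept_genes
            if any(gene_ids[g].startswith(p) for p in prefixes)
        )
        frac = mito / total if total > 0 else 0.0
        spot_keep.append(total >= min_umi and frac <= max_mito)
    return np.array(gene_keep), np.array(spot_keep)
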