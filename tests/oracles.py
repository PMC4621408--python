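"""Independent brute-force oracles used to cross-check the implementations.

Every function here recomputes a quantity from its definition by explicit
enumeration (loops over branches, label permutations, vertex peelings),
deliberately sharing no code with the package.
"""

from __future__ import annotations

from itertools import permutations

import numpy as np


# -- phylogenetic metrics ----------------------------------------------


def faith_pd_bruteforce(observed_otus, tree) -> float:
    """Sum of branch lengths on the union of leaf-to-root paths."""
    edges = set()
    total = 0.0
    for tip in tree.tips():
        if tip.name not in observed_otus:
            continue
        node = tip
        while node.parent is not None:
            if id(node) not in edges:
                edges.add(id(node))
                total += node.length or 0.0
            node = node.parent
    return total


def unifrac_bruteforce(presence_a, presence_b, otu_ids, tree) -> float:
    """Loop over every branch; classify its descendant tips per sample."""
    set_a = {o for o, p in zip(otu_ids, presence_a) if p}
    set_b = {o for o, p in zip(otu_ids, presence_b) if p}
    unique = total = 0.0
    for node in tree.postorder():
        if node.parent is None:
            continue
        tips = {t.name for t in node.tips()} or {node.name}
        in_a = bool(tips & set_a)
        in_b = bool(tips & set_b)
        if in_a or in_b:
            total += node.length or 0.0
            if in_a != in_b:
                unique += node.length or 0.0
    return unique / total


# -- permutation statistics --------------------------------------------


def pseudo_f_bruteforce(dist, labels):
    """Anderson's pseudo-F from its SS definition by explicit loops."""
    dist = np.asarray(dist, dtype=float)
    labels = np.asarray(labels)
    n = len(labels)
    groups = sorted(set(labels.tolist()))
    a = len(groups)
    ss_total = sum(
        dist[i, j] ** 2 for i in range(n) for j in range(i + 1, n)
    ) / n
    ss_within = 0.0
    for g in groups:
        idx = [i for i in range(n) if labels[i] == g]
        ss_within += sum(
            dist[i, j] ** 2 for i in idx for j in idx if i < j
        ) / len(idx)
    ss_between = ss_total - ss_within
    f = (ss_between / (a - 1)) / (ss_within / (n - a))
    return f, ss_between / ss_total


def permanova_exact_p(dist, labels) -> float:
    """Exact p by enumerating every permutation of the label vector."""
    labels = list(labels)
    f_obs, _ = pseudo_f_bruteforce(dist, labels)
    hits = 0
    perms = list(permutations(labels))
    for perm in perms:
        f_perm, _ = pseudo_f_bruteforce(dist, perm)
        if f_perm >= f_obs - 1e-12:
            hits += 1
    return hits / len(perms)


def mantel_r_bruteforce(d1, d2) -> float:
    d1, d2 = np.asarray(d1, float), np.asarray(d2, float)
    n = d1.shape[0]
    x = [d1[i, j] for i in range(n) for j in range(i)]
    y = [d2[i, j] for i in range(n) for j in range(i)]
    return float(np.corrcoef(x, y)[0, 1])


def mantel_exact_p(d1, d2, alternative="two-sided") -> float:
    """Exact two-sided p by enumerating all joint row/column permutations."""
    d2 = np.asarray(d2, float)
    n = d2.shape[0]
    r_obs = mantel_r_bruteforce(d1, d2)
    hits = 0
    perms = list(permutations(range(n)))
    for perm in perms:
        perm = list(perm)
        r = mantel_r_bruteforce(d1, d2[np.ix_(perm, perm)])
        if alternative == "two-sided":
            hits += abs(r) >= abs(r_obs) - 1e-12
        else:
            hits += r >= r_obs - 1e-12
    return hits / len(perms)


def kruskal_h_bruteforce(groups) -> float:
    """Tie-corrected Kruskal-Wallis H from rank sums, by hand."""
    pooled = np.concatenate(groups)
    n = len(pooled)
    order = np.argsort(pooled, kind="stable")
    ranks = np.empty(n)
    sorted_vals = pooled[order]
    i = 0
    while i < n:
        j = i
        while j < n and sorted_vals[j] == sorted_vals[i]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2.0  # mid-rank (1-based)
        i = j
    offset = 0
    h = 0.0
    for g in groups:
        r = ranks[offset: offset + len(g)]
        h += r.sum() ** 2 / len(g)
        offset += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    # tie correction
    _, counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - (counts ** 3 - counts).sum() / (n ** 3 - n)
    return h / correction


def pcc_bruteforce(x) -> np.ndarray:
    """Pairwise Pearson correlations via the definition, pair by pair."""
    x = np.asarray(x, float)
    m = x.shape[1]
    out = np.eye(m)
    for i in range(m):
        for j in range(i + 1, m):
            a, b = x[:, i], x[:, j]
            ac, bc = a - a.mean(), b - b.mean()
            r = (ac * bc).sum() / np.sqrt((ac ** 2).sum() * (bc ** 2).sum())
            out[i, j] = out[j, i] = r
    return out


# -- MCODE vertex weights ----------------------------------------------


def core_peeling(adj: dict) -> tuple[int, set]:
    """Highest k-core by repeated minimum-degree peeling.

    Returns (k_max, nodes of the k_max-core). ``adj`` maps node -> set of
    neighbors, restricted to the subgraph under consideration.
    """
    k = 0
    best = set(adj)
    nodes = {v: set(nb) for v, nb in adj.items()}
    while nodes:
        k_try = k + 1
        current = {v: set(nb) for v, nb in nodes.items()}
        changed = True
        while changed:
            changed = False
            for v in list(current):
                if len(current[v]) < k_try:
                    del current[v]
                    for nb in current.values():
                        nb.discard(v)
                    changed = True
        if current:
            k = k_try
            best = set(current)
            nodes = current
        else:
            break
    return k, best


def mcode_weight_bruteforce(graph, v) -> float:
    """MCODE vertex weight via explicit closed-neighborhood peeling."""
    nbrs = set(graph.neighbors(v)) | {v}
    adj = {u: set(graph.neighbors(u)) & nbrs for u in nbrs}
    if not any(adj.values()):
        return 0.0
    k, core = core_peeling(adj)
    if k == 0 or len(core) < 2:
        return 0.0
    edges = sum(len(adj[u] & core) for u in core) // 2
    density = 2.0 * edges / (len(core) * (len(core) - 1))
    return k * density
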