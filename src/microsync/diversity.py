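"""Alpha and beta diversity, ordination and UPGMA clustering.

Alpha diversity covers the two richness metrics (observed species,
Faith's phylogenetic diversity including the root path) and the two
evenness metrics (Shannon entropy in bits, Gini-Simpson probability).
Beta diversity covers the membership-based Jaccard distance and the
phylogenetic unweighted UniFrac distance. Ordination is classical
principal-coordinate analysis (Gower double centering); sample grouping
is UPGMA with the ultrametric half-height convention.

Distance matrices are `skbio.DistanceMatrix`; trees are `skbio.TreeNode`
(Newick). The metric computations themselves are implemented here from
their definitions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode

from .table import OtuTable, rarefy

__all__ = [
    "observed_species",
    "faith_pd",
    "shannon",
    "simpson",
    "alpha_diversity_frame",
    "rarefaction_curves",
    "jaccard_matrix",
    "unweighted_unifrac",
    "PcoaResult",
    "pcoa",
    "Dendrogram",
    "upgma",
]


class DiversityError(ValueError):
    pass


# -- alpha diversity ----------------------------------------------------


def observed_species(sample_counts) -> int:
    """Number of OTUs with a strictly positive count."""
    counts = np.asarray(sample_counts)
    if (counts < 0).any():
        raise DiversityError("negative counts")
    return int((counts > 0).sum())


def shannon(sample_counts) -> float:
    """Shannon entropy of the count composition, in bits (log base 2)."""
    counts = np.asarray(sample_counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise DiversityError("all-zero sample")
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


def simpson(sample_counts) -> float:
    """Gini-Simpson index 1 - sum(p_i^2): probability two reads differ."""
    counts = np.asarray(sample_counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise DiversityError("all-zero sample")
    p = counts / total
    return float(1.0 - (p ** 2).sum())


def _tree_index(tree: TreeNode):
    """Postorder node list (root excluded) with lengths and leaf index."""
    nodes = [n for n in tree.postorder() if n is not tree]
    lengths = np.array([n.length or 0.0 for n in nodes])
    node_pos = {id(n): i for i, n in enumerate(nodes)}
    return nodes, lengths, node_pos


def faith_pd(sample_counts, otu_ids, tree: TreeNode) -> float:
    """Faith's PD: total branch length of the minimal rooted subtree
    spanning the observed OTUs and the root ("PD whole tree" convention).
    """
    counts = np.asarray(sample_counts)
    observed = [o for o, c in zip(otu_ids, counts) if c > 0]
    tips = {t.name: t for t in tree.tips()}
    kept: set[int] = set()
    for otu in observed:
        if otu not in tips:
            raise DiversityError(f"OTU {otu!r} not found in tree")
        node = tips[otu]
        while node is not None and node.parent is not None:
            if id(node) in kept:
                break
            kept.add(id(node))
            node = node.parent
    nodes = [n for n in tree.postorder() if n is not tree]
    return float(sum((n.length or 0.0) for n in nodes if id(n) in kept))


def alpha_diversity_frame(table: OtuTable, tree: TreeNode | None = None) -> pd.DataFrame:
    """All four alpha metrics per sample in one DataFrame."""
    rows = {}
    for sid in table.sample_ids:
        counts = table.data.loc[sid].to_numpy()
        row = {
            "observed_species": observed_species(counts),
            "shannon": shannon(counts),
            "simpson": simpson(counts),
        }
        if tree is not None:
            row["faith_pd"] = faith_pd(counts, table.otu_ids, tree)
        rows[sid] = row
    return pd.DataFrame.from_dict(rows, orient="index")


def rarefaction_curves(
    table: OtuTable,
    depths,
    reps: int = 10,
    seed: int = 0,
    metric=observed_species,
) -> pd.DataFrame:
    """Mean metric over ``reps`` rarefactions, per sample per depth.

    Depths beyond a sample's total yield NaN for that sample.
    """
    depths = list(depths)
    if sorted(depths) != depths:
        raise DiversityError("depths must be sorted ascending")
    rng = np.random.default_rng(seed)
    totals = table.sample_totals()
    out = pd.DataFrame(np.nan, index=table.sample_ids, columns=depths)
    for depth in depths:
        reachable = [s for s in table.sample_ids if totals[s] >= depth]
        if not reachable:
            continue
        sub = table.select_samples(reachable)
        vals = np.zeros((len(reachable), reps))
        for r in range(reps):
            rare = rarefy(sub, depth, int(rng.integers(2**31)))
            for i, s in enumerate(reachable):
                vals[i, r] = metric(rare.data.loc[s].to_numpy())
        out.loc[reachable, depth] = vals.mean(axis=1)
    return out


# -- beta diversity -----------------------------------------------------


def jaccard_matrix(table: OtuTable) -> DistanceMatrix:
    """Jaccard distance 1 - |A & B| / |A | B| on presence/absence sets."""
    if table.shape[0] < 2:
        raise DiversityError("need at least 2 samples")
    presence = table.counts > 0
    sizes = presence.sum(axis=1)
    if (sizes == 0).any():
        empty = [s for s, z in zip(table.sample_ids, sizes) if z == 0]
        raise DiversityError(f"samples with no observed OTUs: {empty}")
    inter = presence.astype(np.int64) @ presence.astype(np.int64).T
    union = sizes[:, None] + sizes[None, :] - inter
    d = 1.0 - inter / union
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix((d + d.T) / 2.0, ids=table.sample_ids)


def unweighted_unifrac(table: OtuTable, tree: TreeNode) -> DistanceMatrix:
    """Unweighted UniFrac: unique / total observed branch length per pair.

    A branch counts toward a sample if any of its descendant tips is
    observed in that sample; branches with no observed descendants in
    either sample of a pair are ignored.
    """
    if table.shape[0] < 2:
        raise DiversityError("need at least 2 samples")
    presence = table.counts > 0
    if (~presence.any(axis=1)).any():
        empty = [s for s, row in zip(table.sample_ids, presence) if not row.any()]
        raise DiversityError(f"samples with no observed OTUs: {empty}")
    tip_col = {o: j for j, o in enumerate(table.otu_ids)}
    nodes, lengths, node_pos = _tree_index(tree)
    n_samples = table.shape[0]
    # member[i, s]: subtree under node i contains an OTU observed in sample s
    member = np.zeros((len(nodes), n_samples), dtype=bool)
    for i, node in enumerate(nodes):
        if node.is_tip():
            if node.name not in tip_col:
                continue
            member[i] = presence[:, tip_col[node.name]]
        else:
            for child in node.children:
                member[i] |= member[node_pos[id(child)]]
    d = np.zeros((n_samples, n_samples))
    for a in range(n_samples):
        for b in range(a + 1, n_samples):
            either = member[:, a] | member[:, b]
            both = member[:, a] & member[:, b]
            total = lengths[either].sum()
            if total == 0:
                raise DiversityError("no observed branch length for a sample pair")
            unique = lengths[either & ~both].sum()
            d[a, b] = d[b, a] = unique / total
    return DistanceMatrix(d, ids=table.sample_ids)


# -- ordination ---------------------------------------------------------


@dataclass
class PcoaResult:
    coordinates: pd.DataFrame          # samples x retained axes, scaled by sqrt(eig)
    eigenvalues: np.ndarray            # all eigenvalues, descending (negatives included)
    proportion_explained: np.ndarray   # per retained axis, relative to positive eigs


def pcoa(dm: DistanceMatrix, eps: float = 1e-9) -> PcoaResult:
    """Classical (metric) multidimensional scaling of a distance matrix.

    Gower double centering of -1/2 d^2 followed by eigendecomposition;
    axes with eigenvalue <= ``eps`` x largest are omitted, negative
    eigenvalues are reported unchanged.
    """
    d = dm.data
    n = d.shape[0]
    a = -0.5 * d ** 2
    centering = np.eye(n) - np.ones((n, n)) / n
    b = centering @ a @ centering
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    cutoff = eps * max(eigvals.max(), 0.0)
    keep = eigvals > cutoff
    coords = eigvecs[:, keep] * np.sqrt(eigvals[keep])
    pos_sum = eigvals[eigvals > 0].sum()
    prop = eigvals[keep] / pos_sum if pos_sum > 0 else eigvals[keep] * 0.0
    frame = pd.DataFrame(
        coords, index=list(dm.ids), columns=[f"PC{i+1}" for i in range(keep.sum())]
    )
    return PcoaResult(frame, eigvals, prop)


# -- UPGMA --------------------------------------------------------------


@dataclass
class Dendrogram:
    """Rooted binary merge tree with ultrametric heights.

    ``merges`` is a list of (left, right, height) triples where left/right
    are either leaf ids or earlier cluster indices ("#k"), in merge order.
    """

    leaves: list[str]
    merges: list[tuple[str, str, float]]

    def heights(self) -> list[float]:
        return [h for _, _, h in self.merges]

    def _newick_parts(self):
        parts: dict[str, tuple[str, float]] = {l: (l, 0.0) for l in self.leaves}
        for k, (left, right, h) in enumerate(self.merges):
            lstr, lh = parts[left]
            rstr, rh = parts[right]
            parts[f"#{k}"] = (f"({lstr}:{h - lh:.10g},{rstr}:{h - rh:.10g})", h)
        return parts

    def to_newick(self) -> str:
        root = f"#{len(self.merges) - 1}" if self.merges else self.leaves[0]
        return self._newick_parts()[root][0] + ";"

    def members(self, node: str) -> frozenset[str]:
        if not node.startswith("#"):
            return frozenset([node])
        left, right, _ = self.merges[int(node[1:])]
        return self.members(left) | self.members(right)

    def cut(self, k: int) -> dict[str, int]:
        """Partition leaves into k groups by undoing the k-1 last merges."""
        if not (1 <= k <= len(self.leaves)):
            raise DiversityError("k out of range")
        active = [f"#{len(self.merges) - 1}"]
        # repeatedly split the active cluster with the greatest height
        while len(active) < k:
            splittable = [a for a in active if a.startswith("#")]
            top = max(splittable, key=lambda a: self.merges[int(a[1:])][2])
            left, right, _ = self.merges[int(top[1:])]
            active.remove(top)
            active.extend([left, right])
        out = {}
        for g, node in enumerate(sorted(active, key=lambda a: sorted(self.members(a))[0])):
            for leaf in self.members(node):
                out[leaf] = g
        return out

    def cophenetic(self) -> DistanceMatrix:
        """Pairwise merge height x2 (the ultrametric distance)."""
        ids = sorted(self.leaves)
        idx = {l: i for i, l in enumerate(ids)}
        d = np.zeros((len(ids), len(ids)))
        done = np.zeros_like(d, dtype=bool)
        for left, right, h in self.merges:
            for a in self.members(left):
                for b in self.members(right):
                    i, j = idx[a], idx[b]
                    if not done[i, j]:
                        d[i, j] = d[j, i] = 2.0 * h
                        done[i, j] = done[j, i] = True
        return DistanceMatrix(d, ids=ids)


def upgma(dm: DistanceMatrix) -> Dendrogram:
    """Average-linkage agglomeration with merge height = half the average
    inter-cluster distance; ties broken lexicographically for determinism.
    """
    ids = list(dm.ids)
    if len(ids) < 2:
        raise DiversityError("need at least 2 samples")
    base = pd.DataFrame(dm.data, index=ids, columns=ids)
    clusters: dict[str, list[str]] = {i: [i] for i in ids}  # node label -> members
    merges: list[tuple[str, str, float]] = []

    def avg_dist(a: str, b: str) -> float:
        return float(base.loc[clusters[a], clusters[b]].to_numpy().mean())

    while len(clusters) > 1:
        names = sorted(clusters, key=lambda c: sorted(clusters[c])[0])
        best = None
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                d = avg_dist(names[i], names[j])
                key = (d, sorted(clusters[names[i]])[0], sorted(clusters[names[j]])[0])
                if best is None or key < best[0]:
                    best = (key, names[i], names[j])
        _, left, right = best
        h = avg_dist(left, right) / 2.0
        new = f"#{len(merges)}"
        merges.append((left, right, h))
        clusters[new] = clusters.pop(left) + clusters.pop(right)
    return Dendrogram(leaves=ids, merges=merges)
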