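"""Stage-specific OTU co-occurrence networks.

For each seasonal stage (a group of samples), OTUs observed in fewer than
half of the stage's samples are discarded, pairwise Pearson correlations
of per-sample relative abundances are computed, and an undirected signed
network is built by thresholding |PCC|. The threshold can be fixed (the
study-wide 0.90) or chosen on a grid by maximizing the goodness of a
power-law fit to the degree distribution (the scale-free criterion).
"""

from __future__ import annotations

import math
import warnings

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sstats

from .table import OtuTable

__all__ = [
    "prevalence_filter",
    "pcc_matrix",
    "build_network",
    "degree_powerlaw_fit",
    "select_threshold",
    "network_density",
]


class CooccurrenceError(ValueError):
    pass


def prevalence_filter(
    table: OtuTable,
    group_samples,
    min_fraction: float = 0.5,
) -> list[str]:
    """OTUs present (count > 0) in at least ``min_fraction`` of the group.

    The default 0.5 implements "OTUs in fewer than half of the samples are
    removed": an OTU present in 4 of 9 samples is dropped, 5 of 9 is kept.
    OTUs absent from every group sample are always dropped.
    """
    group_samples = list(group_samples)
    if not group_samples:
        raise CooccurrenceError("empty sample group")
    sub = table.select_samples(group_samples)
    presence = (sub.counts > 0).sum(axis=0)
    need = max(1, math.ceil(min_fraction * len(group_samples)))
    return [o for o, p in zip(sub.otu_ids, presence) if p >= need]


def pcc_matrix(
    table: OtuTable,
    group_samples,
    retained_otus,
    use_relative: bool = True,
) -> pd.DataFrame:
    """Pearson correlations of OTU abundances across the group's samples.

    Abundances are per-sample relative (counts / sample total) by default.
    Zero-variance OTUs within the group are dropped with a warning.
    """
    group_samples = list(group_samples)
    if len(group_samples) < 4:
        raise CooccurrenceError("need at least 4 samples to estimate correlations")
    sub = table.select_samples(group_samples).select_otus(list(retained_otus))
    x = sub.counts.astype(float)
    if use_relative:
        totals = x.sum(axis=1, keepdims=True)
        if (totals == 0).any():
            raise CooccurrenceError("group contains an empty sample")
        x = x / totals
    sd = x.std(axis=0)
    keep = sd > 0
    if not keep.all():
        dropped = [o for o, k in zip(sub.otu_ids, keep) if not k]
        warnings.warn(
            f"pcc_matrix: dropped {len(dropped)} zero-variance OTU(s)", stacklevel=2
        )
        x = x[:, keep]
    otus = [o for o, k in zip(sub.otu_ids, keep) if k]
    if len(otus) < 2:
        raise CooccurrenceError("need at least 2 OTUs with variance")
    cm = np.corrcoef(x, rowvar=False)
    np.fill_diagonal(cm, 1.0)
    return pd.DataFrame(cm, index=otus, columns=otus)


def build_network(
    cm: pd.DataFrame,
    threshold: float,
    stage: str | None = None,
) -> nx.Graph:
    """Threshold |PCC| >= ``threshold`` into a signed undirected graph.

    All correlated OTUs stay in the node set even if isolated; edges carry
    the PCC as ``weight`` and its sign (+1 co-occurrence, -1 mutual
    exclusion) as ``sign``.
    """
    if not (0 < threshold <= 1):
        raise CooccurrenceError("threshold must be in (0, 1]")
    g = nx.Graph(threshold=threshold, stage=stage)
    otus = list(cm.index)
    g.add_nodes_from(otus)
    vals = cm.to_numpy()
    ii, jj = np.where(np.triu(np.abs(vals) >= threshold, k=1))
    for i, j in zip(ii, jj):
        r = float(vals[i, j])
        g.add_edge(otus[i], otus[j], weight=r, sign=1 if r >= 0 else -1)
    return g


def degree_powerlaw_fit(net: nx.Graph) -> tuple[float, float]:
    """Least-squares power-law fit to the degree distribution.

    Regresses log10 N(k) on log10 k over positive degrees k with N(k) > 0;
    returns (exponent, r_squared) where exponent = -slope. Requires at
    least 3 distinct positive degrees.
    """
    degrees = np.array([d for _, d in net.degree() if d >= 1])
    if degrees.size == 0:
        raise CooccurrenceError("network has no positive-degree nodes")
    ks, counts = np.unique(degrees, return_counts=True)
    if ks.size < 3:
        raise CooccurrenceError("fewer than 3 distinct positive degrees: fit undefined")
    fit = sstats.linregress(np.log10(ks), np.log10(counts))
    return float(-fit.slope), float(fit.rvalue ** 2)


def select_threshold(
    cm: pd.DataFrame,
    grid=None,
    min_nodes: int = 10,
) -> float:
    """Grid threshold maximizing the power-law fit r^2 (scale-free
    criterion); feasible points must keep >= ``min_nodes`` non-isolated
    nodes and admit a fit; ties prefer the larger threshold.
    """
    if grid is None:
        grid = np.round(np.arange(0.50, 0.99, 0.02), 2)
    grid = sorted(set(float(t) for t in grid))
    if not grid:
        raise CooccurrenceError("empty threshold grid")
    best: tuple[float, float] | None = None
    for t in grid:
        net = build_network(cm, t)
        non_isolated = sum(1 for _, d in net.degree() if d > 0)
        if non_isolated < min_nodes:
            continue
        try:
            _, r2 = degree_powerlaw_fit(net)
        except CooccurrenceError:
            continue
        if best is None or (r2, t) > best:
            best = (r2, t)
    if best is None:
        raise CooccurrenceError("no feasible threshold on the grid")
    return best[1]


def network_density(net: nx.Graph, mode: str = "mean_degree") -> float:
    """Average number of edges per node: mean degree 2E/N (default) or
    the literal edges-per-node ratio E/N."""
    n = net.number_of_nodes()
    if n == 0:
        raise CooccurrenceError("empty network")
    e = net.number_of_edges()
    if mode == "mean_degree":
        return 2.0 * e / n
    if mode == "edges_per_node":
        return e / n
    raise CooccurrenceError(f"unknown mode {mode!r}")
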