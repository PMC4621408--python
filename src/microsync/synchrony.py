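"""Genus synchrony: monthly abundance profiles, Z-scores, K-means.

A genus's temporal profile is the log of its summed (depth-normalized)
read counts per sampling month, Abund[G, T] = log10(1 + sum_s R_{G,T,s}),
where the sum runs over the sites sampled in month T. Profiles are
standardized per genus to Z-scores, Z[G, T] = (Abund[G, T] - mean) / sd,
so genera are compared by the *shape* of their seasonal variation, not
its level. Genera with identical abundance in every month carry no shape
information; they are flagged degenerate, set to all-zero rows and
excluded from clustering.

K-means (Lloyd's algorithm, Euclidean distance on the 9-dimensional Z
rows, best of 100 random restarts by within-cluster sum of squares)
groups synchronized genera; the within-SS / between-SS ratio as a
function of k guides the choice of k.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .table import OtuTable, SampleMetadata, month_sort_key

__all__ = [
    "month_abundance",
    "ZProfile",
    "zscore",
    "SynchronyClustering",
    "kmeans_best",
    "ss_ratio_curve",
    "elbow_k",
    "cluster_summary",
]


class SynchronyError(ValueError):
    pass


def month_abundance(
    genus_table: OtuTable,
    meta: SampleMetadata,
    agg: str = "sum",
    log_base: float = 10.0,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Genus x month log-abundance profile.

    ``agg="sum"`` (default) adds the resampled counts of all sites in the
    month before taking the log; ``agg="mean"`` averages them instead. The
    table is expected to be rarefied so per-sample depths are comparable.
    """
    if agg not in ("sum", "mean"):
        raise SynchronyError("agg must be 'sum' or 'mean'")
    by_month = meta.samples_by_month(genus_table.sample_ids)
    if not by_month:
        raise SynchronyError("no samples with month metadata")
    for month, sids in by_month.items():
        if not sids:
            raise SynchronyError(f"month {month} has no samples")
    months = sorted(by_month, key=month_sort_key)
    cols = {}
    for month in months:
        sub = genus_table.data.loc[by_month[month]]
        tot = sub.sum(axis=0) if agg == "sum" else sub.mean(axis=0)
        cols[month] = np.log(pseudocount + tot.to_numpy()) / np.log(log_base)
    return pd.DataFrame(cols, index=genus_table.otu_ids)


@dataclass
class ZProfile:
    z: pd.DataFrame              # genus x month standardized scores
    degenerate: pd.Series        # bool per genus: zero temporal variance


def zscore(profile: pd.DataFrame) -> ZProfile:
    """Standardize each genus row to mean 0, sample sd 1 (ddof=1).

    Zero-variance rows are set to all zeros and flagged degenerate.
    """
    if profile.shape[1] < 2:
        raise SynchronyError("need at least 2 months")
    vals = profile.to_numpy(dtype=float)
    mean = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=1, keepdims=True)
    degenerate = sd[:, 0] == 0
    safe_sd = np.where(sd == 0, 1.0, sd)
    z = (vals - mean) / safe_sd
    z[degenerate] = 0.0
    return ZProfile(
        pd.DataFrame(z, index=profile.index, columns=profile.columns),
        pd.Series(degenerate, index=profile.index, name="degenerate"),
    )


@dataclass
class SynchronyClustering:
    k: int
    assignment: pd.Series        # genus -> cluster id (0..k-1), all genera
    centers: pd.DataFrame        # k x months
    within_ss: float
    between_ss: float
    total_ss: float
    n_restarts: int
    seed: int


def kmeans_best(
    z: ZProfile,
    k: int,
    n_restarts: int = 100,
    seed: int = 0,
) -> SynchronyClustering:
    """Best-of-``n_restarts`` K-means on the non-degenerate Z rows.

    Initial centers are drawn uniformly from the data points (Forgy); the
    restart with the smallest within-cluster SS wins. Degenerate genera
    are excluded from fitting and assigned to the nearest final center.
    """
    fit_idx = z.z.index[~z.degenerate]
    x = z.z.loc[fit_idx].to_numpy(dtype=float)
    if k < 1:
        raise SynchronyError("k must be >= 1")
    if k > len(fit_idx):
        raise SynchronyError(f"k={k} exceeds the {len(fit_idx)} non-degenerate genera")
    km = KMeans(
        n_clusters=k,
        init="random",
        n_init=n_restarts,
        algorithm="lloyd",
        random_state=seed % (2**32),
    ).fit(x)
    centers = km.cluster_centers_
    within_ss = float(km.inertia_)
    total_ss = float(((x - x.mean(axis=0)) ** 2).sum())
    between_ss = total_ss - within_ss
    assignment = pd.Series(0, index=z.z.index, dtype=int, name="cluster")
    assignment.loc[fit_idx] = km.labels_
    degen_idx = z.z.index[z.degenerate]
    if len(degen_idx):
        xd = z.z.loc[degen_idx].to_numpy(dtype=float)
        d2 = ((xd[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        assignment.loc[degen_idx] = d2.argmin(axis=1)
    return SynchronyClustering(
        k=k,
        assignment=assignment,
        centers=pd.DataFrame(centers, columns=z.z.columns),
        within_ss=within_ss,
        between_ss=between_ss,
        total_ss=total_ss,
        n_restarts=n_restarts,
        seed=seed,
    )


def ss_ratio_curve(
    z: ZProfile,
    k_range,
    n_restarts: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Within-SS / between-SS of the best clustering, per candidate k."""
    rows = []
    for k in k_range:
        fit = kmeans_best(z, k, n_restarts=n_restarts, seed=seed)
        ratio = fit.within_ss / fit.between_ss if fit.between_ss > 0 else np.inf
        if fit.within_ss == 0:
            ratio = 0.0
        rows.append({"k": k, "within_ss": fit.within_ss,
                     "between_ss": fit.between_ss, "ss_ratio": ratio})
    return pd.DataFrame(rows).set_index("k")


def elbow_k(curve: pd.DataFrame) -> int:
    """k with the largest relative drop of the SS ratio from k-1 to k."""
    ks = curve.index.to_numpy()
    ratio = curve["ss_ratio"].to_numpy(dtype=float)
    if len(ks) < 2:
        raise SynchronyError("need at least two k values")
    rel_drop = (ratio[:-1] - ratio[1:]) / np.where(ratio[:-1] == 0, 1.0, ratio[:-1])
    return int(ks[1:][rel_drop.argmax()])


def cluster_summary(
    clustering: SynchronyClustering,
    genus_table: OtuTable,
    phylum_of: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Per-cluster abundance share, representative genera and, when a
    genus -> phylum map is given, the abundance-dominant phylum.

    Representatives are the smallest prefix of the cluster's genera, in
    descending total abundance, whose cumulative share of the cluster
    abundance strictly exceeds 50%.
    """
    totals = genus_table.otu_totals()
    grand = float(totals.sum())
    rows = []
    for c in range(clustering.k):
        members = clustering.assignment.index[clustering.assignment == c]
        member_totals = totals.reindex(members).fillna(0).sort_values(
            ascending=False, kind="stable"
        )
        cluster_total = float(member_totals.sum())
        reps: list[str] = []
        cum = 0.0
        for genus, t in member_totals.items():
            reps.append(genus)
            cum += float(t)
            if cluster_total > 0 and cum > 0.5 * cluster_total:
                break
        if cluster_total == 0:
            reps = []
        row = {
            "cluster": c,
            "n_genera": int(len(members)),
            "abundance_pct": 100.0 * cluster_total / grand if grand else 0.0,
            "representatives": ";".join(reps),
        }
        if phylum_of is not None:
            by_phylum: dict[str, float] = {}
            for genus, t in member_totals.items():
                p = phylum_of.get(genus, "unclassified")
                by_phylum[p] = by_phylum.get(p, 0.0) + float(t)
            row["dominant_phylum"] = (
                max(by_phylum, key=lambda p: (by_phylum[p], p)) if by_phylum else ""
            )
        rows.append(row)
    return pd.DataFrame(rows).set_index("cluster")
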