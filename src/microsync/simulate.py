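"""Synthetic lake-survey data with planted structure.

The generator emulates a 9-sites x 9-months freshwater 16S survey:
log-normally distributed genus base abundances (a few taxa dominate the
community), four phase-shifted seasonal archetypes driving genus-level
month-to-month variation, per-genus site effects, and per-OTU sampling
noise, with integer counts drawn multinomially at a fixed per-sample
depth. On top of the seasonal background, blocks of "module OTUs" are
planted per seasonal stage: within a block, each sample in the stage
draws a shared latent factor and the block members' relative abundances
are scaled by correlated multipliers with pairwise latent correlation
``rho``, so the block becomes a dense co-occurrence clique at high PCC
thresholds in its own stage and disappears in the others.

Every generator is a pure function of (config, seed); the returned
:class:`GroundTruth` records the planted archetype labels, module
memberships and month-to-stage assignment for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode
from scipy.spatial.distance import squareform, pdist

from .table import (
    CALENDAR_MONTHS,
    STAGES,
    STUDY_MONTHS,
    OtuTable,
    SampleMetadata,
    TaxonomyMap,
    month_sort_key,
    stage_of_month,
)

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_table",
    "make_archetype_profiles",
    "simulate_tree",
    "perturb_table",
    "make_permanova_fixture",
]

_PHYLA = (
    "Actinobacteria", "Proteobacteria", "Cyanobacteria",
    "Bacteroidetes", "Verrucomicrobia", "Acidobacteria",
)

#: Calendar peak month index of each seasonal archetype (spring, autumn,
#: winter, summer).
_ARCHETYPE_PEAKS = (3, 9, 0, 6)


@dataclass
class SimulationConfig:
    n_sites: int = 9
    months: tuple[str, ...] = STUDY_MONTHS
    n_genera: int = 120
    n_otus: int = 600                 # regular OTUs, module OTUs come on top
    depth: int = 50_000
    # seasonal background (log10 units)
    base_sd: float = 1.0              # genus base abundance spread
    amplitude: float = 1.0            # archetype curve amplitude
    noise_sd: float = 0.1             # per OTU x month profile noise
    site_sd: float = 0.1              # per genus x site effect
    otu_noise_sd: float = 0.3         # per OTU x sample noise
    n_archetypes: int = 4
    # planted co-occurrence modules (bloom-like taxa: abundant and
    # factor-driven inside their stage, rare outside it)
    modules_per_stage: int = 2
    module_size: int = 10
    rho: float = 0.95                 # latent pairwise correlation in a block
    module_strength: float = 0.5       # sd of the linear latent multiplier
    module_base_weight: float = 30.0  # unnormalized in-stage weight of a module OTU
    module_offstage_factor: float = 0.05  # out-of-stage weight multiplier
    seed: int = 0

    @property
    def sites(self) -> list[str]:
        return [f"S{i+1}" for i in range(self.n_sites)]


@dataclass
class GroundTruth:
    archetype: dict[str, int]                      # genus -> archetype id
    modules: dict[str, list[list[str]]]            # stage -> blocks of OTU ids
    month_stage: dict[str, str | None] = field(default_factory=dict)

    def module_frame(self) -> pd.DataFrame:
        rows = []
        for stage, blocks in self.modules.items():
            for b, otus in enumerate(blocks):
                for otu in otus:
                    rows.append({"otu": otu, "stage": stage, "block": b})
        return pd.DataFrame(rows)

    def archetype_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"genus": list(self.archetype), "archetype": list(self.archetype.values())}
        ).set_index("genus")


def _archetype_curve(peak: int, month: str) -> float:
    return float(np.cos(2 * np.pi * (month_sort_key(month) - peak) / 12.0))


def simulate_table(
    cfg: SimulationConfig,
) -> tuple[OtuTable, TaxonomyMap, SampleMetadata, GroundTruth]:
    """Simulate an OTU count table with planted seasonal and module structure."""
    rng = np.random.default_rng(cfg.seed)
    months = sorted(cfg.months, key=month_sort_key)
    sites = cfg.sites
    if cfg.depth < cfg.n_otus:
        import warnings

        warnings.warn("depth below the number of OTUs: table will be very sparse")

    # --- regular genera and their OTUs ---------------------------------
    genera = [f"g{g+1:03d}" for g in range(cfg.n_genera)]
    archetype = {g: i % cfg.n_archetypes for i, g in enumerate(genera)}
    base = 10.0 ** rng.normal(0.0, cfg.base_sd, size=cfg.n_genera)
    # OTUs per genus: even split of n_otus, remainder to the first genera
    per_genus = np.full(cfg.n_genera, cfg.n_otus // cfg.n_genera)
    per_genus[: cfg.n_otus % cfg.n_genera] += 1
    otu_ids: list[str] = []
    otu_genus_idx: list[int] = []
    split_w: list[float] = []
    for gi, g in enumerate(genera):
        k = per_genus[gi]
        if k == 0:
            continue
        dirichlet = rng.dirichlet(np.full(k, 0.8))
        for j in range(k):
            otu_ids.append(f"OTU_{g}_{j+1}")
            otu_genus_idx.append(gi)
            split_w.append(base[gi] * dirichlet[j])
    n_reg = len(otu_ids)

    # --- planted module OTUs -------------------------------------------
    stages = [s for s in STAGES if set(STAGES[s]) & set(months)]
    modules: dict[str, list[list[str]]] = {s: [] for s in stages}
    mod_ids: list[str] = []
    mod_weight: list[float] = []
    mod_stage: list[str] = []
    mod_block: list[int] = []
    for stage in stages:
        for b in range(cfg.modules_per_stage):
            block = []
            for j in range(cfg.module_size):
                oid = f"OTU_mod_{stage}_{b+1}_{j+1}"
                block.append(oid)
                mod_ids.append(oid)
                mod_weight.append(
                    cfg.module_base_weight * 10.0 ** rng.normal(0.0, 0.15)
                )
                mod_stage.append(stage)
                mod_block.append(b)
            modules[stage].append(block)
    n_mod = len(mod_ids)

    # --- taxonomy -------------------------------------------------------
    lineages: dict[str, tuple[str, ...]] = {}
    for oid, gi in zip(otu_ids, otu_genus_idx):
        g = genera[gi]
        fam = f"fam{gi // 2 + 1:03d}"
        order = f"ord{gi // 4 + 1:03d}"
        cls = f"cls{gi // 8 + 1:02d}"
        phylum = _PHYLA[gi % len(_PHYLA)]
        lineages[oid] = ("Bacteria", phylum, cls, order, fam, g, "")
    for oid, stage, b in zip(mod_ids, mod_stage, mod_block):
        g = f"gmod_{stage}_{b+1}"
        fam = f"fam_mod_{stage}_{b+1}"
        lineages[oid] = ("Bacteria", _PHYLA[b % len(_PHYLA)], "clsMod", "ordMod", fam, g, "")
    tax = TaxonomyMap(lineages)

    # --- per-sample expected weights and counts -------------------------
    eps_month = rng.normal(0.0, cfg.noise_sd, size=(n_reg, len(months)))
    site_eff = rng.normal(0.0, cfg.site_sd, size=(cfg.n_genera, len(sites)))
    sample_ids = [f"{m}.{s}" for m in months for s in sites]
    counts = np.zeros((len(sample_ids), n_reg + n_mod), dtype=np.int64)
    row = 0
    sqrt_rho, sqrt_not = np.sqrt(cfg.rho), np.sqrt(1.0 - cfg.rho)
    for mi, month in enumerate(months):
        stage_of_m = stage_of_month(month)
        for si, site in enumerate(sites):
            w = np.empty(n_reg + n_mod)
            g_idx = np.array(otu_genus_idx)
            curve = np.array(
                [_archetype_curve(_ARCHETYPE_PEAKS[archetype[genera[gi]]], month)
                 for gi in range(cfg.n_genera)]
            )
            log_shift = (
                cfg.amplitude * curve[g_idx]
                + eps_month[:, mi]
                + site_eff[g_idx, si]
                + rng.normal(0.0, cfg.otu_noise_sd, size=n_reg)
            )
            w[:n_reg] = np.array(split_w) * 10.0 ** log_shift
            # module OTUs: correlated latent multiplier inside their stage,
            # near-absent outside it (bloom dynamics); the combined latent
            # score is winsorized at |z| <= 1.96 to keep the linear
            # multiplier positive without skewing it
            factors = {
                (stage, b): rng.normal()
                for stage in stages
                for b in range(cfg.modules_per_stage)
            }
            for k in range(n_mod):
                base_w = mod_weight[k]
                if mod_stage[k] == stage_of_m:
                    z = (
                        sqrt_rho * factors[(mod_stage[k], mod_block[k])]
                        + sqrt_not * rng.normal()
                    )
                    mult = 1.0 + cfg.module_strength * float(np.clip(z, -1.96, 1.96))
                else:
                    mult = cfg.module_offstage_factor * 10.0 ** rng.normal(0.0, 0.1)
                w[n_reg + k] = base_w * mult
            counts[row] = rng.multinomial(cfg.depth, w / w.sum())
            row += 1

    table = OtuTable(
        pd.DataFrame(counts, index=sample_ids, columns=otu_ids + mod_ids)
    )
    meta = SampleMetadata.from_sample_ids(sample_ids)
    truth = GroundTruth(
        archetype=archetype,
        modules=modules,
        month_stage={m: stage_of_month(m) for m in months},
    )
    return table, tax, meta, truth


def make_archetype_profiles(
    n_genera: int = 120,
    noise_sd: float = 0.3,
    months: tuple[str, ...] = STUDY_MONTHS,
    n_archetypes: int = 4,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Genus x month profiles drawn directly from the seasonal archetypes.

    Each genus's profile is its archetype's phase-shifted seasonal curve
    plus i.i.d. Gaussian noise of sd ``noise_sd`` — the planted ground
    truth for synchrony-clustering recovery, bypassing the count layer.
    """
    rng = np.random.default_rng(seed)
    months = sorted(months, key=month_sort_key)
    genera = [f"g{g+1:03d}" for g in range(n_genera)]
    labels = pd.Series([g % n_archetypes for g in range(n_genera)], index=genera)
    curves = np.array(
        [[_archetype_curve(_ARCHETYPE_PEAKS[a], m) for m in months]
         for a in range(n_archetypes)]
    )
    vals = curves[labels.to_numpy()] + rng.normal(0.0, noise_sd, (n_genera, len(months)))
    return pd.DataFrame(vals, index=genera, columns=months), labels


def _join_random(nodes: list[TreeNode], rng: np.random.Generator, scale: float) -> TreeNode:
    nodes = list(nodes)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        parent = TreeNode(children=[a, b])
        a.length = float(rng.exponential(scale)) + 1e-6
        b.length = float(rng.exponential(scale)) + 1e-6
        nodes.append(parent)
    return nodes[0]


def simulate_tree(
    otu_ids,
    seed: int,
    tax: TaxonomyMap | None = None,
    scale: float = 0.1,
) -> TreeNode:
    """Random rooted tree over the OTUs with exponential branch lengths.

    When a taxonomy is given, OTUs of the same genus are placed as a clade
    so the tree is consistent with the taxonomic grouping (Yule-style
    random joins within and between genus subtrees).
    """
    otu_ids = list(otu_ids)
    if len(otu_ids) < 2:
        raise ValueError("need at least 2 OTUs")
    rng = np.random.default_rng(seed)
    groups: dict[str, list[str]] = {}
    for o in otu_ids:
        label = tax.label_at(o, "genus") if tax is not None and o in tax else o
        groups.setdefault(label, []).append(o)
    subtrees = []
    for label in sorted(groups):
        tips = [TreeNode(name=o) for o in groups[label]]
        subtrees.append(tips[0] if len(tips) == 1 else _join_random(tips, rng, scale))
    root = subtrees[0] if len(subtrees) == 1 else _join_random(subtrees, rng, scale)
    root.length = None
    return root


def perturb_table(table: OtuTable, sd: float, seed: int) -> OtuTable:
    """Technical-replicate emulation: multiply each count by a small
    log-normal factor and re-draw reads multinomially at each sample's
    original depth."""
    rng = np.random.default_rng(seed)
    counts = table.counts.astype(float)
    noisy = counts * 10.0 ** rng.normal(0.0, sd, size=counts.shape)
    out = np.zeros_like(table.counts)
    for i in range(counts.shape[0]):
        depth = int(counts[i].sum())
        p = noisy[i] / noisy[i].sum()
        out[i] = rng.multinomial(depth, p)
    return OtuTable(pd.DataFrame(out, index=table.sample_ids, columns=table.otu_ids))


def make_permanova_fixture(
    n_groups: int = 9,
    n_per_group: int = 9,
    delta: float = 20.0,
    n_features: int = 5,
    seed: int = 0,
) -> tuple[DistanceMatrix, list[str]]:
    """Euclidean distance matrix of Gaussian point clouds with a
    between-group mean shift of ``delta`` within-group standard deviations.

    ``delta = 0`` gives an exchangeable null; ``delta >= 20`` guarantees
    the observed pseudo-F beats every label permutation.
    """
    rng = np.random.default_rng(seed)
    points = []
    labels = []
    dims = max(n_features, n_groups)
    for g in range(n_groups):
        mean = np.zeros(dims)
        mean[g] = delta
        points.append(mean + rng.normal(size=(n_per_group, dims)))
        labels.extend([f"G{g+1}"] * n_per_group)
    x = np.vstack(points)
    ids = [f"pt{i+1}" for i in range(x.shape[0])]
    return DistanceMatrix(squareform(pdist(x)), ids=ids), labels
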