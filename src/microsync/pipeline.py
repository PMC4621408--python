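"""End-to-end orchestration of the analysis stages.

Each stage reads the previous stage's TSV/Newick artifacts from the
output directory, computes, and writes its own artifacts there, so any
stage can be re-run in isolation. A single global seed is split into
independent per-stage seeds; every run appends its parameters and seeds
to ``run.log`` in the output directory.

Stages: simulate -> preprocess -> diversity -> ordinate -> stage ->
synchrony -> network -> modules -> report.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml
from skbio import DistanceMatrix, TreeNode

from . import cooccurrence as cooc
from . import diversity as dv
from . import mcode
from . import permstats as ps
from . import synchrony as sy
from .simulate import SimulationConfig, simulate_table, simulate_tree
from .table import (
    STAGES,
    OtuTable,
    SampleMetadata,
    aggregate_by_rank,
    filter_low_abundance,
    rarefy,
    read_otu_table,
    remove_lineage,
    write_otu_table,
)

__all__ = ["PipelineConfig", "PipelineError", "run", "SUBCOMMANDS"]

log = logging.getLogger("microsync")


class PipelineError(RuntimeError):
    pass


@dataclasses.dataclass
class PipelineConfig:
    outdir: str = "results/pipeline"
    # preprocess
    rarefaction_depth: int = 20_000
    filter_fraction: float = 1e-5
    exclude_rank: str = "class"
    exclude_name: str = "Chloroplast"
    # diversity / staging
    beta_metric: str = "unifrac"        # or "jaccard"
    stage_mode: str = "months"          # "months" (fixed map) or "upgma"
    upgma_k: int = 4
    # synchrony
    synchrony_k: int = 4
    k_range: tuple[int, ...] = tuple(range(2, 9))
    n_restarts: int = 100
    formula_agg: str = "sum"
    log_base: float = 10.0
    # networks
    threshold: float | None = 0.9       # None -> scale-free grid selection
    prevalence_fraction: float = 0.5
    min_nodes: int = 10
    # mcode
    vwp: float = 0.2
    haircut: bool = True
    fluff: bool = False
    module_source_stage: str = "Mar-Apr"
    # permutation tests
    n_permutations: int = 999
    seed: int = 0
    simulation: SimulationConfig = dataclasses.field(default_factory=SimulationConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("simulation", {})
        valid = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - valid
        if bad:
            raise PipelineError(
                f"invalid config keys {sorted(bad)}; valid keys: {sorted(valid)}"
            )
        sim_valid = {f.name for f in dataclasses.fields(SimulationConfig)}
        bad = set(sim_raw) - sim_valid
        if bad:
            raise PipelineError(
                f"invalid simulation keys {sorted(bad)}; valid: {sorted(sim_valid)}"
            )
        cfg = cls(**raw)
        cfg.simulation = SimulationConfig(**sim_raw)
        if "k_range" in raw:
            cfg.k_range = tuple(raw["k_range"])
        return cfg

    def stage_seed(self, name: str) -> int:
        """Deterministic per-stage seed derived from the global seed."""
        order = list(SUBCOMMANDS)
        ss = np.random.SeedSequence(self.seed, spawn_key=(order.index(name),))
        return int(ss.generate_state(1)[0] % (2**31))


def _out(cfg: PipelineConfig) -> Path:
    p = Path(cfg.outdir)
    p.mkdir(parents=True, exist_ok=True)
    return p


def _setup_log(cfg: PipelineConfig) -> None:
    if not any(
        isinstance(h, logging.FileHandler)
        and Path(getattr(h, "baseFilename", "")) == (_out(cfg) / "run.log").resolve()
        for h in log.handlers
    ):
        handler = logging.FileHandler(_out(cfg) / "run.log")
        handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
        log.addHandler(handler)
    log.setLevel(logging.INFO)


def _require(cfg: PipelineConfig, *names: str) -> list[Path]:
    paths = []
    for name in names:
        p = _out(cfg) / name
        if not p.exists():
            raise PipelineError(
                f"missing dependency {p}: run the earlier stage that produces it"
            )
        paths.append(p)
    return paths


def _read_dm(path: Path) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return DistanceMatrix(df.to_numpy(), ids=list(df.index))


def _write_dm(dm: DistanceMatrix, path: Path) -> None:
    pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids)).to_csv(path, sep="\t")


# -- stages -------------------------------------------------------------


def stage_simulate(cfg: PipelineConfig) -> None:
    sim = dataclasses.replace(cfg.simulation, seed=cfg.stage_seed("simulate"))
    log.info("simulate: %s", sim)
    table, tax, meta, truth = simulate_table(sim)
    out = _out(cfg)
    write_otu_table(table, out / "table.tsv", tax)
    meta.write(out / "metadata.tsv")
    tree = simulate_tree(table.otu_ids, seed=sim.seed + 1, tax=tax)
    (out / "tree.nwk").write_text(str(tree))
    truth.module_frame().to_csv(out / "truth_modules.tsv", sep="\t", index=False)
    truth.archetype_frame().to_csv(out / "truth_archetypes.tsv", sep="\t")


def stage_preprocess(cfg: PipelineConfig) -> None:
    (table_path,) = _require(cfg, "table.tsv")
    table, tax = read_otu_table(table_path)
    n0 = table.shape[1]
    table = filter_low_abundance(table, cfg.filter_fraction)
    if tax is not None:
        table = remove_lineage(table, tax, cfg.exclude_rank, cfg.exclude_name)
    seed = cfg.stage_seed("preprocess")
    rare = rarefy(table, cfg.rarefaction_depth, seed)
    log.info(
        "preprocess: %d -> %d OTUs after filters; rarefied %d samples to depth %d (seed %d)",
        n0, table.shape[1], rare.shape[0], cfg.rarefaction_depth, seed,
    )
    write_otu_table(rare, _out(cfg) / "rarefied.tsv", tax)


def stage_diversity(cfg: PipelineConfig) -> None:
    (rare_path,) = _require(cfg, "rarefied.tsv")
    table, _ = read_otu_table(rare_path)
    out = _out(cfg)
    tree = None
    if (out / "tree.nwk").exists():
        tree = TreeNode.read(str(out / "tree.nwk"))
    alpha = dv.alpha_diversity_frame(table, tree)
    alpha.to_csv(out / "alpha_diversity.tsv", sep="\t")
    _write_dm(dv.jaccard_matrix(table), out / "dm_jaccard.tsv")
    if tree is not None:
        _write_dm(dv.unweighted_unifrac(table, tree), out / "dm_unifrac.tsv")
    log.info("diversity: alpha metrics + beta distance matrices written")


def _beta_dm(cfg: PipelineConfig) -> DistanceMatrix:
    name = "dm_unifrac.tsv" if cfg.beta_metric == "unifrac" else "dm_jaccard.tsv"
    (path,) = _require(cfg, name)
    return _read_dm(path)


def stage_ordinate(cfg: PipelineConfig) -> None:
    dm = _beta_dm(cfg)
    out = _out(cfg)
    res = dv.pcoa(dm)
    res.coordinates.to_csv(out / "pcoa_coordinates.tsv", sep="\t")
    pd.DataFrame(
        {"eigenvalue": res.eigenvalues}
    ).to_csv(out / "pcoa_eigenvalues.tsv", sep="\t", index_label="axis")
    dendro = dv.upgma(dm)
    (out / "upgma.nwk").write_text(dendro.to_newick() + "\n")
    log.info("ordinate: PCoA (%d axes) and UPGMA written", res.coordinates.shape[1])


def stage_stage(cfg: PipelineConfig) -> None:
    """Assign samples to seasonal stages and test time/site/stage factors."""
    (meta_path,) = _require(cfg, "metadata.tsv")
    meta = SampleMetadata.read(meta_path)
    dm = _beta_dm(cfg)
    out = _out(cfg)
    if cfg.stage_mode == "upgma":
        dendro = dv.upgma(dm)
        groups = dendro.cut(cfg.upgma_k)
        for sid, g in groups.items():
            meta.set_stage(sid, f"group{g+1}")
    else:
        for sid in dm.ids:
            meta.set_stage(sid, None if sid not in meta else
                           next((s for s, ms in STAGES.items()
                                 if meta.month(sid) in ms), None))
    meta.write(out / "metadata_staged.tsv")
    seed = cfg.stage_seed("stage")
    rows = []
    for factor, lab in (
        ("month", {s: meta.month(s) for s in dm.ids}),
        ("site", {s: meta.site(s) for s in dm.ids}),
        ("stage", {s: meta.stage(s) or "none" for s in dm.ids}),
    ):
        res = ps.permanova(dm, lab, n_permutations=cfg.n_permutations, seed=seed)
        rows.append({"factor": factor, "pseudo_F": res.statistic,
                     "R2": res.effect_size, "p_value": res.p_value,
                     "n_permutations": res.n_permutations, "seed": seed})
        log.info("adonis %s: F=%.3f R2=%.3f p=%.4g", factor,
                 res.statistic, res.effect_size, res.p_value)
    pd.DataFrame(rows).to_csv(out / "adonis.tsv", sep="\t", index=False)


def stage_synchrony(cfg: PipelineConfig) -> None:
    rare_path, meta_path = _require(cfg, "rarefied.tsv", "metadata_staged.tsv")
    table, tax = read_otu_table(rare_path)
    if tax is None:
        raise PipelineError("synchrony requires a taxonomy column in rarefied.tsv")
    meta = SampleMetadata.read(meta_path)
    out = _out(cfg)
    genus = aggregate_by_rank(table, tax, "genus")
    profile = sy.month_abundance(genus, meta, agg=cfg.formula_agg, log_base=cfg.log_base)
    z = sy.zscore(profile)
    z.z.to_csv(out / "z_profiles.tsv", sep="\t")
    seed = cfg.stage_seed("synchrony")
    curve = sy.ss_ratio_curve(z, cfg.k_range, n_restarts=cfg.n_restarts, seed=seed)
    curve.to_csv(out / "ss_ratio_curve.tsv", sep="\t")
    fit = sy.kmeans_best(z, cfg.synchrony_k, n_restarts=cfg.n_restarts, seed=seed)
    fit.assignment.to_frame().to_csv(out / "genus_clusters.tsv", sep="\t")
    fit.centers.to_csv(out / "cluster_centers.tsv", sep="\t", index_label="cluster")
    # majority phylum per aggregated genus label, for the cluster summary
    phylum_votes: dict[str, dict[str, int]] = {}
    for otu in table.otu_ids:
        if otu in tax:
            label = tax.label_at(otu, "genus")
            phylum = tax.name_at(otu, "phylum") or "unclassified"
            phylum_votes.setdefault(label, {}).setdefault(phylum, 0)
            phylum_votes[label][phylum] += 1
    phylum_of = {g: max(v, key=v.get) for g, v in phylum_votes.items()}
    sy.cluster_summary(fit, genus, phylum_of).to_csv(
        out / "cluster_summary.tsv", sep="\t"
    )
    log.info(
        "synchrony: k=%d within_ss=%.2f between_ss=%.2f (seed %d, %d restarts); "
        "elbow at k=%d",
        cfg.synchrony_k, fit.within_ss, fit.between_ss, seed, cfg.n_restarts,
        sy.elbow_k(curve),
    )


def stage_network(cfg: PipelineConfig) -> None:
    rare_path, meta_path = _require(cfg, "rarefied.tsv", "metadata_staged.tsv")
    table, _ = read_otu_table(rare_path)
    meta = SampleMetadata.read(meta_path)
    out = _out(cfg)
    by_stage = meta.samples_by_stage(table.sample_ids)
    if not by_stage:
        raise PipelineError("no stage assignments; run the stage subcommand first")
    summary = []
    edges_frames = []
    for stage, sids in sorted(by_stage.items()):
        retained = cooc.prevalence_filter(table, sids, cfg.prevalence_fraction)
        cm = cooc.pcc_matrix(table, sids, retained)
        threshold = (
            cfg.threshold
            if cfg.threshold is not None
            else cooc.select_threshold(cm, min_nodes=cfg.min_nodes)
        )
        net = cooc.build_network(cm, threshold, stage=stage)
        nx.write_graphml(net, out / f"network_{stage}.graphml")
        rows = [
            {"otu_i": u, "otu_j": v, "pcc": d["weight"], "sign": d["sign"], "stage": stage}
            for u, v, d in net.edges(data=True)
        ]
        edges_frames.append(pd.DataFrame(rows))
        try:
            exponent, r2 = cooc.degree_powerlaw_fit(net)
        except cooc.CooccurrenceError:
            exponent, r2 = float("nan"), float("nan")
        summary.append({
            "stage": stage, "n_samples": len(sids), "threshold": threshold,
            "nodes": net.number_of_nodes(), "edges": net.number_of_edges(),
            "density": cooc.network_density(net),
            "powerlaw_exponent": exponent, "powerlaw_r2": r2,
        })
        log.info("network %s: %d nodes %d edges density %.2f (threshold %.2f)",
                 stage, net.number_of_nodes(), net.number_of_edges(),
                 cooc.network_density(net), threshold)
    pd.concat(edges_frames, ignore_index=True).to_csv(
        out / "edges.tsv", sep="\t", index=False
    )
    pd.DataFrame(summary).to_csv(out / "network_summary.tsv", sep="\t", index=False)


def stage_modules(cfg: PipelineConfig) -> None:
    (rare_path,) = _require(cfg, "rarefied.tsv")
    _require(cfg, "network_summary.tsv")
    _, tax = read_otu_table(rare_path)
    out = _out(cfg)
    nets = {}
    for p in sorted(out.glob("network_*.graphml")):
        stage = p.stem.removeprefix("network_")
        nets[stage] = nx.read_graphml(p)
        nets[stage].graph["stage"] = stage
    if cfg.module_source_stage not in nets:
        raise PipelineError(
            f"module source stage {cfg.module_source_stage!r} has no network; "
            f"available: {sorted(nets)}"
        )
    source = nets[cfg.module_source_stage]
    modules = mcode.find_complexes(
        source, vwp=cfg.vwp, haircut=cfg.haircut, fluff=cfg.fluff
    )[:10]
    rows = []
    for m in modules:
        fam = mcode.module_taxonomy(m, tax) if tax is not None else []
        rows.append({
            "rank": m.rank, "stage": m.stage, "size": len(m),
            "avg_degree": m.avg_degree, "score": m.score, "seed_node": m.seed,
            "members": ";".join(m.members),
            "families": ";".join(f"{f}:{c}" for f, c in fam),
        })
    pd.DataFrame(rows).to_csv(out / "modules.tsv", sep="\t", index=False)
    traces = mcode.trace_modules(modules, nets, cfg.module_source_stage)
    # annotate every stage's GraphML with traced module membership
    membership = {otu: m.rank for m in modules for otu in m.members}
    for stage, net in nets.items():
        for v in net.nodes:
            net.nodes[v]["module_rank"] = membership.get(v, 0)
        nx.write_graphml(net, out / f"network_{stage}.graphml")
    pd.DataFrame([
        {"module_rank": t.module_rank, "target_stage": t.target_stage,
         "retained": len(t.retained_members), "induced_edges": t.induced_edges,
         "edge_retention": t.edge_retention,
         "first_neighbors": len(t.first_neighbors)}
        for t in traces
    ]).to_csv(out / "module_traces.tsv", sep="\t", index=False)
    log.info("modules: %d modules in %s traced across %d stages",
             len(modules), cfg.module_source_stage, len(nets))


def stage_report(cfg: PipelineConfig) -> None:
    out = _out(cfg)
    parts = []
    for name in ("adonis.tsv", "cluster_summary.tsv", "network_summary.tsv",
                 "modules.tsv", "module_traces.tsv"):
        if (out / name).exists():
            parts.append(f"## {name}\n\n" + (out / name).read_text())
    if not parts:
        raise PipelineError("nothing to report: run earlier stages first")
    (out / "report.md").write_text("\n".join(parts))
    log.info("report: collated %d tables", len(parts))


SUBCOMMANDS = {
    "simulate": stage_simulate,
    "preprocess": stage_preprocess,
    "diversity": stage_diversity,
    "ordinate": stage_ordinate,
    "stage": stage_stage,
    "synchrony": stage_synchrony,
    "network": stage_network,
    "modules": stage_modules,
    "report": stage_report,
}


def run(subcommand: str, cfg: PipelineConfig) -> None:
    if subcommand not in SUBCOMMANDS:
        raise PipelineError(
            f"unknown subcommand {subcommand!r}; choose from {sorted(SUBCOMMANDS)}"
        )
    _setup_log(cfg)
    from . import __version__

    log.info(
        "run %s (microsync %s, numpy %s, outdir=%s, seed=%d)",
        subcommand, __version__, np.__version__, cfg.outdir, cfg.seed,
    )
    SUBCOMMANDS[subcommand](cfg)
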