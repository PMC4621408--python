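"""Emulate the lake survey: 81 samples (9 sites x 9 months), log-normal
genus abundances, 4 seasonal archetypes, per-stage planted co-occurrence
modules, a genus-consistent phylogeny, and ground-truth tables."""

from pathlib import Path

from config import make_config
from microsync.pipeline import run
from microsync.table import read_otu_table

cfg = make_config()
run("simulate", cfg)

table, tax = read_otu_table(Path(cfg.outdir) / "table.tsv")
print(f"simulated {table.shape[0]} samples x {table.shape[1]} OTUs "
      f"at depth {cfg.simulation.depth} (seed {cfg.seed})")
print(f"artifacts in {cfg.outdir}: table.tsv, metadata.tsv, tree.nwk, "
      f"truth_archetypes.tsv, truth_modules.tsv")
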