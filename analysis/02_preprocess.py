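"""Preprocess the OTU table: drop OTUs at <= 0.001% of total reads,
exclude the Chloroplast class, rarefy every sample to a common depth."""

from pathlib import Path

from config import make_config
from microsync.pipeline import run
from microsync.table import read_otu_table

cfg = make_config()
run("preprocess", cfg)

rare, _ = read_otu_table(Path(cfg.outdir) / "rarefied.tsv")
print(f"rarefied table: {rare.shape[0]} samples x {rare.shape[1]} OTUs, "
      f"each at {cfg.rarefaction_depth} reads -> rarefied.tsv")
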