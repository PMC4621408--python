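"""Assign samples to the four seasonal stages (Dec-Jan, Mar-Apr, May-Jun,
Aug-Oct) and test month, site and stage factors with one-way PERMANOVA;
screen per-genus stage differences with Kruskal-Wallis + Bonferroni."""

from pathlib import Path

import pandas as pd

from config import make_config
from microsync.pipeline import run
from microsync.permstats import kruskal_wallis_screen
from microsync.table import SampleMetadata, aggregate_by_rank, read_otu_table

cfg = make_config()
run("stage", cfg)

out = Path(cfg.outdir)
adonis = pd.read_csv(out / "adonis.tsv", sep="\t")
print("one-way PERMANOVA (9999 permutations):")
print(adonis.round(4).to_string(index=False))

table, tax = read_otu_table(out / "rarefied.tsv")
meta = SampleMetadata.read(out / "metadata_staged.tsv")
genus = aggregate_by_rank(table, tax, "genus")
stages = {s: meta.stage(s) for s in genus.sample_ids}
screen = kruskal_wallis_screen(genus, stages)
screen.to_csv(out / "kruskal_wallis_stage.tsv", sep="\t")
n_sig = int(screen["significant"].sum())
print(f"Kruskal-Wallis: {n_sig}/{len(screen)} genera differ between stages "
      f"(Bonferroni p < 0.05) -> kruskal_wallis_stage.tsv")
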