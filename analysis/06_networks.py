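"""Build one OTU co-occurrence network per seasonal stage: prevalence
filter (>= half the stage's samples), Pearson correlations of relative
abundances, |PCC| >= 0.9 edges; report density and power-law fit."""

from pathlib import Path

import pandas as pd

from config import make_config
from microsync.pipeline import run

cfg = make_config()
run("network", cfg)

out = Path(cfg.outdir)
summary = pd.read_csv(out / "network_summary.tsv", sep="\t")
print(f"per-stage networks at threshold {cfg.threshold}:")
print(summary.round(3).to_string(index=False))
print("-> edges.tsv, network_<stage>.graphml")
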