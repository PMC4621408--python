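"""Cluster genera by the synchrony of their monthly abundance profiles:
log10 month abundances -> per-genus Z-scores -> best-of-100 K-means, with
the within/between SS ratio guiding the choice of k."""

from pathlib import Path

import pandas as pd

from config import make_config
from microsync.pipeline import run
from microsync.synchrony import elbow_k

cfg = make_config()
run("synchrony", cfg)

out = Path(cfg.outdir)
curve = pd.read_csv(out / "ss_ratio_curve.tsv", sep="\t", index_col=0)
summary = pd.read_csv(out / "cluster_summary.tsv", sep="\t", index_col=0)
print("SS ratio by k:", {int(k): round(v, 3) for k, v in curve["ss_ratio"].items()})
print(f"largest relative drop at k = {elbow_k(curve)}; fitted k = {cfg.synchrony_k}")
print("clusters (abundance share and representatives):")
print(summary.assign(
    representatives=summary["representatives"].str.slice(0, 60)
).round(2).to_string())
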