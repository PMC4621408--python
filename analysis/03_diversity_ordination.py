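"""Alpha diversity per sample, Jaccard and unweighted-UniFrac distance
matrices, PCoA ordination and the UPGMA dendrogram of all samples."""

from pathlib import Path

import pandas as pd

from config import make_config
from microsync.pipeline import run

cfg = make_config()
run("diversity", cfg)
run("ordinate", cfg)

out = Path(cfg.outdir)
alpha = pd.read_csv(out / "alpha_diversity.tsv", sep="\t", index_col=0)
eig = pd.read_csv(out / "pcoa_eigenvalues.tsv", sep="\t", index_col=0)["eigenvalue"]
pos = eig[eig > 0]
print("alpha diversity (mean over samples):")
print(alpha.mean().round(3).to_string())
print(f"PCoA: first two axes explain "
      f"{100 * pos.iloc[0] / pos.sum():.1f}% + {100 * pos.iloc[1] / pos.sum():.1f}% "
      f"of positive inertia -> pcoa_coordinates.tsv, upgma.nwk")
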