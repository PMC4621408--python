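"""Shared configuration for the numbered analysis drivers.

One emulated lake survey (9 sites x 9 months, planted seasonal archetypes
and per-stage co-occurrence modules) analysed end to end. All drivers
write into results/survey/ and are deterministic for the global seed.
"""

from pathlib import Path

from microsync.pipeline import PipelineConfig
from microsync.simulate import SimulationConfig

SEED = 20120101  # nominal first sampling date of the emulated survey year

RESULTS = Path(__file__).resolve().parent.parent / "results" / "survey"


def make_config() -> PipelineConfig:
    return PipelineConfig(
        outdir=str(RESULTS),
        seed=SEED,
        rarefaction_depth=20_000,
        synchrony_k=4,
        k_range=tuple(range(2, 9)),
        n_restarts=100,
        threshold=0.9,
        n_permutations=9999,
        module_source_stage="Mar-Apr",
        simulation=SimulationConfig(seed=SEED),
    )
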