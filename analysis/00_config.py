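"""Shared configuration for the numbered analysis drivers.

One seeded synthetic study stands in for a genus's EST download: 60 genes
with microsatellites planted in known contexts, sequenced into a redundant,
error-bearing EST set.  All drivers share the working directory
``results/analysis`` so each stage reads its predecessor's outputs.
"""

from pathlib import Path

from ssrmine import pipeline as pl
from ssrmine.synthetic_data import SimParams

SEED = 1
ROOT = Path(__file__).resolve().parent.parent
WORKDIR = ROOT / "results" / "analysis"


def make_config() -> pl.PipelineConfig:
    return pl.PipelineConfig(
        outdir=WORKDIR,
        seed=SEED,
        sim=SimParams(seed=SEED, n_genes=60),
    )
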