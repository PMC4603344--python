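"""Simulate the study data: an annotated toy genome and a redundant EST set.

Writes reference.fasta / annotation.gff3 / ests.fasta plus the ground-truth
tables under results/analysis, and prints what was planted where.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from importlib import import_module

config_mod = import_module("00_config")

from ssrmine import pipeline as pl


def main() -> None:
    cfg = config_mod.make_config()
    records, truth = pl.run_stage("simulate", cfg)
    planted = truth.ssrs[truth.ssrs["planted"]]
    print(f"genome: {len(truth.reference[cfg.sim.chrom]):,} bp, "
          f"{len(truth.genes)} genes")
    by_context = {k: int(v) for k, v in planted["context"].value_counts().items()}
    print(f"planted SSRs: {len(planted)} ({by_context})")
    print(f"spontaneous background SSRs: {int((~truth.ssrs['planted']).sum())}")
    print(f"EST records: {len(records)} -> {cfg.outdir}/ests.fasta")


if __name__ == "__main__":
    main()
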