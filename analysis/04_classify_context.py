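"""Align SSR-bearing unique sequences back to the annotated genome and
classify each repeat's context: exon (CDS), UTR, intron, or genomic."""

import sys
from importlib import import_module
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
config_mod = import_module("00_config")

from ssrmine import pipeline as pl


def main() -> None:
    cfg = config_mod.make_config()
    calls, table = pl.run_stage("context", cfg)
    print(f"{len(calls)} context calls -> {cfg.outdir}/context_calls.tsv")
    print(f"exclusion fraction (no significant hit): "
          f"{table.exclusion_fraction:.3f}")
    print(table.to_wide(index="period", columns="category"))


if __name__ == "__main__":
    main()
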