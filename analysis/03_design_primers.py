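"""Design flanking primer pairs for every mined SSR; only loci with a fully
compliant pair (length/Tm/GC/product-size windows) enter the marker catalog."""

import sys
from importlib import import_module
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
config_mod = import_module("00_config")

from ssrmine import pipeline as pl


def main() -> None:
    cfg = config_mod.make_config()
    catalog = pl.run_stage("primers", cfg)
    print(f"{len(catalog)} loci with compliant primer pairs "
          f"-> {cfg.outdir}/catalog.tsv")
    if catalog:
        best = min(catalog, key=lambda t: t[1].penalty)
        locus, pair = best
        print(f"best-penalty pair ({pair.penalty:.2f}): "
              f"({locus.motif})_{locus.repeat_count} on {locus.unique_seq_id}, "
              f"product {pair.product_size} bp, "
              f"Tm {pair.tm_f:.1f}/{pair.tm_r:.1f} degC")


if __name__ == "__main__":
    main()
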