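"""Collapse redundant ESTs into unique sequences, apply the >100 bp filter,
and mine perfect Class-I microsatellites; print the funnel counts."""

import sys
from importlib import import_module
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
config_mod = import_module("00_config")

from ssrmine import pipeline as pl


def main() -> None:
    cfg = config_mod.make_config()
    records, uniques, filtered = pl.run_stage("reduce", cfg)
    contigs = sum(1 for u in uniques if u.kind == "contig")
    print(f"{len(records)} EST records -> {len(uniques)} unique sequences "
          f"({contigs} contigs, {len(uniques) - contigs} singletons)")
    print(f"{len(filtered)} unique sequences longer than {cfg.min_length} bp")
    filtered, loci = pl.run_stage("mine", cfg)
    sources = len({l.unique_seq_id for l in loci})
    print(f"{len(loci)} perfect Class-I SSR loci on {sources} sequences "
          f"-> {cfg.outdir}/loci.tsv")
    by_period = {}
    for l in loci:
        by_period[l.period] = by_period.get(l.period, 0) + 1
    print(f"by period: {dict(sorted(by_period.items()))}")


if __name__ == "__main__":
    main()
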