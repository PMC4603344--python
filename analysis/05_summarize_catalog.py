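"""Compositional summaries of the mined catalog (repeat types, motif
families) plus a bar figure of family counts, and comparison with the
planted ground truth."""

import sys
from importlib import import_module
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
config_mod = import_module("00_config")

import pandas as pd

from ssrmine import pipeline as pl
from ssrmine import synthetic_data as syn
from ssrmine.io_formats import read_fasta


def main() -> None:
    cfg = config_mod.make_config()
    table = pl.run_stage("summarize", cfg)
    print(f"{table.grand_total} loci summarized")
    fam = table.margin("canonical_family").sort_values(ascending=False)
    print("family counts:")
    print(fam.to_string())
    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(7, 3.5))
        fam.plot.bar(ax=ax, color="#4477aa")
        ax.set_ylabel("SSR count")
        ax.set_xlabel("canonical motif family")
        fig.tight_layout()
        fig.savefig(cfg.outdir / "family_counts.png", dpi=120)
        print(f"figure -> {cfg.outdir}/family_counts.png")
    except ImportError:
        print("matplotlib unavailable; skipped the figure")


if __name__ == "__main__":
    main()
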