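"""Stage orchestration: simulate -> reduce -> mine -> primers -> context -> summarize.

Each stage reads its upstream outputs from the working directory, writes its
own outputs there, and appends a manifest line (stage, parameter digest,
output checksums), so re-running any stage with unchanged inputs reproduces
identical checksums.  ``run_all`` chains the stages and reports the funnel
counts: input records -> unique sequences -> length-filtered -> SSR-bearing
-> primer-bearing.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import genome_context, io_formats, primer_design, redundancy, ssr_detect
from . import summarize as summarize_mod
from . import synthetic_data

log = logging.getLogger("ssrmine")

STAGES = ("simulate", "reduce", "mine", "primers", "context", "summarize")


class StageDependencyError(RuntimeError):
    """An upstream stage's outputs are missing."""


@dataclass
class PipelineConfig:
    outdir: Path
    seed: int = 0
    genus: str | None = None
    input_fasta: Path | None = None  # if unset, the simulate stage provides input
    reference_fasta: Path | None = None
    annotation_gff3: Path | None = None
    alignments_tsv: Path | None = None
    min_length: int = 100
    mining: ssr_detect.MiningParams = field(default_factory=ssr_detect.MiningParams)
    cluster: redundancy.ClusterParams = field(default_factory=redundancy.ClusterParams)
    primers: primer_design.PrimerParams = field(default_factory=primer_design.PrimerParams)
    significance: genome_context.SignificanceParams = field(
        default_factory=genome_context.SignificanceParams
    )
    sim: synthetic_data.SimParams | None = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        if self.sim is None:
            self.sim = synthetic_data.SimParams(seed=self.seed)

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "PipelineConfig":
        """Flat key: value YAML file; explicit keyword overrides win."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update(overrides)
        kwargs: dict = {}
        simple = {
            "outdir", "seed", "genus", "input_fasta", "reference_fasta",
            "annotation_gff3", "alignments_tsv", "min_length", "log_level",
        }
        for key, value in raw.items():
            if key in simple:
                kwargs[key] = value
            elif key == "relaxed" and value:
                kwargs["mining"] = ssr_detect.MiningParams.relaxed()
            elif key.startswith("min_repeats_"):
                period = int(key.rsplit("_", 1)[1])
                mining = kwargs.setdefault("mining", ssr_detect.MiningParams())
                mining.min_repeats = dict(mining.min_repeats)
                mining.min_repeats[period] = int(value)
            elif key.startswith("sim_"):
                sim_kwargs = kwargs.setdefault("_sim_kwargs", {})
                sim_kwargs[key[4:]] = value
            else:
                raise ValueError(f"unknown configuration key {key!r}")
        sim_kwargs = kwargs.pop("_sim_kwargs", {})
        cfg = cls(**kwargs)
        if sim_kwargs:
            cfg.sim = synthetic_data.SimParams(
                seed=cfg.seed, **sim_kwargs
            )
        return cfg


def _digest(obj) -> str:
    return hashlib.sha256(repr(obj).encode()).hexdigest()[:16]


def _file_digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _manifest_append(config: PipelineConfig, stage: str, params, outputs: list[Path]):
    entry = {
        "stage": stage,
        "params": _digest(params),
        "outputs": {p.name: _file_digest(p) for p in outputs},
    }
    with open(config.outdir / "manifest.jsonl", "a") as fh:
        fh.write(json.dumps(entry, sort_keys=True) + "\n")
    return entry


def _require(config: PipelineConfig, stage: str, *paths: Path) -> None:
    missing = [p for p in paths if not p.exists()]
    if missing:
        raise StageDependencyError(
            f"stage {stage!r} requires outputs of an earlier stage; missing: "
            + ", ".join(str(p) for p in missing)
        )


# ---------------------------------------------------------------------------
# Stages


def stage_simulate(config: PipelineConfig):
    config.outdir.mkdir(parents=True, exist_ok=True)
    truth = synthetic_data.simulate_genome(config.sim)
    records, truth = synthetic_data.simulate_ests(truth, config.sim)
    out = config.outdir
    ref_records = [
        type("R", (), {"id": name, "sequence": seq})
        for name, seq in truth.reference.items()
    ]
    io_formats.write_fasta(ref_records, out / "reference.fasta")
    io_formats.write_gff3(truth.genes, out / "annotation.gff3")
    io_formats.write_fasta(records, out / "ests.fasta")
    truth.ssrs.to_csv(out / "truth_ssrs.tsv", sep="\t", index=False)
    truth.fragments.to_csv(out / "truth_fragments.tsv", sep="\t", index=False)
    _manifest_append(
        config, "simulate", config.sim,
        [out / n for n in ("reference.fasta", "annotation.gff3", "ests.fasta",
                           "truth_ssrs.tsv", "truth_fragments.tsv")],
    )
    return records, truth


def stage_reduce(config: PipelineConfig, records=None):
    out = config.outdir
    out.mkdir(parents=True, exist_ok=True)
    if records is None:
        src = config.input_fasta or out / "ests.fasta"
        _require(config, "reduce", Path(src))
        records = io_formats.read_fasta(
            src, genus=config.genus or (None if config.input_fasta else config.sim.genus)
        )
    uniques = redundancy.reduce_redundancy(records, config.cluster)
    filtered = redundancy.filter_min_length(uniques, config.min_length)
    io_formats.write_fasta(uniques, out / "uniques.fasta")
    io_formats.write_fasta(filtered, out / "uniques_filtered.fasta")
    membership = pd.DataFrame(
        [
            {"unique_id": u.id, "kind": u.kind, "member_id": m}
            for u in uniques
            for m in u.member_ids
        ]
    )
    membership.to_csv(out / "membership.tsv", sep="\t", index=False)
    _manifest_append(
        config, "reduce", config.cluster,
        [out / n for n in ("uniques.fasta", "uniques_filtered.fasta",
                           "membership.tsv")],
    )
    log.info(
        "reduce: %d records -> %d unique (%d contigs) -> %d after >%d bp filter",
        len(records), len(uniques),
        sum(1 for u in uniques if u.kind == "contig"),
        len(filtered), config.min_length,
    )
    return records, uniques, filtered


def _load_filtered(config: PipelineConfig, stage: str = "mine") -> list[redundancy.UniqueSequence]:
    out = config.outdir
    _require(config, stage, out / "uniques_filtered.fasta", out / "membership.tsv")
    membership = pd.read_csv(out / "membership.tsv", sep="\t")
    by_unique = membership.groupby("unique_id")
    kinds = dict(zip(membership["unique_id"], membership["kind"]))
    members = {uid: list(grp["member_id"]) for uid, grp in by_unique}
    genus = config.genus or config.sim.genus
    return [
        redundancy.UniqueSequence(
            id=r.id, kind=kinds[r.id], sequence=r.sequence,
            member_ids=members[r.id], genus=genus,
        )
        for r in io_formats.read_fasta(out / "uniques_filtered.fasta", genus=genus)
    ]


def stage_mine(config: PipelineConfig, filtered=None):
    out = config.outdir
    if filtered is None:
        filtered = _load_filtered(config)
    loci = ssr_detect.mine_genus(filtered, config.mining)
    frame = pd.DataFrame(
        [
            {
                "unique_seq_id": L.unique_seq_id,
                "genus": L.genus,
                "start": L.start + 1,  # 1-based inclusive at the file boundary
                "end": L.end,
                "period": L.period,
                "motif": L.motif,
                "repeat_count": L.repeat_count,
                "canonical_family": L.canonical_family,
                "display_alias": L.display_alias,
            }
            for L in loci
        ],
        columns=["unique_seq_id", "genus", "start", "end", "period", "motif",
                 "repeat_count", "canonical_family", "display_alias"],
    )
    frame.to_csv(out / "loci.tsv", sep="\t", index=False)
    _manifest_append(config, "mine", config.mining.min_repeats, [out / "loci.tsv"])
    log.info("mine: %d loci on %d/%d unique sequences",
             len(loci), len({L.unique_seq_id for L in loci}), len(filtered))
    return filtered, loci


def _load_loci(config: PipelineConfig, stage: str = "primers") -> list[ssr_detect.SSRLocus]:
    out = config.outdir
    _require(config, stage, out / "loci.tsv")
    frame = pd.read_csv(out / "loci.tsv", sep="\t")
    loci = []
    for _, r in frame.iterrows():
        loci.append(
            ssr_detect.SSRLocus(
                unique_seq_id=r["unique_seq_id"], genus=r["genus"],
                start=int(r["start"]) - 1, end=int(r["end"]),
                period=int(r["period"]), motif=r["motif"],
                repeat_count=int(r["repeat_count"]),
                canonical_family=r["canonical_family"],
                display_alias=r["display_alias"],
            )
        )
    return loci


def stage_primers(config: PipelineConfig, filtered=None, loci=None):
    out = config.outdir
    if filtered is None:
        filtered = _load_filtered(config)
    if loci is None:
        loci = _load_loci(config)
    templates = {u.id: u for u in filtered}
    catalog = primer_design.catalog_with_primers(loci, templates, config.primers)
    frame = pd.DataFrame(
        [
            {
                "locus_id": f"{L.unique_seq_id}:{L.start + 1}-{L.end}",
                "unique_seq_id": L.unique_seq_id,
                "motif": f"({L.motif})_{L.repeat_count}",
                "canonical_family": L.canonical_family,
                "forward": P.forward_seq,
                "reverse": P.reverse_seq,
                "product_size": P.product_size,
                "tm_f": f"{P.tm_f:.2f}",
                "tm_r": f"{P.tm_r:.2f}",
                "penalty": f"{P.penalty:.4f}",
                "tm_model": P.tm_model,
            }
            for L, P in catalog
        ],
        columns=["locus_id", "unique_seq_id", "motif", "canonical_family",
                 "forward", "reverse", "product_size", "tm_f", "tm_r",
                 "penalty", "tm_model"],
    )
    frame.to_csv(out / "catalog.tsv", sep="\t", index=False)
    _manifest_append(config, "primers", config.primers, [out / "catalog.tsv"])
    log.info("primers: %d/%d loci designable", len(catalog), len(loci))
    return catalog


def stage_context(config: PipelineConfig, filtered=None, loci=None):
    out = config.outdir
    if filtered is None:
        filtered = _load_filtered(config, "context")
    if loci is None:
        loci = _load_loci(config, "context")
    ref_path = config.reference_fasta or out / "reference.fasta"
    gff_path = config.annotation_gff3 or out / "annotation.gff3"
    genes = None
    hits_by_query: dict[str, list] = {}
    if config.alignments_tsv:
        hits = io_formats.read_alignments_tabular(config.alignments_tsv)
        for h in hits:
            hits_by_query.setdefault(h.query_id, []).append(h)
        _require(config, "context", Path(gff_path))
        genes = io_formats.read_gff3(gff_path)
    else:
        _require(config, "context", Path(ref_path), Path(gff_path))
        genes = io_formats.read_gff3(gff_path)
        reference = {
            r.id: r.sequence for r in io_formats.read_fasta(ref_path)
        }
        index = genome_context.ReferenceIndex(reference)
        ssr_sources = {L.unique_seq_id for L in loci}
        for u in filtered:
            if u.id in ssr_sources:
                hits_by_query[u.id] = genome_context.align_local(
                    u.sequence, index, query_id=u.id
                )
    calls = [
        genome_context.classify_context(
            L, hits_by_query.get(L.unique_seq_id, []), genes, config.significance
        )
        for L in loci
    ]
    frame = pd.DataFrame(
        [
            {
                "unique_seq_id": c.ssr.unique_seq_id,
                "start": c.ssr.start + 1,
                "end": c.ssr.end,
                "period": c.ssr.period,
                "canonical_family": c.ssr.canonical_family,
                "category": c.category,
                "subject_id": c.subject_id or "",
                "subject_start": "" if c.subject_interval is None
                else c.subject_interval[0] + 1,
                "subject_end": "" if c.subject_interval is None
                else c.subject_interval[1],
            }
            for c in calls
        ],
        columns=["unique_seq_id", "start", "end", "period", "canonical_family",
                 "category", "subject_id", "subject_start", "subject_end"],
    )
    frame.to_csv(out / "context_calls.tsv", sep="\t", index=False)
    table = genome_context.context_table(calls)
    table.to_wide(index="period", columns="category").to_csv(
        out / "context_table.tsv", sep="\t"
    )
    _manifest_append(
        config, "context", config.significance,
        [out / "context_calls.tsv", out / "context_table.tsv"],
    )
    log.info("context: %d calls, exclusion fraction %.3f",
             len(calls), table.exclusion_fraction)
    return calls, table


def stage_summarize(config: PipelineConfig, loci=None, taxa=None):
    out = config.outdir
    if loci is None:
        loci = _load_loci(config, "summarize")
    if taxa is None:
        genus = config.genus or config.sim.genus
        taxa = io_formats.load_taxonomy(extra={genus: "Eudicotyledoneae"})
    table = summarize_mod.compose_counts(loci, taxa)
    table.to_wide(index="genus", columns="period").to_csv(
        out / "counts_by_period.tsv", sep="\t"
    )
    fam = table.margin("canonical_family").sort_index()
    fam.to_csv(out / "counts_by_family.tsv", sep="\t", header=["count"])
    _manifest_append(
        config, "summarize", None,
        [out / "counts_by_period.tsv", out / "counts_by_family.tsv"],
    )
    return table


def run_stage(name: str, config: PipelineConfig):
    """Run one named stage against the working directory."""
    if name not in STAGES:
        raise ValueError(f"unknown stage {name!r}; expected one of {STAGES}")
    return {
        "simulate": stage_simulate,
        "reduce": stage_reduce,
        "mine": stage_mine,
        "primers": stage_primers,
        "context": stage_context,
        "summarize": stage_summarize,
    }[name](config)


def run_all(config: PipelineConfig, with_context: bool | None = None) -> dict:
    """Execute the full pipeline; returns the funnel report.

    The context stage runs when a reference+annotation is available (always
    true for simulated input unless explicitly disabled).
    """
    logging.basicConfig(level=config.log_level)
    config.outdir.mkdir(parents=True, exist_ok=True)
    truth = None
    if config.input_fasta is None:
        records, truth = stage_simulate(config)
    else:
        records = io_formats.read_fasta(config.input_fasta, genus=config.genus)
    records, uniques, filtered = stage_reduce(config, records)
    filtered, loci = stage_mine(config, filtered)
    catalog = stage_primers(config, filtered, loci)
    if with_context is None:
        with_context = (
            config.input_fasta is None
            or (config.reference_fasta is not None
                and config.annotation_gff3 is not None)
            or config.alignments_tsv is not None
        )
    calls = table = None
    if with_context:
        calls, table = stage_context(config, filtered, loci)
    summary = stage_summarize(config, loci)
    ssr_sources = {L.unique_seq_id for L in loci}
    catalog_sources = {L.unique_seq_id for L, _ in catalog}
    report = {
        "n_input_records": len(records),
        "n_unique": len(uniques),
        "n_contigs": sum(1 for u in uniques if u.kind == "contig"),
        "n_singletons": sum(1 for u in uniques if u.kind == "singleton"),
        "n_length_filtered": len(filtered),
        "n_ssr_bearing": len(ssr_sources),
        "n_primer_bearing": len(catalog_sources),
        "n_loci": len(loci),
        "n_catalog": len(catalog),
    }
    if calls is not None:
        report["n_context_calls"] = len(calls)
        report["exclusion_fraction"] = table.exclusion_fraction
    with open(config.outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    log.info("funnel: %s", report)
    result = {"report": report, "loci": loci, "catalog": catalog,
              "uniques": uniques, "filtered": filtered, "records": records,
              "summary": summary}
    if truth is not None:
        result["truth"] = truth
    if calls is not None:
        result["calls"] = calls
        result["context_table"] = table
    return result
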