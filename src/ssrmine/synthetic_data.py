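"""Synthetic annotated genomes, transcripts and EST sets with planted SSRs.

From a single seed this module generates (i) a toy genome of multi-exon
genes with UTR-exon-intron architecture on an i.i.d. background of given GC
content, with microsatellites planted at known positions in known contexts
(CDS, UTR, intron, intergenic); (ii) redundant, error-bearing EST fragment
sets drawn from the spliced mRNAs, with configurable minority fractions of
intron-retaining pre-mRNA fragments, intergenic genomic fragments, short
(<100 bp) fragments, and exact duplicates; and (iii) ground-truth tables
keyed so that every pipeline stage can be scored without external data.

Planted repeats are inserted (flanks displaced, never overwritten) with the
bases adjacent to the run forced off the repeat's periodicity, so the
ground-truth repeat count is exactly what the miner should report.  Because
a random background occasionally contains genuine repeat runs, the final
genome is re-mined and such spontaneous loci are recorded in the ground
truth alongside the planted ones.

A single numpy Generator seeded once drives every draw, so identical
(params, seed) reproduce byte-identical artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import ESTRecord, GeneModel
from .ssr_detect import (
    MiningParams,
    canonical_family,
    find_perfect_ssrs,
    is_primitive,
    revcomp,
)

CONTEXTS = ("CDS", "UTR", "intron", "intergenic")
#: truth context -> the category the classifier should call
CONTEXT_TO_CATEGORY = {
    "CDS": "exon",
    "UTR": "UTR",
    "intron": "intron",
    "intergenic": "genomic",
}

_BASES = np.array(list("ACGT"))


def _default_family_freqs() -> dict[str, dict[str, float]]:
    # tri-enriched in coding sequence, di-enriched in untranslated/non-coding
    return {
        "CDS": {"ACC": 0.30, "AAG": 0.25, "CCG": 0.15, "AGG": 0.10,
                "AGC": 0.10, "AAGGAG": 0.10},
        "UTR": {"AG": 0.45, "AC": 0.15, "AT": 0.10, "AAG": 0.20,
                "AAAT": 0.05, "AAAAT": 0.05},
        "intron": {"AG": 0.35, "AT": 0.25, "AC": 0.15, "AAT": 0.15,
                   "AAAT": 0.10},
        "intergenic": {"AG": 0.30, "AT": 0.25, "AC": 0.15, "AAT": 0.15,
                       "AAAT": 0.10, "AAAAT": 0.05},
    }


@dataclass
class SimParams:
    """Generator knobs; defaults emulate a plant EST study at toy scale."""

    seed: int = 0
    n_genes: int = 100
    exon_count_range: tuple[int, int] = (2, 5)
    exon_len_range: tuple[int, int] = (150, 400)
    intron_len_range: tuple[int, int] = (130, 350)
    utr_len_range: tuple[int, int] = (130, 250)
    intergenic_len_range: tuple[int, int] = (300, 800)
    gc_background: float = 0.44
    ssr_plant_rate: float = 0.5
    context_mix: dict[str, float] = field(
        default_factory=lambda: {"CDS": 0.43, "UTR": 0.33,
                                 "intron": 0.12, "intergenic": 0.12}
    )
    family_freqs: dict[str, dict[str, float]] = field(
        default_factory=_default_family_freqs
    )
    repeat_count_range: dict[int, tuple[int, int]] = field(
        default_factory=lambda: {2: (10, 16), 3: (7, 12), 4: (5, 8),
                                 5: (4, 6), 6: (4, 5)}
    )
    coverage_per_transcript: float = 3.0
    fragment_len_range: tuple[int, int] = (250, 700)
    error_rate: float = 0.002
    intron_retention_rate: float = 0.05
    genomic_fragment_rate: float = 0.05
    short_fragment_rate: float = 0.05
    duplicate_rate: float = 0.15
    guarantee_ssr_coverage: bool = True
    flank_guarantee: int = 60
    genus: str = "Synthea"
    chrom: str = "chr1"

    def __post_init__(self) -> None:
        if abs(sum(self.context_mix.values()) - 1.0) > 1e-9:
            raise ValueError("context_mix must sum to 1")
        for ctx, freqs in self.family_freqs.items():
            if ctx not in CONTEXTS:
                raise ValueError(f"unknown context {ctx!r}")
            if abs(sum(freqs.values()) - 1.0) > 1e-9:
                raise ValueError(f"family_freqs[{ctx}] must sum to 1")
            for motif in freqs:
                if not is_primitive(motif) or set(motif) - set("ACGT"):
                    raise ValueError(f"bad motif {motif!r}")
                if len(motif) not in self.repeat_count_range:
                    raise ValueError(f"no repeat_count_range for {motif!r}")
        for rate in (self.ssr_plant_rate, self.error_rate,
                     self.intron_retention_rate, self.genomic_fragment_rate,
                     self.short_fragment_rate, self.duplicate_rate):
            if not 0 <= rate <= 1:
                raise ValueError("rates must lie in [0, 1]")

    def marginal_family_freqs(self, contexts: Sequence[str] | None = None):
        """Family frequencies marginalized over (a subset of) contexts,
        expressed on canonical family names."""
        contexts = list(contexts or CONTEXTS)
        weight = {c: self.context_mix[c] for c in contexts}
        z = sum(weight.values())
        out: dict[str, float] = {}
        for c in contexts:
            for motif, p in self.family_freqs[c].items():
                fam = canonical_family(motif)[0]
                out[fam] = out.get(fam, 0.0) + p * weight[c] / z
        return out


@dataclass
class GroundTruth:
    """Everything needed to score the pipeline against the simulation."""

    params: SimParams
    reference: dict[str, str]
    genes: list[GeneModel]
    ssrs: pd.DataFrame  # one row per planted or spontaneous SSR
    mrna_seqs: dict[str, str]
    premrna_seqs: dict[str, str]
    gene_offsets: dict[str, int]  # genome start of each gene's pre-mRNA
    intergenic: list[tuple[int, int]]  # genome intervals
    fragments: pd.DataFrame | None = None

    def covered_ssr_ids(
        self, flank: int | None = None, clean_run: bool = False
    ) -> set[str]:
        """Planted SSRs covered (run + flank on both sides) by at least one
        retained (>100 bp) fragment in the appropriate source sequence.

        With ``clean_run``, a covering fragment only counts when none of its
        substitution errors fall inside the repeat run itself -- an error in
        the run legitimately destroys the perfect repeat, so such loci are
        excluded from recall denominators at nonzero error rates.
        """
        if self.fragments is None:
            raise ValueError("fragments not simulated yet")
        flank = self.params.flank_guarantee if flank is None else flank
        covered: set[str] = set()
        frags = self.fragments[~self.fragments["is_short"]]
        by_key: dict[tuple, list[tuple[int, int, set[int]]]] = {}
        for _, f in frags.iterrows():
            errors = (
                {int(x) + int(f["src_start"]) for x in str(f["error_positions"]).split(",") if x}
                if clean_run and f["n_errors"]
                else set()
            )
            by_key.setdefault((f["source"], f["gene_id"]), []).append(
                (int(f["src_start"]), int(f["src_end"]), errors)
            )
        for _, s in self.ssrs[self.ssrs["planted"]].iterrows():
            if s["context"] in ("CDS", "UTR"):
                lo, hi = s["mrna_start"] - flank, s["mrna_end"] + flank
                keys = [("mRNA", s["gene_id"]), ("premRNA", s["gene_id"])]
                pre = (s["pre_start"] - flank, s["pre_end"] + flank)
            elif s["context"] == "intron":
                lo, hi = s["pre_start"] - flank, s["pre_end"] + flank
                keys = [("premRNA", s["gene_id"])]
                pre = (lo, hi)
            else:
                lo, hi = s["g_start"] - flank, s["g_end"] + flank
                keys = [("genomic", "")]
                pre = (lo, hi)
            for key in keys:
                want = pre if key[0] == "premRNA" else (lo, hi)
                run = (want[0] + flank, want[1] - flank)  # the repeat itself
                if any(
                    a <= want[0]
                    and want[1] <= b
                    and not any(run[0] <= e < run[1] for e in errs)
                    for a, b, errs in by_key.get(key, [])
                ):
                    covered.add(s["ssr_id"])
                    break
        return covered


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_BASES, size=length, p=probs))


def _break_periodicity(seq: list[str], pos: int, banned: str,
                       rng: np.random.Generator) -> None:
    """Force seq[pos] to differ from ``banned`` (keeps everything ACGT)."""
    if 0 <= pos < len(seq) and seq[pos] == banned:
        choices = [b for b in "ACGT" if b != banned]
        seq[pos] = choices[int(rng.integers(len(choices)))]


def simulate_genome(params: SimParams) -> GroundTruth:
    """Build the annotated toy genome with planted SSRs and ground truth."""
    rng = np.random.default_rng(params.seed)
    contexts = list(params.context_mix)
    ctx_probs = np.array([params.context_mix[c] for c in contexts])

    chrom_parts: list[str] = []
    genes: list[GeneModel] = []
    ssr_rows: list[dict] = []
    mrna_seqs: dict[str, str] = {}
    premrna_seqs: dict[str, str] = {}
    gene_offsets: dict[str, int] = {}
    intergenic: list[tuple[int, int]] = []
    pos = 0
    ssr_serial = 0

    def rint(lohi: tuple[int, int]) -> int:
        return int(rng.integers(lohi[0], lohi[1] + 1))

    def plant(segment: list[str], context: str) -> dict:
        """Insert one SSR into a mutable segment; return its local record."""
        nonlocal ssr_serial
        freqs = params.family_freqs[context]
        motifs = sorted(freqs)
        motif = motifs[int(rng.choice(len(motifs), p=np.array([freqs[m] for m in motifs])))]
        p = len(motif)
        count = rint(params.repeat_count_range[p])
        fg = params.flank_guarantee
        if len(segment) < 2 * fg + 2:
            raise ValueError(
                f"segment of {len(segment)} bp too short to host an SSR with "
                f"{fg} bp flanks; enlarge the feature length ranges"
            )
        off = int(rng.integers(fg, len(segment) - fg))
        run = list(motif * count)
        _break_periodicity(segment, off - 1, motif[p - 1], rng)
        _break_periodicity(segment, off, motif[0], rng)
        new = segment[:off] + run + segment[off:]
        segment.clear()
        segment.extend(new)
        ssr_serial += 1
        canon, alias = canonical_family(motif)
        return {
            "ssr_id": f"ssr{ssr_serial:04d}",
            "context": context,
            "motif": motif,
            "period": p,
            "repeat_count": count,
            "canonical_family": canon,
            "local_start": off,
            "local_end": off + p * count,
        }

    for gi in range(1, params.n_genes + 1):
        gene_id = f"g{gi:04d}"
        spacer = list(_random_seq(rng, rint(params.intergenic_len_range),
                                  params.gc_background))
        plant_here = rng.random() < params.ssr_plant_rate
        context = (
            contexts[int(rng.choice(len(contexts), p=ctx_probs))]
            if plant_here
            else None
        )
        spacer_ssr = None
        if context == "intergenic":
            spacer_ssr = plant(spacer, "intergenic")
        intergenic.append((pos, pos + len(spacer)))
        if spacer_ssr is not None:
            spacer_ssr.update(
                gene_id="",
                g_start=pos + spacer_ssr["local_start"],
                g_end=pos + spacer_ssr["local_end"],
            )
            ssr_rows.append(spacer_ssr)
        chrom_parts.append("".join(spacer))
        pos += len(spacer)

        # gene architecture: 5'UTR, (exon, intron)*, exon, 3'UTR
        n_exons = rint(params.exon_count_range)
        segments: list[tuple[str, list[str]]] = [
            ("five_prime_UTR",
             list(_random_seq(rng, rint(params.utr_len_range), params.gc_background)))
        ]
        for e in range(n_exons):
            segments.append(
                ("CDS",
                 list(_random_seq(rng, rint(params.exon_len_range),
                                  params.gc_background)))
            )
            if e < n_exons - 1:
                segments.append(
                    ("intron",
                     list(_random_seq(rng, rint(params.intron_len_range),
                                      params.gc_background)))
                )
        segments.append(
            ("three_prime_UTR",
             list(_random_seq(rng, rint(params.utr_len_range), params.gc_background)))
        )
        gene_ssr = None
        if context in ("CDS", "UTR", "intron"):
            want = {"CDS": ["CDS"], "UTR": ["five_prime_UTR", "three_prime_UTR"],
                    "intron": ["intron"]}[context]
            candidates = [i for i, (t, _) in enumerate(segments) if t in want]
            if not candidates:  # single-exon gene has no intron: fall back
                candidates = [i for i, (t, _) in enumerate(segments) if t == "CDS"]
                context = "CDS"
            idx = int(rng.choice(candidates))
            gene_ssr = plant(segments[idx][1], context)
            gene_ssr["segment_index"] = idx

        gene_start = pos
        gene_offsets[gene_id] = gene_start
        features: list[tuple[str, int, int]] = []
        mrna_chunks: list[str] = []
        pre_chunks: list[str] = []
        local = 0
        mrna_pos = 0
        for idx, (ftype, seg) in enumerate(segments):
            seq = "".join(seg)
            features.append((ftype, gene_start + local, gene_start + local + len(seq)))
            pre_chunks.append(seq)
            if gene_ssr is not None and gene_ssr.get("segment_index") == idx:
                gene_ssr.update(
                    gene_id=gene_id,
                    g_start=gene_start + local + gene_ssr["local_start"],
                    g_end=gene_start + local + gene_ssr["local_end"],
                    pre_start=local + gene_ssr["local_start"],
                    pre_end=local + gene_ssr["local_end"],
                )
                if ftype != "intron":
                    gene_ssr.update(
                        mrna_start=mrna_pos + gene_ssr["local_start"],
                        mrna_end=mrna_pos + gene_ssr["local_end"],
                    )
            if ftype != "intron":
                mrna_chunks.append(seq)
                mrna_pos += len(seq)
            local += len(seq)
        if gene_ssr is not None:
            gene_ssr.pop("segment_index", None)
            ssr_rows.append(gene_ssr)
        genes.append(
            GeneModel(gene_id=gene_id, seq_id=params.chrom, strand="+",
                      features=tuple(features))
        )
        mrna_seqs[gene_id] = "".join(mrna_chunks)
        premrna_seqs[gene_id] = "".join(pre_chunks)
        chrom_parts.append("".join(pre_chunks))
        pos += local
    tail = _random_seq(rng, rint(params.intergenic_len_range), params.gc_background)
    intergenic.append((pos, pos + len(tail)))
    chrom_parts.append(tail)
    genome = "".join(chrom_parts)

    columns = ["ssr_id", "gene_id", "context", "motif", "period", "repeat_count",
               "canonical_family", "g_start", "g_end", "pre_start", "pre_end",
               "mrna_start", "mrna_end"]
    ssrs = pd.DataFrame(ssr_rows).reindex(columns=columns + ["local_start", "local_end"])
    ssrs = ssrs.drop(columns=["local_start", "local_end"])
    ssrs["planted"] = True

    # verify every planted run reads back exactly, then record spontaneous runs
    for _, s in ssrs.iterrows():
        g0, g1 = int(s["g_start"]), int(s["g_end"])
        assert genome[g0:g1] == s["motif"] * int(s["repeat_count"]), s["ssr_id"]

    planted_intervals = [(int(s["g_start"]), int(s["g_end"])) for _, s in ssrs.iterrows()]
    spont_rows = []
    for locus in find_perfect_ssrs(genome, MiningParams()):
        if any(not (locus.end <= a or locus.start >= b) for a, b in planted_intervals):
            continue
        ssr_serial += 1
        spont_rows.append(
            {"ssr_id": f"ssr{ssr_serial:04d}", "gene_id": "", "context": "spontaneous",
             "motif": locus.motif, "period": locus.period,
             "repeat_count": locus.repeat_count,
             "canonical_family": locus.canonical_family,
             "g_start": locus.start, "g_end": locus.end, "planted": False}
        )
    if spont_rows:
        ssrs = pd.concat([ssrs, pd.DataFrame(spont_rows)], ignore_index=True)

    return GroundTruth(
        params=params,
        reference={params.chrom: genome},
        genes=genes,
        ssrs=ssrs,
        mrna_seqs=mrna_seqs,
        premrna_seqs=premrna_seqs,
        gene_offsets=gene_offsets,
        intergenic=intergenic,
    )


def _apply_errors(seq: str, rate: float, rng: np.random.Generator):
    if rate <= 0:
        return seq, []
    n = rng.binomial(len(seq), rate)
    if n == 0:
        return seq, []
    positions = sorted(rng.choice(len(seq), size=n, replace=False).tolist())
    out = list(seq)
    for p in positions:
        alternatives = [b for b in "ACGT" if b != out[p]]
        out[p] = alternatives[int(rng.integers(3))]
    return "".join(out), positions


def simulate_ests(
    truth: GroundTruth, params: SimParams | None = None
) -> tuple[list[ESTRecord], GroundTruth]:
    """Draw redundant, error-bearing EST fragments from the simulated genes.

    Fragment bookkeeping (source, interval, strand, error positions,
    duplicate group, short flag) is appended to the ground truth.
    """
    params = params or truth.params
    rng = np.random.default_rng(params.seed + 1)
    genome = truth.reference[params.chrom]
    records: list[ESTRecord] = []
    rows: list[dict] = []
    serial = 0
    dup_group = 0

    def emit(source: str, gene_id: str | None, src_seq: str,
             lo: int, hi: int, forced: bool = False) -> None:
        nonlocal serial, dup_group
        frag = src_seq[lo:hi]
        is_short = False
        if not forced and rng.random() < params.short_fragment_rate:
            cut = int(rng.integers(40, 100))
            if cut < hi - lo:
                hi = lo + cut
                frag = src_seq[lo:hi]
            is_short = len(frag) <= 100
        frag, errors = _apply_errors(frag, params.error_rate, rng)
        strand = "+" if rng.random() < 0.5 else "-"
        stored = frag if strand == "+" else revcomp(frag)
        dup_group += 1
        copies = 1 + (1 if rng.random() < params.duplicate_rate else 0)
        for _ in range(copies):
            serial += 1
            records.append(
                ESTRecord(id=f"{params.genus}_est{serial:05d}",
                          genus=params.genus, sequence=stored)
            )
            rows.append(
                {"frag_id": f"{params.genus}_est{serial:05d}", "source": source,
                 "gene_id": gene_id, "src_start": lo, "src_end": hi,
                 "strand": strand, "n_errors": len(errors),
                 "error_positions": ",".join(map(str, errors)),
                 "dup_group": f"d{dup_group:05d}",
                 "is_short": len(stored) <= 100}
            )

    def draw_fragment(src_seq: str, need_span: tuple[int, int] | None = None):
        flen = int(rng.integers(*params.fragment_len_range))
        flen = min(flen, len(src_seq))
        if need_span is not None:
            lo_n = max(0, need_span[0])
            hi_n = min(len(src_seq), need_span[1])
            flen = max(flen, hi_n - lo_n)
            flen = min(flen, len(src_seq))
            lo_min = max(0, hi_n - flen)
            lo_max = min(lo_n, len(src_seq) - flen)
            lo = int(rng.integers(lo_min, lo_max + 1)) if lo_max >= lo_min else lo_min
        else:
            lo = int(rng.integers(0, len(src_seq) - flen + 1))
        return lo, lo + flen

    for gene in truth.genes:
        gid = gene.gene_id
        n_frags = rng.poisson(params.coverage_per_transcript)
        for _ in range(n_frags):
            r = rng.random()
            if r < params.genomic_fragment_rate:
                span = truth.intergenic[int(rng.integers(len(truth.intergenic)))]
                lo, hi = draw_fragment(genome[span[0]:span[1]])
                emit("genomic", "", genome, span[0] + lo, span[0] + hi)
            elif r < params.genomic_fragment_rate + params.intron_retention_rate:
                src = truth.premrna_seqs[gid]
                lo, hi = draw_fragment(src)
                emit("premRNA", gid, src, lo, hi)
            else:
                src = truth.mrna_seqs[gid]
                lo, hi = draw_fragment(src)
                emit("mRNA", gid, src, lo, hi)

    if params.guarantee_ssr_coverage:
        fg = params.flank_guarantee
        for _, s in truth.ssrs[truth.ssrs["planted"]].iterrows():
            if s["context"] in ("CDS", "UTR"):
                src = truth.mrna_seqs[s["gene_id"]]
                span = (int(s["mrna_start"]) - fg, int(s["mrna_end"]) + fg)
                lo, hi = draw_fragment(src, need_span=span)
                emit("mRNA", s["gene_id"], src, lo, hi, forced=True)
            elif s["context"] == "intron" and params.intron_retention_rate > 0:
                src = truth.premrna_seqs[s["gene_id"]]
                span = (int(s["pre_start"]) - fg, int(s["pre_end"]) + fg)
                lo, hi = draw_fragment(src, need_span=span)
                emit("premRNA", s["gene_id"], src, lo, hi, forced=True)
            elif s["context"] == "intergenic" and params.genomic_fragment_rate > 0:
                span = (int(s["g_start"]) - fg, int(s["g_end"]) + fg)
                lo, hi = draw_fragment(genome, need_span=span)
                emit("genomic", "", genome, lo, hi, forced=True)

    truth.fragments = pd.DataFrame(
        rows,
        columns=["frag_id", "source", "gene_id", "src_start", "src_end",
                 "strand", "n_errors", "error_positions", "dup_group", "is_short"],
    )
    return records, truth


# ---------------------------------------------------------------------------
# Scoring helpers against the ground truth


def match_loci_to_truth(loci, uniques, truth: GroundTruth) -> dict[int, str]:
    """Map mined locus indices to planted ssr_ids.

    A mined locus matches a planted SSR when its unique sequence contains a
    fragment covering that SSR (run plus guard flanks) and the
    (canonical_family, period, repeat_count) signatures agree.
    """
    frag_cover: dict[str, set[str]] = {}
    covered = truth.covered_ssr_ids()
    frags = truth.fragments
    planted = truth.ssrs[truth.ssrs["planted"]]
    fg = truth.params.flank_guarantee
    for _, s in planted.iterrows():
        if s["ssr_id"] not in covered:
            continue
        if s["context"] in ("CDS", "UTR"):
            key_src, gene, lo, hi = "mRNA", s["gene_id"], s["mrna_start"], s["mrna_end"]
        elif s["context"] == "intron":
            key_src, gene, lo, hi = "premRNA", s["gene_id"], s["pre_start"], s["pre_end"]
        else:
            key_src, gene, lo, hi = "genomic", "", s["g_start"], s["g_end"]
        sel = frags[
            (frags["source"] == key_src)
            & (frags["gene_id"] == gene)
            & (frags["src_start"] <= lo - fg)
            & (frags["src_end"] >= hi + fg)
        ]
        for fid in sel["frag_id"]:
            frag_cover.setdefault(fid, set()).add(s["ssr_id"])
    member_to_unique = {
        mid: u.id for u in uniques for mid in u.member_ids
    }
    unique_ssrs: dict[str, set[str]] = {}
    for fid, ssr_ids in frag_cover.items():
        uid = member_to_unique.get(fid)
        if uid:
            unique_ssrs.setdefault(uid, set()).update(ssr_ids)
    sig = {
        row["ssr_id"]: (row["canonical_family"], row["period"], row["repeat_count"])
        for _, row in planted.iterrows()
    }
    matches: dict[int, str] = {}
    for i, locus in enumerate(loci):
        for ssr_id in sorted(unique_ssrs.get(locus.unique_seq_id, ())):
            if sig[ssr_id] == (locus.canonical_family, locus.period, locus.repeat_count):
                matches[i] = ssr_id
                break
    return matches


def planted_recall(
    loci, uniques, truth: GroundTruth, clean_run: bool | None = None
) -> float:
    """Fraction of covered planted SSRs recovered by the miner.

    At nonzero error rates the denominator excludes, by default, SSRs whose
    every covering fragment has an error inside the run (the perfect repeat
    is genuinely absent from the EST set).
    """
    if clean_run is None:
        clean_run = truth.params.error_rate > 0
    covered = truth.covered_ssr_ids(clean_run=clean_run)
    if not covered:
        return float("nan")
    matches = match_loci_to_truth(loci, uniques, truth)
    return len(set(matches.values()) & covered) / len(covered)
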