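"""Constraint-based PCR primer-pair selection around microsatellite loci.

A locus enters the final marker catalog only if at least one primer pair
flanking the repeat satisfies every hard constraint: primer length 18-23 nt
(optimum 20), melting temperature 55-65 degC (optimum 60), GC content 30-70 %
(optimum 50 %), product size 90-320 bp, pair Tm difference and a
self-complementarity screen.  Surviving pairs are ranked by a weighted
penalty of deviations from the optima; ties go to the smaller product, then
the leftmost forward primer.

Two melting-temperature models are provided: a nearest-neighbor two-state
estimate (the default; Biopython's Tm_NN under 50 mM monovalent salt and
500 nM total oligonucleotide), and the closed-form GC-linear approximation
Tm = 64.9 + 41*(nGC - 16.4)/N for testable arithmetic.  The model and its
conditions are recorded on every pair.

Hairpin/dimer thermodynamics and mispriming libraries of a full primer
picker are intentionally not modeled; a longest self-complementary-run
screen stands in for them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Sequence

from Bio.SeqUtils import MeltingTemp

from .redundancy import UniqueSequence
from .ssr_detect import SSRLocus, revcomp


@dataclass(frozen=True)
class PrimerParams:
    len_range: tuple[int, int] = (18, 23)
    len_opt: int = 20
    tm_range: tuple[float, float] = (55.0, 65.0)
    tm_opt: float = 60.0
    gc_range: tuple[float, float] = (0.30, 0.70)
    gc_opt: float = 0.50
    product_size_range: tuple[int, int] = (90, 320)
    max_tm_difference: float = 3.0
    max_self_complementary_run: int = 8
    tm_model: str = "nearest_neighbor"  # or "gc_linear"
    salt_mM: float = 50.0
    oligo_nM: float = 500.0
    w_len: float = 1.0
    w_tm: float = 1.0
    w_gc: float = 0.5  # per percentage point
    w_pair: float = 1.0

    def __post_init__(self) -> None:
        for lo, hi, opt in (
            (*self.len_range, self.len_opt),
            (*self.tm_range, self.tm_opt),
            (*self.gc_range, self.gc_opt),
        ):
            if not lo <= opt <= hi:
                raise ValueError("range does not contain its optimum")
        if self.product_size_range[0] > self.product_size_range[1]:
            raise ValueError("empty product size range")
        if self.tm_model not in ("nearest_neighbor", "gc_linear"):
            raise ValueError(f"unknown tm_model {self.tm_model!r}")


@dataclass
class PrimerPair:
    """A compliant forward/reverse primer pair around one SSR locus."""

    ssr: SSRLocus
    forward_seq: str
    reverse_seq: str  # 5'->3' on the minus strand
    f_start: int
    f_end: int
    r_start: int
    r_end: int
    tm_f: float
    tm_r: float
    gc_f: float
    gc_r: float
    penalty: float
    tm_model: str = "nearest_neighbor"

    @property
    def product_size(self) -> int:
        return self.r_end - self.f_start


def gc_fraction(seq: str) -> float:
    """(#G + #C) / length; ambiguity codes are an error."""
    if not seq:
        raise ValueError("empty sequence")
    if set(seq) - set("ACGT"):
        raise ValueError(f"ambiguity codes in {seq!r}")
    return (seq.count("G") + seq.count("C")) / len(seq)


@lru_cache(maxsize=200_000)
def _tm_nn_cached(seq: str, salt_mM: float, oligo_nM: float) -> float:
    # two-state nearest-neighbor estimate; total strand conc = oligo_nM
    return MeltingTemp.Tm_NN(
        seq, Na=salt_mM, dnac1=oligo_nM / 2, dnac2=oligo_nM / 2
    )


def melting_temperature(
    seq: str,
    model: str = "nearest_neighbor",
    salt_mM: float = 50.0,
    oligo_nM: float = 500.0,
) -> float:
    """Duplex melting temperature in degC for a primer-length oligo."""
    if set(seq) - set("ACGT"):
        raise ValueError(f"ambiguity codes in {seq!r}")
    if len(seq) < 14:
        raise ValueError("sequence shorter than 14 nt: Tm formulas invalid")
    if model == "gc_linear":
        ngc = seq.count("G") + seq.count("C")
        return 64.9 + 41.0 * (ngc - 16.4) / len(seq)
    if model == "nearest_neighbor":
        return _tm_nn_cached(seq, salt_mM, oligo_nM)
    raise ValueError(f"unknown tm model {model!r}")


def longest_self_complementary_run(seq: str) -> int:
    """Length of the longest substring whose reverse complement also occurs
    in the sequence (a proxy for self-annealing potential)."""
    n = len(seq)
    for L in range(n, 0, -1):
        subs = {seq[i : i + L] for i in range(n - L + 1)}
        if any(revcomp(s) in subs for s in subs):
            return L
    return 0


def _single_primer_ok(seq: str, params: PrimerParams) -> tuple[float, float] | None:
    """Return (tm, gc) if the primer passes all single-primer constraints."""
    if set(seq) - set("ACGT"):
        return None
    gc = gc_fraction(seq)
    if not params.gc_range[0] <= gc <= params.gc_range[1]:
        return None
    tm = melting_temperature(seq, params.tm_model, params.salt_mM, params.oligo_nM)
    if not params.tm_range[0] <= tm <= params.tm_range[1]:
        return None
    if longest_self_complementary_run(seq) > params.max_self_complementary_run:
        return None
    return tm, gc


def _pair_penalty(
    len_f: int, len_r: int, tm_f: float, tm_r: float, gc_f: float, gc_r: float,
    params: PrimerParams,
) -> float:
    return (
        params.w_len * (abs(len_f - params.len_opt) + abs(len_r - params.len_opt))
        + params.w_tm * (abs(tm_f - params.tm_opt) + abs(tm_r - params.tm_opt))
        + params.w_gc
        * (
            abs(gc_f - params.gc_opt) * 100.0
            + abs(gc_r - params.gc_opt) * 100.0
        )
        + params.w_pair * abs(tm_f - tm_r)
    )


def design_primers(
    template: UniqueSequence | str,
    ssr: SSRLocus,
    params: PrimerParams | None = None,
) -> list[PrimerPair]:
    """All compliant primer pairs for one SSR, best penalty first.

    Enumerates every forward window wholly left of the repeat and every
    reverse window wholly right of it that could yield an in-range product,
    discards windows violating any hard constraint, then scores and sorts
    the surviving pairs.  An empty result marks the SSR as undesignable.
    """
    params = params or PrimerParams()
    seq = template.sequence if hasattr(template, "sequence") else template
    n = len(seq)
    lmin, lmax = params.len_range
    pmin, pmax = params.product_size_range
    # product = r_end - f_start constrains the searchable flanks
    f_lo = max(0, ssr.end - pmax)
    r_hi = min(n, ssr.start + pmax)
    forwards = []
    for f_end in range(min(ssr.start, n) , f_lo + lmin - 1, -1):
        for L in range(lmin, lmax + 1):
            f_start = f_end - L
            if f_start < f_lo:
                continue
            cand = seq[f_start:f_end]
            ok = _single_primer_ok(cand, params)
            if ok:
                forwards.append((f_start, f_end, cand, *ok))
    reverses = []
    for r_start in range(ssr.end, r_hi - lmin + 1):
        for L in range(lmin, lmax + 1):
            r_end = r_start + L
            if r_end > r_hi or r_end > n:
                continue
            cand = revcomp(seq[r_start:r_end])
            ok = _single_primer_ok(cand, params)
            if ok:
                reverses.append((r_start, r_end, cand, *ok))
    pairs: list[PrimerPair] = []
    for f_start, f_end, fseq, tm_f, gc_f in forwards:
        for r_start, r_end, rseq, tm_r, gc_r in reverses:
            product = r_end - f_start
            if not pmin <= product <= pmax:
                continue
            if abs(tm_f - tm_r) > params.max_tm_difference:
                continue
            pairs.append(
                PrimerPair(
                    ssr=ssr,
                    forward_seq=fseq,
                    reverse_seq=rseq,
                    f_start=f_start,
                    f_end=f_end,
                    r_start=r_start,
                    r_end=r_end,
                    tm_f=tm_f,
                    tm_r=tm_r,
                    gc_f=gc_f,
                    gc_r=gc_r,
                    penalty=_pair_penalty(
                        f_end - f_start, r_end - r_start,
                        tm_f, tm_r, gc_f, gc_r, params,
                    ),
                    tm_model=params.tm_model,
                )
            )
    pairs.sort(key=lambda p: (p.penalty, p.product_size, p.f_start))
    return pairs


def catalog_with_primers(
    loci: Sequence[SSRLocus],
    templates: dict[str, UniqueSequence],
    params: PrimerParams | None = None,
) -> list[tuple[SSRLocus, PrimerPair]]:
    """Retain exactly the loci with a designable pair, best pair attached."""
    params = params or PrimerParams()
    catalog = []
    for locus in loci:
        pairs = design_primers(templates[locus.unique_seq_id], locus, params)
        if pairs:
            catalog.append((locus, pairs[0]))
    return catalog
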