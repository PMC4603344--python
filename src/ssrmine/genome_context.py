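"""Genomic-context classification of EST-borne microsatellites.

Each SSR-bearing unique sequence is aligned to an annotated reference; the
SSR interval is projected through the best alignment onto reference
coordinates and classified by its overlap with gene-model features into one
of four categories: exon (CDS), UTR (5' and 3' merged), intron, or genomic
(no annotated feature).  Sequences without a significant hit are excluded
from context statistics and reported as a no_hit fraction -- mirroring the
common situation where a fraction of database ESTs fails to match its
nominal source genome (contamination, misassignment).

The internal aligner is a toy-scale seed-and-chain local aligner: exact
k-mer seeds grouped by diagonal, ungapped X-drop extension, then collinear
chaining of segments into multi-block hits so that spliced queries produce
blocks flanking introns.  Pre-computed 12-column tabular alignments from an
external aligner are accepted interchangeably.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Sequence

from .io_formats import AlignmentHit, GeneModel
from .ssr_detect import SSRLocus, revcomp


@dataclass
class SignificanceParams:
    """What counts as a significant hit.

    ``evalue`` mode uses the E-value carried by external alignments;
    ``identity_length`` mode (internal aligner, which has no E-value model)
    requires a minimum identity over a minimum aligned length.
    """

    mode: str = "identity_length"
    evalue_max: float = 1e-5
    min_identity: float = 0.90
    min_aligned_length: int = 50

    def __post_init__(self) -> None:
        if self.mode not in ("evalue", "identity_length"):
            raise ValueError(f"unknown significance mode {self.mode!r}")
        if min(self.evalue_max, self.min_identity, self.min_aligned_length) <= 0:
            raise ValueError("significance thresholds must be positive")

    def is_significant(self, hit: AlignmentHit) -> bool:
        if self.mode == "evalue" and hit.significance is not None:
            return hit.significance <= self.evalue_max
        return (
            hit.percent_identity >= self.min_identity
            and hit.aligned_length >= self.min_aligned_length
        )


CATEGORIES = ("exon", "UTR", "intron", "genomic", "no_hit")
_PRIORITY = {"exon": 0, "UTR": 1, "intron": 2}


@dataclass
class ContextCall:
    ssr: SSRLocus
    category: str
    subject_id: str | None = None
    subject_interval: tuple[int, int] | None = None
    overlap_fractions: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"bad category {self.category!r}")


# ---------------------------------------------------------------------------
# Internal seed-and-chain aligner


@dataclass
class AlignScoring:
    match: int = 1
    mismatch: int = -2
    xdrop: int = 10
    kmer_size: int = 11
    max_subject_gap: int = 20_000  # intron-scale chaining
    max_query_gap: int = 25


class ReferenceIndex:
    """Exact k-mer index over one or more reference sequences."""

    def __init__(self, references: dict[str, str], k: int = 11):
        self.k = k
        self.references = {name: seq.upper() for name, seq in references.items()}
        self.index: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for name, seq in self.references.items():
            for i in range(len(seq) - k + 1):
                kmer = seq[i : i + k]
                if "N" not in kmer:
                    self.index[kmer].append((name, i))


def _extend_segments(
    q: str, s: str, positions: list[tuple[int, int]], scoring: AlignScoring
) -> list[tuple[int, int, int]]:
    """Merge/extend same-diagonal seed positions into (q0, q1, matches)."""
    k = scoring.kmer_size
    segments: list[tuple[int, int, int]] = []  # query intervals on this diagonal
    diag = positions[0][1] - positions[0][0]
    qpos = sorted(p[0] for p in positions)
    used_until = -1
    for qp in qpos:
        if qp <= used_until:
            continue
        # extend right from the seed with X-drop
        q1 = qp + k
        best_q1, score, best = qp + k, k * scoring.match, k * scoring.match
        i = q1
        while i < len(q) and i + diag < len(s):
            score += scoring.match if q[i] == s[i + diag] else scoring.mismatch
            i += 1
            if score > best:
                best, best_q1 = score, i
            elif best - score > scoring.xdrop:
                break
        # extend left
        q0, best_q0 = qp, qp
        score = best
        i = qp - 1
        while i >= 0 and i + diag >= 0:
            score += scoring.match if q[i] == s[i + diag] else scoring.mismatch
            if score > best:
                best, best_q0 = score, i
            elif best - score > scoring.xdrop:
                break
            i -= 1
        matches = sum(
            1 for t in range(best_q0, best_q1) if q[t] == s[t + diag]
        )
        segments.append((best_q0, best_q1, matches))
        used_until = best_q1 - 1
    # merge overlapping segments on the diagonal
    segments.sort()
    merged: list[list[int]] = []
    for q0, q1, m in segments:
        if merged and q0 <= merged[-1][1]:
            if q1 > merged[-1][1]:
                extra = sum(
                    1 for t in range(merged[-1][1], q1) if q[t] == s[t + diag]
                )
                merged[-1][1] = q1
                merged[-1][2] += extra
        else:
            merged.append([q0, q1, m])
    return [tuple(x) for x in merged]


_CHAIN_OVERLAP_SLACK = 40  # bases of extension overshoot tolerated at junctions


def _chain(hsps: list[tuple[int, int, int, int, int]], scoring: AlignScoring):
    """Best collinear chain over HSPs (q0, q1, s0, s1, matches); DP by score.

    Small query overlaps between neighbouring HSPs (chance matches across a
    splice junction) are allowed here and trimmed by the caller.
    """
    if not hsps:
        return []
    hsps = sorted(hsps, key=lambda h: (h[0], h[2]))
    n = len(hsps)
    best_score = [h[4] for h in hsps]
    prev = [-1] * n
    for i in range(n):
        q0i, _, s0i, _, mi = hsps[i]
        for j in range(i):
            _, q1j, _, s1j, _ = hsps[j]
            if (
                -_CHAIN_OVERLAP_SLACK <= q0i - q1j <= scoring.max_query_gap
                and -_CHAIN_OVERLAP_SLACK <= s0i - s1j <= scoring.max_subject_gap
            ):
                # overlaps are double-counted matches: charge them, so chains
                # of mutually overlapping low-complexity HSPs never pay
                overlap = max(q1j - q0i, s1j - s0i, 0)
                cand = best_score[j] + mi - 2 * overlap
                if cand > best_score[i]:
                    best_score[i] = cand
                    prev[i] = j
    end = max(range(n), key=lambda i: best_score[i])
    chain = []
    while end != -1:
        chain.append(hsps[end])
        end = prev[end]
    chain.reverse()
    # trim query overlaps: advance the later block's start on both axes
    trimmed = [list(chain[0])]
    for q0, q1, s0, s1, m in chain[1:]:
        prev_q1, prev_s1 = trimmed[-1][1], trimmed[-1][3]
        delta = max(prev_q1 - q0, prev_s1 - s0, 0)
        q0, s0, m = q0 + delta, s0 + delta, max(m - delta, 0)
        if q0 >= q1 or s0 >= s1:
            continue
        trimmed.append([q0, q1, s0, s1, m])
    return [tuple(x) for x in trimmed]


def align_local(
    query: str,
    reference: ReferenceIndex | dict[str, str] | str,
    scoring: AlignScoring | None = None,
    query_id: str = "query",
) -> list[AlignmentHit]:
    """Local alignment of a query against toy-scale references, both strands.

    Returns at most one chained hit per (subject, strand); substitutions are
    absorbed by X-drop extension, and intron-scale gaps in the subject become
    separate blocks of one hit.
    """
    scoring = scoring or AlignScoring()
    if isinstance(reference, str):
        reference = {"ref": reference}
    if not isinstance(reference, ReferenceIndex):
        reference = ReferenceIndex(reference, k=scoring.kmer_size)
    k = reference.k
    hits: list[AlignmentHit] = []
    qlen = len(query)
    for strand in "+-":
        q = query.upper() if strand == "+" else revcomp(query.upper())
        seeds: dict[tuple[str, int], list[tuple[int, int]]] = defaultdict(list)
        for i in range(len(q) - k + 1):
            for name, sp in reference.index.get(q[i : i + k], ()):
                seeds[(name, sp - i)].append((i, sp))
        per_subject: dict[str, list[tuple[int, int, int, int, int]]] = defaultdict(list)
        for (name, diag), positions in seeds.items():
            s = reference.references[name]
            for q0, q1, m in _extend_segments(q, s, positions, scoring):
                per_subject[name].append((q0, q1, q0 + diag, q1 + diag, m))
        for name, hsps in per_subject.items():
            # trim query overlaps between neighbouring HSPs before chaining
            hsps.sort(key=lambda h: (h[0], h[2]))
            chain = _chain(hsps, scoring)
            if not chain:
                continue
            blocks = []
            matches = 0
            aligned = 0
            for q0, q1, s0, s1, m in chain:
                if strand == "+":
                    blocks.append((q0, q1, s0, s1))
                else:
                    blocks.append((qlen - q1, qlen - q0, s0, s1))
                matches += m
                aligned += q1 - q0
            if strand == "-":
                blocks.sort(key=lambda b: b[0])
            if aligned == 0:
                continue
            hits.append(
                AlignmentHit(
                    query_id=query_id,
                    subject_id=name,
                    blocks=blocks,
                    percent_identity=matches / aligned,
                    aligned_length=aligned,
                    subject_strand=strand,
                )
            )
    hits.sort(key=lambda h: -(h.percent_identity * h.aligned_length))
    return hits


# ---------------------------------------------------------------------------
# Projection and classification


def project_interval(
    hit: AlignmentHit, q_interval: tuple[int, int]
) -> tuple[int, int] | None:
    """Project a query interval through the hit's blocks onto the subject.

    Returns the subject interval spanned by the first and last aligned base,
    or None when fewer than half of the interval's bases are aligned.
    """
    a, b = q_interval
    if a < 0 or b < a:
        raise ValueError(f"bad query interval {q_interval}")
    qspan = hit.query_span
    if b > max(qspan[1], a):
        # interval beyond the aligned query region is permitted; bounds
        # outside the query itself are the caller's error, checked loosely
        pass
    aligned = 0
    s_points: list[int] = []
    minus = hit.subject_strand == "-"
    for q0, q1, s0, s1 in hit.blocks:
        lo, hi = max(a, q0), min(b, q1)
        if lo >= hi:
            continue
        aligned += hi - lo
        if minus:
            # within a minus-strand block, ascending q maps to descending s
            s_points.extend((s1 - (lo - q0), s1 - (hi - q0)))
        else:
            s_points.extend((s0 + (lo - q0), s0 + (hi - q0)))
    if aligned * 2 < (b - a) or not s_points:
        return None
    return min(s_points), max(s_points)


def best_hit(
    hits: Sequence[AlignmentHit], params: SignificanceParams
) -> AlignmentHit | None:
    sig = [h for h in hits if params.is_significant(h)]
    if not sig:
        return None
    if params.mode == "evalue" and all(h.significance is not None for h in sig):
        return min(
            sig,
            key=lambda h: (h.significance, -h.percent_identity * h.aligned_length),
        )
    return max(sig, key=lambda h: h.percent_identity * h.aligned_length)


def classify_context(
    ssr: SSRLocus,
    hits: Sequence[AlignmentHit],
    genes: Sequence[GeneModel],
    params: SignificanceParams | None = None,
) -> ContextCall:
    """Classify one SSR as exon / UTR / intron / genomic / no_hit.

    Takes the best significant hit of the SSR's source sequence, projects the
    repeat interval onto the reference, and assigns the majority-overlap
    feature type (ties broken exon > UTR > intron); projections overlapping
    no annotated feature are 'genomic'.
    """
    params = params or SignificanceParams()
    hit = best_hit(hits, params)
    if hit is None:
        return ContextCall(ssr=ssr, category="no_hit")
    projected = project_interval(hit, (ssr.start, ssr.end))
    if projected is None:
        return ContextCall(ssr=ssr, category="no_hit")
    p0, p1 = projected
    plen = max(1, p1 - p0)
    overlap = {"exon": 0, "UTR": 0, "intron": 0}
    for gene in genes:
        if gene.seq_id != hit.subject_id:
            continue
        for ftype, f0, f1 in gene.features:
            ov = min(p1, f1) - max(p0, f0)
            if ov <= 0:
                continue
            if ftype == "CDS":
                overlap["exon"] += ov
            elif ftype in ("five_prime_UTR", "three_prime_UTR"):
                overlap["UTR"] += ov
            else:
                overlap["intron"] += ov
    fractions = {t: v / plen for t, v in overlap.items() if v > 0}
    if not fractions:
        category = "genomic"
    else:
        best = max(fractions.values())
        winners = [t for t, v in fractions.items() if v == best]
        category = min(winners, key=lambda t: _PRIORITY[t])
    return ContextCall(
        ssr=ssr,
        category=category,
        subject_id=hit.subject_id,
        subject_interval=projected,
        overlap_fractions=fractions,
    )


def context_table(calls: Sequence[ContextCall]):
    """Cross-tabulate period x category (no_hit excluded) as a CountTable;
    the exclusion fraction is attached as ``.exclusion_fraction``."""
    import pandas as pd

    from .summarize import CountTable

    rows = [
        {"period": c.ssr.period, "category": c.category, "count": 1}
        for c in calls
        if c.category != "no_hit"
    ]
    frame = (
        pd.DataFrame(rows, columns=["period", "category", "count"])
        .groupby(["period", "category"], as_index=False)["count"]
        .sum()
    )
    table = CountTable.from_frame(frame, axes=("period", "category"))
    n_total = len(calls)
    n_excluded = sum(1 for c in calls if c.category == "no_hit")
    table.exclusion_fraction = n_excluded / n_total if n_total else 0.0
    return table
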