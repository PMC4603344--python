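"""Redundancy reduction: collapse a genus's ESTs into unique sequences.

EST libraries oversample abundant transcripts, so the same cDNA is read many
times.  Before microsatellite mining, each genus's reads are collapsed into
non-redundant unique sequences -- contigs (>= 2 members) and singletons --
with a greedy representative-based clustering:

* process sequences in (length desc, id asc) order, so the procedure is
  deterministic regardless of input order;
* a sequence joins the first existing cluster whose representative shares at
  least one exact k-mer and into which it aligns (infix, either orientation)
  at >= ``min_identity`` over >= ``min_overlap_fraction`` of the shorter
  sequence; otherwise it founds a new cluster;
* a contig's consensus is the per-column majority over the star alignment of
  members to the representative (ties keep the representative's base).

This is redundancy removal, not assembly: staggered partial overlaps below
the identity/containment criterion stay separate, which is the conservative
choice for marker mining.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import edlib

from .io_formats import ESTRecord
from .ssr_detect import revcomp


@dataclass
class ClusterParams:
    min_identity: float = 0.95
    min_overlap_fraction: float = 0.80
    kmer_size: int = 12
    check_revcomp: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.min_identity <= 1:
            raise ValueError("min_identity must be in (0, 1]")
        if not 0 < self.min_overlap_fraction <= 1:
            raise ValueError("min_overlap_fraction must be in (0, 1]")


@dataclass
class UniqueSequence:
    id: str
    kind: str  # "contig" | "singleton"
    sequence: str
    member_ids: list[str]
    genus: str

    def __post_init__(self) -> None:
        if self.kind not in ("contig", "singleton"):
            raise ValueError(f"bad kind {self.kind!r}")
        if (self.kind == "contig") != (len(self.member_ids) >= 2):
            raise ValueError("kind inconsistent with member count")


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


@dataclass
class _Cluster:
    representative: ESTRecord
    # (record, oriented sequence, edlib result against representative)
    members: list[tuple[ESTRecord, str, dict]] = field(default_factory=list)


def _try_join(seq: str, rep: str, params: ClusterParams) -> dict | None:
    """Infix-align seq into rep; return the edlib result on acceptance."""
    if len(seq) > len(rep):
        return None
    res = edlib.align(seq, rep, mode="HW", task="path")
    if res["editDistance"] < 0:
        return None
    identity = 1.0 - res["editDistance"] / len(seq)
    # infix alignment covers the whole shorter sequence, so the overlap
    # fraction of the shorter sequence is 1.0 by construction
    if identity >= params.min_identity and 1.0 >= params.min_overlap_fraction:
        return res
    return None


def _consensus(cluster: _Cluster) -> str:
    """Per-column majority over members star-aligned to the representative."""
    rep = cluster.representative.sequence
    counts: list[dict[str, int]] = [dict() for _ in rep]
    for _, oriented, res in cluster.members:
        start = res["locations"][0][0]
        nice = edlib.getNiceAlignment(res, oriented, rep)
        pos = start
        for qc, tc in zip(nice["query_aligned"], nice["target_aligned"]):
            if tc == "-":  # insertion relative to representative: ignored
                continue
            if qc != "-":
                counts[pos][qc] = counts[pos].get(qc, 0) + 1
            pos += 1
    out = []
    for i, base in enumerate(rep):
        col = dict(counts[i])
        col[base] = col.get(base, 0) + 1  # representative votes too
        best = max(col.values())
        winners = [b for b, c in col.items() if c == best]
        out.append(base if base in winners else min(winners))
    return "".join(out)


def reduce_redundancy(
    records: Sequence[ESTRecord], params: ClusterParams | None = None
) -> list[UniqueSequence]:
    """Greedy clustering of one genus's ESTs into contigs and singletons."""
    params = params or ClusterParams()
    if not records:
        return []
    genus = records[0].genus
    order = sorted(records, key=lambda r: (-r.length, r.id))
    clusters: list[_Cluster] = []
    kmer_index: dict[str, set[int]] = {}
    k = params.kmer_size
    for rec in order:
        seq = rec.sequence
        cand_ids: set[int] = set()
        if len(seq) < k:
            # too short to share an indexed k-mer: compare against everything
            cand_ids = set(range(len(clusters)))
        else:
            for orient_seq in (seq, revcomp(seq)) if params.check_revcomp else (seq,):
                for i in range(len(orient_seq) - k + 1):
                    cand_ids |= kmer_index.get(orient_seq[i : i + k], set())
        joined = False
        for ci in sorted(cand_ids):  # founding order
            rep = clusters[ci].representative.sequence
            for oriented in (seq, revcomp(seq)) if params.check_revcomp else (seq,):
                res = _try_join(oriented, rep, params)
                if res is not None:
                    clusters[ci].members.append((rec, oriented, res))
                    joined = True
                    break
            if joined:
                break
        if not joined:
            ci = len(clusters)
            clusters.append(_Cluster(representative=rec))
            for i in range(len(seq) - k + 1):
                kmer_index.setdefault(seq[i : i + k], set()).add(ci)
    uniques: list[UniqueSequence] = []
    for serial, cluster in enumerate(clusters, start=1):
        member_ids = [cluster.representative.id] + [m[0].id for m in cluster.members]
        if len(member_ids) >= 2:
            uniques.append(
                UniqueSequence(
                    id=f"{genus}_u{serial}",
                    kind="contig",
                    sequence=_consensus(cluster),
                    member_ids=member_ids,
                    genus=genus,
                )
            )
        else:
            uniques.append(
                UniqueSequence(
                    id=f"{genus}_u{serial}",
                    kind="singleton",
                    sequence=cluster.representative.sequence,
                    member_ids=member_ids,
                    genus=genus,
                )
            )
    return uniques


def filter_min_length(
    uniques: Sequence[UniqueSequence], min_len: int = 100
) -> list[UniqueSequence]:
    """Keep unique sequences strictly longer than ``min_len`` bases."""
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    return [u for u in uniques if len(u.sequence) > min_len]
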