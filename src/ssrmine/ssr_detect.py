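"""Perfect tandem-repeat (microsatellite) detection in unique EST sequences.

Finds all maximal perfect repeats of period 2-6 with primitive motifs, groups
motifs into canonical families (equivalence under cyclic rotation and reverse
complementation, named by the lexicographic minimum), and applies Class-I
repeat-count thresholds: a Class-I microsatellite spans at least 20 bp, i.e.
>=10 di-, >=7 tri-, >=5 tetra- and >=4 penta-/hexanucleotide repeat units.
Mononucleotide runs are never reported, and primitivity prevents them (or any
shorter-period run) from masquerading as a higher period.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: Class-I thresholds: minimum repeat units per period (>= 20 bp total).
CLASS_I_MIN_REPEATS: dict[int, int] = {2: 10, 3: 7, 4: 5, 5: 4, 6: 4}
#: Relaxed profile: at least four repeat units for every period.
RELAXED_MIN_REPEATS: dict[int, int] = {p: 4 for p in range(2, 7)}

#: Families whose published display name is not the lexicographic minimum.
DISPLAY_ALIASES: dict[str, str] = {"CCG": "GGC", "CG": "GC", "ATC": "TGA"}


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def is_primitive(motif: str) -> bool:
    """True when the motif is not a whole-number power of a shorter string."""
    n = len(motif)
    for d in range(1, n):
        if n % d == 0 and motif == motif[:d] * (n // d):
            return False
    return True


def canonical_family(motif: str) -> tuple[str, str]:
    """Canonical family name and display alias for a primitive ACGT motif.

    The canonical name is the lexicographic minimum over all rotations of the
    motif and all rotations of its reverse complement; the alias is the
    published display name for the family where one exists, else the
    canonical name itself.
    """
    if not 2 <= len(motif) <= 6:
        raise ValueError(f"motif length {len(motif)} outside 2..6")
    if set(motif) - set("ACGT"):
        raise ValueError(f"motif {motif!r} contains non-ACGT characters")
    if not is_primitive(motif):
        raise ValueError(f"motif {motif!r} is not primitive")
    rc = revcomp(motif)
    variants = {motif[i:] + motif[:i] for i in range(len(motif))}
    variants |= {rc[i:] + rc[:i] for i in range(len(rc))}
    canonical = min(variants)
    return canonical, DISPLAY_ALIASES.get(canonical, canonical)


@dataclass
class MiningParams:
    """Thresholds for the perfect-SSR search."""

    min_repeats: Mapping[int, int] = field(
        default_factory=lambda: dict(CLASS_I_MIN_REPEATS)
    )
    periods: tuple[int, ...] = (2, 3, 4, 5, 6)

    def __post_init__(self) -> None:
        for p in self.periods:
            if p not in self.min_repeats:
                raise ValueError(f"no min_repeats entry for period {p}")
            if self.min_repeats[p] < 2:
                raise ValueError("min_repeats values must be >= 2")

    @classmethod
    def relaxed(cls) -> "MiningParams":
        return cls(min_repeats=dict(RELAXED_MIN_REPEATS))


@dataclass(frozen=True)
class SSRLocus:
    """A maximal perfect tandem repeat on one unique sequence."""

    unique_seq_id: str
    genus: str
    start: int
    end: int
    period: int
    motif: str
    repeat_count: int
    canonical_family: str
    display_alias: str

    @property
    def length_bp(self) -> int:
        return self.end - self.start


def is_class_I(period: int, repeat_count: int, params: MiningParams | None = None) -> bool:
    """Whether a (period, repeat_count) run meets the Class-I threshold."""
    params = params or MiningParams()
    if period not in params.min_repeats:
        raise ValueError(f"period {period} outside the mined range")
    return repeat_count >= params.min_repeats[period]


def _clean_segments(sequence: str) -> Iterable[tuple[int, str]]:
    """Maximal ACGT-only stretches (offset, subsequence); runs containing
    ambiguity codes are broken at those characters."""
    start = None
    for i, ch in enumerate(sequence):
        if ch in "ACGT":
            if start is None:
                start = i
        else:
            if start is not None:
                yield start, sequence[start:i]
                start = None
    if start is not None:
        yield start, sequence[start:]


def find_perfect_ssrs(
    sequence: str,
    params: MiningParams | None = None,
    *,
    seq_id: str = "",
    genus: str = "",
) -> list[SSRLocus]:
    """All maximal perfect primitive-motif repeats meeting the thresholds.

    Overlapping candidates of different periods are resolved in favor of the
    longer run (ties to the smaller period), so no two reported loci overlap.
    Output is sorted by start coordinate.
    """
    params = params or MiningParams()
    candidates: list[SSRLocus] = []
    for offset, seg in _clean_segments(sequence):
        n = len(seg)
        for p in params.periods:
            i = 0
            while i + p < n:
                if seg[i] != seg[i + p]:
                    i += 1
                    continue
                j = i
                while j + p < n and seg[j] == seg[j + p]:
                    j += 1
                # tandem span [i, j+p); whole-motif copies only
                count = (j + p - i) // p
                motif = seg[i : i + p]
                if count >= params.min_repeats[p] and is_primitive(motif):
                    canon, alias = canonical_family(motif)
                    candidates.append(
                        SSRLocus(
                            unique_seq_id=seq_id,
                            genus=genus,
                            start=offset + i,
                            end=offset + i + p * count,
                            period=p,
                            motif=motif,
                            repeat_count=count,
                            canonical_family=canon,
                            display_alias=alias,
                        )
                    )
                i = j + 1
    # overlap resolution: longer run wins, tie -> smaller period
    candidates.sort(key=lambda L: (-L.length_bp, L.period, L.start))
    kept: list[SSRLocus] = []
    for cand in candidates:
        if all(cand.end <= k.start or cand.start >= k.end for k in kept):
            kept.append(cand)
    kept.sort(key=lambda L: L.start)
    return kept


def mine_genus(uniques: Sequence, params: MiningParams | None = None) -> list[SSRLocus]:
    """Run the miner over a genus's (length-filtered) unique sequences."""
    params = params or MiningParams()
    loci: list[SSRLocus] = []
    for u in uniques:
        loci.extend(
            find_perfect_ssrs(u.sequence, params, seq_id=u.id, genus=u.genus)
        )
    return loci
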