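"""Compositional and empirical-test summary statistics for EST-SSR catalogs.

Produces the repeat-type / motif-family frequency tables by taxonomic group
and genomic context, and the wet-lab screening summaries: amplification rate
(a locus amplifies when any tested species gives a product, stutter peaks
included), and cross-species transferability (a locus transfers when it is
functional in both congeneric species and the union of observed alleles has
at least two members; stutter loci are discarded from the denominator).

Rounding convention throughout: half away from zero at the reported
precision (2 decimals for shares, 1 for rates).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import pandas as pd

from .io_formats import TaxonMap
from .ssr_detect import SSRLocus

AXES = ("taxonomic_group", "genus", "period", "canonical_family", "category")


def round_half_away(x: float, ndigits: int) -> float:
    """Round half away from zero (Python's round() banker-rounds)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class CountTable:
    """Non-negative integer counts over an ordered subset of axes."""

    axes: tuple[str, ...]
    data: pd.DataFrame  # long form: axis columns + 'count'
    metadata: pd.DataFrame | None = None
    exclusion_fraction: float | None = None
    unmapped_genera: list[str] = field(default_factory=list)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, axes: Sequence[str]) -> "CountTable":
        axes = tuple(axes)
        frame = frame[list(axes) + ["count"]].copy()
        if (frame["count"] < 0).any():
            raise ValueError("negative counts")
        frame = frame.groupby(list(axes), as_index=False)["count"].sum()
        return cls(axes=axes, data=frame)

    @property
    def grand_total(self) -> int:
        return int(self.data["count"].sum())

    def margin(self, *axes: str) -> pd.Series:
        """Totals summed onto the given axes."""
        missing = set(axes) - set(self.axes)
        if missing:
            raise KeyError(f"axes not in table: {sorted(missing)}")
        return self.data.groupby(list(axes))["count"].sum()

    def cell(self, **coords) -> int:
        mask = pd.Series(True, index=self.data.index)
        for axis, value in coords.items():
            mask &= self.data[axis] == value
        return int(self.data.loc[mask, "count"].sum())

    def to_wide(self, index: str, columns: str) -> pd.DataFrame:
        return (
            self.data.pivot_table(
                index=index, columns=columns, values="count",
                aggfunc="sum", fill_value=0,
            )
        )


@dataclass
class PCRTestRecord:
    """One locus screened by PCR in one species."""

    locus_id: str
    genus: str
    species: str
    n_individuals: int
    outcome: str  # product | no_product | stutter
    n_alleles: int | None = None
    size_range: tuple[int, int] | None = None
    expected_size: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.outcome not in ("product", "no_product", "stutter"):
            raise ValueError(f"bad outcome {self.outcome!r}")
        if self.n_alleles is not None:
            if self.outcome != "product":
                raise ValueError("allele count requires a product outcome")
            if self.n_alleles < 1:
                raise ValueError("n_alleles must be >= 1")


def compose_counts(loci: Sequence[SSRLocus], taxa: TaxonMap) -> CountTable:
    """Counts by taxonomic group x genus x period x family, with unmapped
    genera reported (under group 'unmapped'), never silently dropped."""
    rows = []
    unmapped: set[str] = set()
    for locus in loci:
        group = taxa.group_of(locus.genus)
        if group is None:
            unmapped.add(locus.genus)
            group = "unmapped"
        rows.append(
            {
                "taxonomic_group": group,
                "genus": locus.genus,
                "period": locus.period,
                "canonical_family": locus.canonical_family,
                "count": 1,
            }
        )
    frame = pd.DataFrame(
        rows,
        columns=["taxonomic_group", "genus", "period", "canonical_family", "count"],
    )
    axes = ("taxonomic_group", "genus", "period", "canonical_family")
    if frame.empty:
        table = CountTable(axes=axes, data=frame)
    else:
        table = CountTable.from_frame(frame, axes=axes)
    table.unmapped_genera = sorted(unmapped)
    return table


def percent_of_total(table: CountTable, slice_axis: str | Sequence[str]) -> pd.Series:
    """Percentages (2 decimals, half away from zero) of each slice cell
    relative to the table's grand total."""
    axes = [slice_axis] if isinstance(slice_axis, str) else list(slice_axis)
    total = table.grand_total
    if total <= 0:
        raise ValueError("zero total: percentages undefined")
    shares = table.margin(*axes) * 100.0 / total
    return shares.map(lambda v: round_half_away(v, 2))


def location_distribution(table: CountTable) -> dict[str, pd.Series | pd.DataFrame]:
    """Category shares of total and per-period conditional category shares
    for a period x category context table (categories restricted to
    genomic / intron / UTR / exon)."""
    allowed = {"genomic", "intron", "UTR", "exon"}
    cats = set(table.data["category"].unique())
    if not cats <= allowed:
        raise ValueError(f"unexpected categories: {sorted(cats - allowed)}")
    by_category = percent_of_total(table, "category")
    wide = table.to_wide(index="period", columns="category")
    conditional = wide.div(wide.sum(axis=1), axis=0) * 100.0
    conditional = conditional.map(lambda v: round_half_away(v, 2))
    return {"by_category": by_category, "by_period_within_category": conditional}


def summarize_amplification(records: Sequence[PCRTestRecord]) -> dict:
    """Per-genus and overall amplification rates (percent, 1 decimal).

    A locus counts as amplified if any species shows product or stutter.
    """
    by_locus: dict[str, dict] = {}
    for r in records:
        entry = by_locus.setdefault(r.locus_id, {"genus": r.genus, "amplified": False})
        if r.outcome in ("product", "stutter"):
            entry["amplified"] = True
    per_genus: dict[str, dict] = {}
    for locus, entry in by_locus.items():
        g = per_genus.setdefault(entry["genus"], {"tested": 0, "amplified": 0})
        g["tested"] += 1
        g["amplified"] += int(entry["amplified"])
    out = {
        "overall": {
            "tested": len(by_locus),
            "amplified": sum(int(e["amplified"]) for e in by_locus.values()),
        },
        "per_genus": per_genus,
    }
    for scope in [out["overall"], *per_genus.values()]:
        scope["rate_pct"] = (
            round_half_away(100.0 * scope["amplified"] / scope["tested"], 1)
            if scope["tested"]
            else 0.0
        )
    return out


def _allele_union_size(records: Sequence[PCRTestRecord]) -> int:
    """Lower bound on distinct alleles across a genus from (n_alleles,
    size_range) summaries: >= 2 when any species has >= 2 alleles or the
    species' size ranges differ."""
    n_max = max((r.n_alleles or 0) for r in records)
    ranges = {r.size_range for r in records if r.size_range is not None}
    if n_max >= 2 or len(ranges) >= 2:
        return 2
    return 1 if n_max == 1 else 0


def summarize_transferability(records: Sequence[PCRTestRecord]) -> dict:
    """Per-locus transferability calls and the overall rate.

    Loci showing stutter are discarded from the denominator.  A retained
    locus is transferable iff it amplified in both congeneric species and at
    least two alleles were observed across the genus.
    """
    by_locus: dict[str, list[PCRTestRecord]] = {}
    for r in records:
        by_locus.setdefault(r.locus_id, []).append(r)
    calls: dict[str, str] = {}
    retained = transferable = 0
    for locus, recs in by_locus.items():
        if any(r.outcome == "stutter" for r in recs):
            calls[locus] = "discarded_stutter"
            continue
        if len({r.species for r in recs}) < 2:
            raise ValueError(f"locus {locus}: need records for >= 2 species")
        retained += 1
        functional = all(r.outcome == "product" for r in recs)
        polymorphic = _allele_union_size(recs) >= 2
        if functional and polymorphic:
            calls[locus] = "transferable"
            transferable += 1
        elif not functional:
            calls[locus] = "not_functional"
        else:
            calls[locus] = "not_polymorphic"
    rate = round_half_away(100.0 * transferable / retained, 1) if retained else 0.0
    return {
        "calls": calls,
        "retained": retained,
        "transferable": transferable,
        "rate_pct": rate,
    }
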