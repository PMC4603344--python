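"""Readers and writers for every external representation the pipeline touches.

Coordinate convention: everything in memory is 0-based, half-open, on the plus
strand.  1-based inclusive coordinates exist only at file boundaries (GFF3,
12-column tabular alignments, report TSVs).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

IUPAC_DNA = set("ACGTNRYSWKMBDHV")

#: GeneModel feature vocabulary (exon rows in GFF3 are used to synthesize introns)
GENE_FEATURE_TYPES = ("five_prime_UTR", "CDS", "intron", "three_prime_UTR")

TAXONOMIC_GROUPS = (
    "Florideophyceae",
    "Charophyceae",
    "Monilophyta",
    "Lycopodiophyta",
    "Acrogymnospermae",
    "Magnoliidae",
    "Monocotyledoneae",
    "Eudicotyledoneae",
)


class ParseError(ValueError):
    """Malformed input file."""


class ValidationError(ValueError):
    """Structurally valid input that violates a consistency requirement."""


@dataclass(frozen=True)
class ESTRecord:
    """One raw expressed-sequence-tag read."""

    id: str
    genus: str
    sequence: str

    def __post_init__(self) -> None:
        bad = set(self.sequence) - IUPAC_DNA
        if bad:
            raise ValidationError(
                f"record {self.id!r}: non-IUPAC characters {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneModel:
    """An annotated gene: ordered (type, start, end) features, 0-based half-open.

    Feature types are five_prime_UTR / CDS / intron / three_prime_UTR; introns
    are explicit (synthesized from exon gaps when reading GFF3).
    """

    gene_id: str
    seq_id: str
    strand: str
    features: tuple[tuple[str, int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValidationError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        prev_end = None
        for ftype, start, end in sorted(self.features, key=lambda f: f[1]):
            if ftype not in GENE_FEATURE_TYPES:
                raise ValidationError(f"gene {self.gene_id}: bad feature {ftype!r}")
            if not start < end:
                raise ValidationError(
                    f"gene {self.gene_id}: empty feature {ftype} [{start},{end})"
                )
            if prev_end is not None and start < prev_end:
                raise ValidationError(f"gene {self.gene_id}: overlapping features")
            prev_end = end

    @property
    def span(self) -> tuple[int, int]:
        starts = [f[1] for f in self.features]
        ends = [f[2] for f in self.features]
        return min(starts), max(ends)


@dataclass
class AlignmentHit:
    """A (possibly multi-block) gapless-block alignment of query to subject.

    Blocks are (q_start, q_end, s_lo, s_hi) with subject intervals stored on
    the plus strand; for minus-strand hits, subject intervals decrease as
    query coordinates increase.
    """

    query_id: str
    subject_id: str
    blocks: list[tuple[int, int, int, int]]
    percent_identity: float
    aligned_length: int
    subject_strand: str = "+"
    significance: float | None = None

    def __post_init__(self) -> None:
        prev_qend = -1
        for q0, q1, s0, s1 in self.blocks:
            if q1 - q0 != s1 - s0:
                raise ValidationError("block with unequal query/subject lengths")
            if q0 < prev_qend:
                raise ValidationError("blocks not increasing in query coordinates")
            prev_qend = q1

    @property
    def query_span(self) -> tuple[int, int]:
        return self.blocks[0][0], self.blocks[-1][1]

    @property
    def subject_span(self) -> tuple[int, int]:
        los = [b[2] for b in self.blocks]
        his = [b[3] for b in self.blocks]
        return min(los), max(his)


@dataclass
class TaxonMap:
    """Genus -> taxonomic-group lookup with explicit bookkeeping of misses."""

    mapping: dict[str, str]

    def group_of(self, genus: str) -> str | None:
        return self.mapping.get(genus)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path, genus: str | None = None) -> list[ESTRecord]:
    """Read a FASTA file into ESTRecords (uppercased, pre-whitespace ids).

    ``genus`` defaults to the file stem.  Duplicate ids and illegal sequence
    characters raise :class:`ParseError` naming the offending line.
    """
    path = Path(path)
    genus = genus if genus is not None else path.stem
    # line-level validation first, so errors can name a line number
    seen_header = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith(">"):
                seen_header = True
                if len(line) == 1:
                    raise ParseError(f"{path}:{lineno}: empty FASTA header")
            else:
                if not seen_header:
                    raise ParseError(f"{path}:{lineno}: sequence before any header")
                bad = set(line.upper()) - IUPAC_DNA
                if bad:
                    raise ParseError(
                        f"{path}:{lineno}: illegal sequence characters {sorted(bad)}"
                    )
    records: list[ESTRecord] = []
    ids: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in ids:
            raise ParseError(f"{path}: duplicated FASTA id {rec.id!r}")
        ids.add(rec.id)
        records.append(ESTRecord(id=rec.id, genus=genus, sequence=str(rec.seq).upper()))
    return records


def write_fasta(records: Iterable, path: str | Path, width: int = 60) -> None:
    """Write records (anything with .id and .sequence) as FASTA."""
    seqrecs = [
        SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqrecs)


# ---------------------------------------------------------------------------
# 12-column tabular alignments (BLAST outfmt-6 convention)

TABULAR_COLUMNS = (
    "query subject pident length mismatch gapopen "
    "qstart qend sstart send evalue bitscore"
).split()


def read_alignments_tabular(path: str | Path) -> list[AlignmentHit]:
    """Ingest 12-column tabular alignments (1-based inclusive; sstart > send
    denotes a minus-strand hit).  Each row becomes one single-block hit."""
    hits: list[AlignmentHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ParseError(
                    f"{path}:{lineno}: expected 12 tab-separated fields, "
                    f"got {len(fields)}"
                )
            try:
                pident = float(fields[2])
                length = int(fields[3])
                qstart, qend = int(fields[6]), int(fields[7])
                sstart, send = int(fields[8]), int(fields[9])
                evalue = float(fields[10])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric field: {exc}") from exc
            q0, q1 = qstart - 1, qend
            if sstart <= send:
                strand, s0, s1 = "+", sstart - 1, send
            else:
                strand, s0, s1 = "-", send - 1, sstart
            hits.append(
                AlignmentHit(
                    query_id=fields[0],
                    subject_id=fields[1],
                    blocks=[(q0, q1, s0, s1)],
                    percent_identity=pident / 100.0,
                    aligned_length=length,
                    subject_strand=strand,
                    significance=evalue,
                )
            )
    return hits


def to_tabular_row(hit: AlignmentHit) -> str:
    """Render a single-block hit back to the external 12-column convention."""
    if len(hit.blocks) != 1:
        raise ValueError("only single-block hits have a tabular representation")
    q0, q1, s0, s1 = hit.blocks[0]
    if hit.subject_strand == "+":
        sstart, send = s0 + 1, s1
    else:
        sstart, send = s1, s0 + 1
    evalue = hit.significance if hit.significance is not None else 0.0
    return "\t".join(
        str(x)
        for x in (
            hit.query_id,
            hit.subject_id,
            f"{hit.percent_identity * 100:.2f}".rstrip("0").rstrip("."),
            hit.aligned_length,
            0,
            0,
            q0 + 1,
            q1,
            sstart,
            send,
            evalue,
            0,
        )
    )


# ---------------------------------------------------------------------------
# GFF3


def read_gff3(path: str | Path) -> list[GeneModel]:
    """One GeneModel per mRNA; introns synthesized from gaps between exons.

    CDS segments extending outside their mRNA's exons raise
    :class:`ValidationError`.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneModel] = []
    for mrna in db.features_of_type("mRNA", order_by="start"):
        exons = sorted(
            (f.start - 1, f.end) for f in db.children(mrna, featuretype="exon")
        )
        feats: list[tuple[str, int, int]] = []
        for ftype in ("CDS", "five_prime_UTR", "three_prime_UTR"):
            for f in db.children(mrna, featuretype=ftype):
                start, end = f.start - 1, f.end
                if ftype == "CDS" and exons:
                    if not any(e0 <= start and end <= e1 for e0, e1 in exons):
                        raise ValidationError(
                            f"mRNA {mrna.id}: CDS [{start},{end}) outside exons"
                        )
                feats.append((ftype, start, end))
        for (e0, e1), (n0, n1) in zip(exons, exons[1:]):
            if n0 > e1:
                feats.append(("intron", e1, n0))
        feats.sort(key=lambda f: f[1])
        genes.append(
            GeneModel(
                gene_id=mrna.id,
                seq_id=mrna.seqid,
                strand=mrna.strand,
                features=tuple(feats),
            )
        )
    return genes


def write_gff3(genes: Sequence[GeneModel], path: str | Path) -> None:
    """Write gene/mRNA/exon + feature rows (1-based inclusive) for the models."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gene in genes:
            g0, g1 = gene.span
            gid = gene.gene_id
            fh.write(
                "\t".join(
                    [gene.seq_id, "ssrmine", "gene", str(g0 + 1), str(g1),
                     ".", gene.strand, ".", f"ID=gene:{gid}"]
                )
                + "\n"
            )
            fh.write(
                "\t".join(
                    [gene.seq_id, "ssrmine", "mRNA", str(g0 + 1), str(g1),
                     ".", gene.strand, ".", f"ID={gid};Parent=gene:{gid}"]
                )
                + "\n"
            )
            # exons: maximal non-intron spans
            exonic = sorted(
                (s, e) for t, s, e in gene.features if t != "intron"
            )
            merged: list[list[int]] = []
            for s, e in exonic:
                if merged and s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            for i, (s, e) in enumerate(merged, start=1):
                fh.write(
                    "\t".join(
                        [gene.seq_id, "ssrmine", "exon", str(s + 1), str(e),
                         ".", gene.strand, ".",
                         f"ID={gid}.exon{i};Parent={gid}"]
                    )
                    + "\n"
                )
            for i, (t, s, e) in enumerate(gene.features, start=1):
                if t == "intron":
                    continue
                fh.write(
                    "\t".join(
                        [gene.seq_id, "ssrmine", t, str(s + 1), str(e),
                         ".", gene.strand, ".",
                         f"ID={gid}.{t}{i};Parent={gid}"]
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# Packaged fixtures (transcriptions of the published summary tables)

FIXTURE_NAMES = ("table1", "table2", "table3", "table4", "taxonomy")


def _fixture_path(name: str) -> Path:
    res = importlib.resources.files("ssrmine") / "fixtures" / f"{name}.tsv"
    return Path(str(res))


def load_taxonomy(extra: dict[str, str] | None = None) -> TaxonMap:
    """The packaged genus -> taxonomic-group map (extensible by callers)."""
    import pandas as pd

    df = pd.read_csv(_fixture_path("taxonomy"), sep="\t")
    mapping = dict(zip(df["genus"], df["group"]))
    if extra:
        mapping.update(extra)
    bad = set(mapping.values()) - set(TAXONOMIC_GROUPS)
    if bad:
        raise ValidationError(f"unknown taxonomic groups: {sorted(bad)}")
    return TaxonMap(mapping)


def load_published_table(name: str):
    """Load a packaged summary-table fixture.

    ``table1`` and ``table2`` return :class:`~ssrmine.summarize.CountTable`;
    ``table3`` and ``table4`` return lists of
    :class:`~ssrmine.summarize.PCRTestRecord`.  Every fixture is validated
    (totals equal the sum of their parts) before being returned.
    """
    from . import summarize  # local import: summarize depends on types here

    if name not in FIXTURE_NAMES:
        raise ValueError(f"unknown fixture {name!r}; expected one of {FIXTURE_NAMES}")
    import pandas as pd

    path = _fixture_path(name)
    if name == "table1":
        df = pd.read_csv(path, sep="\t")
        body = df[df["period"] != "total"].copy()
        body["period"] = body["period"].astype(int)
        totals = df[df["period"] == "total"].set_index("genus")
        errors = []
        cat_cols = ["genomic", "intron", "utr", "exon"]
        for _, row in body.iterrows():
            if int(row[cat_cols].sum()) != int(row["total"]):
                errors.append(f"{row['genus']} period {row['period']}")
        for genus, grp in body.groupby("genus"):
            for col in cat_cols + ["total"]:
                if int(grp[col].sum()) != int(totals.loc[genus, col]):
                    errors.append(f"{genus} column {col}")
        if errors:
            raise ValidationError(f"table1 internal sums fail: {errors}")
        long = body.melt(
            id_vars=["genus", "period"],
            value_vars=cat_cols,
            var_name="category",
            value_name="count",
        )
        long["category"] = long["category"].replace({"utr": "UTR"})
        return summarize.CountTable.from_frame(
            long, axes=("genus", "period", "category")
        )
    if name == "table2":
        df = pd.read_csv(path, sep="\t")
        body = df[df["group"] != "Total"].copy()
        total = df[df["group"] == "Total"].iloc[0]
        type_cols = ["di", "tri", "tetra", "penta", "hexa"]
        errors = []
        for _, row in body.iterrows():
            if int(row[type_cols].sum()) != int(row["total"]):
                errors.append(f"row {row['group']}")
        for col in type_cols + ["total", "n_genera", "n_genera_ssr"]:
            if int(body[col].sum()) != int(total[col]):
                errors.append(f"column {col}")
        # n_est grand total is transcribed as printed and known not to equal
        # the column sum; it is exempt from the check.
        if errors:
            raise ValidationError(f"table2 internal sums fail: {errors}")
        long = body.melt(
            id_vars=["group"],
            value_vars=type_cols,
            var_name="period",
            value_name="count",
        )
        long["period"] = long["period"].map(
            {"di": 2, "tri": 3, "tetra": 4, "penta": 5, "hexa": 6}
        )
        table = summarize.CountTable.from_frame(
            long.rename(columns={"group": "taxonomic_group"}),
            axes=("taxonomic_group", "period"),
        )
        table.metadata = body.set_index("group")[
            ["n_genera", "n_genera_ssr", "n_est", "commonest_motifs"]
        ]
        return table
    # tables 3 and 4: empirical PCR-test records
    df = pd.read_csv(path, sep="\t", na_values=["."])
    records = []
    for _, row in df.iterrows():
        n_alleles = None if pd.isna(row["n_alleles"]) else int(row["n_alleles"])
        size_range = (
            None
            if pd.isna(row["size_min"])
            else (int(row["size_min"]), int(row["size_max"]))
        )
        expected = (
            (int(row["expected_min"]), int(row["expected_max"]))
            if "expected_min" in row.index
            else None
        )
        records.append(
            summarize.PCRTestRecord(
                locus_id=row["locus"],
                genus=row["genus"],
                species=row["species"],
                n_individuals=int(row["n_individuals"]) if "n_individuals" in row.index else 0,
                outcome=row["outcome"],
                n_alleles=n_alleles,
                size_range=size_range,
                expected_size=expected,
            )
        )
    errors = [
        r.locus_id
        for r in records
        if r.n_alleles is not None and r.outcome != "product"
    ]
    if errors:
        raise ValidationError(f"{name}: allele counts without product: {errors}")
    return records
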