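"""Alignment, projection and exon/UTR/intron/genomic classification."""

import pytest

from conftest import random_dna
from ssrmine import genome_context as gc
from ssrmine.io_formats import AlignmentHit, GeneModel
from ssrmine.ssr_detect import SSRLocus, revcomp


def locus(start, end, period=3, seq_id="u1"):
    return SSRLocus(unique_seq_id=seq_id, genus="G", start=start, end=end,
                    period=period, motif="ACC", repeat_count=(end - start) // period,
                    canonical_family="ACC", display_alias="ACC")


# ---------------------------------------------------------------------------
# align_local


def test_exact_substring_single_block(rng):
    ref = random_dna(rng, 3000)
    q = ref[500:900]
    (hit, *_) = gc.align_local(q, ref)
    assert hit.percent_identity == 1.0
    assert hit.subject_strand == "+"
    assert hit.blocks[0] == (0, 400, 500, 900)


def test_revcomp_query_minus_strand(rng):
    ref = random_dna(rng, 3000)
    q = revcomp(ref[500:900])
    (hit, *_) = gc.align_local(q, ref)
    assert hit.subject_strand == "-"
    assert hit.subject_span == (500, 900)
    assert hit.percent_identity == 1.0


def test_spliced_query_blocks_flank_intron(rng):
    exon1 = random_dna(rng, 220)
    intron = random_dna(rng, 300)
    exon2 = random_dna(rng, 180)
    ref = random_dna(rng, 400) + exon1 + intron + exon2 + random_dna(rng, 400)
    q = exon1 + exon2
    (hit, *_) = gc.align_local(q, ref)
    assert len(hit.blocks) == 2
    (q0, q1, s0, s1), (q2, q3, s2, s3) = hit.blocks
    assert (s0, s1) == (400, 620)
    assert (s2, s3) == (920, 1100)
    assert (q0, q1, q2, q3) == (0, 220, 220, 400)


def test_substitution_errors_absorbed(rng):
    ref = random_dna(rng, 2000)
    q = list(ref[300:800])
    for p in (50, 200, 380):
        q[p] = [b for b in "ACGT" if b != q[p]][0]
    (hit, *_) = gc.align_local("".join(q), ref)
    assert hit.query_span == (0, 500)
    assert hit.percent_identity == pytest.approx(497 / 500)


# ---------------------------------------------------------------------------
# project_interval


def test_project_single_block_offset():
    hit = AlignmentHit(query_id="q", subject_id="s",
                       blocks=[(0, 100, 200, 300)],
                       percent_identity=1.0, aligned_length=100)
    assert gc.project_interval(hit, (10, 30)) == (210, 230)


def test_project_between_blocks_absent():
    hit = AlignmentHit(query_id="q", subject_id="s",
                       blocks=[(0, 50, 100, 150), (80, 130, 200, 250)],
                       percent_identity=1.0, aligned_length=100)
    assert gc.project_interval(hit, (55, 75)) is None


def test_project_minus_strand_reflection():
    hit = AlignmentHit(query_id="q", subject_id="s",
                       blocks=[(0, 100, 200, 300)], subject_strand="-",
                       percent_identity=1.0, aligned_length=100)
    projected = gc.project_interval(hit, (10, 30))
    assert projected == (270, 290)  # reflected, length preserved
    assert projected[1] - projected[0] == 20


def test_project_bad_interval():
    hit = AlignmentHit(query_id="q", subject_id="s",
                       blocks=[(0, 100, 200, 300)],
                       percent_identity=1.0, aligned_length=100)
    with pytest.raises(ValueError):
        gc.project_interval(hit, (-5, 10))


# ---------------------------------------------------------------------------
# classify_context


def single_hit(q_len, s_start, strand="+"):
    if strand == "+":
        blocks = [(0, q_len, s_start, s_start + q_len)]
    else:
        blocks = [(0, q_len, s_start, s_start + q_len)]
    return AlignmentHit(query_id="u1", subject_id="chr1", blocks=blocks,
                        subject_strand=strand, percent_identity=1.0,
                        aligned_length=q_len)


GENE = GeneModel(
    gene_id="g1", seq_id="chr1", strand="+",
    features=(("five_prime_UTR", 1000, 1100), ("CDS", 1100, 1400),
              ("intron", 1400, 1600), ("CDS", 1600, 1900),
              ("three_prime_UTR", 1900, 2000)),
)


def test_wholly_inside_cds_is_exon():
    call = gc.classify_context(locus(50, 80), [single_hit(400, 1150)], [GENE])
    assert call.category == "exon"
    assert call.overlap_fractions == {"exon": 1.0}


def test_majority_overlap_utr():
    # projected interval [1880, 1930): 20 bases CDS+..., 60% in 3'UTR
    call = gc.classify_context(locus(0, 50, period=5),
                               [single_hit(400, 1880)], [GENE])
    assert call.subject_interval == (1880, 1930)
    assert call.category == "UTR"


def test_tie_breaks_prefer_exon():
    # [1890, 1910): 10 bases CDS, 10 bases UTR -> exon by priority
    call = gc.classify_context(locus(0, 20, period=2),
                               [single_hit(200, 1890)], [GENE])
    assert call.category == "exon"


def test_intergenic_projection_is_genomic():
    call = gc.classify_context(locus(10, 40), [single_hit(200, 5000)], [GENE])
    assert call.category == "genomic"


def test_no_significant_hit_is_no_hit():
    weak = AlignmentHit(query_id="u1", subject_id="chr1",
                        blocks=[(0, 30, 100, 130)],
                        percent_identity=0.80, aligned_length=30)
    call = gc.classify_context(locus(0, 21), [weak], [GENE])
    assert call.category == "no_hit"
    assert gc.classify_context(locus(0, 21), [], [GENE]).category == "no_hit"


def test_minus_strand_mirror_invariance(rng):
    """Classification is invariant under swapping a hit for its mirrored
    minus-strand representation."""
    ref = random_dna(rng, 3000)
    q = ref[1100:1500]
    hit_plus = gc.align_local(q, ref)[0]
    hit_minus = gc.align_local(revcomp(q), ref)[0]
    assert hit_minus.subject_strand == "-"
    L = len(q)
    ssr_plus = locus(120, 150)
    ssr_minus = locus(L - 150, L - 120)
    call_plus = gc.classify_context(ssr_plus, [hit_plus], [GENE])
    call_minus = gc.classify_context(ssr_minus, [hit_minus], [GENE])
    assert call_plus.category == call_minus.category
    assert call_plus.subject_interval == call_minus.subject_interval


def brute_force_category(hit, q_interval, genes):
    """Independent per-base oracle: map every aligned base individually and
    vote feature membership base by base."""
    qmap = {}
    for q0, q1, s0, s1 in hit.blocks:
        for q in range(q0, q1):
            if hit.subject_strand == "+":
                qmap[q] = s0 + (q - q0)
            else:
                qmap[q] = s1 - 1 - (q - q0)
    bases = [qmap[q] for q in range(*q_interval) if q in qmap]
    if 2 * len(bases) < q_interval[1] - q_interval[0] or not bases:
        return "no_hit"
    lo, hi = min(bases), max(bases) + 1
    votes = {"exon": 0, "UTR": 0, "intron": 0}
    for s in range(lo, hi):
        for gene in genes:
            if gene.seq_id != hit.subject_id:
                continue
            for ftype, f0, f1 in gene.features:
                if f0 <= s < f1:
                    if ftype == "CDS":
                        votes["exon"] += 1
                    elif ftype.endswith("UTR"):
                        votes["UTR"] += 1
                    else:
                        votes["intron"] += 1
    if not any(votes.values()):
        return "genomic"
    best = max(votes.values())
    for cat in ("exon", "UTR", "intron"):
        if votes[cat] == best:
            return cat


def test_classifier_matches_per_base_oracle(rng):
    for _ in range(60):
        s_start = int(rng.integers(800, 2300))
        q_len = int(rng.integers(100, 400))
        strand = "+" if rng.random() < 0.5 else "-"
        hit = single_hit(q_len, s_start, strand)
        a = int(rng.integers(0, q_len - 20))
        b = a + int(rng.integers(20, min(60, q_len - a)))
        ssr = locus(a, b, period=2)
        call = gc.classify_context(ssr, [hit], [GENE])
        assert call.category == brute_force_category(hit, (a, b), [GENE])


# ---------------------------------------------------------------------------
# context_table


def test_context_table_counts_and_exclusion():
    calls = [
        gc.ContextCall(ssr=locus(0, 21), category="exon"),
        gc.ContextCall(ssr=locus(0, 21), category="exon"),
        gc.ContextCall(ssr=locus(0, 20, period=2), category="UTR"),
        gc.ContextCall(ssr=locus(0, 21), category="no_hit"),
    ]
    table = gc.context_table(calls)
    assert table.grand_total == 3
    assert table.cell(category="exon") == 2
    assert table.exclusion_fraction == pytest.approx(0.25)
    empty = gc.context_table(
        [gc.ContextCall(ssr=locus(0, 21), category="no_hit")]
    )
    assert empty.grand_total == 0
    assert empty.exclusion_fraction == 1.0


def test_fixture_table1_through_context_type():
    from ssrmine.io_formats import load_published_table
    t1 = load_published_table("table1")
    assert t1.cell(genus="Oryza") == 397
    assert t1.cell(genus="Arabidopsis") == 139
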