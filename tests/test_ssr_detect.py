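"""Perfect-repeat miner: canonical families, thresholds, maximality,
primitivity, and equivalence with a brute-force oracle."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import random_dna
from ssrmine import ssr_detect as det


# ---------------------------------------------------------------------------
# canonical families


def enumeration_family_oracle(motif):
    """Independent oracle: explicit enumeration of the equivalence set."""
    rc = det.revcomp(motif)
    members = set()
    for m in (motif, rc):
        for i in range(len(m)):
            members.add(m[i:] + m[:i])
    return min(members), members


@pytest.mark.parametrize(
    "motif,canonical,alias",
    [
        ("TC", "AG", "AG"),
        ("GGC", "CCG", "GGC"),
        ("AT", "AT", "AT"),
        ("TGA", "ATC", "TGA"),
        ("CG", "CG", "GC"),
        ("ATG", "ATC", "TGA"),  # same family as TGA
    ],
)
def test_canonical_family_examples(motif, canonical, alias):
    got_canonical, got_alias = det.canonical_family(motif)
    assert got_canonical == canonical
    assert got_alias == alias
    assert enumeration_family_oracle(motif)[0] == canonical


def test_canonical_family_full_enumeration_closure():
    """Every primitive motif of length 2-6: family equals the enumeration
    oracle, is invariant under rotation/reverse-complement, and idempotent."""
    for k in range(2, 7):
        for tup in itertools.product("ACGT", repeat=k):
            motif = "".join(tup)
            if not det.is_primitive(motif):
                continue
            canonical, members = enumeration_family_oracle(motif)
            got, _ = det.canonical_family(motif)
            assert got == canonical
            for m in members:
                assert det.canonical_family(m)[0] == canonical
            assert det.canonical_family(canonical)[0] == canonical


def test_canonical_family_rejects_bad_input():
    with pytest.raises(ValueError):
        det.canonical_family("ATAT")  # non-primitive
    with pytest.raises(ValueError):
        det.canonical_family("AN")
    with pytest.raises(ValueError):
        det.canonical_family("ACGTACG")  # length 7


# ---------------------------------------------------------------------------
# Class-I thresholds


@pytest.mark.parametrize(
    "period,count,expected",
    [(2, 10, True), (2, 9, False), (3, 7, True), (3, 6, False),
     (4, 5, True), (5, 4, True), (6, 4, True), (6, 3, False)],
)
def test_class_I_boundaries(period, count, expected):
    assert det.is_class_I(period, count) is expected


def test_class_I_rejects_bad_period():
    with pytest.raises(ValueError):
        det.is_class_I(7, 10)


# ---------------------------------------------------------------------------
# find_perfect_ssrs


def test_detects_di_run():
    seq = "CTTGCCAATCGC" + "AG" * 11 + "TTCGATACCGTA"
    (locus,) = det.find_perfect_ssrs(seq)
    assert (locus.period, locus.repeat_count, locus.canonical_family) == (2, 11, "AG")
    assert locus.start == 12 and locus.end == 12 + 22
    assert seq[locus.start:locus.end] == locus.motif * locus.repeat_count


def test_detects_tri_at_threshold():
    seq = "GATTTCGCATGA" + "ACC" * 7 + "TGAATCGTCAGT"
    (locus,) = det.find_perfect_ssrs(seq)
    assert (locus.period, locus.repeat_count) == (3, 7)


def test_below_threshold_not_emitted():
    seq = "CCGGTTCCGGTC" + "AT" * 9 + "CGGATCCGGATC"
    assert det.find_perfect_ssrs(seq) == []


def test_non_primitive_reported_at_true_period():
    seq = "CCTGC" + "ATAT" * 5 + "GGCAA"
    loci = det.find_perfect_ssrs(seq)
    assert len(loci) == 1
    assert loci[0].period == 2
    assert loci[0].repeat_count == 10
    assert loci[0].canonical_family == "AT"


def test_run_broken_at_ambiguity():
    seq = "TGCAC" + "AG" * 6 + "N" + "AG" * 6 + "CGTGA"
    assert det.find_perfect_ssrs(seq) == []  # both halves below threshold
    seq2 = "TGCAC" + "AG" * 10 + "N" + "AG" * 10 + "CGTGA"
    loci = det.find_perfect_ssrs(seq2)
    assert [l.repeat_count for l in loci] == [10, 10]


def test_relaxed_profile_supersets_class_I():
    seq = "CCGGTTCCGGTC" + "AT" * 5 + "CGGATCAGTCCTGA" + "AG" * 12 + "TTGCAATC"
    strict = det.find_perfect_ssrs(seq)
    relaxed = det.find_perfect_ssrs(seq, det.MiningParams.relaxed())
    assert len(relaxed) > len(strict)
    strict_keys = {(l.start, l.end) for l in strict}
    assert strict_keys <= {(l.start, l.end) for l in relaxed}


def test_mine_genus_tags_sources(small_truth):
    from ssrmine.redundancy import UniqueSequence

    u = UniqueSequence(id="G_u1", kind="singleton", genus="G",
                       member_ids=["a"],
                       sequence="CTTGCCAATCGG" + "AG" * 11 + "TTCGATACCG")
    loci = det.mine_genus([u])
    assert loci[0].unique_seq_id == "G_u1" and loci[0].genus == "G"
    assert det.mine_genus([]) == []


# ---------------------------------------------------------------------------
# Brute-force oracle


def brute_force_ssrs(seq, min_repeats):
    """Independent O(n * periods) check of every start position for a
    maximal, primitive, threshold-passing perfect run."""
    n = len(seq)
    found = []
    for p in range(2, 7):
        for start in range(n - p):
            motif = seq[start:start + p]
            if len(motif) < p or set(motif) - set("ACGT"):
                continue
            if any(p % d == 0 and motif == motif[:d] * (p // d)
                   for d in range(1, p)):
                continue
            count = 1
            while seq[start + count * p:start + (count + 1) * p] == motif:
                count += 1
            if count < min_repeats[p]:
                continue
            if start >= p and seq[start - p:start] == motif:
                continue  # not left-maximal
            found.append((start, start + count * p, p, motif, count))
    found.sort(key=lambda t: (-(t[1] - t[0]), t[2], t[0]))
    kept = []
    for c in found:
        if all(c[1] <= k[0] or c[0] >= k[1] for k in kept):
            kept.append(c)
    return sorted(kept)


def seeded_test_sequence(rng, length=800):
    """Random DNA with occasional planted runs so the comparison is not
    vacuously about empty outputs."""
    seq = random_dna(rng, length, gc=float(rng.uniform(0.3, 0.7)))
    out = list(seq)
    for _ in range(int(rng.integers(0, 4))):
        p = int(rng.integers(2, 7))
        motif = "".join(rng.choice(list("ACGT"), size=p))
        count = int(rng.integers(3, 14))
        pos = int(rng.integers(0, length - 1))
        out[pos:pos] = list(motif * count)
    return "".join(out)


def test_miner_equals_brute_force_oracle(rng):
    params = det.MiningParams()
    for _ in range(40):
        seq = seeded_test_sequence(rng)
        expected = brute_force_ssrs(seq, params.min_repeats)
        got = [
            (l.start, l.end, l.period, l.motif, l.repeat_count)
            for l in det.find_perfect_ssrs(seq)
        ]
        assert sorted(got) == expected


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.text(alphabet="ACGTN", min_size=0, max_size=300))
def test_miner_invariants(seq):
    loci = det.find_perfect_ssrs(seq)
    prev_end = -1
    for l in sorted(loci, key=lambda l: l.start):
        assert l.start >= prev_end, "emitted loci overlap"
        prev_end = l.end
        assert seq[l.start:l.end] == l.motif * l.repeat_count
        assert det.is_primitive(l.motif)
        assert l.length_bp >= 20
    # strand symmetry: same multiset of (family, period, count)
    mirrored = det.find_perfect_ssrs(det.revcomp(seq))
    key = lambda ls: sorted((l.canonical_family, l.period, l.repeat_count) for l in ls)
    assert key(loci) == key(mirrored)
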