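"""Primer selection: GC/Tm arithmetic, hard-constraint enforcement, penalty
ranking, and equivalence with an exhaustive window-pair oracle."""

import pytest
from Bio.SeqUtils import MeltingTemp

from conftest import random_dna
from ssrmine import primer_design as pd_mod
from ssrmine.redundancy import UniqueSequence
from ssrmine.ssr_detect import SSRLocus, canonical_family, find_perfect_ssrs, revcomp


def make_locus(template, motif, count, start):
    canon, alias = canonical_family(motif)
    return SSRLocus(
        unique_seq_id="u1", genus="G", start=start, end=start + len(motif) * count,
        period=len(motif), motif=motif, repeat_count=count,
        canonical_family=canon, display_alias=alias,
    )


def template_with_ssr(rng, left, right, motif="ACC", count=8, gc=0.5):
    lseq = random_dna(rng, left, gc)
    rseq = random_dna(rng, right, gc)
    seq = lseq + motif * count + rseq
    return seq, make_locus(seq, motif, count, left)


# ---------------------------------------------------------------------------
# gc / Tm


def test_gc_fraction_examples():
    assert pd_mod.gc_fraction("CAACCAGTGGTGTGAGTAGGA") == pytest.approx(11 / 21)
    assert pd_mod.gc_fraction("ACGT") == 0.5
    assert pd_mod.gc_fraction("AAAA") == 0.0
    with pytest.raises(ValueError):
        pd_mod.gc_fraction("ACGN")


def test_gc_linear_closed_form():
    seq = "A" * 10 + "G" * 10  # 50% GC over 20 nt
    assert pd_mod.melting_temperature(seq, "gc_linear") == pytest.approx(
        64.9 + 41 * (10 - 16.4) / 20
    )
    assert pd_mod.melting_temperature("AT" * 10, "gc_linear") == pytest.approx(
        64.9 + 41 * (0 - 16.4) / 20
    )


def test_nearest_neighbor_palindrome_symmetry():
    seq = "GGATCCTTAAGGATCC" + "ACGT"
    assert pd_mod.melting_temperature(seq) == pytest.approx(
        pd_mod.melting_temperature(revcomp(seq))
    )


def test_tm_length_validity():
    with pytest.raises(ValueError):
        pd_mod.melting_temperature("ACGTACGTACGACGT"[:13])


# ---------------------------------------------------------------------------
# hard constraints on emitted pairs


def test_emitted_pairs_satisfy_all_hard_constraints(rng):
    params = pd_mod.PrimerParams()
    checked = 0
    for _ in range(8):
        seq, locus = template_with_ssr(rng, 150, 150, gc=float(rng.uniform(0.4, 0.6)))
        for pair in pd_mod.design_primers(seq, locus, params)[:20]:
            checked += 1
            for primer in (pair.forward_seq, pair.reverse_seq):
                assert 18 <= len(primer) <= 23
                assert 0.30 <= pd_mod.gc_fraction(primer) <= 0.70
                tm = pd_mod.melting_temperature(primer)
                assert 55.0 <= tm <= 65.0
            assert abs(pair.tm_f - pair.tm_r) <= params.max_tm_difference
            assert 90 <= pair.product_size <= 320
            assert pair.product_size == pair.r_end - pair.f_start
            # primers never overlap the repeat run
            assert pair.f_end <= locus.start and pair.r_start >= locus.end
            # sequences really come from the template
            assert seq[pair.f_start:pair.f_end] == pair.forward_seq
            assert revcomp(seq[pair.r_start:pair.r_end]) == pair.reverse_seq
    assert checked > 0


def test_no_room_for_forward_primer(rng):
    seq, _ = template_with_ssr(rng, 10, 200)
    locus = make_locus(seq, "ACC", 8, 10)
    assert pd_mod.design_primers(seq, locus) == []


def test_n_rich_flanks_undesignable(rng):
    left = "N" * 120
    right = random_dna(rng, 150)
    seq = left + "ACC" * 8 + right
    locus = make_locus(seq, "ACC", 8, 120)
    assert pd_mod.design_primers(seq, locus) == []


def test_penalty_formula_and_zero_condition():
    params = pd_mod.PrimerParams()
    p = pd_mod._pair_penalty(20, 20, 60.0, 60.0, 0.5, 0.5, params)
    assert p == 0.0
    p2 = pd_mod._pair_penalty(19, 22, 58.0, 61.0, 0.45, 0.60, params)
    assert p2 == pytest.approx(1 + 2 + 2 + 1 + 0.5 * (5 + 10) + 3.0)


def test_monotonicity_of_relaxing_product_range(rng):
    tight = pd_mod.PrimerParams(product_size_range=(120, 200))
    loose = pd_mod.PrimerParams(product_size_range=(90, 320))
    n_tight = n_loose = 0
    for _ in range(6):
        seq, locus = template_with_ssr(rng, 140, 140)
        n_tight += bool(pd_mod.design_primers(seq, locus, tight))
        n_loose += bool(pd_mod.design_primers(seq, locus, loose))
    assert n_loose >= n_tight


def test_catalog_filter_semantics(rng):
    seqs = {}
    loci = []
    for i in range(5):
        if i < 2:  # undesignable: no left flank at all
            seq, _ = template_with_ssr(rng, 0, 200)
            locus = make_locus(seq, "ACC", 8, 0)
        else:
            seq, locus = template_with_ssr(rng, 150, 150)
        locus = SSRLocus(**{**locus.__dict__, "unique_seq_id": f"u{i}"})
        seqs[f"u{i}"] = UniqueSequence(id=f"u{i}", kind="singleton", genus="G",
                                       member_ids=[f"m{i}"], sequence=seq)
        loci.append(locus)
    catalog = pd_mod.catalog_with_primers(loci, seqs)
    assert len(catalog) == 3
    assert {L.unique_seq_id for L, _ in catalog} == {"u2", "u3", "u4"}


# ---------------------------------------------------------------------------
# exhaustive oracle


def exhaustive_best_pair(seq, locus, params):
    """Independent enumeration of every window pair with direct constraint
    re-measurement (Biopython Tm called directly)."""
    tm_memo = {}

    def tm(s):
        if s not in tm_memo:
            tm_memo[s] = MeltingTemp.Tm_NN(s, Na=params.salt_mM,
                                           dnac1=params.oligo_nM / 2,
                                           dnac2=params.oligo_nM / 2)
        return tm_memo[s]

    ok_memo = {}

    def ok(s):
        if s in ok_memo:
            return ok_memo[s]
        ok_memo[s] = _ok_uncached(s)
        return ok_memo[s]

    def _ok_uncached(s):
        if set(s) - set("ACGT"):
            return None
        gc = (s.count("G") + s.count("C")) / len(s)
        if not params.gc_range[0] <= gc <= params.gc_range[1]:
            return None
        t = tm(s)
        if not params.tm_range[0] <= t <= params.tm_range[1]:
            return None
        if pd_mod.longest_self_complementary_run(s) > params.max_self_complementary_run:
            return None
        return t, gc

    best = None
    n = len(seq)
    for f_end in range(locus.start + 1):
        for lf in range(params.len_range[0], params.len_range[1] + 1):
            f_start = f_end - lf
            if f_start < 0:
                continue
            f = ok(seq[f_start:f_end])
            if not f:
                continue
            for r_start in range(locus.end, n):
                if r_start + params.len_range[0] - f_start > params.product_size_range[1]:
                    break  # pure geometry: product can only grow from here
                for lr in range(params.len_range[0], params.len_range[1] + 1):
                    r_end = r_start + lr
                    if r_end > n:
                        continue
                    product = r_end - f_start
                    if not params.product_size_range[0] <= product <= params.product_size_range[1]:
                        continue
                    r = ok(revcomp(seq[r_start:r_end]))
                    if not r:
                        continue
                    if abs(f[0] - r[0]) > params.max_tm_difference:
                        continue
                    pen = (
                        abs(lf - 20) + abs(lr - 20)
                        + abs(f[0] - 60) + abs(r[0] - 60)
                        + 0.5 * (abs(f[1] - 0.5) + abs(r[1] - 0.5)) * 100
                        + abs(f[0] - r[0])
                    )
                    key = (pen, product, f_start)
                    if best is None or key < best[0]:
                        best = (key, f_start, f_end, r_start, r_end)
    return best


def test_designer_matches_exhaustive_oracle(rng):
    params = pd_mod.PrimerParams()
    compared = 0
    for _ in range(6):
        seq, locus = template_with_ssr(
            rng, int(rng.integers(100, 160)), int(rng.integers(100, 160)),
            gc=float(rng.uniform(0.40, 0.60)),
        )
        got = pd_mod.design_primers(seq, locus, params)
        want = exhaustive_best_pair(seq, locus, params)
        if want is None:
            assert got == []
            continue
        compared += 1
        best = got[0]
        assert (best.f_start, best.f_end, best.r_start, best.r_end) == want[1:]
        assert best.penalty == pytest.approx(want[0][0])
    assert compared >= 3
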