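"""Duplex expectation scoring, site scanning, and allele re-scoring."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mirvar.errors import RefAlleleMismatch, ValidationError
from mirvar.scoring import (
    AlleleEdit,
    AlleleEffect,
    Bulge,
    DuplexAlignment,
    Inhibition,
    MiRNA,
    alignment_text,
    best_alignment_for,
    classify_inhibition,
    find_sites,
    rescore_with_alleles,
    score_duplex,
    to_rna,
    upe_proxy,
)

from oracles import brute_force_expectation, best_structures

POLY_U = MiRNA("polyU", "U" * 21)


def ungapped(mirna, site, tid="t"):
    L = len(mirna)
    pairs = tuple(
        _cls(mirna.sequence[i - 1], site[L - i]) for i in range(1, L + 1))
    return DuplexAlignment(mirna.id, tid, 1, L, pairs)


def _cls(m, t):
    if (m, t) in {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}:
        return "match"
    if (m, t) in {("G", "U"), ("U", "G")}:
        return "wobble"
    return "mismatch"


class TestScoreDuplex:
    def test_perfect_complement_scores_zero(self):
        site = "A" * 21
        assert score_duplex(POLY_U, site, ungapped(POLY_U, site)) == 0.0

    def test_single_wobble_outside_seed(self):
        # G at the site position pairing miRNA position 15 -> U:G wobble
        site = list("A" * 21)
        site[21 - 15] = "G"
        site = "".join(site)
        assert score_duplex(POLY_U, site, ungapped(POLY_U, site)) == 0.5

    def test_seed_mismatch_doubled(self):
        # C pairing miRNA position 5 (in the seed): 1.0 * 2
        site = list("A" * 21)
        site[21 - 5] = "C"
        site = "".join(site)
        assert score_duplex(POLY_U, site, ungapped(POLY_U, site)) == 2.0

    def test_target_bulge_outside_seed(self):
        # one extra target base anchored at miRNA position 20
        L, a = 21, 20
        site = "A" * 22
        pairs = ("match",) * L
        aln = DuplexAlignment(
            "polyU", "t", 1, 22, pairs, (Bulge("target", a, "A"),))
        assert score_duplex(POLY_U, site, aln) == 2.0

    def test_inconsistent_alignment_names_position(self):
        site = "A" * 21
        aln = ungapped(POLY_U, site)
        wrong = DuplexAlignment(
            aln.mirna_id, aln.target_id, 1, 21,
            ("mismatch",) + aln.pairs[1:], ())
        with pytest.raises(ValidationError, match="position 1"):
            score_duplex(POLY_U, site, wrong)

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(st.data())
    def test_matches_brute_force_oracle(self, data):
        """Score equals an independent per-position penalty summation
        for random duplexes over all three geometries."""
        rng_bases = "ACGU"
        L = data.draw(st.integers(18, 25))
        mir = MiRNA("m", "".join(
            data.draw(st.sampled_from(rng_bases)) for _ in range(L)))
        kind = data.draw(st.sampled_from(["ungapped", "target", "mirna"]))
        if kind == "ungapped":
            M, bulge = L, None
        elif kind == "target":
            M, bulge = L + 1, ("target", data.draw(st.integers(1, L - 1)))
        else:
            M, bulge = L - 1, ("mirna", data.draw(st.integers(2, L - 1)))
        site = "".join(
            data.draw(st.sampled_from(rng_bases)) for _ in range(M))
        hits = find_sites(mir, site, max_expectation=float("inf"))
        match = next(
            h for h in hits
            if h.alignment.site_start == 1 and h.alignment.site_end == M
            and ((not h.alignment.bulges and bulge is None)
                 or (h.alignment.bulges
                     and (h.alignment.bulges[0].strand,
                          h.alignment.bulges[0].anchor) == bulge)))
        expected = brute_force_expectation(mir.sequence, site, bulge)
        assert match.expectation == pytest.approx(expected)
        assert score_duplex(mir, site, match.alignment) == pytest.approx(
            expected)


class TestFindSites:
    def test_exact_reverse_complement_found_with_zero_e(self):
        mir = MiRNA("m", "ACGUACGUACGUACGUACGUA")
        rc = {"A": "U", "C": "G", "G": "C", "U": "A"}
        site = "".join(rc[b] for b in reversed(mir.sequence))
        tx = "C" * 40 + site + "C" * 40
        hits = [h for h in find_sites(mir, tx, 3.5) if h.expectation == 0.0]
        assert [(h.alignment.site_start, h.alignment.site_end)
                for h in hits] == [(41, 61)]

    def test_polyA_transcript_all_windows_hit(self):
        hits = find_sites(POLY_U, "A" * 100, max_expectation=0.0)
        assert len(hits) == 100 - 21 + 1

    def test_cutoff_excludes_high_e(self):
        # best possible window has two seed mismatches: E = 4.0 > 3.5
        site = list("A" * 21)
        site[21 - 5] = "C"
        site[21 - 6] = "C"
        tx = "".join(site)
        assert find_sites(POLY_U, tx, 3.5) == []

    def test_candidate_count_at_infinite_cutoff(self):
        """N-L+1 ungapped + (N-L)(L-1) target-bulge + (N-L+2)(L-2)
        miRNA-bulge candidates."""
        N, L = 40, 21
        mir = MiRNA("m", "U" * L)
        hits = find_sites(mir, "A" * N, max_expectation=float("inf"))
        expected = (N - L + 1) + (N - L) * (L - 1) + (N - L + 2) * (L - 2)
        assert len(hits) == expected
        # every reported E is reproduced by score_duplex on its alignment
        for h in hits[:50]:
            seq = h.site_seq
            assert score_duplex(mir, seq, h.alignment) == pytest.approx(
                h.expectation)

    def test_site_lengths_confined_to_l_pm_1(self):
        mir = MiRNA("m", "U" * 21)
        hits = find_sites(mir, "A" * 60, max_expectation=float("inf"))
        lengths = {h.alignment.site_length for h in hits}
        assert lengths == {20, 21, 22}

    def test_empty_transcript_returns_empty(self):
        assert find_sites(POLY_U, "") == []

    def test_non_nucleotide_raises(self):
        with pytest.raises(ValidationError):
            find_sites(POLY_U, "A" * 30 + "X" + "A" * 30)

    def test_sorted_by_expectation_then_position(self):
        mir = MiRNA("m", "U" * 21)
        hits = find_sites(mir, "A" * 50, max_expectation=float("inf"))
        keys = [(h.expectation, h.alignment.site_start) for h in hits]
        assert keys == sorted(keys)


class TestClassifyInhibition:
    def test_perfect_complement_is_cleavage(self):
        site = "A" * 21
        aln = ungapped(POLY_U, site)
        assert classify_inhibition(aln) is Inhibition.CLEAVAGE

    def test_central_mismatch_is_translation(self):
        site = list("A" * 21)
        site[21 - 10] = "C"
        site = "".join(site)
        aln = ungapped(POLY_U, site)
        assert classify_inhibition(aln) is Inhibition.TRANSLATION

    def test_seed_mismatch_outside_center_is_cleavage(self):
        site = list("A" * 21)
        site[21 - 5] = "C"
        site = "".join(site)
        aln = ungapped(POLY_U, site)
        assert classify_inhibition(aln) is Inhibition.CLEAVAGE

    def test_central_wobble_stays_cleavage(self):
        site = list("A" * 21)
        site[21 - 10] = "G"  # U:G wobble at position 10
        site = "".join(site)
        aln = ungapped(POLY_U, site)
        assert classify_inhibition(aln) is Inhibition.CLEAVAGE

    def test_central_target_bulge_is_translation(self):
        site = "A" * 22
        aln = DuplexAlignment("polyU", "t", 1, 22, ("match",) * 21,
                              (Bulge("target", 10, "A"),))
        assert classify_inhibition(aln) is Inhibition.TRANSLATION


class TestUpeProxy:
    def test_unpaired_context_is_zero(self):
        assert upe_proxy("A" * 120, 30, 50) == 0.0

    def test_gc_hairpin_site_on_stem(self):
        assert upe_proxy("GGGGAAAACCCC", 1, 4, flank=8) == 12.0

    def test_gc_hairpin_site_in_loop(self):
        assert upe_proxy("GGGGAAAACCCC", 5, 8, flank=8) == 0.0

    def test_interval_out_of_bounds(self):
        with pytest.raises(ValidationError):
            upe_proxy("ACGU" * 5, 10, 30)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.data())
    def test_dp_optimum_matches_exhaustive_enumeration(self, data):
        """On windows <= 12 nt the folding optimum equals full
        enumeration of nested structures, and the traceback structure
        is one of the co-optimal ones."""
        n = data.draw(st.integers(5, 12))
        seq = "".join(data.draw(st.sampled_from("ACGU")) for _ in range(n))
        best_w, opts = best_structures(seq)
        # whole window as the "site": proxy = total weight of the chosen
        # optimal structure = DP optimum
        got = upe_proxy(seq, 1, n, flank=0)
        assert got == pytest.approx(best_w)

    def test_shorter_window_never_increases_optimum(self):
        seq = "GGCGAUAAAGCUAGCGCCGAUC"
        full = upe_proxy(seq, 1, len(seq), flank=0)
        inner = upe_proxy(seq[2:-2], 1, len(seq) - 4, flank=0)
        assert inner <= full + 1e-9


class TestRescoreWithAlleles:
    def _perfect_site(self):
        mir = MiRNA("m", "ACGUACGUACGUACGUACGUA")
        rc = {"A": "U", "C": "G", "G": "C", "U": "A"}
        site = "".join(rc[b] for b in reversed(mir.sequence))
        tx = "C" * 40 + site + "C" * 40
        hit = find_sites(mir, tx, 0.0)[0]
        return mir, tx, hit

    def test_central_mismatch_edit_impairs_by_two(self):
        mir, tx, site = self._perfect_site()
        L = 21
        j = L - 10 + 1  # in-site position pairing miRNA position 10
        ref = site.site_seq[j - 1]
        alt = next(b for b in "ACGU"
                   if _cls(mir.sequence[9], b) == "mismatch")
        res = rescore_with_alleles(site, [(j, ref, alt)])
        assert res.delta_e == pytest.approx(2.0)
        assert res.effect is AlleleEffect.IMPAIRED

    def test_wobble_to_match_enhances(self):
        # poly-U miRNA against a site with one G (wobble) outside seed
        site_seq = list("A" * 21)
        site_seq[21 - 15] = "G"
        tx = "".join(site_seq)
        hit = find_sites(POLY_U, tx, 1.0)[0]
        assert hit.expectation == 0.5
        res = rescore_with_alleles(hit, [(21 - 15 + 1, "G", "A")])
        assert res.delta_e == pytest.approx(-0.5)
        assert res.effect is AlleleEffect.ENHANCED

    def test_empty_edit_list_is_neutral(self):
        _, _, site = self._perfect_site()
        res = rescore_with_alleles(site, [])
        assert res.delta_e == 0.0
        assert res.effect is AlleleEffect.NEUTRAL
        assert res.e_alt == res.e_ref

    def test_ref_mismatch_raises_with_positions(self):
        _, _, site = self._perfect_site()
        wrong = "G" if site.site_seq[4] != "G" else "C"
        with pytest.raises(RefAlleleMismatch) as exc:
            rescore_with_alleles(site, [(5, wrong, "A")])
        assert exc.value.position == 5

    def test_inverse_edits_compose_to_identity(self):
        mir, tx, site = self._perfect_site()
        j = 3
        ref = site.site_seq[j - 1]
        alt = "A" if ref != "A" else "G"
        fwd = rescore_with_alleles(site, [(j, ref, alt)])
        # build the edited site and rescore back
        alt_seq = site.site_seq[:j - 1] + alt + site.site_seq[j:]
        e_alt, pairs, bulges = best_alignment_for(mir.sequence, alt_seq)
        from mirvar.scoring import TargetSite
        edited = TargetSite(
            alignment=DuplexAlignment(mir.id, "t", site.alignment.site_start,
                                      site.alignment.site_end, pairs, bulges),
            site_seq=alt_seq, mirna_seq=mir.sequence,
            expectation=e_alt, inhibition=site.inhibition)
        back = rescore_with_alleles(edited, [(j, alt, ref)])
        assert back.delta_e == pytest.approx(-fwd.delta_e)

    def test_site_destroying_deletion(self):
        """A deletion in the seed-pairing region that pushes E past the
        retention cutoff marks the site destroyed."""
        mir, tx, site = self._perfect_site()
        # delete 2 bases pairing seed positions -> shorter site, big E
        res = rescore_with_alleles(
            site, [(10, site.site_seq[9:12], site.site_seq[9])])
        assert res.e_alt > 3.5
        assert res.effect is AlleleEffect.SITE_DESTROYED

    def test_upe_recomputed_with_context(self):
        mir, tx, site = self._perfect_site()
        j = 5
        ref = site.site_seq[j - 1]
        alt = "A" if ref != "A" else "G"
        res = rescore_with_alleles(site, [(j, ref, alt)], context_seq=tx)
        assert res.upe_ref is not None and res.upe_alt is not None


def test_alignment_text_rows_align():
    site = "A" * 21
    s = find_sites(POLY_U, "A" * 21, 0.0)[0]
    rows = alignment_text(s).splitlines()
    assert len(rows) == 3
    assert "A" * 21 in rows[0]
    assert rows[1].strip() == "|" * 21
    assert "U" * 21 in rows[2]


def test_mirna_validation():
    with pytest.raises(ValidationError):
        MiRNA("short", "ACGU")
    m = MiRNA("t2u", "ACGT" * 5 + "A")
    assert "T" not in m.sequence and "U" in m.sequence
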