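"""Dimer detection, binding-site search, amplicon prediction, scoring matrix."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import _oracles as orc
from plexprimer.fixtures import random_dna
from plexprimer.interaction import (
    BindingSite,
    InteractionSettings,
    build_index,
    build_scoring_matrix,
    cross_compatible,
    dimer_dg,
    find_binding_sites,
    is_dimer,
    predict_amplicons,
    ps_is_specific,
)
from plexprimer.thermo import perfect_duplex_dg, revcomp

dna = st.text(alphabet="ACGT", min_size=8, max_size=28)


class TestDimer:
    @given(p1=dna, p2=dna)
    def test_symmetric_in_arguments(self, p1, p2):
        assert dimer_dg(p1, p2) == pytest.approx(dimer_dg(p2, p1), abs=1e-9)

    def test_full_reverse_complement_reaches_perfect_duplex(self):
        p = "AGCTTCGGATCAAGGCTTAA"
        assert dimer_dg(p, revcomp(p)) == pytest.approx(perfect_duplex_dg(p), abs=1e-9)
        assert is_dimer(p, revcomp(p))

    def test_purine_only_oligos_cannot_pair(self):
        assert dimer_dg("A" * 12, "G" * 12) == 0.0
        assert not is_dimer("AGAGAGAGAGAG", "GGAAGGAAGGAA")

    def test_infinitely_strict_cutoff_never_fires(self):
        p = "AGCTTCGGATCAAGGCTTAA"
        assert not is_dimer(p, revcomp(p), cutoff=-1e9)

    @given(p1=dna, p2=dna)
    def test_matches_all_offsets_enumeration_oracle(self, p1, p2):
        assert dimer_dg(p1, p2) == pytest.approx(orc.dimer_dg(p1, p2), abs=1e-9)

    def test_short_oligo_rejected(self):
        with pytest.raises(ValueError):
            dimer_dg("ACGTACG", "ACGTACGT")


class TestKmerIndex:
    def test_single_record_word_count(self):
        seq = random_dna(np.random.default_rng(0), 120)
        idx = build_index({"R": seq}, 9)
        assert idx.n_plus_words("R") == len(seq) - 9 + 1

    def test_word_and_reverse_complement_index_distinct_entries(self):
        w = "ACGGATCGT"
        seq = w + "A" * 20 + revcomp(w)
        idx = build_index({"R": seq}, 9)
        naive_plus = [("R", j) for j in range(len(seq) - 8) if seq[j : j + 9] == w]
        naive_minus = [("R", j) for j in range(len(seq) - 8)
                       if seq[j : j + 9] == revcomp(w)]
        assert idx.plus_positions(w) == naive_plus == [("R", 0)]
        assert idx.minus_positions(w) == naive_minus
        assert set(naive_plus).isdisjoint(naive_minus)

    def test_lookups_agree_with_naive_scan(self):
        rng = np.random.default_rng(5)
        seq = random_dna(rng, 3000)
        idx = build_index({"R": seq}, 9)
        for _ in range(30):
            i = int(rng.integers(0, len(seq) - 9))
            w = seq[i : i + 9]
            naive_plus = [("R", j) for j in range(len(seq) - 8) if seq[j : j + 9] == w]
            naive_minus = [("R", j) for j in range(len(seq) - 8)
                           if seq[j : j + 9] == revcomp(w)]
            assert idx.plus_positions(w) == naive_plus
            assert idx.minus_positions(w) == naive_minus

    def test_empty_database_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            build_index({}, 9)


class TestBindingSites:
    def test_absent_seed_yields_no_sites(self, clean3_index):
        # a pyrimidine-only primer: its seed cannot occur in the purine zones
        # and the screened padding avoids candidate seeds anyway
        primer = "TCTTCTTCCTCCTTCTCTTC"
        hits = find_binding_sites(primer, clean3_index, InteractionSettings())
        oracle = orc.find_sites(primer, clean3_index.records, 9, -9.0)
        assert [(s.db_id, s.strand, s.three_prime_position) for s in hits] == [
            (rid, strand, t3) for rid, strand, t3, _, _ in oracle
        ]

    def test_primer_designed_from_template_finds_origin_site(self, clean3, clean3_index):
        ps = clean3.candidate_sets["T1"][0]
        sites = find_binding_sites(ps.forward, clean3_index)
        assert any(
            s.db_id == "T1" and s.strand == "+" and s.five_prime_position == ps.forward.start
            for s in sites
        )

    def test_sites_match_naive_full_scan_oracle(self, clean3, clean3_index):
        st_ = InteractionSettings()
        for tid in clean3.template_ids:
            for ps in clean3.candidate_sets[tid][:2]:
                for primer in (ps.forward, ps.reverse):
                    mine = find_binding_sites(primer, clean3_index, st_)
                    oracle = orc.find_sites(primer.sequence, clean3_index.records,
                                            st_.seed_length, st_.min_binding_dg)
                    assert [(s.db_id, s.strand, s.three_prime_position,
                             s.five_prime_position) for s in mine] == [
                        o[:4] for o in oracle
                    ]
                    for s, o in zip(mine, oracle):
                        assert s.binding_dg == pytest.approx(o[4], abs=1e-9)

    def test_every_site_clears_binding_threshold(self, clean3, clean3_index):
        st_ = InteractionSettings()
        ps = clean3.candidate_sets["T2"][0]
        for s in find_binding_sites(ps.forward, clean3_index, st_):
            assert s.binding_dg <= st_.min_binding_dg


def _site(strand, t3, t5, rid="R", pid="p", dg=-15.0, L=20):
    return BindingSite(pid, rid, strand, t3, t5, dg, 9, L)


class TestPredictAmplicons:
    def test_no_minus_strand_sites_no_amplicons(self):
        assert predict_amplicons([_site("+", 119, 100)], [], 2000) == []

    def test_planted_five_prime_arithmetic(self):
        f = _site("+", 119, 100)
        r = _site("-", 480, 499)
        (amp,) = predict_amplicons([f], [r], 2000)
        assert amp.size == 499 - 100 + 1 == 400

    def test_equals_exhaustive_pairing_oracle(self):
        rng = np.random.default_rng(8)
        fs = [_site("+", int(p) + 19, int(p)) for p in rng.integers(0, 2000, 12)]
        rs = [_site("-", int(p), int(p) + 19) for p in rng.integers(0, 2000, 12)]
        mine = predict_amplicons(fs, rs, 800)
        oracle = orc.amplicons(
            [("R", "+", s.three_prime_position, s.five_prime_position, s.binding_dg) for s in fs],
            [("R", "-", s.three_prime_position, s.five_prime_position, s.binding_dg) for s in rs],
            800,
        )
        assert [(a.db_id, a.forward_site.five_prime_position,
                 a.reverse_site.five_prime_position, a.size) for a in mine] == oracle

    def test_size_cap_enforced(self):
        f = _site("+", 119, 100)
        r = _site("-", 2580, 2599)
        assert predict_amplicons([f], [r], 2000) == []


class TestStepOneSpecificity:
    def test_clean_database_is_specific(self, clean3, clean3_index):
        for tid in clean3.template_ids:
            ok, detail = ps_is_specific(clean3.candidate_sets[tid][0], clean3_index)
            assert ok, detail

    def test_duplicated_template_record_breaks_specificity(self, clean3):
        t1 = clean3.templates["T1"]
        idx = build_index({**clean3.templates, "DUP": t1}, 9)
        ok, detail = ps_is_specific(clean3.candidate_sets["T1"][0], idx)
        assert not ok and "amplicons" in detail

    def test_missing_template_flagged_as_database_mismatch(self, clean3):
        idx = build_index({"T2": clean3.templates["T2"]}, 9)
        ok, detail = ps_is_specific(clean3.candidate_sets["T1"][0], idx)
        assert not ok and detail == "template_missing_from_database"


class TestCrossCompatible:
    def test_unrelated_clean_templates_are_compatible(self, clean3, clean3_index):
        a = clean3.candidate_sets["T1"][0]
        b = clean3.candidate_sets["T2"][0]
        ok, reason = cross_compatible(a, b, clean3_index)
        assert ok and reason.tag == "compatible"

    def test_planted_decoy_blocks_pair_with_pp5_reason(self, decoy3):
        idx = build_index(decoy3.background, 9)
        d = decoy3.manifest["decoys"][0]
        a = decoy3.candidate_sets[d["template_i"]][d["rank_i"]]
        b = decoy3.candidate_sets[d["template_j"]][d["rank_j"]]
        ok, reason = cross_compatible(a, b, idx)
        assert not ok
        assert reason.tag == "nonspecific_amplicon"
        assert reason.detail.startswith("PP5")
        assert f"{d['expected_size']}bp" in reason.detail

    def test_same_template_pair_rejected(self, clean3, clean3_index):
        a, b = clean3.candidate_sets["T1"][:2]
        with pytest.raises(ValueError, match="different templates"):
            cross_compatible(a, b, clean3_index)

    def test_agrees_with_composite_brute_force_referee(self, decoy3):
        idx = build_index(decoy3.background, 9)
        st_ = InteractionSettings()
        tids = decoy3.template_ids
        for i in range(len(tids)):
            for j in range(i + 1, len(tids)):
                for a in decoy3.candidate_sets[tids[i]][:2]:
                    for b in decoy3.candidate_sets[tids[j]][:2]:
                        mine, _ = cross_compatible(a, b, idx, st_)
                        ref = orc.cross_ok(a, b, decoy3.background, st_.seed_length,
                                           st_.min_binding_dg, st_.max_amplicon,
                                           st_.dimer_cutoff)
                        assert mine == ref


class TestScoringMatrix:
    def test_symmetric_with_same_template_exclusions(self, clean3, clean3_index):
        all_ps = [ps for sets in clean3.candidate_sets.values() for ps in sets]
        m = build_scoring_matrix(all_ps, clean3_index)
        assert np.array_equal(m.values, m.values.T)
        for i, a in enumerate(all_ps):
            for j, b in enumerate(all_ps):
                if a.template_id == b.template_id:
                    assert m.reasons[i][j].tag == "same_template"
                    assert not m.compatible(a, b)

    def test_clean_fixture_matrix_is_all_ones(self, clean3, clean3_index):
        all_ps = [ps for sets in clean3.candidate_sets.values() for ps in sets]
        m = build_scoring_matrix(all_ps, clean3_index)
        for i, a in enumerate(all_ps):
            for j, b in enumerate(all_ps):
                if a.template_id != b.template_id:
                    assert m.values[i, j] == 1

    def test_cells_replay_pairwise_cross_compatible(self, decoy3):
        idx = build_index(decoy3.background, 9)
        all_ps = [ps for sets in decoy3.candidate_sets.values() for ps in sets]
        m = build_scoring_matrix(all_ps, idx)
        for i, a in enumerate(all_ps):
            for j, b in enumerate(all_ps):
                if i < j and a.template_id != b.template_id:
                    ok, reason = cross_compatible(a, b, idx)
                    assert m.values[i, j] == (1 if ok else 0)
                    assert m.reasons[i][j].tag == reason.tag

    def test_growing_database_only_removes_compatibility(self, clean3, decoy3):
        """clean3 and decoy3 share templates/candidates (same seed); the decoy
        background is a superset in content, so cells may only flip 1 -> 0."""
        all_clean = [ps for sets in clean3.candidate_sets.values() for ps in sets]
        all_decoy = [ps for sets in decoy3.candidate_sets.values() for ps in sets]
        assert [ps.id() for ps in all_clean] == [ps.id() for ps in all_decoy]
        m_clean = build_scoring_matrix(all_clean, build_index(clean3.background, 9))
        m_decoy = build_scoring_matrix(all_decoy, build_index(decoy3.background, 9))
        assert np.all(m_decoy.values <= m_clean.values)
        assert m_decoy.values.sum() < m_clean.values.sum()

    def test_deterministic(self, clean3, clean3_index):
        all_ps = [ps for sets in clean3.candidate_sets.values() for ps in sets]
        m1 = build_scoring_matrix(all_ps, clean3_index)
        m2 = build_scoring_matrix(all_ps, clean3_index)
        assert np.array_equal(m1.values, m2.values)
        assert m1.to_tsv() == m2.to_tsv()
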