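import itertools
import math

import pytest
from hypothesis import given, settings, strategies as st

from effectorkit.selection import (
    CodonAlignment,
    SaturationError,
    back_translate,
    codon_sites,
    ng86,
    pathway_differences,
    screen_groups,
    trim_codon_alignment,
    GENETIC_CODE,
    STOP_CODONS,
)
from effectorkit.synthetic import simulate_codon_pair

from _ng86_oracle import oracle_counts, oracle_differences, oracle_sites

SENSE_CODONS = sorted(c for c in GENETIC_CODE if c not in STOP_CODONS)


class TestBackTranslate:
    def test_gap_becomes_codon_gap(self):
        aln = back_translate({"s": "M-K"}, {"s": "ATGAAA"})
        assert aln.rows["s"] == "ATG---AAA"

    def test_length_mismatch_names_id(self):
        with pytest.raises(ValueError, match="s1"):
            back_translate({"s1": "MKV"}, {"s1": "ATGAAA"})

    def test_trailing_stop_dropped(self):
        aln = back_translate({"s": "MK"}, {"s": "ATGAAATAA"})
        assert aln.rows["s"] == "ATGAAA"

    def test_translation_mismatch_reports_position(self):
        with pytest.raises(ValueError, match="column 2"):
            back_translate({"s": "MM"}, {"s": "ATGAAA"})

    def test_ungapping_reproduces_cds(self):
        cds = {"x": "ATGGCTAAA", "y": "ATGGCCAAG"}
        aln = back_translate({"x": "MA-K", "y": "MA-K"},
                             {"x": "ATGGCTAAA", "y": "ATGGCCAAG"})
        for sid in cds:
            assert aln.rows[sid].replace("-", "") == cds[sid]


class TestTrim:
    def test_gapped_codon_column_removed(self):
        aln = CodonAlignment({"a": "ATG---AAA", "b": "ATGGCTAAA"})
        out = trim_codon_alignment(aln)
        assert out.rows == {"a": "ATGAAA", "b": "ATGAAA"}

    def test_mask_region_removed_before_gap_trim(self):
        # removing the first 40 codons of a repeat region = 120 nt
        rows = {"a": "ATG" * 50, "b": "ATG" * 50}
        out = trim_codon_alignment(CodonAlignment(rows), mask_regions=[(1, 40)])
        assert len(out.rows["a"]) == 30

    def test_identity_when_nothing_to_trim(self):
        rows = {"a": "ATGGCT", "b": "ATGGCC"}
        out = trim_codon_alignment(CodonAlignment(rows))
        assert out.rows == rows

    def test_out_of_bounds_mask_rejected(self):
        with pytest.raises(ValueError, match="out of bounds"):
            trim_codon_alignment(CodonAlignment({"a": "ATGGCT"}), mask_regions=[(1, 3)])


class TestNG86Basics:
    def test_identical_sequences(self):
        r = ng86("ATGGCTAAA", "ATGGCTAAA")
        assert r.dn == 0 and r.ds == 0 and r.omega is None

    def test_single_synonymous_difference_reports_omega_zero(self):
        r = ng86("ATGGCT", "ATGGCC")
        assert r.dn == 0.0
        assert r.ds > 0
        assert r.omega == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            ng86("ATGGCT", "ATG")

    def test_gap_rejected(self):
        with pytest.raises(ValueError, match="[Gg]ap"):
            ng86("ATG---", "ATGGCT")

    def test_internal_stop_rejected(self):
        with pytest.raises(ValueError, match="stop"):
            ng86("ATGTAAGCT", "ATGGCTGCT")

    def test_saturation_error(self):
        # every codon differs nonsynonymously -> pN stays beyond the JC limit
        a = "TGG" * 30  # Trp
        b = "CAT" * 30  # His, 3 differences per codon
        with pytest.raises(SaturationError):
            ng86(a, b)

    def test_symmetry(self):
        a, b = simulate_codon_pair(60, 1.0, 0.3, 17)
        ra, rb = ng86(a, b), ng86(b, a)
        assert math.isclose(ra.dn, rb.dn, rel_tol=1e-12)
        assert math.isclose(ra.ds, rb.ds, rel_tol=1e-12)


class TestSiteCounts:
    def test_sites_sum_to_three_per_codon(self):
        for codon in SENSE_CODONS:
            s, n = codon_sites(codon)
            assert math.isclose(s + n, 3.0, rel_tol=1e-12)

    def test_sites_match_oracle_for_all_sense_codons(self):
        for codon in SENSE_CODONS:
            s, n = codon_sites(codon)
            os, on = oracle_sites(codon)
            assert math.isclose(s, float(os), abs_tol=1e-12)
            assert math.isclose(n, float(on), abs_tol=1e-12)

    def test_total_sites_sum_to_sequence_length(self):
        a, b = simulate_codon_pair(50, 1.0, 0.2, 3)
        r = ng86(a, b)
        assert math.isclose(r.sites_s + r.sites_n, len(a), rel_tol=1e-12)


class TestPathwayCounts:
    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.sampled_from(SENSE_CODONS), st.sampled_from(SENSE_CODONS))
    def test_pathway_average_matches_oracle(self, ca, cb):
        sd, nd = pathway_differences(ca, cb)
        osd, ond = oracle_differences(ca, cb)
        assert math.isclose(sd, float(osd), abs_tol=1e-12)
        assert math.isclose(nd, float(ond), abs_tol=1e-12)

    def test_stop_blocked_pathways_excluded(self):
        # AGA -> TGG: the ordering via TGA passes through a stop and must
        # not contribute; the surviving path AGA->AGG->TGG has one
        # synonymous and one nonsynonymous step
        sd, nd = pathway_differences("AGA", "TGG")
        assert (sd, nd) == (1.0, 1.0)
        osd, ond = oracle_differences("AGA", "TGG")
        assert (float(osd), float(ond)) == (1.0, 1.0)

    def test_total_steps_equal_hamming_distance(self):
        for ca, cb in itertools.product(["ATG", "GCT", "TTA"], ["GCC", "ATA"]):
            diff = sum(1 for x, y in zip(ca, cb) if x != y)
            sd, nd = pathway_differences(ca, cb)
            assert math.isclose(sd + nd, diff, rel_tol=1e-12)


class TestNG86FullOracle:
    def test_ten_codon_pair_with_mixed_differences(self):
        a = "ATGGCTAAACCGTTTGGGCACGATTGCATA"
        b = "ATGGCGAAACCGTTTGGACACGCTTGCATA"
        r = ng86(a, b)
        S, N, Sd, Nd = oracle_counts(a, b)
        assert math.isclose(r.sites_s, float(S), abs_tol=1e-12)
        assert math.isclose(r.sites_n, float(N), abs_tol=1e-12)
        assert math.isclose(r.diffs_s, float(Sd), abs_tol=1e-12)
        assert math.isclose(r.diffs_n, float(Nd), abs_tol=1e-12)
        ps, pn = float(Sd / S), float(Nd / N)
        assert math.isclose(r.ds, -0.75 * math.log(1 - 4 * ps / 3), rel_tol=1e-12)
        assert math.isclose(r.dn, -0.75 * math.log(1 - 4 * pn / 3), rel_tol=1e-12)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_random_pairs_match_oracle(self, seed):
        a, b = simulate_codon_pair(30, 1.0, 0.3, seed)
        r = ng86(a, b)
        S, N, Sd, Nd = oracle_counts(a, b)
        assert math.isclose(r.sites_s, float(S), abs_tol=1e-12)
        assert math.isclose(r.diffs_s, float(Sd), abs_tol=1e-12)
        assert math.isclose(r.diffs_n, float(Nd), abs_tol=1e-12)


class TestScreenGroups:
    def _aln(self, seqs):
        return CodonAlignment(dict(seqs))

    def test_identical_pair_excluded_from_percentages(self):
        groups = {"g1": ["a", "b"]}
        alns = {"g1": self._aln({"a": "ATGGCTAAA", "b": "ATGGCTAAA"})}
        results, summary = screen_groups(groups, alns)
        assert results[0].omega_aggregate is None
        assert summary["n_screened"] == 0
        assert summary["n_omega_undefined"] == 1
        assert summary["percent_flagged"] is None

    def test_singleton_group_skipped_with_note(self):
        results, summary = screen_groups({"g1": ["only"]}, {})
        assert "skipped" in results[0].note
        assert summary["n_skipped_small"] == 1

    def test_positive_selection_flagged(self):
        a, b = simulate_codon_pair(300, 3.0, 0.2, 5)
        results, summary = screen_groups({"g": ["a", "b"]}, {"g": self._aln({"a": a, "b": b})})
        assert results[0].positive_selection
        assert summary["n_flagged"] == 1

    def test_conserved_group_not_flagged(self):
        a, b = simulate_codon_pair(300, 0.1, 0.2, 5)
        results, _ = screen_groups({"g": ["a", "b"]}, {"g": self._aln({"a": a, "b": b})})
        assert not results[0].positive_selection
        assert results[0].omega_aggregate < 0.3

    def test_median_aggregation_over_pairs(self):
        seqs = {}
        root, other = simulate_codon_pair(100, 1.0, 0.4, 9)
        seqs["a"], seqs["b"], seqs["c"] = root, other, root
        results, _ = screen_groups({"g": list(seqs)}, {"g": self._aln(seqs)})
        omegas = sorted(p.omega for p in results[0].pairs if p.omega is not None)
        mid = len(omegas) // 2
        expected = omegas[mid] if len(omegas) % 2 else 0.5 * (omegas[mid - 1] + omegas[mid])
        assert results[0].omega_aggregate == pytest.approx(expected)

    def test_ds_zero_flag_option(self):
        # one nonsynonymous difference, no synonymous ones: dS = 0
        a, b = "ATGTGG", "ATGCGG"
        groups = {"g": ["a", "b"]}
        alns = {"g": self._aln({"a": a, "b": b})}
        res_off, _ = screen_groups(groups, alns)
        res_on, _ = screen_groups(groups, alns, flag_ds_zero=True)
        assert not res_off[0].positive_selection
        assert res_on[0].positive_selection

    def test_effector_group_filter(self):
        a, b = simulate_codon_pair(60, 1.0, 0.2, 2)
        groups = {"g1": ["a", "b"], "g2": ["c", "d"]}
        alns = {"g1": self._aln({"a": a, "b": b}), "g2": self._aln({"c": a, "d": b})}
        results, _ = screen_groups(groups, alns, effector_groups={"g1"})
        assert [r.group_id for r in results] == ["g1"]
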