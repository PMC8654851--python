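"""Caller behaviour: window scoring, candidate detection, guide matching."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rgenseq.align_io import ReadEndTrack
from rgenseq.cutsite_caller import (
    CallerParams,
    ContextError,
    call_cut_sites,
    detect_candidates,
    enumerate_genome_matches,
    match_guide,
    window_score,
)
from rgenseq.sequences import revcomp
from rgenseq.synthetic_data import GuideRNA, generate_genome, plant_sites
from _oracles import brute_genome_scan, brute_window_sum

GUIDE = GuideRNA("g", "ACGTACGTACGTACGTACGT")


class TestWindowScore:
    def test_empty_track_scores_zero(self):
        assert window_score(ReadEndTrack(), "c", 100) == 0

    def test_all_ends_in_one_bin(self):
        t = ReadEndTrack()
        t.add_end("c", "+", 100, 7)
        assert window_score(t, "c", 100) == 7

    def test_window_is_half_open_minus5_plus4(self):
        t = ReadEndTrack()
        for pos in (95, 104, 105):  # in, in, out for a window centered at 100
            t.add_end("c", "+", pos)
        assert window_score(t, "c", 100) == 2

    def test_unknown_chromosome_raises(self):
        t = ReadEndTrack()
        t.add_end("c", "+", 1)
        with pytest.raises(KeyError):
            window_score(t, "nope", 10)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        ends=st.lists(
            st.tuples(st.sampled_from("+-"), st.integers(0, 80), st.integers(1, 4)),
            max_size=25,
        ),
        center=st.integers(5, 75),
    )
    def test_matches_direct_enumeration(self, ends, center):
        t = ReadEndTrack()
        flat = {}
        for strand, pos, n in ends:
            t.add_end("c", strand, pos, n)
            flat[("c", pos)] = flat.get(("c", pos), 0) + n
        assert window_score(t, "c", center) == brute_window_sum(flat, "c", center)


class TestDetectCandidates:
    def test_empty_track_empty_list(self):
        assert detect_candidates(ReadEndTrack()) == []

    def test_single_clean_site_candidate_at_breakpoint(self):
        t = ReadEndTrack()
        t.add_end("c", "+", 500, 40)
        t.add_end("c", "-", 499, 40)
        cands = detect_candidates(t)
        assert [(c, p) for c, p, _ in cands] == [("c", 500)]
        assert cands[0][2] == 80

    def test_two_sites_one_kb_apart(self):
        t = ReadEndTrack()
        for b in (500, 1500):
            t.add_end("c", "+", b, 30)
            t.add_end("c", "-", b - 1, 30)
        cands = detect_candidates(t)
        assert [p for _, p, _ in cands] == [500, 1500]

    def test_bidirectional_filter_suppresses_one_sided_spike(self):
        t = ReadEndTrack()
        t.add_end("c", "+", 500, 50)  # one-sided pileup
        assert detect_candidates(t) == []
        relaxed = CallerParams(require_bidirectional=False)
        assert [p for _, p, _ in detect_candidates(t, relaxed)] == [500]

    def test_min_score_threshold(self):
        t = ReadEndTrack()
        t.add_end("c", "+", 500, 2)
        t.add_end("c", "-", 499, 2)
        assert detect_candidates(t, CallerParams(min_score=5)) == []
        assert len(detect_candidates(t, CallerParams(min_score=4))) == 1

    def test_raising_min_score_gives_nested_outputs(self, standard_scenario):
        track = standard_scenario.track
        lengths = standard_scenario.chrom_lengths
        prev = None
        for threshold in (5, 50, 5000, 50_000):
            got = {
                (c, p) for c, p, _ in
                detect_candidates(track, CallerParams(min_score=threshold), lengths)
            }
            if prev is not None:
                assert got <= prev
            prev = got


class TestMatchGuide:
    def _planted(self, strand, mm=0, seed=3):
        genome = {"c": generate_genome(20_000, 0.5, seed)}
        planted, sites = plant_sites(genome, GUIDE, [(mm, strand, 8.0)], seed=seed)
        return planted, sites[0]

    def test_plus_strand_zero_mismatch(self):
        genome, site = self._planted("+")
        m = match_guide(genome, "c", site.cut_position, GUIDE)
        assert m.strand == "+" and m.mismatches == 0
        assert m.cut_position == site.protospacer_start + 17
        assert m.matched_sequence[:20] == GUIDE.protospacer

    def test_minus_strand_mirrored(self):
        genome, site = self._planted("-", mm=2, seed=5)
        m = match_guide(genome, "c", site.cut_position, GUIDE)
        assert m.strand == "-" and m.mismatches == 2
        assert m.cut_position == site.protospacer_start + 3

    def test_candidate_within_tolerance_still_matches_exact_breakpoint(self):
        genome, site = self._planted("+")
        m = match_guide(genome, "c", site.cut_position + 2, GUIDE)
        assert m is not None and m.cut_position == site.cut_position

    def test_random_sequence_has_no_match(self):
        genome = {"c": generate_genome(20_000, 0.5, 11)}
        assert match_guide(genome, "c", 10_000, GUIDE, CallerParams(max_mismatches=3)) is None

    def test_insufficient_context_raises(self):
        genome = {"c": generate_genome(1_000, 0.5, 2)}
        with pytest.raises(ContextError):
            match_guide(genome, "c", 5, GUIDE)


class TestCallCutSites:
    def test_background_only_below_threshold_is_empty(self):
        genome = {"c": generate_genome(50_000, 0.5, 7)}
        t = ReadEndTrack()
        rng = np.random.default_rng(1)
        for pos in rng.integers(0, 50_000, size=200):  # sparse background
            t.add_end("c", "+" if rng.random() < 0.5 else "-", int(pos))
        assert len(call_cut_sites(t, genome, GUIDE)) == 0

    def test_recovers_all_low_mismatch_sites_exactly(self, standard_scenario, standard_calls):
        truth = {s.cut_position: s for s in standard_scenario.sites if s.mismatches <= 3}
        called = {r.cut_position: r for r in standard_calls if r.mismatches is not None}
        for cut, site in truth.items():
            near = [r for p, r in called.items() if abs(p - cut) <= 1]
            assert len(near) == 1
            assert near[0].strand == site.strand
            assert near[0].mismatches == site.mismatches

    def test_score_equals_window_sum_at_cut(self, standard_scenario, standard_calls):
        for r in standard_calls:
            assert r.score == window_score(standard_scenario.track, r.chrom, r.cut_position)

    def test_site_identities_stable_across_library_seeds(self, standard_scenario):
        from dataclasses import replace
        from rgenseq.synthetic_data import simulate_library

        sim2 = simulate_library(
            standard_scenario.genome, standard_scenario.sites,
            replace(standard_scenario.config, seed=standard_scenario.config.seed + 1),
        )
        key = lambda calls: {
            (r.chrom, r.cut_position, r.strand)
            for r in calls if r.mismatches is not None and r.mismatches <= 3
        }
        a = key(call_cut_sites(standard_scenario.track, standard_scenario.genome,
                               standard_scenario.guide))
        b = key(call_cut_sites(sim2.track, standard_scenario.genome, standard_scenario.guide))
        assert a == b

    def test_output_sorted_and_deterministic(self, standard_scenario, standard_calls):
        keys = [(r.chrom, r.cut_position) for r in standard_calls]
        assert keys == sorted(keys)
        again = call_cut_sites(standard_scenario.track, standard_scenario.genome,
                               standard_scenario.guide)
        assert [(r.cut_position, r.score) for r in again] == [
            (r.cut_position, r.score) for r in standard_calls
        ]

    def test_pam_offset_law_on_end_repaired_library(self, standard_scenario, standard_calls):
        """Every matched call has an NGG in the genome exactly 3 bp from its cut."""
        from rgenseq.sequences import matches_iupac

        seq = standard_scenario.genome["chr_sim"]
        matched = [r for r in standard_calls if r.mismatches is not None]
        assert matched
        for r in matched:
            if r.strand == "+":
                pam = seq[r.cut_position + 3 : r.cut_position + 6]
            else:
                pam = revcomp(seq[r.cut_position - 6 : r.cut_position - 3])
            assert matches_iupac(pam, "NGG")
            assert r.matched_sequence[20:] == pam


class TestEnumerateGenomeMatches:
    def test_single_exact_embedding(self):
        genome = {"c": "T" * 200 + GUIDE.protospacer + "AGG" + "T" * 200}
        hits = enumerate_genome_matches(genome, GUIDE, 0)
        assert hits == [("c", 200, "+", 0)]

    def test_minus_strand_embedding(self):
        insert = revcomp(GUIDE.protospacer + "TGG")
        genome = {"c": "T" * 100 + insert + "T" * 100}
        hits = enumerate_genome_matches(genome, GUIDE, 0)
        assert hits == [("c", 103, "-", 0)]

    def test_hopeless_guide_on_monotone_genome(self):
        guide = GuideRNA("a", "A" * 20)
        assert enumerate_genome_matches({"c": "C" * 5000}, guide, 3) == []

    def test_agrees_with_bruteforce_on_random_genome(self):
        genome = {"c": generate_genome(20_000, 0.42, 19)}
        fast = enumerate_genome_matches(genome, GUIDE, 4)
        slow = brute_genome_scan(genome, GUIDE.protospacer, "NGG", 4)
        assert fast == slow

    def test_iupac_pam_patterns(self):
        guide = GuideRNA("g", GUIDE.protospacer, pam_pattern="NAG")
        genome = {"c": "T" * 100 + GUIDE.protospacer + "CAG" + "T" * 100}
        assert enumerate_genome_matches(genome, guide, 0) == [("c", 100, "+", 0)]
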