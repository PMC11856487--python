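"""Alignment-based decomposition of allele-length differences by region."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ssrbridge as sb
from ssrbridge.decompose import (
    DecomposeError,
    LocusLayout,
    _left_normalize,
    align_global,
    decompose,
    decompose_pair,
    expected_platform_lengths,
    layout_from_annotation,
    primer_site_report,
)
from ssrbridge.repeats import RepeatAnnotation, extract_amplicon, find_repeat
from _oracles import nw_linear_score


def _sim_layout(panel, refs, name):
    locus = [l for l in panel if l.name == name][0]
    ref = refs[name]
    ann = find_repeat(ref)
    hit = extract_amplicon(ref, locus)
    return ref, layout_from_annotation(
        ann,
        (hit.forward_site.start, hit.forward_site.end),
        (hit.reverse_site.start, hit.reverse_site.end),
    )


class TestAlignGlobal:
    def test_identity_alignment(self):
        aln = align_global("ACGTACGT", "ACGTACGT")
        assert aln.score == 16
        assert "-" not in str(aln[0]) and "-" not in str(aln[1])

    def test_single_deletion_left_aligned(self):
        ref, obs = "ACGTACGT", "ACGACGT"
        layout = LocusLayout(fwd_primer=(0, 0), repeat=(0, 0), rev_primer=(8, 8))
        dec = decompose_pair(obs, ref, layout)
        assert len(dec.events) == 1
        ev = dec.events[0]
        assert (ev.position, ev.length) == (3, -1)

    def test_scores_match_linear_gap_dp_oracle(self):
        rng = random.Random(11)
        for _ in range(120):
            a = "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 20)))
            b = "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 20)))
            aln = align_global(a, b, match=2, mismatch=-3, gap_open=-2, gap_extend=-2)
            assert aln.score == pytest.approx(
                nw_linear_score(b, a, 2, -3, -2), abs=1e-9
            ), (a, b)

    def test_ambiguous_n_matches_anything(self):
        aln = align_global("ACGT", "ACNT")
        assert aln.score == 6  # three matches + one zero-score N column
        layout = LocusLayout(fwd_primer=(0, 0), repeat=(0, 0), rev_primer=(4, 4))
        dec = decompose(aln, layout)
        assert dec.substitutions == 0

    def test_empty_sequence_rejected(self):
        with pytest.raises(DecomposeError):
            align_global("", "ACGT")


class TestLeftNormalize:
    def test_deletion_shifts_to_leftmost_equivalent(self):
        # deleting either A of "CAAT" is equivalent; report the leftmost
        assert _left_normalize([(2, -1, "")], "CAAT") == [(1, -1, "")]

    def test_insertion_shifts_with_content_rotation(self):
        # inserting G after "AG" == inserting G before position 1
        assert _left_normalize([(2, 1, "G")], "AGT") == [(1, 1, "G")]

    def test_decomposition_idempotent(self, tmp_path):
        panel, refs, truth = sb.simulate_panel(
            seed=21, planted={"L2": [("flank5", 3, -1), ("flank5", 8, -1)]}
        )
        ref, layout = _sim_layout(panel, refs, "L2")
        obs = truth.strains["S1"]["L2"][0].sequence
        aln = align_global(obs, ref)
        d1 = decompose(aln, layout)
        d2 = decompose(aln, layout)
        assert d1.events == d2.events


class TestDecompose:
    def test_identical_sequences_give_zero_deltas(self):
        panel, refs, truth = sb.simulate_panel(seed=22)
        ref, layout = _sim_layout(panel, refs, "L1")
        dec = decompose_pair(ref, ref, layout)
        assert dec.events == [] and dec.delta_total == 0 and dec.substitutions == 0

    def test_three_flank5_deletions_classified(self):
        """The pattern seen at the second marker: three separate -1 bp
        deletions 5' of the repeat, explaining a consistent -3 bp shift."""
        panel, refs, truth = sb.simulate_panel(
            seed=23,
            planted={"L2": [("flank5", 3, -1), ("flank5", 8, -1), ("flank5", 13, -1)]},
        )
        ref, layout = _sim_layout(panel, refs, "L2")
        allele = truth.strains["S1"]["L2"][0]
        dec = decompose_pair(allele.sequence, ref, layout)
        assert dec.delta_flank5 == -3
        mlen = len(truth.loci["L2"].spec.motif)
        expected_repeat = (allele.repeat_copies - truth.loci["L2"].reference_copies) * mlen
        assert dec.delta_repeat == expected_repeat
        assert dec.delta_total == dec.delta_repeat - 3

    def test_insertion_plus_deletion_net_one(self):
        """A +2 bp insertion and separate -1 bp deletion 5' of the repeat
        combine to +1 bp via two events."""
        panel, refs, truth = sb.simulate_panel(
            seed=24, planted={"L3": [("flank5", 4, 2), ("flank5", 11, -1)]}
        )
        ref, layout = _sim_layout(panel, refs, "L3")
        allele = truth.strains["S1"]["L3"][0]
        dec = decompose_pair(allele.sequence, ref, layout)
        assert dec.delta_flank5 == 1
        lengths = sorted(e.length for e in dec.events if e.region == "flank5")
        assert lengths == [-1, 2]

    def test_overlapping_repeat_and_primer_coordinates_rejected(self):
        ann = RepeatAnnotation(motif="AC", start=10, end=20, copies=5.0)
        with pytest.raises(DecomposeError, match="overlap"):
            layout_from_annotation(ann, (0, 15), (30, 50))

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(st.data())
    def test_conservation_on_random_planted_indels(self, data):
        """Region deltas always sum exactly to the observed length change."""
        rng = random.Random(data.draw(st.integers(0, 10**6)))
        flank = lambda n: "".join(rng.choice("ACGT") for _ in range(n))
        ref = flank(30) + "AC" * 10 + flank(30)
        layout = LocusLayout(fwd_primer=(0, 15), repeat=(30, 50), rev_primer=(65, 80))
        obs = list(ref)
        for _ in range(rng.randint(1, 4)):
            pos = rng.randrange(5, len(obs) - 5)
            if rng.random() < 0.5:
                del obs[pos : pos + rng.randint(1, 3)]
            else:
                obs.insert(pos, rng.choice("ACGT"))
        obs = "".join(obs)
        dec = decompose_pair(obs, ref, layout)
        assert dec.delta_total == len(obs) - len(ref)
        assert (
            dec.delta_repeat + dec.delta_flank5 + dec.delta_flank3 + dec.delta_primers
            == dec.delta_total
        )


class TestPrimerSiteReport:
    def test_primer_footprint_deletion_is_length_neutral(self):
        """A base missing inside the forward-primer footprint (as seen 7 bp
        into the first marker's primer) does not change amplified length."""
        panel, refs, truth = sb.simulate_panel(
            seed=25, planted={"L1": [("fwd_primer", 7, -1), ("flank3", 5, -1)]}
        )
        ref, layout = _sim_layout(panel, refs, "L1")
        allele = truth.strains["S1"]["L1"][0]
        records = primer_site_report(allele.sequence, ref, layout)
        dels = [r for r in records if r.kind == "deletion"]
        assert len(dels) == 1
        assert dels[0].consequence == "length-neutral under amplification"

    def test_first_base_substitution_flagged_efficiency_risk(self):
        panel, refs, truth = sb.simulate_panel(seed=26)
        ref, layout = _sim_layout(panel, refs, "L4")
        obs = ("T" if ref[0] != "T" else "A") + ref[1:]
        records = primer_site_report(obs, ref, layout)
        assert len(records) == 1
        rec = records[0]
        assert rec.kind == "substitution" and rec.position_in_primer == 0
        assert rec.consequence == "efficiency risk, length-neutral"

    def test_exact_match_gives_empty_report(self):
        panel, refs, truth = sb.simulate_panel(seed=27)
        ref, layout = _sim_layout(panel, refs, "L5")
        assert primer_site_report(ref, ref, layout) == []


class TestExpectedPlatformLengths:
    def test_primer_indel_restored_by_amplification(self):
        """One -1 bp in the primer footprint plus one -1 bp in the 3' flank:
        amplified platforms see -1, direct sequencing sees -2."""
        panel, refs, truth = sb.simulate_panel(
            seed=28, planted={"L1": [("fwd_primer", 7, -1), ("flank3", 5, -1)]}
        )
        ref, layout = _sim_layout(panel, refs, "L1")
        sim = truth.loci["L1"]
        allele = truth.strains["S1"]["L1"][0]
        # hold repeat length at the reference count to isolate flank effects
        mlen = len(sim.spec.motif)
        obs = (
            allele.sequence[: allele.tract_start]
            + sim.spec.motif * sim.reference_copies
            + allele.sequence[allele.tract_start + allele.tract_length :]
        )
        dec = decompose_pair(obs, ref, layout)
        amplified, sequenced = expected_platform_lengths(dec)
        assert (amplified, sequenced) == (-1, -2)

    def test_no_primer_indels_means_amplified_equals_sequenced(self):
        dec = sb.Decomposition(
            delta_total=4, delta_repeat=4, delta_flank5=0, delta_flank3=0,
            delta_primers=0,
        )
        assert expected_platform_lengths(dec) == (4, 4)

    def test_conservation_enforced_at_construction(self):
        with pytest.raises(DecomposeError):
            sb.Decomposition(
                delta_total=3, delta_repeat=1, delta_flank5=0, delta_flank3=0,
                delta_primers=0,
            )
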