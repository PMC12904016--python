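"""Consequence classification, junction context and splicing prioritization."""

import numpy as np
import pytest
from Bio.Seq import Seq
from hypothesis import given, settings
from hypothesis import strategies as st

from ncsplice.annotate import (
    AnnotatedVariant,
    JunctionContext,
    classify_variant,
    junction_context,
    missense_deleterious,
    prioritize,
    select_for_validation,
)
from ncsplice.reference import CdnaPosition, map_c_to_g, map_g_to_c, reverse_complement


def _snv(t, genome, gpos, alt=None):
    ref = genome.contigs[t.contig][gpos - 1]
    if alt is None:
        alt = next(b for b in "ACGT" if b != ref)
    return AnnotatedVariant(contig=t.contig, pos=gpos, ref=ref, alt=alt, transcript_id=t.transcript_id)


class TestClassify:
    def test_intronic_vs_canonical_boundary(self, toy_genome_transcripts):
        genome, transcripts = toy_genome_transcripts
        t = transcripts[0]
        donor_c = sum(t.exon_lengths()[:1])
        for off, expected in [(1, "canonical_splicing"), (2, "canonical_splicing"), (3, "intronic"), (4, "intronic")]:
            g = map_c_to_g(t, CdnaPosition(donor_c, off))
            assert classify_variant(_snv(t, genome, g), t) == expected

    def test_random_snvs_match_retranslation_oracle(self, toy_genome_transcripts):
        """Exonic SNV classes agree with brute-force whole-CDS re-translation."""
        genome, transcripts = toy_genome_transcripts
        rng = np.random.default_rng(3)
        checked = 0
        for t in transcripts[:4]:
            for _ in range(250):
                base = int(rng.integers(1, len(t.cds) + 1))
                g = map_c_to_g(t, CdnaPosition(base))
                v = _snv(t, genome, g)
                got = classify_variant(v, t)
                # oracle: substitute in the CDS and translate both fully
                alt_t = v.alt if t.strand == "+" else reverse_complement(v.alt)
                alt_cds = t.cds[: base - 1] + alt_t + t.cds[base:]
                ref_p = str(Seq(t.cds).translate())
                alt_p = str(Seq(alt_cds).translate())
                if alt_p == ref_p:
                    expected = "synonymous"
                elif base <= 3:
                    expected = "start_loss"
                elif ref_p[(base - 1) // 3] == "*":
                    expected = "stop_loss"
                elif alt_p[(base - 1) // 3] == "*":
                    expected = "stop_gain"
                else:
                    expected = "missense"
                assert got == expected, (t.transcript_id, base, got, expected)
                checked += 1
        assert checked == 1000

    def test_indel_classes(self, toy_genome_transcripts):
        genome, transcripts = toy_genome_transcripts
        t = transcripts[0]
        g = map_c_to_g(t, CdnaPosition(30))
        ref = genome.contigs[t.contig][g - 1 : g + 3]
        v = AnnotatedVariant(contig=t.contig, pos=g, ref=ref, alt=ref[0])  # 3-nt deletion
        assert classify_variant(v, t) == "nonframeshift"
        v2 = AnnotatedVariant(contig=t.contig, pos=g, ref=ref[:2], alt=ref[0])  # 1-nt deletion
        assert classify_variant(v2, t) == "frameshift"


class TestJunctionContext:
    def test_intronic_donor_plus4_in_consensus(self, toy_genome_transcripts):
        genome, transcripts = toy_genome_transcripts
        t = transcripts[0]
        donor_c = sum(t.exon_lengths()[:1])
        g = map_c_to_g(t, CdnaPosition(donor_c, 4))
        ctx = junction_context(_snv(t, genome, g), t)
        assert (ctx.junction_side, ctx.signed_distance, ctx.region) == ("donor", 4, "intronic")
        assert ctx.in_consensus

    def test_intronic_acceptor_minus13_outside_consensus(self, toy_genome_transcripts):
        genome, transcripts = toy_genome_transcripts
        t = next(t for t in transcripts if min(len(s) for s in t.intron_seqs) > 30)
        acc_c = sum(t.exon_lengths()[:1]) + 1
        g = map_c_to_g(t, CdnaPosition(acc_c, -13))
        ctx = junction_context(_snv(t, genome, g), t)
        assert (ctx.junction_side, ctx.signed_distance, ctx.in_consensus) == ("acceptor", -13, False)

    def test_exonic_base_adjacent_to_donor_is_minus1(self, toy_genome_transcripts):
        genome, transcripts = toy_genome_transcripts
        t = transcripts[0]
        donor_c = sum(t.exon_lengths()[:1])
        g = map_c_to_g(t, CdnaPosition(donor_c))
        ctx = junction_context(_snv(t, genome, g), t)
        assert (ctx.junction_side, ctx.signed_distance, ctx.region) == ("donor", -1, "exonic")
        assert ctx.in_consensus

    def test_exonic_base_after_acceptor_is_positive(self, toy_genome_transcripts):
        genome, transcripts = toy_genome_transcripts
        t = transcripts[0]
        acc_c = sum(t.exon_lengths()[:1]) + 1
        g = map_c_to_g(t, CdnaPosition(acc_c + 1))  # two bases into exon 2
        ctx = junction_context(_snv(t, genome, g), t)
        assert (ctx.junction_side, ctx.signed_distance, ctx.region) == ("acceptor", 2, "exonic")

    def test_consensus_windows(self):
        assert JunctionContext.consensus("donor", -3) and JunctionContext.consensus("donor", 8)
        assert not JunctionContext.consensus("donor", -4) and not JunctionContext.consensus("donor", 9)
        assert JunctionContext.consensus("acceptor", -12) and JunctionContext.consensus("acceptor", 2)
        assert not JunctionContext.consensus("acceptor", -13) and not JunctionContext.consensus("acceptor", 3)


def _v(spliceai=None, spcards=None):
    return AnnotatedVariant(contig="c", pos=1, ref="A", alt="G", spliceai=spliceai, spcards_count=spcards)


class TestPrioritize:
    @pytest.mark.parametrize(
        "spcards,spliceai,prioritized,arms",
        [
            (14, 0.9482, True, {"spcards", "spliceai"}),
            (2, 0.6563, True, {"spliceai"}),
            (15, None, True, {"spcards"}),
            (8, 0.49, False, set()),
            (None, None, False, set()),
            (9, None, True, {"spcards"}),
            (None, 0.5, True, {"spliceai"}),
        ],
    )
    def test_dual_threshold_rule(self, spcards, spliceai, prioritized, arms):
        dec = prioritize(_v(spliceai, spcards))
        assert dec.prioritized is prioritized and set(dec.arms) == arms

    @settings(max_examples=200, deadline=None)
    @given(
        sc=st.integers(0, 18),
        sa=st.floats(0, 1),
        dsc=st.integers(0, 5),
        dsa=st.floats(0, 0.5),
    )
    def test_monotonicity(self, sc, sa, dsc, dsa):
        """Raising either score never un-prioritizes a variant."""
        base = prioritize(_v(sa, sc)).prioritized
        up = prioritize(_v(min(1.0, sa + dsa), min(18, sc + dsc))).prioritized
        assert up or not base


class TestSelection:
    def test_lof_classes_removed(self):
        catalog = []
        for cls, n in [("canonical_splicing", 112), ("stop_gain", 12), ("intronic", 18), ("missense", 35), ("synonymous", 8)]:
            for i in range(n):
                v = _v(0.9, 15)
                v.pos = len(catalog) + 1
                v.consequence_class = cls
                catalog.append(v)
        selected = select_for_validation(catalog)
        assert len(selected) == 61
        assert {v.consequence_class for v in selected} == {"intronic", "missense", "synonymous"}

    def test_empty_and_prior_validated(self):
        assert select_for_validation([]) == []
        v = _v(0.9, 15)
        v.consequence_class = "intronic"
        v.prior_validation = "validated"
        assert select_for_validation([v]) == []
        assert select_for_validation([v], requeue={v.key}) == [v]


class TestMissenseDeleterious:
    def test_three_calls_with_missing_tool(self):
        v = _v()
        v.consequence_class = "missense"
        v.predictor_calls = {"SIFT": "D", "MutationTaster": "D"}
        v.cadd = 25.8
        assert missense_deleterious(v)[0] is True

    def test_two_calls_not_deleterious(self):
        v = _v()
        v.consequence_class = "missense"
        v.predictor_calls = {"SIFT": "T", "PolyPhen2": "B", "MutationTaster": "D"}
        v.cadd = 25.8
        assert missense_deleterious(v)[0] is False

    def test_all_missing_retained(self):
        v = _v()
        v.consequence_class = "missense"
        ok, why = missense_deleterious(v)
        assert ok is True and "missing" in why
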