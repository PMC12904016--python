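"""Splice-event application, HGVS p. naming, disrupted fractions and PVS1."""

import numpy as np
import pytest

from ncsplice.consequence import (
    NcsvClass,
    ProteinConsequence,
    SpliceEvent,
    apply_event,
    disrupted_fraction,
    ncsv_classify,
    parse_hgvs_p,
    protein_consequence,
    pvs1_call,
)
from ncsplice.simulate import (
    SimulationConfig,
    gen_transcriptome,
    oracle_apply,
    oracle_consequence,
    spike_events,
)


class TestApplyEvent:
    def test_codon_aligned_skip_preserves_frame(self, toy_genome_transcripts):
        _, transcripts = toy_genome_transcripts
        t = next(t for t in transcripts if t.exon_lengths()[1] % 3 == 0)
        ln = t.exon_lengths()[1]
        edited = apply_event(t, SpliceEvent("exon_skipping", 2))
        assert len(t.mrna) - len(edited.alt_mrna) == ln
        assert edited.net_cds_indel == -ln and edited.net_cds_indel % 3 == 0

    def test_two_nt_retention_shifts_frame(self, toy_genome_transcripts):
        _, transcripts = toy_genome_transcripts
        t = transcripts[0]
        edited = apply_event(t, SpliceEvent("intron_retention", 1, (1, 2)))
        assert edited.net_cds_indel == 2
        assert len(edited.alt_mrna) == len(t.mrna) + 2

    def test_random_events_match_string_surgery_oracle(self):
        cfg = SimulationConfig(seed=9, n_variants=600, spike_fraction=1.0)
        genome, transcripts = gen_transcriptome(cfg)
        _, truths = spike_events(genome, transcripts, cfg)
        tx = {t.transcript_id: t for t in transcripts}
        n = 0
        for tr in truths:
            t = tx[tr.transcript_id]
            edited = apply_event(t, tr.events)
            oracle_cds, oracle_net = oracle_apply(t, tr.events)
            assert edited.alt_cds == oracle_cds
            assert edited.net_cds_indel == oracle_net
            n += 1
        assert n >= 400

    def test_invalid_events_rejected(self, toy_transcript):
        with pytest.raises(ValueError):
            apply_event(toy_transcript, SpliceEvent("exon_skipping", 99))
        with pytest.raises(ValueError):
            SpliceEvent("partial_exon_deletion", 2)  # missing sub_interval
        with pytest.raises(ValueError):
            # retention sub-interval not anchored to an intron end
            ilen = len(toy_transcript.intron_seqs[0])
            apply_event(toy_transcript, SpliceEvent("intron_retention", 1, (2, ilen - 1)))


class TestProteinConsequence:
    def test_identity_is_none(self, toy_transcript):
        t = toy_transcript
        cons = protein_consequence(t.protein, t.cds, frame_shifted=False)
        assert cons.kind == "none"

    def test_engine_matches_oracle_on_spiked_events(self):
        """kind/positions/fraction equal the independent oracle on every spike."""
        cfg = SimulationConfig(seed=13, n_variants=800, spike_fraction=1.0)
        genome, transcripts = gen_transcriptome(cfg)
        _, truths = spike_events(genome, transcripts, cfg)
        tx = {t.transcript_id: t for t in transcripts}
        n = 0
        for tr in truths:
            t = tx[tr.transcript_id]
            edited = apply_event(t, tr.events)
            cons = protein_consequence(t.protein, edited.alt_cds, frame_shifted=edited.net_cds_indel % 3 != 0)
            assert cons.hgvs_p == tr.expected_hgvs_p
            assert cons.kind == tr.expected_kind
            assert cons.disrupted_count == tr.expected_count
            assert cons.disrupted_fraction == pytest.approx(tr.expected_fraction)
            n += 1
        assert n >= 500

    def test_conservation_for_codon_aligned_skip(self, toy_genome_transcripts):
        """An in-frame skipped exon deletes exactly exon_nt/3 residues."""
        _, transcripts = toy_genome_transcripts
        for t in transcripts:
            for k in range(2, t.n_exons):
                ln = t.exon_lengths()[k - 1]
                if ln % 3:
                    continue
                start_nt = sum(t.exon_lengths()[: k - 1])
                if start_nt % 3:
                    continue
                edited = apply_event(t, SpliceEvent("exon_skipping", k))
                cons = protein_consequence(t.protein, edited.alt_cds, frame_shifted=False)
                if cons.kind == "inframe_deletion":
                    assert cons.disrupted_count == ln // 3

    def test_frameshift_fraction_decreases_in_first_res(self):
        c1 = ProteinConsequence(kind="frameshift", fs_first_res=10)
        c2 = ProteinConsequence(kind="frameshift", fs_first_res=50)
        n1, f1 = disrupted_fraction(c1, 100)
        n2, f2 = disrupted_fraction(c2, 100)
        assert f1 > f2 and n1 == 90 and n2 == 50


class TestDisruptedFraction:
    @pytest.mark.parametrize(
        "cons,length,count,pct",
        [
            (ProteinConsequence(kind="inframe_deletion", start_res=430, end_res=475), 940, 46, 4.89),
            (ProteinConsequence(kind="frameshift", fs_first_res=69), 134, 65, 48.51),
            (ProteinConsequence(kind="inframe_insertion", start_res=211, end_res=212, inserted="LA"), 1512, 2, 0.13),
            (ProteinConsequence(kind="frameshift", fs_first_res=1), 100, 99, 99.00),
            (ProteinConsequence(kind="stop_gain", start_res=394, end_res=394, fs_first_res=394), 587, 193, 32.88),
        ],
    )
    def test_counting_conventions(self, cons, length, count, pct):
        from ncsplice.stats import rate

        n, frac = disrupted_fraction(cons, length)
        assert n == count
        assert rate(n, length) == pct

    def test_out_of_range_positions_rejected(self):
        with pytest.raises(ValueError):
            disrupted_fraction(ProteinConsequence(kind="inframe_deletion", start_res=5, end_res=20), 10)


class TestPvs1:
    def test_lof_above_threshold_is_strong(self):
        c = ProteinConsequence(kind="frameshift", fs_first_res=194, disrupted_fraction=0.8675)
        assert pvs1_call(c).strength == "PVS1_Strong"

    def test_lof_below_threshold_not_met(self):
        c = ProteinConsequence(kind="frameshift", fs_first_res=3744, disrupted_fraction=0.0536)
        assert pvs1_call(c).strength == "not_met"

    def test_inframe_never_qualifies(self):
        c = ProteinConsequence(kind="inframe_deletion", start_res=161, end_res=197, disrupted_fraction=0.1474)
        assert pvs1_call(c).strength == "not_met"

    def test_exactly_ten_percent_not_met(self):
        c = ProteinConsequence(kind="frameshift", fs_first_res=90, disrupted_fraction=0.10)
        assert pvs1_call(c).strength == "not_met"


class TestNcsvClass:
    @pytest.mark.parametrize(
        "region,ev,label",
        [
            ("exonic", "exon_skipping", "A"),
            ("intronic", "exon_skipping", "B"),
            ("exonic", "partial_exon_deletion", "C"),
            ("intronic", "partial_exon_deletion", "D"),
            ("exonic", "intron_retention", "E"),
            ("intronic", "intron_retention", "F"),
        ],
    )
    def test_six_classes(self, region, ev, label):
        sub = (1, 5) if ev == "partial_exon_deletion" else None
        out = ncsv_classify(region, SpliceEvent(ev, 2, sub))
        assert [c.label for c in out] == [label]

    def test_compound_event_yields_two_labels(self):
        evs = [
            SpliceEvent("intron_retention", 1),
            SpliceEvent("partial_exon_deletion", 2, (1, 65)),
        ]
        labels = {c.label for c in ncsv_classify("exonic", evs)}
        assert labels == {"C", "E"}


class TestHgvsRoundTrip:
    @pytest.mark.parametrize(
        "text,kind",
        [
            ("p.V430_K475del", "inframe_deletion"),
            ("p.V430del", "inframe_deletion"),
            ("p.N43_A66delinsT", "inframe_delins"),
            ("p.A211_A212insLA", "inframe_insertion"),
            ("p.G194Rfs*7", "frameshift"),
            ("p.A394*", "stop_gain"),
            ("p.(=)", "none"),
        ],
    )
    def test_parse_kinds(self, text, kind):
        assert parse_hgvs_p(text).kind == kind

    def test_round_trip_on_generated_events(self):
        """Parsing an emitted string reconstructs kind and positions."""
        cfg = SimulationConfig(seed=21, n_variants=300, spike_fraction=1.0)
        genome, transcripts = gen_transcriptome(cfg)
        _, truths = spike_events(genome, transcripts, cfg)
        for tr in truths:
            if tr.expected_kind == "none":
                continue
            parsed = parse_hgvs_p(tr.expected_hgvs_p)
            assert parsed.kind == tr.expected_kind
            if parsed.kind in ("inframe_deletion", "inframe_delins", "inframe_insertion"):
                assert parsed.start_res is not None
            if parsed.kind == "frameshift":
                assert parsed.fs_first_res is not None
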