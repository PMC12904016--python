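"""Generator determinism, score calibration and cohort planting."""

import numpy as np
import pytest

from ncsplice.cohort import is_potential_ncsv, screen_cohort
from ncsplice.simulate import (
    SimulationConfig,
    gen_cohort,
    gen_scores,
    gen_transcriptome,
    reconstruct_printed_event,
    spike_events,
)
from ncsplice.stats import score_correlation


def _full_run(seed, **kw):
    cfg = SimulationConfig(seed=seed, **kw)
    genome, ts = gen_transcriptome(cfg)
    variants, truths = spike_events(genome, ts, cfg)
    gen_scores(variants, truths, cfg)
    return cfg, genome, ts, variants, truths


class TestDeterminism:
    def test_same_seed_identical_outputs(self):
        _, g1, t1, v1, tr1 = _full_run(3, n_variants=300)
        _, g2, t2, v2, tr2 = _full_run(3, n_variants=300)
        assert g1.contigs == g2.contigs
        assert [t.protein for t in t1] == [t.protein for t in t2]
        assert [(v.key, v.spliceai, v.spcards_count) for v in v1] == [
            (v.key, v.spliceai, v.spcards_count) for v in v2
        ]
        assert [tr.expected_hgvs_p for tr in tr1] == [tr.expected_hgvs_p for tr in tr2]

    def test_different_seed_differs(self):
        _, g1, *_ = _full_run(3, n_variants=50)
        _, g2, *_ = _full_run(4, n_variants=50)
        assert g1.contigs != g2.contigs


class TestTranscriptome:
    def test_structural_ranges_respected(self):
        cfg = SimulationConfig(seed=8, n_transcripts=15)
        genome, ts = gen_transcriptome(cfg)
        assert len(ts) == 15
        assert any(t.contig == "chrX" for t in ts)
        lo_e, hi_e = cfg.exon_count_range
        lo_l, hi_l = cfg.exon_length_range
        for t in ts:
            assert lo_e <= t.n_exons <= hi_e
            # the last exon may be padded by up to 2 nt to complete the frame
            assert all(lo_l <= ln <= hi_l + 2 for ln in t.exon_lengths())
            for intron in t.intron_seqs:
                assert cfg.intron_length_range[0] <= len(intron) <= cfg.intron_length_range[1]
            assert t.protein.startswith("M") and "*" not in t.protein

    def test_infeasible_config_rejected(self):
        with pytest.raises(ValueError):
            gen_transcriptome(SimulationConfig(exon_count_range=(2, 1)))


class TestScores:
    def test_target_correlation_recovered(self):
        *_, variants, truths = _full_run(1, n_variants=5000)
        res = score_correlation([v.spcards_count for v in variants], [v.spliceai for v in variants])
        assert abs(res["r"] - 0.83) <= 0.05

    def test_zero_correlation(self):
        *_, variants, truths = _full_run(2, n_variants=5000, score_correlation=0.0, spiked_score_shift=0.0)
        res = score_correlation([v.spcards_count for v in variants], [v.spliceai for v in variants])
        assert abs(res["r"]) < 0.05

    def test_separated_scores_give_perfect_prioritization(self):
        from ncsplice.annotate import prioritize

        *_, variants, truths = _full_run(5, n_variants=1000, separated_scores=True)
        truth = {tr.variant_key: tr.is_splice_altering for tr in truths}
        for v in variants:
            assert prioritize(v).prioritized == truth[v.key]


class TestCohort:
    def test_planted_patterns_recovered_exactly(self):
        cfg, genome, ts, variants, truths = _full_run(1, n_variants=4000)
        patients, cohort_truth = gen_cohort(genome, ts, variants, truths, cfg)
        assert len(patients) == cfg.cohort_size
        all_v = {v.key: v for v in variants}
        for p in patients:
            for v, _ in p.calls:
                all_v.setdefault(v.key, v)
        flags = {k: is_potential_ncsv(v) for k, v in all_v.items()}
        cands = screen_cohort(patients, flags)
        from collections import Counter

        patterns = Counter(c.pattern for c in cands)
        assert patterns == {"homozygous": 7, "compound_het": 9, "hemizygous": 1}
        planted = {
            (ct.planted_pattern, ct.variant_key)
            for ct in cohort_truth
            if ct.planted_pattern in ("homozygous", "compound_het", "hemizygous")
        }
        recovered = {(c.pattern, c.variants[0].key) for c in cands}
        # every planted configuration is found via its NCSV allele
        assert {k for _, k in planted} <= {k for c in cands for k in [v.key for v in c.variants]}
        assert len(cands) == 17

    def test_all_decoy_cohort_yields_nothing(self):
        cfg, genome, ts, variants, truths = _full_run(
            6, n_variants=2000, cohort_size=8, planted_hom=0, planted_comp_het=0, planted_hemi=0
        )
        patients, _ = gen_cohort(genome, ts, variants, truths, cfg)
        all_v = {v.key: v for v in variants}
        for p in patients:
            for v, _ in p.calls:
                all_v.setdefault(v.key, v)
        flags = {k: is_potential_ncsv(v) for k, v in all_v.items()}
        assert screen_cohort(patients, flags) == []

    def test_shuffled_call_order_gives_identical_candidates(self):
        cfg, genome, ts, variants, truths = _full_run(7, n_variants=3000)
        patients, _ = gen_cohort(genome, ts, variants, truths, cfg)
        all_v = {v.key: v for v in variants}
        for p in patients:
            for v, _ in p.calls:
                all_v.setdefault(v.key, v)
        flags = {k: is_potential_ncsv(v) for k, v in all_v.items()}
        before = [(c.patient_id, c.pattern, sorted(v.key for v in c.variants)) for c in screen_cohort(patients, flags)]
        for p in patients:
            p.calls.reverse()
        after = [(c.patient_id, c.pattern, sorted(v.key for v in c.variants)) for c in screen_cohort(patients, flags)]
        assert before == after


class TestReconstruction:
    def test_unsupported_alteration_rejected(self):
        with pytest.raises(ValueError):
            reconstruct_printed_event(100, "Exon 2 skipping", "p.bogus")

    def test_spiked_truths_cover_all_six_classes(self):
        cfg = SimulationConfig(seed=10, n_variants=600, spike_fraction=0.5)
        genome, ts = gen_transcriptome(cfg)
        _, truths = spike_events(genome, ts, cfg)
        seen = {(tr.region, tr.events[0].event_type) for tr in truths if tr.is_splice_altering}
        assert len(seen) == 6
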