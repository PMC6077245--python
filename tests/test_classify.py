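"""Class codes, ORF scanning, coding potential and the filter cascade."""

import re
import statistics

import numpy as np
import pytest

from lactlnc.classify import (
    CascadeParams,
    ClassCode,
    ReferenceAnnotation,
    apply_filter_cascade,
    assign_class_code,
    baseline_coding_score,
    conservation_score,
    kozak_scan,
    longest_orf,
    train_hexamer_table,
)
from lactlnc.genome_io import FeatureTrack, GenomicInterval, TranscriptModel
from lactlnc.synthetic import (
    default_hexamer_table,
    sample_coding_sequence,
    sample_noncoding_sequence,
)

from conftest import brute_force_class_code, brute_force_orf, random_annotation
from conftest import random_transcript


def tx(exons, tid="t", strand="+", chrom="chr1"):
    return TranscriptModel(
        tid, f"g_{tid}",
        tuple(GenomicInterval(chrom, s, e, strand) for s, e in exons),
    )


class TestClassCodes:
    @pytest.fixture
    def ref(self):
        # one 3-exon gene on '+' with two introns
        gene = tx([(1000, 1300), (3000, 3300), (5000, 5400)], tid="REF.t1")
        return ReferenceAnnotation([gene])

    def test_intron_chain_match_is_known_gene(self, ref):
        same = tx([(950, 1300), (3000, 3300), (5000, 5500)], tid="q")
        assert assign_class_code(same, ref).code == "="

    def test_transcript_inside_first_intron_is_intronic(self, ref):
        # the CSN3-intron-1 pattern: a two-exon transcript fully inside intron 1
        q = tx([(1400, 1600), (1900, 2100)], tid="q", strand="-")
        code = assign_class_code(q, ref)
        assert code.code == "i"
        assert code.matched_ref_id == "REF.t1"

    def test_no_overlap_is_intergenic(self, ref):
        q = tx([(8000, 8300), (8700, 9000)], tid="q")
        code = assign_class_code(q, ref)
        assert code.code == "u"
        assert code.matched_ref_id is None

    def test_antisense_exon_overlap(self, ref):
        q = tx([(1200, 1500), (1900, 2100)], tid="q", strand="-")
        assert assign_class_code(q, ref).code == "x"

    def test_same_strand_partial_overlap_is_other(self, ref):
        q = tx([(1200, 1500), (1900, 2100)], tid="q", strand="+")
        assert assign_class_code(q, ref).code == "o"

    def test_unstranded_query_flagged_other(self, ref):
        q = tx([(1200, 1500)], tid="q", strand=".")
        assert assign_class_code(q, ref).code == "o"

    def test_agrees_with_brute_force_on_random_instances(self):
        rng = np.random.default_rng(10)
        refs = random_annotation(rng, 30)
        ann = ReferenceAnnotation(refs)
        for i in range(500):
            q = random_transcript(rng, f"q{i}")
            assert assign_class_code(q, ann).code == brute_force_class_code(
                q, refs
            ), q

    def test_classcode_invariants(self):
        with pytest.raises(ValueError):
            ClassCode("u", matched_ref_id="x")
        with pytest.raises(ValueError):
            ClassCode("=", matched_ref_id=None)


class TestLongestOrf:
    def test_no_atg_gives_zero(self):
        assert longest_orf("CCCTTTGGG").aa_length == 0

    def test_boundary_119_vs_120_aa(self):
        below = "ATG" + "GCA" * 118 + "TAA"
        at = "ATG" + "GCA" * 119 + "TAA"
        assert longest_orf(below).aa_length == 119
        assert longest_orf(at).aa_length == 120

    def test_requires_in_frame_stop_by_default(self):
        open_ended = "ATG" + "GCA" * 50
        assert longest_orf(open_ended).aa_length == 0
        assert longest_orf(open_ended, require_stop=False).aa_length == 51

    @pytest.mark.parametrize("require_stop", [True, False])
    def test_matches_exhaustive_scan_on_random_sequences(self, require_stop):
        rng = np.random.default_rng(11)
        for _ in range(60):
            seq = "".join(rng.choice(list("ACGT"), size=2_000))
            got = longest_orf(seq, require_stop=require_stop)
            aa, frame, start = brute_force_orf(seq, require_stop=require_stop)
            assert got.aa_length == aa
            if aa > 0:
                assert (got.frame, got.start_offset) == (frame, start)


class TestCodingScore:
    def test_sign_separates_training_distributions(self):
        table = default_hexamer_table(seed=0)
        rng = np.random.default_rng(12)
        coding = [sample_coding_sequence(rng, 150) for _ in range(50)]
        noncoding = [sample_noncoding_sequence(rng, 450) for _ in range(50)]
        c_scores = [baseline_coding_score(s, table) for s in coding]
        n_scores = [baseline_coding_score(s, table) for s in noncoding]
        assert np.mean(c_scores) > 0
        assert np.mean(n_scores) < 0

    def test_uniform_table_scores_exactly_zero(self):
        rng = np.random.default_rng(13)
        seqs = [sample_coding_sequence(rng, 60)]
        table = train_hexamer_table(seqs, seqs)  # identical classes
        assert baseline_coding_score(seqs[0], table) == 0.0

    def test_short_sequence_scores_zero(self):
        assert baseline_coding_score("ACG", default_hexamer_table(0)) == 0.0


class TestKozak:
    def test_match_with_upstream_gcc(self):
        hits = kozak_scan("GCCGCCACCATGG")
        assert len(hits) == 1
        assert hits[0].has_upstream_gcc

    def test_purine_position_rejects_t(self):
        assert kozak_scan("GCCGCCTCCATGG") == []

    def test_matches_independent_window_oracle(self):
        rng = np.random.default_rng(14)
        for _ in range(40):
            seq = "".join(rng.choice(list("ACGT"), p=[0.3, 0.25, 0.25, 0.2],
                                     size=500))
            # make matches non-vanishing
            pos = int(rng.integers(0, 480))
            seq = seq[:pos] + "GCCACCATGG" + seq[pos + 10:]
            expected = [
                i
                for i in range(len(seq) - 9)
                if re.fullmatch("GCC[AG]CCATGG", seq[i : i + 10])
            ]
            assert [h.offset for h in kozak_scan(seq)] == expected


class TestConservation:
    def track(self, scores):  # scores: {(chrom, pos0): score}
        return FeatureTrack(
            [
                (GenomicInterval(c, p, p + 1), f"b{i}", {"score": s})
                for i, ((c, p), s) in enumerate(sorted(scores.items()))
            ],
            kind="conservation",
        )

    def test_constant_track(self):
        t = tx([(10, 14)])
        track = self.track({("chr1", p): 0.5 for p in range(10, 14)})
        assert conservation_score(t, track) == 0.5

    def test_median_of_three_scored_bases(self):
        t = tx([(0, 10)])
        track = self.track({("chr1", 1): 0.1, ("chr1", 5): 0.2, ("chr1", 9): 0.9})
        assert conservation_score(t, track) == pytest.approx(0.2)

    def test_unscored_transcript_is_undefined(self):
        t = tx([(100, 200)])
        assert conservation_score(t, self.track({})) is None

    def test_matches_concatenate_then_median_oracle(self):
        rng = np.random.default_rng(15)
        for i in range(20):
            t = random_transcript(rng, f"t{i}", region=3_000)
            scores = {}
            vals = []
            for e in t.exons:
                for p in range(e.start, e.end):
                    if rng.random() < 0.3:
                        v = float(rng.random())
                        scores[("chr1", p)] = v
                        vals.append((p, v))
            got = conservation_score(t, self.track(scores))
            if not vals:
                assert got is None
            else:
                assert got == pytest.approx(
                    statistics.median(v for _, v in sorted(vals))
                )


class TestCascade:
    def make_inputs(self, t, code="u", fpkm=(1.0,), orf_aa=50,
                    scores=None, hits=None):
        return dict(
            transcripts=[t],
            class_codes={t.transcript_id: ClassCode(
                code, None if code == "u" else "REF.t1")},
            fpkm={t.transcript_id: list(fpkm)},
            orf_lengths={t.transcript_id: orf_aa},
            coding_scores={t.transcript_id: scores or {}},
            domain_hits=hits or {},
        )

    def test_short_two_exon_transcript_fails_structure(self):
        t = tx([(0, 75), (200, 275)])  # 150 nt, 2 exons
        (d,) = apply_filter_cascade(**self.make_inputs(t))
        assert (d.verdict, d.first_failed_step) == ("rejected", "structure")

    def test_low_fpkm_fails_expression(self):
        t = tx([(0, 250), (400, 650)])
        (d,) = apply_filter_cascade(**self.make_inputs(t, fpkm=(0.2, 0.1)))
        assert (d.verdict, d.first_failed_step) == ("rejected", "expression")

    def test_long_orf_routes_to_novel_mrna(self):
        t = tx([(0, 500), (700, 1200)])
        (d,) = apply_filter_cascade(**self.make_inputs(t, orf_aa=130))
        assert (d.verdict, d.first_failed_step) == ("novel_mRNA", "orf")

    def test_clean_intergenic_transcript_is_lincRNA(self):
        t = tx([(0, 500), (700, 1200)])
        (d,) = apply_filter_cascade(
            **self.make_inputs(
                t, orf_aa=80, scores={"CPC": -1, "PLEK": -0.2, "CNCI": -0.5}
            )
        )
        assert (d.verdict, d.category, d.first_failed_step) == (
            "lncRNA", "lincRNA", "none",
        )

    @pytest.mark.parametrize(
        "code,category", [("u", "lincRNA"), ("i", "ilncRNA"), ("x", "lncNAT")]
    )
    def test_category_map_total_on_surviving_codes(self, code, category):
        t = tx([(0, 500), (700, 1200)])
        (d,) = apply_filter_cascade(**self.make_inputs(t, code=code))
        assert d.category == category

    def test_any_vs_all_combine_rule(self):
        t = tx([(0, 500), (700, 1200)])
        mixed = {"CPC": 0.5, "PLEK": -1.0, "CNCI": -1.0}
        (d_any,) = apply_filter_cascade(
            **self.make_inputs(t, scores=mixed),
            params=CascadeParams(coding_combine="any"),
        )
        (d_all,) = apply_filter_cascade(
            **self.make_inputs(t, scores=mixed),
            params=CascadeParams(coding_combine="all"),
        )
        assert d_any.verdict == "novel_mRNA"
        assert d_all.verdict == "lncRNA"

    def test_significant_domain_hit_rejects(self):
        t = tx([(0, 500), (700, 1200)])
        (d,) = apply_filter_cascade(
            **self.make_inputs(t, hits={"t": [("PF00001", 1e-8)]})
        )
        assert (d.verdict, d.first_failed_step) == ("rejected", "domain_hit")
        (d2,) = apply_filter_cascade(
            **self.make_inputs(t, hits={"t": [("PF00001", 1e-3)]})
        )
        assert d2.verdict == "lncRNA"  # above the e-value threshold

    def test_match_code_is_known_gene(self):
        t = tx([(0, 500), (700, 1200)])
        (d,) = apply_filter_cascade(**self.make_inputs(t, code="="))
        assert d.verdict == "known_gene"

    def test_missing_fpkm_errors_with_id(self):
        t = tx([(0, 500), (700, 1200)])
        inputs = self.make_inputs(t)
        inputs["fpkm"] = {}
        with pytest.raises(KeyError, match="'t'"):
            apply_filter_cascade(**inputs)

    def test_every_transcript_gets_exactly_one_verdict(self, study):
        from lactlnc.pipeline import run_pipeline

        res = run_pipeline(study)
        assert len(res.decisions) == len(res.merged)
        assert sum(res.verdict_counts().values()) == len(res.merged)

    def test_noise_free_recovery_is_exact(self, study):
        from lactlnc.pipeline import run_pipeline

        res = run_pipeline(study)
        planted = study.truth.ids_with_label("lincRNA", "ilncRNA", "lncNAT")
        assert res.lnc_ids == planted  # precision = recall = 1.0
        by_id = {d.transcript_id: d for d in res.decisions}
        for tid, label in study.truth.labels.items():
            if tid in by_id and label in ("lincRNA", "ilncRNA", "lncNAT"):
                assert by_id[tid].category == label

    def test_relaxing_a_threshold_never_shrinks_the_lnc_set(self, study):
        from lactlnc.pipeline import run_pipeline

        strict = run_pipeline(study).lnc_ids
        relaxed_params = [
            CascadeParams(min_length=100),
            CascadeParams(min_fpkm=0.0),
            CascadeParams(max_orf_aa=200),
            CascadeParams(domain_evalue=1e-30),
        ]
        for params in relaxed_params:
            assert strict <= run_pipeline(study, cascade_params=params).lnc_ids
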