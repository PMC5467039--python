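"""Scoring, calling, ROC/PR oracles, validation rate, end-to-end pipeline."""

import numpy as np
import pytest

from editml import (FEATURE_NAMES, DegenerateDataError, FeatureOrderError,
                    Model, Observation, PileupColumn, call_sites,
                    evaluate_roc_pr, extract_candidates, pileup_at,
                    read_calls_tsv, run_pipeline, score_sites,
                    validation_rate)
from editml.detection import EditingCall


def make_model(weights, intercept=0.0, dim=None, names=None):
    dim = dim if dim is not None else len(weights)
    names = names or tuple(f"f{i}" for i in range(dim))
    return Model(feature_names=names, center=np.zeros(dim), scale=np.ones(dim),
                 weights=np.asarray(weights, dtype=float),
                 intercept=intercept, penalty="l2", C=1.0, positive_weight=2.0)


def roc_auc_pairwise(scores, labels):
    """Brute force over all positive-negative pairs; ties count one half."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0
               for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestScoreSites:
    def test_zero_model_scores_half(self):
        model = make_model([0.0, 0.0])
        assert np.allclose(score_sites(model, np.ones((3, 2))), 0.5)

    def test_large_intercept_saturates(self):
        model = make_model([0.0], intercept=30.0)
        assert score_sites(model, np.zeros((2, 1)))[0] == pytest.approx(1.0)

    def test_matches_direct_arithmetic(self):
        rng = np.random.default_rng(9)
        dim = 5
        model = Model(feature_names=tuple(f"f{i}" for i in range(dim)),
                      center=rng.normal(size=dim),
                      scale=np.abs(rng.normal(size=dim)) + 0.5,
                      weights=rng.normal(size=dim),
                      intercept=float(rng.normal()), penalty="l2", C=1.0,
                      positive_weight=2.0)
        X = rng.normal(size=(20, dim))
        z = ((X - model.center) / model.scale) @ model.weights + model.intercept
        assert np.allclose(score_sites(model, X), 1 / (1 + np.exp(-z)))

    def test_feature_order_mismatch_is_hard_error(self):
        model = make_model([1.0, -1.0], names=("a", "b"))
        with pytest.raises(FeatureOrderError):
            score_sites(model, np.ones((1, 2)), feature_names=("b", "a"))
        with pytest.raises(FeatureOrderError):
            score_sites(model, np.ones((1, 3)))


def scored_candidates(scores):
    cands = []
    for i, _ in enumerate(scores):
        col = PileupColumn("c", i, "A", [
            Observation("G", 30, 60, 0.5, 20, 0, 0.0, "+", 10**9)
            for _ in range(5)] + [
            Observation("A", 30, 60, 0.5, 20, 0, 0.0, "-", 10**9)
            for _ in range(5)])
        cands.extend(extract_candidates([col], 1, 0.01, 1))
    return cands


class TestCallSites:
    def test_threshold_boundaries(self):
        cands = scored_candidates([0.4, 0.6, 0.95])
        for threshold, expected in [(0.9, 1), (0.5, 2), (0.0, 3), (0.96, 0)]:
            calls = call_sites(cands, [0.4, 0.6, 0.95], threshold)
            assert sum(c.passed for c in calls) == expected
            assert len(calls) == 3  # full scored list retained
        assert all(c.pos == c.key[1] + 1 for c in calls)  # 1-based output


class TestEvaluateRocPr:
    def test_perfect_separation(self):
        res = evaluate_roc_pr([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert res.roc_auc == 1.0
        assert res.pr_auc == 1.0

    def test_pairwise_example(self):
        res = evaluate_roc_pr([0.9, 0.3, 0.8, 0.2], [1, 1, 0, 0])
        assert res.roc_auc == pytest.approx(3 / 4)

    def test_all_tied_scores(self):
        res = evaluate_roc_pr([0.5] * 6, [1, 0, 1, 0, 1, 0])
        assert res.roc_auc == pytest.approx(0.5)

    def test_matches_pairwise_oracle_with_ties(self):
        rng = np.random.default_rng(13)
        scores = np.round(rng.random(200), 2)  # rounding forces ties
        labels = (rng.random(200) < 0.4).astype(int)
        res = evaluate_roc_pr(scores, labels)
        assert res.roc_auc == pytest.approx(
            roc_auc_pairwise(scores, labels), abs=1e-12)

    def test_threshold_counts_non_increasing(self):
        rng = np.random.default_rng(14)
        scores = rng.random(500)
        labels = (rng.random(500) < 0.3).astype(int)
        res = evaluate_roc_pr(scores, labels)
        counts = [res.threshold_counts[t] for t in sorted(res.threshold_counts)]
        assert counts == sorted(counts, reverse=True)

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateDataError):
            evaluate_roc_pr([0.1, 0.9], [1, 1])


class TestValidationRate:
    def _columns(self, cov, alt_reads, alt="G"):
        obs = [Observation(alt, 30, 60, 0.5, 20, 0, 0.0, "+", 10**9)
               for _ in range(alt_reads)]
        obs += [Observation("A", 30, 60, 0.5, 20, 0, 0.0, "+", 10**9)
                for _ in range(cov - alt_reads)]
        return PileupColumn("c", 0, "A", obs)

    def _call(self, score=0.9, passed=True):
        return EditingCall("c", 1, "A", "G", 30, 9, 0.3, score, passed)

    def test_low_coverage_excluded_from_denominator(self):
        cols = {("c", 0): self._columns(10, 5)}
        with pytest.raises(DegenerateDataError):
            validation_rate([self._call()], cols, min_coverage=20)

    def test_validated_iff_enough_alt_reads(self):
        ok = validation_rate([self._call()], {("c", 0): self._columns(25, 3)},
                             min_coverage=20, min_var_reads=3)
        assert ok["rate"] == 1.0 and ok["assessable"] == 1
        bad = validation_rate([self._call()], {("c", 0): self._columns(25, 2)},
                              min_coverage=20, min_var_reads=3)
        assert bad["rate"] == 0.0

    def test_error_free_two_platform_truth_rate(self, errorfree_dataset,
                                                tmp_path):
        from editml import PlatformProfile, generate_alignments

        data = errorfree_dataset
        profile = PlatformProfile("perfect2", 0.0, 120, 30.0, 2.0,
                                  low_mapq_frac=0.0, softclip_prob=0.0)
        val_bam = generate_alignments(data["ref"], data["truth"], 40, profile,
                                      99, str(tmp_path / "val.bam"))
        from editml import build_pileup

        cands = extract_candidates(
            build_pileup(data["bam"], data["ref"], only_variant_columns=True))
        truth_map = data["truth"].by_position()
        edit_cands = [c for c in cands
                      if (ev := truth_map.get(c.key)) and ev.kind == "editing"]
        calls = call_sites(edit_cands, [1.0] * len(edit_cands), 0.5)
        cols = pileup_at(val_bam, data["ref"], [c.key for c in calls])
        result = validation_rate(calls, cols, min_coverage=20, min_var_reads=3)
        assert result["rate"] == 1.0


class TestRunPipeline:
    @pytest.fixture(scope="class")
    @staticmethod
    def trained_model():
        # a hand-built model keyed on the A-to-I flag is enough for plumbing
        weights = np.zeros(28)
        weights[list(FEATURE_NAMES).index("is_a_to_i")] = 6.0
        return make_model(weights, intercept=-3.0, names=FEATURE_NAMES)

    def test_end_to_end_counts_and_determinism(self, small_dataset,
                                               trained_model, tmp_path):
        kwargs = dict(
            alignments=small_dataset["bam"], ref=small_dataset["ref_fa"],
            alu_bed=small_dataset["alu"], repeats_bed=small_dataset["repeats"],
            model=trained_model, threshold=0.5,
        )
        calls1, report = run_pipeline(**kwargs,
                                      out_tsv=str(tmp_path / "c1.tsv"))
        calls2, _ = run_pipeline(**kwargs, out_tsv=str(tmp_path / "c2.tsv"))
        assert open(tmp_path / "c1.tsv").read() == \
            open(tmp_path / "c2.tsv").read()
        assert report["counts"]["candidates"] == len(calls1)
        assert report["counts"]["passing"] == sum(c.passed for c in calls1)
        again = read_calls_tsv(str(tmp_path / "c1.tsv"))
        assert [(c.contig, c.pos, c.score) for c in again] == \
            [(c.contig, c.pos, round(c.score, 6)) for c in calls1]

    def test_threshold_sweep_counts_non_increasing(self, small_dataset,
                                                   trained_model):
        calls, _ = run_pipeline(
            alignments=small_dataset["bam"], ref=small_dataset["ref"],
            alu_bed=small_dataset["alu"], repeats_bed=small_dataset["repeats"],
            model=trained_model, threshold=0.0,
        )
        scores = np.array([c.score for c in calls])
        counts = [int((scores >= t).sum()) for t in (0.5, 0.6, 0.7, 0.8, 0.9)]
        assert counts == sorted(counts, reverse=True)

    def test_genotype_filter_stage(self, small_dataset, trained_model):
        calls, report = run_pipeline(
            alignments=small_dataset["bam"], ref=small_dataset["ref"],
            alu_bed=small_dataset["alu"], repeats_bed=small_dataset["repeats"],
            model=trained_model, dna_vcf=small_dataset["snps"],
        )
        assert report["counts"]["genotype_filtered"] > 0
        snp_keys = {(e.contig, e.pos0)
                    for e in small_dataset["truth"].snp_events()}
        assert all(c.key not in snp_keys for c in calls)
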