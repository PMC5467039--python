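"""Desk-scale benchmark: the full classifier experiment on synthetic data.

This module re-creates, at laptop scale, the labeled-set construction and
evaluation protocol the classifier is built around:

* simulate a small genome with planted editing sites and SNPs, sequence it
  with an Illumina-like profile (the detection platform) and an Ion-Torrent-
  like profile (the independent validation platform);
* positives = planted editing sites recovered as candidates and re-observed
  on the validation platform (consensus-validated; candidates recovered only
  sub-threshold but still validated are tagged two-method-validated);
* negatives = seven per-criterion hard-filter-fail pools, platform-discordant
  sites, expressed SNPs and unvalidated calls, at the canonical pool sizes
  (7x150 + 300 + 1200 + 375 = 2925);
* subsample positives to 1475 so the full set has 4400 examples at a ~1:2
  positive:negative mix, split 80/20 stratified, train the class-weighted LR
  with five-fold CV grid search, and evaluate ROC/PR areas on the held-out
  20%.

The default :class:`BenchmarkConditions` are the study conditions; they are
documented (with rationale) in the package methods note.
"""

from __future__ import annotations

import os
import tempfile
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .candidates import CandidateSite, extract_candidates
from .detection import (SWEEP_THRESHOLDS, evaluate_roc_pr, run_pipeline,
                        score_sites)
from .errors import CapacityError
from .features import build_interval_index, featurize_candidates
from .pileup import build_pileup, pileup_at
from .synthetic import (ILLUMINA, PROTON, PlatformProfile, ReferenceGenome,
                        TruthTable, generate_alignments, generate_annotations,
                        plant_truth, simulate_reference)
from .training import (HyperParameterGrid, LabeledExample, Model, PoolSizes,
                       assemble_training_set, split_train_test,
                       train_classifier)

__all__ = ["BenchmarkConditions", "LabeledCandidates", "build_labeled_candidates",
           "run_classifier_benchmark", "average_benchmark", "threshold_sweep"]


@dataclass(frozen=True)
class BenchmarkConditions:
    """Synthetic study conditions for the classifier benchmark."""

    genome_length: int = 80_000
    n_contigs: int = 2
    gc: float = 0.41
    n_edit: int = 2400
    n_snp: int = 1500
    coverage: float = 30.0
    alu_fraction: float = 0.9
    level_floor: float = 0.1
    n_positives: int = 1475
    pool_sizes: PoolSizes = field(default_factory=PoolSizes)
    detection_profile: PlatformProfile = ILLUMINA
    validation_profile: PlatformProfile = PROTON
    #: validation gates mirroring the positive/negative construction
    positive_validation_coverage: int = 15
    negative_validation_coverage: int = 20
    validation_var_reads: int = 3
    #: relaxed pre-filter used only to enumerate sub-threshold columns
    relaxed_var_reads: int = 1
    relaxed_level: float = 0.02
    relaxed_coverage: int = 5


@dataclass
class LabeledCandidates:
    """Featurized labeled examples plus the artifacts that produced them."""

    examples: List[LabeledExample]
    X: np.ndarray
    y: np.ndarray
    ref: ReferenceGenome
    truth: TruthTable
    meta: Dict


def _proton_support(col, alt: str) -> Tuple[int, int]:
    if col is None:
        return 0, 0
    return col.coverage, sum(1 for o in col.obs if o.base == alt)


# Seven class-2 artifact criteria standing in for the hard filters behind the
# per-criterion negative pools.  Each takes (candidate) -> failed?
def _var_obs(c: CandidateSite):
    return [o for o in c.column.obs if o.base == c.alt]


_FILTER_CRITERIA = (
    ("one_sided_strand", lambda c: len({o.strand for o in _var_obs(c)}) == 1),
    ("near_read_end", lambda c: np.mean(
        [o.end_dist <= 5 for o in _var_obs(c)]) >= 0.5),
    ("position_clustered", lambda c: float(np.std(
        [o.relpos for o in _var_obs(c)])) < 0.05),
    ("low_base_quality", lambda c: float(np.mean(
        [o.baseq for o in _var_obs(c)])) < 30.0),
    ("low_mapping_quality", lambda c: float(np.mean(
        [o.mapq for o in _var_obs(c)])) < 50.0),
    ("excess_mismatches", lambda c: float(np.mean(
        [o.mismatches for o in _var_obs(c)])) >= 2.0),
    ("soft_clipped", lambda c: float(np.mean(
        [o.softclip_frac for o in _var_obs(c)])) > 0.0),
)


def build_labeled_candidates(
    seed: int,
    cond: Optional[BenchmarkConditions] = None,
    workdir: Optional[str] = None,
) -> LabeledCandidates:
    """Simulate one study and assemble the featurized labeled candidate set."""
    cond = cond or BenchmarkConditions()
    seed = int(seed)
    tmp_ctx = None
    if workdir is None:
        tmp_ctx = tempfile.TemporaryDirectory(prefix="editml_bench_")
        workdir = tmp_ctx.name
    try:
        ref = simulate_reference(cond.genome_length, cond.n_contigs, cond.gc,
                                 seed)
        truth = plant_truth(ref, cond.n_edit, cond.n_snp, cond.level_floor,
                            seed + 1)
        bam_det = generate_alignments(
            ref, truth, cond.coverage, cond.detection_profile, seed + 2,
            os.path.join(workdir, "detect.bam"))
        bam_val = generate_alignments(
            ref, truth, cond.coverage, cond.validation_profile, seed + 3,
            os.path.join(workdir, "validate.bam"))
        tracks = generate_annotations(ref, truth, cond.alu_fraction, seed + 4,
                                      workdir)

        columns = build_pileup(bam_det, ref, only_variant_columns=True)
        relaxed = extract_candidates(columns, cond.relaxed_var_reads,
                                     cond.relaxed_level, cond.relaxed_coverage)
        val_cols = pileup_at(bam_val, ref, [c.key for c in relaxed])
        truth_map = truth.by_position()

        def strict(c: CandidateSite) -> bool:
            return c.var_reads >= 3 and c.level >= 0.1 and c.coverage >= 10

        consensus: List[CandidateSite] = []
        extra: List[CandidateSite] = []
        snp_pool: List[CandidateSite] = []
        nontruth: List[CandidateSite] = []
        for c in relaxed:
            ev = truth_map.get(c.key)
            if ev is None:
                nontruth.append(c)
                continue
            if ev.kind == "editing" and c.alt == ev.alt:
                cov, alt_reads = _proton_support(val_cols.get(c.key), c.alt)
                validated = (cov >= cond.positive_validation_coverage
                             and alt_reads >= cond.validation_var_reads)
                if validated and strict(c):
                    consensus.append(c)
                elif validated:
                    extra.append(c)
            elif ev.kind == "snp" and strict(c) and c.alt == ev.alt:
                snp_pool.append(c)

        # Partition non-truth sub-threshold sites into the negative pools.
        rng = np.random.default_rng([seed, 4242])
        order = rng.permutation(len(nontruth))
        discordant: List[CandidateSite] = []
        unvalidated: List[CandidateSite] = []
        fail_pools: Dict[str, List[CandidateSite]] = {
            name: [] for name, _ in _FILTER_CRITERIA
        }
        n_disc = cond.pool_sizes.aligner_discordant
        n_unval = cond.pool_sizes.unvalidated
        for idx in order:
            c = nontruth[idx]
            cov, alt_reads = _proton_support(val_cols.get(c.key), c.alt)
            if len(discordant) < n_disc and cov >= 10 and alt_reads == 0:
                discordant.append(c)
                continue
            if (len(unvalidated) < n_unval
                    and cov >= cond.negative_validation_coverage
                    and alt_reads < cond.validation_var_reads):
                unvalidated.append(c)
                continue
            failed = [name for name, crit in _FILTER_CRITERIA if crit(c)]
            if failed:
                target = min(failed, key=lambda n: len(fail_pools[n]))
                fail_pools[target].append(c)

        # Subsample positives to the canonical count, consensus first.
        positives_all = consensus + extra
        if len(positives_all) < cond.n_positives:
            raise CapacityError(
                f"only {len(positives_all)} validated planted editing sites; "
                f"{cond.n_positives} positives requested"
            )
        n_extra = min(len(extra), max(0, cond.n_positives - len(consensus)))
        n_cons = cond.n_positives - n_extra
        rng_pos = np.random.default_rng([seed, 515])
        cons_idx = sorted(rng_pos.choice(len(consensus), size=n_cons,
                                         replace=False))
        extra_idx = sorted(rng_pos.choice(len(extra), size=n_extra,
                                          replace=False)) if n_extra else []
        consensus_s = [consensus[i] for i in cons_idx]
        extra_s = [extra[i] for i in extra_idx]

        examples = assemble_training_set(
            consensus_positives=consensus_s,
            extra_validated=extra_s,
            filter_fail_pools=[fail_pools[name] for name, _ in _FILTER_CRITERIA],
            aligner_discordant=discordant,
            snp_sites=snp_pool,
            unvalidated=unvalidated,
            per_pool_n=cond.pool_sizes,
            seed=seed + 5,
        )

        alu = build_interval_index(tracks["alu"])
        repeats = build_interval_index(tracks["repeats"])
        sites = [e.site for e in examples]
        X = featurize_candidates(sites, alu, repeats, ref)
        y = np.array([e.label for e in examples], dtype=int)
        for e, vec in zip(examples, X):
            e.features = vec
        meta = {
            "seed": seed,
            "n_examples": len(examples),
            "n_positive": int(y.sum()),
            "n_negative": int(len(y) - y.sum()),
            "pool_counts": {
                "consensus": len(consensus), "extra_validated": len(extra),
                "snp": len(snp_pool), "discordant": len(discordant),
                "unvalidated": len(unvalidated),
                **{name: len(pool) for name, pool in fail_pools.items()},
            },
            "tracks": tracks,
        }
        return LabeledCandidates(examples, X, y, ref, truth, meta)
    finally:
        if tmp_ctx is not None:
            tmp_ctx.cleanup()


def run_classifier_benchmark(
    seed: int,
    cond: Optional[BenchmarkConditions] = None,
    grid: Optional[HyperParameterGrid] = None,
) -> Dict:
    """One full benchmark replicate: simulate, assemble, train, evaluate.

    Returns held-out ROC/PR areas, set sizes and the trained model.
    """
    data = build_labeled_candidates(seed, cond)
    train, test = split_train_test(data.examples, 0.2, seed)
    model = train_classifier(train, grid, seed)
    X_test = np.vstack([e.features for e in test])
    y_test = np.array([e.label for e in test], dtype=int)
    scores = score_sites(model, X_test)
    result = evaluate_roc_pr(scores, y_test)
    return {
        "seed": int(seed),
        "roc_auc": result.roc_auc,
        "pr_auc": result.pr_auc,
        "n_examples": data.meta["n_examples"],
        "n_positive": data.meta["n_positive"],
        "n_negative": data.meta["n_negative"],
        "n_test": len(test),
        "model": model,
        "meta": data.meta,
    }


def average_benchmark(
    seeds: Sequence[int],
    cond: Optional[BenchmarkConditions] = None,
    grid: Optional[HyperParameterGrid] = None,
) -> Dict:
    """Benchmark replicates over several simulation seeds, with means."""
    runs = [run_classifier_benchmark(s, cond, grid) for s in seeds]
    return {
        "seeds": [int(s) for s in seeds],
        "mean_roc_auc": float(np.mean([r["roc_auc"] for r in runs])),
        "mean_pr_auc": float(np.mean([r["pr_auc"] for r in runs])),
        "n_examples": int(np.mean([r["n_examples"] for r in runs])),
        "runs": runs,
    }


def threshold_sweep(
    model: Model,
    seed: int,
    cond: Optional[BenchmarkConditions] = None,
    thresholds: Sequence[float] = SWEEP_THRESHOLDS,
) -> Dict:
    """Score a fresh simulated run and sweep the detection threshold.

    Reports, per threshold, the passing call count and the precision against
    the planted truth (a call is true iff its position is a planted editing
    site with the called substitution).
    """
    cond = cond or BenchmarkConditions()
    with tempfile.TemporaryDirectory(prefix="editml_sweep_") as workdir:
        ref = simulate_reference(cond.genome_length, cond.n_contigs, cond.gc,
                                 seed)
        truth = plant_truth(ref, cond.n_edit, cond.n_snp, cond.level_floor,
                            seed + 1)
        bam = generate_alignments(ref, truth, cond.coverage,
                                  cond.detection_profile, seed + 2,
                                  os.path.join(workdir, "detect.bam"))
        tracks = generate_annotations(ref, truth, cond.alu_fraction, seed + 4,
                                      workdir)
        calls, _ = run_pipeline(bam, ref, tracks["alu"], tracks["repeats"],
                                model, threshold=min(thresholds))
    truth_map = truth.by_position()

    def is_true(call) -> bool:
        ev = truth_map.get(call.key)
        return bool(ev is not None and ev.kind == "editing"
                    and ev.alt == call.alt)

    scores = np.array([c.score for c in calls])
    truths = np.array([is_true(c) for c in calls])
    counts: List[int] = []
    precisions: List[float] = []
    for t in thresholds:
        mask = scores >= t
        n = int(mask.sum())
        counts.append(n)
        precisions.append(float(truths[mask].mean()) if n else float("nan"))
    return {
        "thresholds": list(thresholds),
        "counts": counts,
        "precisions": precisions,
        "n_candidates": len(calls),
    }
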