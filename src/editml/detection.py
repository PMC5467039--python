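"""Scoring, calling, evaluation and the end-to-end detection pipeline.

The trained model turns each candidate's feature vector into a confidence
score in [0, 1], interpreted as the probability that the candidate is a true
editing site.  Calls pass at an adjustable threshold (default 0.5; 0.9 is the
highly-confident setting).  Evaluation offers ROC/PR curves (ROC area equals
the pairwise-comparison probability with ties counting 1/2; the PR area uses
the step-wise convention where precision is held from the next-ranked point,
i.e. average precision), per-threshold call counts, and a cross-platform
validation rate binned by validation coverage.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.metrics import (average_precision_score, precision_recall_curve,
                             roc_auc_score, roc_curve)

from .candidates import CandidateSite, GenomicVariantSet, extract_candidates, \
    genotype_filter
from .errors import DegenerateDataError, FeatureOrderError
from .features import build_interval_index, featurize_candidates
from .pileup import PileupColumn, build_pileup
from .synthetic import ReferenceGenome
from .training import Model

DEFAULT_THRESHOLD = 0.5
SWEEP_THRESHOLDS = (0.5, 0.6, 0.7, 0.8, 0.9)
#: validation-coverage gate (calls below it are not assessable)
DEFAULT_VALIDATION_COVERAGE = 20
DEFAULT_VALIDATION_VAR_READS = 3

__all__ = ["EditingCall", "EvaluationResult", "score_sites", "call_sites",
           "evaluate_roc_pr", "validation_rate", "run_pipeline",
           "write_calls_tsv", "read_calls_tsv", "SWEEP_THRESHOLDS"]


@dataclass
class EditingCall:
    contig: str
    pos: int          # 1-based for output
    ref: str
    alt: str
    coverage: int
    var_reads: int
    level: float
    score: float
    passed: bool

    @property
    def key(self) -> Tuple[str, int]:
        return (self.contig, self.pos - 1)


def score_sites(model: Model, vectors: np.ndarray,
                feature_names: Optional[Sequence[str]] = None) -> np.ndarray:
    """Score feature vectors with a trained model.

    If ``feature_names`` is given it must match the model's feature list
    exactly (order included); mismatches raise rather than silently reorder.
    """
    if feature_names is not None and tuple(feature_names) != tuple(model.feature_names):
        raise FeatureOrderError(
            "feature order does not match the model's feature-name list"
        )
    X = np.atleast_2d(np.asarray(vectors, dtype=float))
    if X.shape[1] != len(model.feature_names):
        raise FeatureOrderError(
            f"vectors have {X.shape[1]} features; model expects "
            f"{len(model.feature_names)}"
        )
    return model.predict_proba(X)


def call_sites(candidates: Sequence[CandidateSite], scores: Sequence[float],
               threshold: float = DEFAULT_THRESHOLD) -> List[EditingCall]:
    """Attach scores and a pass flag; the full scored list is retained so
    other thresholds can be re-applied without re-scoring."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    if len(candidates) != len(scores):
        raise ValueError("one score per candidate required")
    return [
        EditingCall(
            contig=c.contig, pos=c.pos0 + 1, ref=c.ref, alt=c.alt,
            coverage=c.coverage, var_reads=c.var_reads, level=c.level,
            score=float(s), passed=bool(s >= threshold),
        )
        for c, s in zip(candidates, scores)
    ]


@dataclass
class EvaluationResult:
    roc_points: np.ndarray        # (fpr, tpr) rows
    pr_points: np.ndarray         # (recall, precision) rows
    roc_auc: float
    pr_auc: float
    threshold_counts: Dict[float, int]
    validation_bins: Optional[Dict[str, float]] = None


def evaluate_roc_pr(scores: Sequence[float], labels: Sequence[int],
                    thresholds: Sequence[float] = SWEEP_THRESHOLDS,
                    ) -> EvaluationResult:
    """ROC and PR curves plus areas for scored, labeled sites."""
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if len(np.unique(y)) < 2:
        raise DegenerateDataError("evaluation requires both labels")
    fpr, tpr, _ = roc_curve(y, s)
    prec, rec, _ = precision_recall_curve(y, s)
    counts = {float(t): int(np.sum(s >= t)) for t in thresholds}
    return EvaluationResult(
        roc_points=np.column_stack([fpr, tpr]),
        pr_points=np.column_stack([rec, prec]),
        roc_auc=float(roc_auc_score(y, s)),
        pr_auc=float(average_precision_score(y, s)),
        threshold_counts=counts,
    )


def validation_rate(
    calls: Sequence[EditingCall],
    validation_columns: Dict[Tuple[str, int], PileupColumn],
    min_coverage: int = DEFAULT_VALIDATION_COVERAGE,
    min_var_reads: int = DEFAULT_VALIDATION_VAR_READS,
    coverage_bins: Sequence[int] = (20, 50, 100),
) -> Dict[str, object]:
    """Cross-platform validation rate of passing calls.

    A call is assessable iff the second platform covers it with at least
    ``min_coverage`` retained observations; an assessable call is validated
    iff the same substitution has at least ``min_var_reads`` supporting
    observations there.  Rates are reported overall and per coverage stratum.
    """
    assessable = 0
    validated = 0
    bin_edges = sorted(coverage_bins)
    bin_stats = {edge: [0, 0] for edge in bin_edges}
    for call in calls:
        if not call.passed:
            continue
        col = validation_columns.get(call.key)
        cov = col.coverage if col is not None else 0
        if cov < min_coverage:
            continue
        assessable += 1
        alt_reads = sum(1 for o in col.obs if o.base == call.alt)
        ok = alt_reads >= min_var_reads
        validated += ok
        for edge in bin_edges:
            if cov >= edge:
                stratum = bin_stats[edge]
                stratum[0] += 1
                stratum[1] += ok
    if assessable == 0:
        raise DegenerateDataError("no assessable calls (coverage gate too strict)")
    bins = {
        f">={edge}x": (stat[1] / stat[0] if stat[0] else float("nan"))
        for edge, stat in bin_stats.items()
    }
    return {
        "rate": validated / assessable,
        "assessable": assessable,
        "validated": validated,
        "by_coverage": bins,
    }


def _digest(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def run_pipeline(
    alignments: str,
    ref: "ReferenceGenome | str",
    alu_bed: str,
    repeats_bed: str,
    model: "Model | str",
    threshold: float = DEFAULT_THRESHOLD,
    dna_vcf: Optional[str] = None,
    min_baseq: int = 20,
    min_mapq: int = 20,
    min_var_reads: int = 3,
    min_level: float = 0.1,
    min_coverage: int = 10,
    out_tsv: Optional[str] = None,
) -> Tuple[List[EditingCall], Dict]:
    """End-to-end: pileup -> candidates -> (genotype filter) -> features ->
    scores -> calls.  Returns all scored calls (pass flag at ``threshold``)
    and a run report with input digests and per-stage counts."""
    genome = ReferenceGenome.from_fasta(ref) if isinstance(ref, str) else ref
    mdl = Model.load(model) if isinstance(model, str) else model
    alu = build_interval_index(alu_bed)
    repeats = build_interval_index(repeats_bed)

    columns = build_pileup(alignments, genome, min_baseq, min_mapq,
                           only_variant_columns=True)
    cands = extract_candidates(columns, min_var_reads, min_level, min_coverage)
    n_candidates = len(cands)
    removed = 0
    if dna_vcf is not None:
        cands, removed = genotype_filter(cands, GenomicVariantSet.from_vcf(dna_vcf))
    X = featurize_candidates(cands, alu, repeats, genome)
    scores = score_sites(mdl, X) if len(cands) else np.empty(0)
    calls = call_sites(cands, scores, threshold)

    report = {
        "inputs": {
            "alignments": {"path": alignments, "sha256_16": _digest(alignments)},
            "alu_bed": {"path": alu_bed, "sha256_16": _digest(alu_bed)},
            "repeats_bed": {"path": repeats_bed, "sha256_16": _digest(repeats_bed)},
            "dna_vcf": ({"path": dna_vcf, "sha256_16": _digest(dna_vcf)}
                        if dna_vcf else None),
        },
        "thresholds": {
            "min_baseq": min_baseq, "min_mapq": min_mapq,
            "min_var_reads": min_var_reads, "min_level": min_level,
            "min_coverage": min_coverage, "score_threshold": threshold,
        },
        "counts": {
            "candidates": n_candidates,
            "genotype_filtered": removed,
            "scored": len(calls),
            "passing": sum(c.passed for c in calls),
        },
    }
    if out_tsv is not None:
        write_calls_tsv(out_tsv, calls)
        report["calls_tsv"] = out_tsv
    return calls, report


_CALL_COLUMNS = ("contig", "pos", "ref", "alt", "coverage", "var_reads",
                 "level", "score", "pass")


def write_calls_tsv(path: str, calls: Sequence[EditingCall]) -> str:
    with open(path, "w") as fh:
        fh.write("\t".join(_CALL_COLUMNS) + "\n")
        for c in calls:
            fh.write(
                f"{c.contig}\t{c.pos}\t{c.ref}\t{c.alt}\t{c.coverage}\t"
                f"{c.var_reads}\t{c.level:.6f}\t{c.score:.6f}\t"
                f"{int(c.passed)}\n"
            )
    return path


def read_calls_tsv(path: str) -> List[EditingCall]:
    calls: List[EditingCall] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != _CALL_COLUMNS:
            from .errors import InputFormatError

            raise InputFormatError(f"{path}: unexpected calls header {header!r}")
        for line in fh:
            contig, pos, ref, alt, cov, vr, level, score, passed = \
                line.rstrip("\n").split("\t")
            calls.append(EditingCall(contig, int(pos), ref, alt, int(cov),
                                     int(vr), float(level), float(score),
                                     bool(int(passed))))
    return calls
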