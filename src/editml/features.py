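"""The 28-feature vector computed for every candidate editing site.

Three feature classes:

* class 1 — basic read support (3): variant reads, coverage, editing level;
* class 2 — sequencing/alignment artifact statistics (13): mapping and base
  qualities, read-position statistics, strand bias (two-sided Fisher exact),
  simple-repeat membership, homopolymer run length, mismatch load, soft-clip
  load, proximity to a splice gap;
* class 3 — editing-biology priors (12): substitution-type flags (A>G, T>C,
  A-to-I = either), Alu membership, and one-hot encodings of the 5' and 3'
  reference neighbors.

Both A>G and T>C are treated symmetrically as putative A-to-I (no
transcript-strand inference).  Features are passed raw to the classifier;
standardization is learned at training time and stored with the model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from intervaltree import IntervalTree
from scipy import stats as sps

from .candidates import CandidateSite
from .errors import DegenerateDataError, InputFormatError
from .pileup import PileupColumn
from .synthetic import BASES, ReferenceGenome

logger = logging.getLogger(__name__)

#: canonical feature order; serialized with every trained model
FEATURE_NAMES: Tuple[str, ...] = (
    # class 1: basic read support
    "var_reads",
    "coverage",
    "editing_level",
    # class 2: artifact statistics
    "mapq_var_mean",
    "mapq_all_mean",
    "baseq_var_mean",
    "relpos_var_mean",
    "relpos_var_sd",
    "near_end_frac",
    "strand_bias_p",
    "var_plus_frac",
    "simple_repeat",
    "homopolymer_len",
    "mismatch_var_mean",
    "softclip_var_mean",
    "near_splice",
    # class 3: editing-biology priors
    "is_ag",
    "is_tc",
    "is_a_to_i",
    "alu",
    "up_A", "up_C", "up_G", "up_T",
    "down_A", "down_C", "down_G", "down_T",
)

N_FEATURES = len(FEATURE_NAMES)
assert N_FEATURES == 28

#: windows for artifact flags (bases)
NEAR_END_WINDOW = 5
NEAR_SPLICE_WINDOW = 4

__all__ = ["FEATURE_NAMES", "N_FEATURES", "IntervalIndex", "build_interval_index",
           "strand_bias_p", "read_position_stats", "homopolymer_length",
           "sequence_context", "featurize", "featurize_candidates",
           "write_feature_table"]


# ---------------------------------------------------------------------------
# Interval index (annotation membership)
# ---------------------------------------------------------------------------

@dataclass
class IntervalIndex:
    """Per-contig interval set with sublinear point-membership queries."""

    trees: Dict[str, IntervalTree] = field(default_factory=dict)

    def add(self, contig: str, start: int, end: int) -> None:
        if end <= start:
            return
        self.trees.setdefault(contig, IntervalTree()).addi(start, end)

    def contains(self, contig: str, pos0: int) -> bool:
        tree = self.trees.get(contig)
        return bool(tree is not None and tree.overlaps_point(pos0))

    def __len__(self) -> int:
        return sum(len(t) for t in self.trees.values())


def build_interval_index(bed_path: str) -> IntervalIndex:
    """Load a 0-based half-open BED file into an :class:`IntervalIndex`."""
    index = IntervalIndex()
    with open(bed_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise InputFormatError(f"{bed_path}:{lineno}: expected >= 3 columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise InputFormatError(
                    f"{bed_path}:{lineno}: non-integer coordinates"
                ) from exc
            if end < start:
                raise InputFormatError(f"{bed_path}:{lineno}: end < start")
            index.add(parts[0], start, end)
    return index


# ---------------------------------------------------------------------------
# Elementary feature statistics
# ---------------------------------------------------------------------------

def strand_bias_p(ref_plus: int, ref_minus: int, alt_plus: int, alt_minus: int) -> float:
    """Two-sided Fisher exact p-value for the ref/alt x strand 2x2 table.

    An all-zero table is defined as 1.0 (no evidence of bias).
    """
    if min(ref_plus, ref_minus, alt_plus, alt_minus) < 0:
        raise ValueError("counts must be non-negative")
    if ref_plus + ref_minus + alt_plus + alt_minus == 0:
        return 1.0
    _, p = sps.fisher_exact([[ref_plus, ref_minus], [alt_plus, alt_minus]],
                            alternative="two-sided")
    return min(float(p), 1.0)


def read_position_stats(
    relative_positions: Sequence[float],
    end_distances: Sequence[int],
    near_end_window: int = NEAR_END_WINDOW,
) -> Tuple[float, float, float]:
    """(mean, population SD, fraction within ``near_end_window`` of a read end)."""
    if not relative_positions or len(relative_positions) != len(end_distances):
        raise DegenerateDataError("non-empty, equal-length lists required")
    arr = np.asarray(relative_positions, dtype=float)
    near = sum(1 for d in end_distances if d <= near_end_window)
    return float(arr.mean()), float(arr.std()), near / len(end_distances)


def homopolymer_length(ref: ReferenceGenome, contig: str, pos0: int) -> int:
    """Length of the maximal single-nucleotide run containing ``pos0``."""
    seq = ref.sequences[contig]
    if not 0 <= pos0 < len(seq):
        raise IndexError(f"{contig}:{pos0} out of range")
    base = seq[pos0]
    left = pos0
    while left > 0 and seq[left - 1] == base:
        left -= 1
    right = pos0
    while right + 1 < len(seq) and seq[right + 1] == base:
        right += 1
    return right - left + 1


def sequence_context(ref: ReferenceGenome, contig: str, pos0: int) -> np.ndarray:
    """One-hot encodings of the 5' and 3' reference neighbors (8 values).

    Neighbors are read in reference orientation.  At a contig edge the
    missing neighbor's group is all-zero (logged once per call site).
    """
    seq = ref.sequences[contig]
    if not 0 <= pos0 < len(seq):
        raise IndexError(f"{contig}:{pos0} out of range")
    out = np.zeros(8)
    if pos0 > 0:
        out[BASES.index(seq[pos0 - 1])] = 1.0
    else:
        logger.warning("no 5' context at contig edge %s:%d", contig, pos0)
    if pos0 + 1 < len(seq):
        out[4 + BASES.index(seq[pos0 + 1])] = 1.0
    else:
        logger.warning("no 3' context at contig edge %s:%d", contig, pos0)
    return out


# ---------------------------------------------------------------------------
# The full vector
# ---------------------------------------------------------------------------

def featurize(
    site: CandidateSite,
    column: PileupColumn,
    alu: IntervalIndex,
    repeats: IntervalIndex,
    ref: ReferenceGenome,
    near_end_window: int = NEAR_END_WINDOW,
    near_splice_window: int = NEAR_SPLICE_WINDOW,
) -> np.ndarray:
    """Compute the fixed-order 28-feature vector for one candidate site."""
    if (site.contig, site.pos0) != (column.contig, column.pos0):
        raise ValueError("column does not correspond to the candidate site")
    obs = column.obs
    var_obs = [o for o in obs if o.base == site.alt]
    if not var_obs:
        raise DegenerateDataError(
            f"candidate {site.contig}:{site.pos0} has no variant observations"
        )
    ref_obs = [o for o in obs if o.base == site.ref]

    mean_relpos, sd_relpos, near_end = read_position_stats(
        [o.relpos for o in var_obs], [o.end_dist for o in var_obs],
        near_end_window,
    )
    alt_plus = sum(1 for o in var_obs if o.strand == "+")
    p_bias = strand_bias_p(
        sum(1 for o in ref_obs if o.strand == "+"),
        sum(1 for o in ref_obs if o.strand == "-"),
        alt_plus,
        len(var_obs) - alt_plus,
    )
    near_splice = float(any(o.splice_dist <= near_splice_window for o in obs))

    is_ag = float(site.ref == "A" and site.alt == "G")
    is_tc = float(site.ref == "T" and site.alt == "C")

    vec = np.empty(N_FEATURES)
    vec[0] = site.var_reads
    vec[1] = site.coverage
    vec[2] = site.level
    vec[3] = float(np.mean([o.mapq for o in var_obs]))
    vec[4] = float(np.mean([o.mapq for o in obs]))
    vec[5] = float(np.mean([o.baseq for o in var_obs]))
    vec[6] = mean_relpos
    vec[7] = sd_relpos
    vec[8] = near_end
    vec[9] = p_bias
    vec[10] = alt_plus / len(var_obs)
    vec[11] = float(repeats.contains(site.contig, site.pos0))
    vec[12] = homopolymer_length(ref, site.contig, site.pos0)
    vec[13] = float(np.mean([o.mismatches for o in var_obs]))
    vec[14] = float(np.mean([o.softclip_frac for o in var_obs]))
    vec[15] = near_splice
    vec[16] = is_ag
    vec[17] = is_tc
    vec[18] = float(is_ag or is_tc)
    vec[19] = float(alu.contains(site.contig, site.pos0))
    vec[20:28] = sequence_context(ref, site.contig, site.pos0)
    return vec


def featurize_candidates(
    sites: Sequence[CandidateSite],
    alu: IntervalIndex,
    repeats: IntervalIndex,
    ref: ReferenceGenome,
) -> np.ndarray:
    """Feature matrix (n_sites x 28) for a batch of candidates."""
    if not sites:
        return np.empty((0, N_FEATURES))
    return np.vstack([featurize(s, s.column, alu, repeats, ref) for s in sites])


def write_feature_table(
    path: str, sites: Sequence[CandidateSite], X: np.ndarray,
    labels: Optional[Sequence[int]] = None,
    provenance: Optional[Sequence[str]] = None,
) -> str:
    """TSV of site identity + the 28 named features (+ optional label columns)."""
    import pandas as pd

    frame = pd.DataFrame(X, columns=list(FEATURE_NAMES))
    frame.insert(0, "contig", [s.contig for s in sites])
    frame.insert(1, "pos0", [s.pos0 for s in sites])
    frame.insert(2, "ref", [s.ref for s in sites])
    frame.insert(3, "alt", [s.alt for s in sites])
    if labels is not None:
        frame["label"] = list(labels)
    if provenance is not None:
        frame["provenance"] = list(provenance)
    frame.to_csv(path, sep="\t", index=False)
    return path
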