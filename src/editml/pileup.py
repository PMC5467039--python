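"""Streaming per-site pileup evidence from sorted alignments.

Built on the samtools pileup engine exposed by pysam.  Policies:

* observations below ``min_baseq`` / ``min_mapq`` are excluded;
* duplicate, secondary, supplementary and QC-fail records are excluded
  (samtools stepper defaults);
* overlapping mate pairs are counted once — samtools' overlap correction
  zeroes the quality of the lower-quality mate base, which the base-quality
  filter then removes (requires ``min_baseq`` >= 1, the default is 20);
* deletions and reference skips contribute no base observation;
* coordinates are 0-based half-open throughout; 1-based only at the VCF/TSV
  boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Iterator, List, NamedTuple, Optional, Tuple

import pysam

from .errors import ConsistencyError, DegenerateDataError, InputFormatError
from .synthetic import ReferenceGenome

#: sentinel "no splice junction anywhere near" distance
NO_SPLICE = 10**9

__all__ = ["Observation", "PileupColumn", "SiteCounts", "build_pileup",
           "pileup_at", "summarize", "NO_SPLICE"]


class Observation(NamedTuple):
    """One retained read base at a column."""

    base: str
    baseq: int
    mapq: int
    relpos: float        # position in the original read orientation, in [0, 1]
    end_dist: int        # distance to the nearer read end, bases
    mismatches: int      # NM of the carrying read
    softclip_frac: float  # soft-clipped share of the carrying read
    strand: str          # "+" or "-"
    splice_dist: int     # ref-distance to the nearest N junction of the read


@dataclass
class PileupColumn:
    contig: str
    pos0: int
    ref_base: str
    obs: List[Observation]

    @property
    def coverage(self) -> int:
        return len(self.obs)

    def base_counts(self) -> Dict[str, int]:
        counts: Dict[str, int] = {}
        for o in self.obs:
            counts[o.base] = counts.get(o.base, 0) + 1
        return counts

    def strand_base_counts(self) -> Dict[Tuple[str, str], int]:
        """Counts keyed by (base, strand)."""
        counts: Dict[Tuple[str, str], int] = {}
        for o in self.obs:
            key = (o.base, o.strand)
            counts[key] = counts.get(key, 0) + 1
        return counts


@dataclass
class SiteCounts:
    coverage: int
    allele_counts: Dict[str, int]
    variant_allele: Optional[str]
    variant_reads: int
    level: float


def summarize(column: PileupColumn) -> SiteCounts:
    """Collapse a column into coverage / variant allele / editing level.

    The variant allele is the most frequent non-reference base; ties are
    broken by the fixed base order A < C < G < T.
    """
    if not column.obs:
        raise DegenerateDataError(
            f"empty pileup column at {column.contig}:{column.pos0}"
        )
    counts = column.base_counts()
    nonref = {b: n for b, n in counts.items() if b != column.ref_base and n > 0}
    if not nonref:
        return SiteCounts(column.coverage, counts, None, 0, 0.0)
    # highest count wins; full ties resolved to the lexicographically first base
    top_count = max(nonref.values())
    allele = min(b for b, n in nonref.items() if n == top_count)
    return SiteCounts(
        coverage=column.coverage,
        allele_counts=counts,
        variant_allele=allele,
        variant_reads=top_count,
        level=top_count / column.coverage,
    )


def _read_stats(aln: pysam.AlignedSegment) -> Tuple[int, float, int, Tuple[int, ...]]:
    """(query length, soft-clip fraction, NM, splice-junction ref positions)."""
    qlen = aln.query_length or aln.infer_query_length() or 0
    softclip = 0
    juncs: List[int] = []
    ref_cursor = aln.reference_start
    for op, length in aln.cigartuples or ():
        if op == 4:  # S
            softclip += length
        elif op in (0, 7, 8):  # M/=/X
            ref_cursor += length
        elif op == 3:  # N
            juncs.append(ref_cursor)          # last aligned base boundary
            ref_cursor += length
            juncs.append(ref_cursor)          # first aligned base after gap
        elif op == 2:  # D
            ref_cursor += length
    try:
        nm = int(aln.get_tag("NM"))
    except KeyError:
        nm = 0
    frac = softclip / qlen if qlen else 0.0
    return qlen, frac, nm, tuple(juncs)


def _check_sorted(bam: pysam.AlignmentFile, path: str) -> None:
    so = (bam.header.get("HD") or {}).get("SO")
    if so != "coordinate":
        raise InputFormatError(
            f"{path}: alignments must be coordinate-sorted (HD:SO={so!r})"
        )


def build_pileup(
    alignments: str,
    ref: ReferenceGenome,
    min_baseq: int = 20,
    min_mapq: int = 20,
    region: Optional[Tuple[str, int, int]] = None,
    only_variant_columns: bool = False,
    _wanted: Optional[set] = None,
) -> Iterator[PileupColumn]:
    """Stream pileup columns from a sorted alignment file.

    ``region`` is a 0-based half-open (contig, start, end) triple and
    requires an index.  With ``only_variant_columns`` set, columns whose
    retained bases all match the reference are skipped cheaply before the
    per-observation records are materialized (the skip cannot change which
    candidate sites exist, since candidates require a non-reference base).
    """
    with pysam.AlignmentFile(alignments) as bam:
        _check_sorted(bam, alignments)
        for contig in bam.references:
            if contig not in ref.sequences:
                raise ConsistencyError(
                    f"alignment contig {contig!r} absent from the reference"
                )
        kwargs = dict(
            stepper="samtools",
            max_depth=100_000,
            min_base_quality=min_baseq,
            min_mapping_quality=min_mapq,
            compute_baq=False,
        )
        if region is not None:
            if not bam.has_index():
                raise InputFormatError(
                    f"{alignments}: an index is required for region queries"
                )
            contig, start, end = region
            if contig not in ref.sequences:
                raise ConsistencyError(f"region contig {contig!r} not in reference")
            pile = bam.pileup(contig, start, end, truncate=True, **kwargs)
        else:
            pile = bam.pileup(**kwargs)

        stats_cache: Dict[Tuple[str, int, int], Tuple[int, float, int, Tuple[int, ...]]] = {}
        for col in pile:
            pos0 = col.reference_pos
            contig = col.reference_name
            if _wanted is not None and (contig, pos0) not in _wanted:
                continue
            ref_base = ref.sequences[contig][pos0]
            if only_variant_columns:
                joined = "".join(col.get_query_sequences()).upper()
                if not joined or joined.count(ref_base) == len(joined):
                    continue
            obs: List[Observation] = []
            for pr in col.pileups:
                if pr.is_del or pr.is_refskip or pr.query_position is None:
                    continue
                aln = pr.alignment
                key = (aln.query_name, aln.flag, aln.reference_start)
                stats = stats_cache.get(key)
                if stats is None:
                    stats = _read_stats(aln)
                    if len(stats_cache) > 4096:
                        stats_cache.clear()
                    stats_cache[key] = stats
                qlen, sc_frac, nm, juncs = stats
                qpos = pr.query_position
                denom = qlen - 1 if qlen > 1 else 1
                rel = qpos / denom
                if aln.is_reverse:
                    rel = 1.0 - rel
                splice_dist = NO_SPLICE
                if juncs:
                    splice_dist = min(abs(j - pos0) for j in juncs)
                obs.append(Observation(
                    base=aln.query_sequence[qpos].upper(),
                    baseq=aln.query_qualities[qpos],
                    mapq=aln.mapping_quality,
                    relpos=rel,
                    end_dist=min(qpos, qlen - 1 - qpos),
                    mismatches=nm,
                    softclip_frac=sc_frac,
                    strand="-" if aln.is_reverse else "+",
                    splice_dist=splice_dist,
                ))
            if obs:
                yield PileupColumn(contig, pos0, ref_base, obs)


def pileup_at(
    alignments: str,
    ref: ReferenceGenome,
    positions: Iterable[Tuple[str, int]],
    min_baseq: int = 20,
    min_mapq: int = 20,
) -> Dict[Tuple[str, int], PileupColumn]:
    """Pileup columns at specific (contig, pos0) sites, keyed by site.

    Sweeps each contig's covering span once and keeps only the requested
    columns; absent keys mean zero retained coverage there.
    """
    wanted = set(positions)
    by_contig: Dict[str, List[int]] = {}
    for contig, pos in wanted:
        by_contig.setdefault(contig, []).append(pos)
    out: Dict[Tuple[str, int], PileupColumn] = {}
    for contig, pos_list in by_contig.items():
        lo, hi = min(pos_list), max(pos_list) + 1
        for col in build_pileup(alignments, ref, min_baseq, min_mapq,
                                region=(contig, lo, hi), _wanted=wanted):
            out[(col.contig, col.pos0)] = col
    return out
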