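"""Candidate editing sites: minimal-evidence filters and genotype filtering.

A candidate is a pileup column with a non-reference allele meeting three
thresholds: variant-supporting reads, editing level (variant fraction) and
total coverage.  The substitution type is *not* filtered here — it is a
classifier feature, and non-A-to-I candidates are exactly what the negative
training classes are made of.  Multi-allelic columns yield one candidate (the
top non-reference allele).

If matched genomic DNA variants are available (VCF), candidates at those
positions can be removed regardless of allele: a DNA variant at the site
undermines the RNA-editing interpretation either way.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, List, Set, Tuple

import pysam

from .errors import InputFormatError
from .pileup import PileupColumn, summarize

__all__ = ["CandidateSite", "GenomicVariantSet", "extract_candidates",
           "genotype_filter"]


@dataclass
class CandidateSite:
    contig: str
    pos0: int
    ref: str
    alt: str
    coverage: int
    var_reads: int
    level: float
    column: PileupColumn = field(repr=False)

    @property
    def key(self) -> Tuple[str, int]:
        return (self.contig, self.pos0)

    @property
    def substitution(self) -> str:
        return f"{self.ref}>{self.alt}"


def extract_candidates(
    columns: Iterable[PileupColumn],
    min_var_reads: int = 3,
    min_level: float = 0.1,
    min_coverage: int = 10,
) -> List[CandidateSite]:
    """Filter pileup columns into candidate sites.

    Defaults: >= 3 variant reads, level >= 0.1 (the training floor of the
    classifier) and coverage >= 10.  Raising any threshold yields a subset of
    the previous candidate list.
    """
    if min_var_reads < 0 or min_coverage < 0:
        raise ValueError("thresholds must be non-negative")
    if not 0.0 <= min_level <= 1.0:
        raise ValueError("min_level must lie in [0, 1]")
    out: List[CandidateSite] = []
    for column in columns:
        if not column.obs:
            continue
        counts = summarize(column)
        if counts.variant_allele is None:
            continue
        if (counts.variant_reads >= min_var_reads
                and counts.level >= min_level
                and counts.coverage >= min_coverage):
            out.append(CandidateSite(
                contig=column.contig,
                pos0=column.pos0,
                ref=column.ref_base,
                alt=counts.variant_allele,
                coverage=counts.coverage,
                var_reads=counts.variant_reads,
                level=counts.level,
                column=column,
            ))
    return out


@dataclass
class GenomicVariantSet:
    """Positions of known genomic variants (from a matched-DNA VCF)."""

    positions: Set[Tuple[str, int]] = field(default_factory=set)

    @classmethod
    def from_vcf(cls, path: str) -> "GenomicVariantSet":
        try:
            vcf = pysam.VariantFile(path)
        except (ValueError, OSError) as exc:
            raise InputFormatError(f"{path}: cannot parse VCF ({exc})") from exc
        positions: Set[Tuple[str, int]] = set()
        with vcf:
            for rec in vcf.fetch() if vcf.index is not None else vcf:
                positions.add((rec.contig, rec.pos - 1))  # VCF is 1-based
        return cls(positions)

    def __contains__(self, key: Tuple[str, int]) -> bool:
        return key in self.positions

    def __len__(self) -> int:
        return len(self.positions)


def genotype_filter(
    candidates: List[CandidateSite], dna: GenomicVariantSet
) -> Tuple[List[CandidateSite], int]:
    """Drop candidates at known genomic-variant positions.

    Returns the surviving candidates (order preserved) and the removed count.
    """
    kept = [c for c in candidates if c.key not in dna]
    return kept, len(candidates) - len(kept)
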