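"""Synthetic aligned-read generator with planted editing/SNP truth.

This module makes the whole detection pipeline testable without any external
data.  It emulates the study design the detector is built for:

* a small reference genome (FASTA),
* a truth table of planted A-to-I editing events (A>G on the + strand, T>C on
  the - strand, in reference coordinates) with editing levels bounded below by
  a configurable floor (default 0.1, the lowest level the classifier is ever
  asked to learn), plus heterozygous/homozygous SNPs as the key confounder
  class,
* coordinate-sorted, indexed alignments (BAM) under configurable platform
  error profiles (an Illumina-like and an Ion-Torrent-like preset differing in
  error rate, base-quality distribution and read length), and
* matching annotation files: Alu intervals (BED), simple-repeat intervals
  (BED) and planted SNPs (VCF).

Reads are emitted pre-aligned with known placement; no aligner is invoked.
All randomness is driven by numpy Generators seeded from the user seed, with
the read layout / planted-allele draws and the error-process draws on separate
streams so that two platform profiles simulated from the same seed plant
variants identically while differing in sequencing errors.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pysam

from .errors import CapacityError, ConsistencyError, InputFormatError

BASES = "ACGT"
_BASE_ORDS = np.frombuffer(b"ACGT", dtype=np.uint8)

__all__ = [
    "ReferenceGenome",
    "TruthEvent",
    "TruthTable",
    "PlatformProfile",
    "ILLUMINA",
    "PROTON",
    "PERFECT",
    "simulate_reference",
    "plant_truth",
    "generate_alignments",
    "generate_annotations",
]


# ---------------------------------------------------------------------------
# Reference genome
# ---------------------------------------------------------------------------

@dataclass
class ReferenceGenome:
    """An in-memory reference: contig name -> uppercase A/C/G/T string."""

    sequences: Dict[str, str]

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ValueError("reference must contain at least one contig")
        for name, seq in self.sequences.items():
            if not seq or set(seq) - set(BASES):
                raise ValueError(f"contig {name!r} contains non-ACGT characters")

    @property
    def lengths(self) -> Dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    @property
    def total_length(self) -> int:
        return sum(self.lengths.values())

    def base(self, contig: str, pos0: int) -> str:
        seq = self.sequences[contig]
        if not 0 <= pos0 < len(seq):
            raise IndexError(f"{contig}:{pos0} out of range (length {len(seq)})")
        return seq[pos0]

    def write_fasta(self, path: str, line_width: int = 60) -> str:
        with open(path, "w") as fh:
            for name, seq in self.sequences.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), line_width):
                    fh.write(seq[i : i + line_width] + "\n")
        pysam.faidx(path)
        return path

    @classmethod
    def from_fasta(cls, path: str) -> "ReferenceGenome":
        seqs: Dict[str, str] = {}
        name = None
        chunks: List[str] = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith(">"):
                    if name is not None:
                        seqs[name] = "".join(chunks).upper()
                    name = line[1:].split()[0]
                    chunks = []
                else:
                    chunks.append(line)
        if name is None:
            raise InputFormatError(f"{path}: no FASTA records found")
        seqs[name] = "".join(chunks).upper()
        return cls(seqs)


def simulate_reference(
    total_length: int, n_contigs: int = 1, gc: float = 0.41, seed: int = 0
) -> ReferenceGenome:
    """Simulate an i.i.d. reference genome with the requested GC content.

    Contig lengths sum exactly to ``total_length`` (the remainder of the even
    split goes to the first contig).  Deterministic for a fixed seed.
    """
    if total_length < 1000:
        raise ValueError("total_length must be >= 1000")
    if not 0.0 < gc < 1.0:
        raise ValueError("gc must lie strictly between 0 and 1")
    if n_contigs < 1 or n_contigs > total_length // 500:
        raise ValueError("n_contigs must be >= 1 and leave >= 500 bp per contig")
    rng = np.random.default_rng([int(seed), 101])
    at = (1.0 - gc) / 2.0
    probs = [at, gc / 2.0, gc / 2.0, at]  # A, C, G, T
    base_len = total_length // n_contigs
    lengths = [base_len] * n_contigs
    lengths[0] += total_length - base_len * n_contigs
    seqs: Dict[str, str] = {}
    for i, length in enumerate(lengths):
        draw = rng.choice(_BASE_ORDS, size=length, p=probs)
        seqs[f"chr{i + 1}"] = draw.tobytes().decode("ascii")
    return ReferenceGenome(seqs)


# ---------------------------------------------------------------------------
# Truth table
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TruthEvent:
    contig: str
    pos0: int
    kind: str  # "editing" | "snp"
    strand: str  # "+" | "-"
    ref: str
    alt: str
    level: Optional[float] = None  # editing only
    genotype: Optional[str] = None  # snp only: "het" | "hom"

    @property
    def allele_fraction(self) -> float:
        """Expected fraction of reads carrying the alt base."""
        if self.kind == "editing":
            assert self.level is not None
            return self.level
        return 0.5 if self.genotype == "het" else 1.0


@dataclass
class TruthTable:
    events: List[TruthEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen = set()
        for ev in self.events:
            key = (ev.contig, ev.pos0)
            if key in seen:
                raise ValueError(f"duplicate truth event at {ev.contig}:{ev.pos0}")
            seen.add(key)

    def by_position(self) -> Dict[Tuple[str, int], TruthEvent]:
        return {(ev.contig, ev.pos0): ev for ev in self.events}

    def editing_events(self) -> List[TruthEvent]:
        return [ev for ev in self.events if ev.kind == "editing"]

    def snp_events(self) -> List[TruthEvent]:
        return [ev for ev in self.events if ev.kind == "snp"]

    def write_tsv(self, path: str) -> str:
        with open(path, "w") as fh:
            fh.write("contig\tpos0\tkind\tstrand\tref\talt\tlevel_or_genotype\n")
            for ev in sorted(self.events, key=lambda e: (e.contig, e.pos0)):
                lg = repr(ev.level) if ev.kind == "editing" else str(ev.genotype)
                fh.write(
                    f"{ev.contig}\t{ev.pos0}\t{ev.kind}\t{ev.strand}\t"
                    f"{ev.ref}\t{ev.alt}\t{lg}\n"
                )
        return path

    @classmethod
    def read_tsv(cls, path: str) -> "TruthTable":
        events: List[TruthEvent] = []
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header[:2] != ["contig", "pos0"]:
                raise InputFormatError(f"{path}: unrecognized truth header {header!r}")
            for line in fh:
                contig, pos0, kind, strand, ref, alt, lg = line.rstrip("\n").split("\t")
                if kind == "editing":
                    ev = TruthEvent(contig, int(pos0), kind, strand, ref, alt,
                                    level=float(lg))
                else:
                    ev = TruthEvent(contig, int(pos0), kind, strand, ref, alt,
                                    genotype=lg)
                events.append(ev)
        return cls(events)


def plant_truth(
    ref: ReferenceGenome,
    n_edit: int,
    n_snp: int,
    level_floor: float = 0.1,
    seed: int = 0,
    level_beta: Tuple[float, float] = (1.0, 3.0),
    het_fraction: float = 2.0 / 3.0,
) -> TruthTable:
    """Plant non-overlapping editing and SNP events on a reference.

    Editing events sit on reference A (annotated + strand, A>G) or T
    (annotated - strand, T>C) at interior positions; their levels are drawn as
    ``level_floor + (1 - level_floor) * Beta(*level_beta)``, i.e. bounded
    below by the floor and skewed toward low levels as in real transcriptomes.
    SNPs get a uniform alt base among the three non-reference bases and are
    heterozygous with probability ``het_fraction``.
    """
    if not 0.0 <= level_floor < 1.0:
        raise ValueError("level_floor must lie in [0, 1)")
    rng = np.random.default_rng([int(seed), 211])
    # Interior positions only, so sequence context always exists.
    at_sites: List[Tuple[str, int]] = []
    other_sites: List[Tuple[str, int]] = []
    for contig, seq in ref.sequences.items():
        for pos in range(1, len(seq) - 1):
            (at_sites if seq[pos] in "AT" else other_sites).append((contig, pos))
    if n_edit > len(at_sites):
        raise CapacityError(
            f"reference hosts only {len(at_sites)} interior A/T positions; "
            f"{n_edit} editing events requested"
        )
    edit_idx = rng.choice(len(at_sites), size=n_edit, replace=False) if n_edit else []
    edit_positions = [at_sites[i] for i in sorted(edit_idx)]
    taken = set(edit_positions)
    snp_pool = [p for p in at_sites if p not in taken] + other_sites
    if n_snp > len(snp_pool):
        raise CapacityError(
            f"only {len(snp_pool)} positions left for {n_snp} SNP events"
        )
    snp_idx = rng.choice(len(snp_pool), size=n_snp, replace=False) if n_snp else []
    snp_positions = [snp_pool[i] for i in sorted(snp_idx)]

    events: List[TruthEvent] = []
    for contig, pos in edit_positions:
        base = ref.base(contig, pos)
        level = float(level_floor + (1.0 - level_floor) * rng.beta(*level_beta))
        if base == "A":
            events.append(TruthEvent(contig, pos, "editing", "+", "A", "G", level=level))
        else:
            events.append(TruthEvent(contig, pos, "editing", "-", "T", "C", level=level))
    for contig, pos in snp_positions:
        base = ref.base(contig, pos)
        alt = rng.choice([b for b in BASES if b != base])
        genotype = "het" if rng.random() < het_fraction else "hom"
        events.append(TruthEvent(contig, pos, "snp", "+", base, str(alt),
                                 genotype=genotype))
    events.sort(key=lambda e: (e.contig, e.pos0))
    return TruthTable(events)


# ---------------------------------------------------------------------------
# Platform profiles and read simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlatformProfile:
    """Error model of a sequencing platform.

    ``error_rate`` is the mean per-base substitution rate; erroneous bases get
    their quality shifted down by ``error_qual_shift`` so that errors are
    quality-correlated.  A fraction ``low_mapq_frac`` of reads receives a
    mapping quality drawn uniformly from [20, 50] (ambiguous placements); the
    rest get MAPQ 60.  ``softclip_prob`` soft-clips one read end by 5-15
    bases; ``splice_prob`` plants an intron gap (N CIGAR, off by default).
    """

    name: str
    error_rate: float
    read_length: int
    qual_mean: float
    qual_sd: float
    indel_rate: float = 0.0
    error_qual_shift: int = 10
    low_mapq_frac: float = 0.10
    softclip_prob: float = 0.05
    splice_prob: float = 0.0
    splice_gap: int = 80

    def __post_init__(self) -> None:
        if not 0.0 <= self.error_rate <= 0.1:
            raise ValueError("error_rate must lie in [0, 0.1]")
        if self.read_length < 30:
            raise ValueError("read_length must be >= 30")


ILLUMINA = PlatformProfile("illumina", error_rate=0.003, read_length=100,
                           qual_mean=37.0, qual_sd=4.0)
PROTON = PlatformProfile("proton", error_rate=0.012, read_length=150,
                         qual_mean=28.0, qual_sd=6.0)
#: Error-free profile used for planted-truth recovery checks.
PERFECT = PlatformProfile("perfect", error_rate=0.0, read_length=100,
                          qual_mean=38.0, qual_sd=2.0,
                          low_mapq_frac=0.0, softclip_prob=0.0)


def _profile_salt(name: str) -> int:
    return sum((i + 1) * b for i, b in enumerate(name.encode("ascii"))) % (2**20)


def generate_alignments(
    ref: ReferenceGenome,
    truth: TruthTable,
    coverage: float,
    profile: PlatformProfile,
    seed: int,
    out_bam: str,
) -> str:
    """Simulate single-end aligned reads and write a sorted, indexed BAM.

    At every editing site the alt base is drawn per overlapping read with
    probability equal to the planted level; at SNPs with probability 0.5 (het)
    or 1.0 (hom).  Placement and planted-allele draws use a seed-only RNG
    stream; errors, qualities, MAPQ and clipping use a profile-salted stream,
    so two profiles with the same read length and seed place reads and plant
    variants identically while differing in error positions.
    """
    if coverage < 1:
        raise ValueError("coverage must be >= 1")
    for ev in truth.events:
        if ev.contig not in ref.sequences:
            raise ConsistencyError(f"truth contig {ev.contig!r} absent from reference")
        if not 0 <= ev.pos0 < len(ref.sequences[ev.contig]):
            raise ConsistencyError(f"truth position {ev.contig}:{ev.pos0} out of range")

    rng_layout = np.random.default_rng([int(seed), 11])
    rng_err = np.random.default_rng([int(seed), 977, _profile_salt(profile.name)])

    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": name, "LN": length} for name, length in ref.lengths.items()],
    }
    by_contig: Dict[str, List[TruthEvent]] = {name: [] for name in ref.sequences}
    for ev in truth.events:
        by_contig[ev.contig].append(ev)

    with pysam.AlignmentFile(out_bam, "wb", header=header) as bam:
        bam_header = bam.header
        for tid, (contig, seq) in enumerate(ref.sequences.items()):
            ref_arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
            contig_len = len(seq)
            read_len = min(profile.read_length, contig_len)
            events = sorted(by_contig[contig], key=lambda e: e.pos0)
            ev_pos = np.array([e.pos0 for e in events], dtype=np.int64)
            ev_alt = np.array([ord(e.alt) for e in events], dtype=np.uint8)
            ev_frac = np.array([e.allele_fraction for e in events], dtype=np.float64)

            n_reads = math.ceil(contig_len * coverage / read_len)
            starts = np.sort(rng_layout.integers(0, contig_len - read_len + 1,
                                                 size=n_reads))
            reverse = rng_layout.random(n_reads) < 0.5
            records: List[pysam.AlignedSegment] = []
            for i in range(n_reads):
                s = int(starts[i])
                # splice gap (optional): two aligned blocks around an intron
                gap = 0
                block1 = read_len
                if (profile.splice_prob > 0.0
                        and rng_layout.random() < profile.splice_prob
                        and s + read_len + profile.splice_gap <= contig_len):
                    gap = profile.splice_gap
                    block1 = read_len // 2
                span_end = s + read_len + gap
                if gap:
                    seq_arr = np.concatenate(
                        [ref_arr[s : s + block1],
                         ref_arr[s + block1 + gap : span_end]]
                    ).copy()
                else:
                    seq_arr = ref_arr[s : s + read_len].copy()

                # planted variants (layout stream: identical across profiles)
                lo = int(np.searchsorted(ev_pos, s))
                hi = int(np.searchsorted(ev_pos, span_end))
                for j in range(lo, hi):
                    p = int(ev_pos[j])
                    if gap and s + block1 <= p < s + block1 + gap:
                        continue  # position falls in the intron gap
                    q = p - s if p < s + block1 else p - s - gap
                    if rng_layout.random() < ev_frac[j]:
                        seq_arr[q] = ev_alt[j]

                # error process (profile-salted stream)
                quals = np.clip(
                    np.rint(rng_err.normal(profile.qual_mean, profile.qual_sd,
                                           read_len)),
                    2, 41,
                ).astype(np.uint8)
                n_err = rng_err.binomial(read_len, profile.error_rate)
                if n_err:
                    err_idx = rng_err.integers(0, read_len, size=n_err)
                    for q in err_idx:
                        cur = seq_arr[q]
                        alts = _BASE_ORDS[_BASE_ORDS != cur]
                        seq_arr[q] = alts[rng_err.integers(0, 3)]
                    quals[err_idx] = np.maximum(
                        quals[err_idx].astype(np.int16) - profile.error_qual_shift, 2
                    ).astype(np.uint8)

                mapq = 60
                if profile.low_mapq_frac and rng_err.random() < profile.low_mapq_frac:
                    mapq = int(rng_err.integers(20, 51))

                clip_left = clip_right = 0
                if (not gap and profile.softclip_prob
                        and rng_err.random() < profile.softclip_prob):
                    k = int(rng_err.integers(5, 16))
                    if rng_err.random() < 0.5:
                        clip_left = k
                    else:
                        clip_right = k

                a = pysam.AlignedSegment(bam_header)
                a.query_name = f"sim_{contig}_{i:07d}"
                a.flag = 16 if reverse[i] else 0
                a.reference_id = tid
                a.reference_start = s + clip_left
                a.mapping_quality = mapq
                cigar: List[Tuple[int, int]] = []
                if clip_left:
                    cigar.append((4, clip_left))
                aligned1 = block1 - clip_left
                if gap:
                    aligned2 = (read_len - block1) - clip_right
                    cigar += [(0, aligned1), (3, gap), (0, aligned2)]
                else:
                    cigar.append((0, read_len - clip_left - clip_right))
                if clip_right:
                    cigar.append((4, clip_right))
                a.cigartuples = cigar
                a.query_sequence = seq_arr.tobytes().decode("ascii")
                a.query_qualities = pysam.qualitystring_to_array(
                    "".join(chr(q + 33) for q in quals)
                )
                # NM over aligned (non-clipped) bases
                if gap:
                    ref_cmp = np.concatenate(
                        [ref_arr[s + clip_left : s + block1],
                         ref_arr[s + block1 + gap : span_end - clip_right]]
                    )
                    qry_cmp = np.concatenate(
                        [seq_arr[clip_left:block1],
                         seq_arr[block1 : read_len - clip_right]]
                    )
                else:
                    ref_cmp = ref_arr[s + clip_left : s + read_len - clip_right]
                    qry_cmp = seq_arr[clip_left : read_len - clip_right]
                a.set_tag("NM", int(np.count_nonzero(ref_cmp != qry_cmp)))
                records.append(a)
            # soft-clipping may nudge reference_start past a neighbour's
            records.sort(key=lambda r: r.reference_start)
            for a in records:
                bam.write(a)
    pysam.index(out_bam)
    return out_bam


# ---------------------------------------------------------------------------
# Annotation tracks
# ---------------------------------------------------------------------------

def _subtract_points(
    intervals: List[Tuple[int, int]], points: Sequence[int]
) -> List[Tuple[int, int]]:
    """Split half-open intervals so they exclude the given points."""
    pts = sorted(set(points))
    out: List[Tuple[int, int]] = []
    for start, end in intervals:
        cur = start
        lo = int(np.searchsorted(pts, start))
        hi = int(np.searchsorted(pts, end))
        for k in range(lo, hi):
            p = pts[k]
            if p > cur:
                out.append((cur, p))
            cur = p + 1
        if cur < end:
            out.append((cur, end))
    return out


def _merge(intervals: List[Tuple[int, int]]) -> List[Tuple[int, int]]:
    merged: List[Tuple[int, int]] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def _write_bed(path: str, per_contig: Dict[str, List[Tuple[int, int]]]) -> str:
    with open(path, "w") as fh:
        for contig in per_contig:
            for start, end in sorted(per_contig[contig]):
                fh.write(f"{contig}\t{start}\t{end}\n")
    return path


def generate_annotations(
    ref: ReferenceGenome,
    truth: TruthTable,
    alu_fraction: float = 0.9,
    seed: int = 0,
    outdir: str = ".",
) -> Dict[str, str]:
    """Emit Alu/simple-repeat BED tracks and a SNP VCF matching the truth.

    A seeded share ``alu_fraction`` of editing events is covered by Alu-like
    intervals (~300 bp, the length of a full Alu element); the Alu track is
    then split so that it never covers planted SNPs or the editing events
    chosen to stay outside it, making Alu membership exactly Bernoulli over
    the editing sites.  Simple-repeat intervals are random and avoid all
    planted events.  BED is 0-based half-open; the VCF is 1-based and contains
    exactly the planted SNPs with genotypes.
    """
    if not 0.0 <= alu_fraction <= 1.0:
        raise ValueError("alu_fraction must lie in [0, 1]")
    rng = np.random.default_rng([int(seed), 29])
    edits = truth.editing_events()
    snps = truth.snp_events()
    n_in = int(round(alu_fraction * len(edits)))
    chosen_idx = set(
        rng.choice(len(edits), size=n_in, replace=False).tolist() if n_in else []
    )

    alu: Dict[str, List[Tuple[int, int]]] = {c: [] for c in ref.sequences}
    for i, ev in enumerate(edits):
        if i not in chosen_idx:
            continue
        length = int(rng.integers(250, 351))
        offset = int(rng.integers(5, length - 5))
        contig_len = len(ref.sequences[ev.contig])
        start = max(0, ev.pos0 - offset)
        end = min(contig_len, start + length)
        alu[ev.contig].append((start, end))
    excluded: Dict[str, List[int]] = {c: [] for c in ref.sequences}
    for ev in snps:
        excluded[ev.contig].append(ev.pos0)
    for i, ev in enumerate(edits):
        if i not in chosen_idx:
            excluded[ev.contig].append(ev.pos0)
    for contig in alu:
        alu[contig] = _subtract_points(_merge(alu[contig]), excluded[contig])

    repeats: Dict[str, List[Tuple[int, int]]] = {c: [] for c in ref.sequences}
    all_points: Dict[str, List[int]] = {c: [] for c in ref.sequences}
    for ev in truth.events:
        all_points[ev.contig].append(ev.pos0)
    for contig, seq in ref.sequences.items():
        contig_len = len(seq)
        n_rep = max(3, contig_len // 2000)
        for _ in range(n_rep):
            length = int(rng.integers(20, 201))
            start = int(rng.integers(0, max(1, contig_len - length)))
            repeats[contig].append((start, start + length))
        repeats[contig] = _subtract_points(_merge(repeats[contig]),
                                           all_points[contig])

    os.makedirs(outdir, exist_ok=True)
    alu_path = _write_bed(os.path.join(outdir, "alu.bed"), alu)
    rep_path = _write_bed(os.path.join(outdir, "repeats.bed"), repeats)
    vcf_path = os.path.join(outdir, "snps.vcf")
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for contig, length in ref.lengths.items():
            fh.write(f"##contig=<ID={contig},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsample1\n")
        for ev in sorted(snps, key=lambda e: (e.contig, e.pos0)):
            gt = "0/1" if ev.genotype == "het" else "1/1"
            fh.write(
                f"{ev.contig}\t{ev.pos0 + 1}\t.\t{ev.ref}\t{ev.alt}\t.\tPASS\t"
                f".\tGT\t{gt}\n"
            )
    return {"alu": alu_path, "repeats": rep_path, "snps": vcf_path}


# ---------------------------------------------------------------------------
# One-call convenience used by the CLI and benchmarks
# ---------------------------------------------------------------------------

def simulate_dataset(
    outdir: str,
    seed: int,
    total_length: int = 30_000,
    n_contigs: int = 1,
    gc: float = 0.41,
    n_edit: int = 200,
    n_snp: int = 100,
    coverage: float = 30.0,
    profile: PlatformProfile = ILLUMINA,
    alu_fraction: float = 0.9,
    level_floor: float = 0.1,
) -> Dict[str, str]:
    """Simulate reference + truth + reads + annotations into ``outdir``."""
    os.makedirs(outdir, exist_ok=True)
    ref = simulate_reference(total_length, n_contigs, gc, seed)
    truth = plant_truth(ref, n_edit, n_snp, level_floor, seed)
    paths = {
        "ref": ref.write_fasta(os.path.join(outdir, "ref.fa")),
        "bam": generate_alignments(ref, truth, coverage, profile, seed,
                                   os.path.join(outdir, "reads.bam")),
        "truth": truth.write_tsv(os.path.join(outdir, "truth.tsv")),
    }
    paths.update(generate_annotations(ref, truth, alu_fraction, seed, outdir))
    return paths
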