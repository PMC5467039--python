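"""Shared fixtures: small simulated datasets and a SAM-text -> BAM helper."""

import os

import pysam
import pytest

from editml import (ILLUMINA, PlatformProfile, generate_alignments,
                    generate_annotations, plant_truth, simulate_reference)


def sam_to_bam(sam_text: str, path: str) -> str:
    """Write SAM text to an indexed BAM (records must be coordinate-sorted)."""
    sam_path = path + ".sam"
    with open(sam_path, "w") as fh:
        fh.write(sam_text)
    with pysam.AlignmentFile(sam_path) as fin, \
            pysam.AlignmentFile(path, "wb", template=fin) as fout:
        for rec in fin:
            fout.write(rec)
    pysam.index(path)
    return path


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """A 20 kb, 2-contig simulation with 100 edits / 50 SNPs at 30x."""
    outdir = str(tmp_path_factory.mktemp("small_sim"))
    ref = simulate_reference(20_000, 2, 0.41, seed=7)
    truth = plant_truth(ref, 100, 50, 0.1, seed=7)
    bam = generate_alignments(ref, truth, 30, ILLUMINA, 7,
                              os.path.join(outdir, "reads.bam"))
    tracks = generate_annotations(ref, truth, 0.9, 7, outdir)
    ref_fa = ref.write_fasta(os.path.join(outdir, "ref.fa"))
    return {"ref": ref, "truth": truth, "bam": bam, "ref_fa": ref_fa,
            "outdir": outdir, **tracks}


@pytest.fixture(scope="session")
def errorfree_dataset(tmp_path_factory):
    """Error-free 12 kb simulation for exact planted-truth checks."""
    outdir = str(tmp_path_factory.mktemp("perfect_sim"))
    profile = PlatformProfile("perfect", error_rate=0.0, read_length=100,
                              qual_mean=38.0, qual_sd=2.0,
                              low_mapq_frac=0.0, softclip_prob=0.0)
    ref = simulate_reference(12_000, 1, 0.41, seed=11)
    truth = plant_truth(ref, 80, 40, 0.1, seed=11)
    bam = generate_alignments(ref, truth, 30, profile, 11,
                              os.path.join(outdir, "reads.bam"))
    tracks = generate_annotations(ref, truth, 0.9, 11, outdir)
    return {"ref": ref, "truth": truth, "bam": bam, "outdir": outdir, **tracks}
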