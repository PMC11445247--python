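"""Shared fixtures: a synthetic contig with aligned reads, an exact
brute-force pileup oracle, and the VCF derived from that oracle.

Everything is generated programmatically at test time from fixed seeds;
no data files ship with the tests.
"""

from __future__ import annotations

import collections
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pysam
import pytest

CONTIG = "chr_syn"
CONTIG_LEN = 10_000
READ_LEN = 100
N_READS = 4_000
BASES = "ACGT"


@dataclass
class SyntheticAlignment:
    """Paths plus the ground-truth read set for oracle pileup."""

    fasta: Path
    bam: Path
    vcf: Path
    reference: str
    reads: list[tuple[int, str]]  # (0-based start, sequence)
    oracle_counts: dict[int, dict[str, int]]  # 0-based pos -> base counts


def _oracle_pileup(reads: list[tuple[int, str]]) -> dict[int, dict[str, int]]:
    """Exact column base counts by direct enumeration over reads."""
    counts: dict[int, dict[str, int]] = collections.defaultdict(
        lambda: collections.defaultdict(int)
    )
    for start, seq in reads:
        for i, base in enumerate(seq):
            counts[start + i][base] += 1
    return {p: dict(c) for p, c in counts.items()}


def oracle_biallelic_sites(
    counts: dict[int, dict[str, int]], reference: str
) -> list[tuple[int, int, int]]:
    """(1-based pos, ref_depth, alt_depth) for exactly-two-allele columns."""
    out = []
    for pos0, c in sorted(counts.items()):
        ref_base = reference[pos0]
        ref_depth = c.get(ref_base, 0)
        alts = sorted(
            ((n, b) for b, n in c.items() if b != ref_base), reverse=True
        )
        if ref_depth == 0 or not alts or len(alts) > 1:
            continue
        out.append((pos0 + 1, ref_depth, alts[0][0]))
    return out


@pytest.fixture(scope="session")
def synthetic_alignment(tmp_path_factory) -> SyntheticAlignment:
    """10 kb contig, ~40x of perfect 100 bp reads, het sites every ~150 bp
    with alternative-allele fractions drawn from {1/4, 1/3, 1/2, 2/3, 3/4}."""
    rng = np.random.default_rng(20_260_924)
    tmp = tmp_path_factory.mktemp("synaln")
    reference = "".join(rng.choice(list(BASES), size=CONTIG_LEN))

    var_pos = np.arange(150, CONTIG_LEN - 150, 150)
    var_frac = rng.choice([0.25, 1 / 3, 0.5, 2 / 3, 0.75], size=var_pos.size)
    var_alt = {}
    for p in var_pos:
        ref_base = reference[p]
        var_alt[int(p)] = rng.choice([b for b in BASES if b != ref_base])
    frac_at = dict(zip((int(p) for p in var_pos), var_frac))

    reads = []
    starts = rng.integers(0, CONTIG_LEN - READ_LEN + 1, size=N_READS)
    for start in sorted(int(s) for s in starts):
        seq = list(reference[start : start + READ_LEN])
        for p, alt in var_alt.items():
            if start <= p < start + READ_LEN and rng.random() < frac_at[p]:
                seq[p - start] = alt
        reads.append((start, "".join(seq)))

    fasta = tmp / "ref.fa"
    fasta.write_text(f">{CONTIG}\n{reference}\n")
    pysam.faidx(str(fasta))

    header = {"HD": {"VN": "1.6", "SO": "coordinate"},
              "SQ": [{"SN": CONTIG, "LN": CONTIG_LEN}]}
    unsorted = tmp / "reads.unsorted.bam"
    with pysam.AlignmentFile(str(unsorted), "wb", header=header) as bam:
        for i, (start, seq) in enumerate(reads):
            a = pysam.AlignedSegment()
            a.query_name = f"r{i}"
            a.query_sequence = seq
            a.flag = 0
            a.reference_id = 0
            a.reference_start = start
            a.mapping_quality = 60
            a.cigarstring = f"{READ_LEN}M"
            a.query_qualities = pysam.qualitystring_to_array("I" * READ_LEN)
            bam.write(a)
    bam_path = tmp / "reads.bam"
    pysam.sort("-o", str(bam_path), str(unsorted))
    pysam.index(str(bam_path))

    counts = _oracle_pileup(reads)
    vcf_path = tmp / "oracle.vcf"
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={CONTIG},length={CONTIG_LEN}>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1",
    ]
    for pos1, ref_d, alt_d in oracle_biallelic_sites(counts, reference):
        ref_base = reference[pos1 - 1]
        alt_base = var_alt[pos1 - 1]
        lines.append(
            f"{CONTIG}\t{pos1}\t.\t{ref_base}\t{alt_base}\t.\tPASS\t.\t"
            f"GT:AD\t0/1:{ref_d},{alt_d}"
        )
    vcf_path.write_text("\n".join(lines) + "\n")

    return SyntheticAlignment(fasta, bam_path, vcf_path, reference, reads, counts)
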