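"""Per-site allelic depth extraction and site filtering.

A biallelic site is summarised by the read depth supporting the reference
allele and the depth supporting the single best-supported alternative
allele.  The alternative-allele fraction ``alt / (ref + alt)`` at retained
heterozygous sites carries the ploidy signal: its modes sit at the dosage
fractions ``k/m`` for an effective copy number ``m``.

Two ingestion paths are provided — a pileup over a coordinate-sorted,
indexed alignment (BAM/CRAM, or SAM with an index) against its reference
FASTA, and a walk over a VCF carrying per-sample allelic depths (the
``AD`` FORMAT field).  Both feed the same :class:`FilterConfig` contract,
so an alignment and a faithfully derived VCF yield the same retained
sites.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pysam

logger = logging.getLogger(__name__)

__all__ = [
    "SiteDepth",
    "FilterConfig",
    "RejectReason",
    "apply_site_filter",
    "read_depths_from_alignment",
    "read_depths_from_variants",
    "filter_sites",
    "write_sites_tsv",
    "read_sites_tsv",
]


@dataclass(frozen=True, order=True)
class SiteDepth:
    """Reference/alternative read counts at one biallelic site.

    Coordinates are 1-based inclusive, matching the variant-format
    convention; the alignment path converts internally.
    """

    contig: str
    pos: int
    ref_depth: int
    alt_depth: int

    def __post_init__(self) -> None:
        if self.ref_depth < 0 or self.alt_depth < 0:
            raise ValueError("read depths must be non-negative")
        if self.pos < 1:
            raise ValueError("pos is 1-based and must be >= 1")

    @property
    def total_depth(self) -> int:
        return self.ref_depth + self.alt_depth

    @property
    def fraction(self) -> float:
        """Alternative-allele fraction alt/(ref+alt)."""
        if self.total_depth == 0:
            raise ZeroDivisionError("fraction undefined at zero depth")
        return self.alt_depth / self.total_depth


class RejectReason(enum.Enum):
    """Machine-readable cause for discarding a site (one cause per site)."""

    TOTAL_BELOW_MIN = "total_below_min"
    TOTAL_ABOVE_MAX = "total_above_max"
    ALT_BELOW_MIN = "alt_below_min"
    REF_BELOW_MIN = "ref_below_min"
    FRACTION_OUTSIDE_WINDOW = "fraction_outside_window"


@dataclass(frozen=True)
class FilterConfig:
    """Site retention rules.

    ``min_total``/``max_total`` bound the total depth (defaults 20–200,
    inclusive).  ``min_alt`` is a strict lower bound: a site is retained
    only when ``alt_depth > min_alt`` (default 7, i.e. at least 8 reads).
    ``min_ref`` applies the symmetric requirement to the reference allele
    so that only confidently heterozygous sites feed the histogram; set it
    to ``None`` to disable.  ``fraction_window`` trims residual
    homozygote/error mass at the fraction extremes.  ``min_mapq`` and
    ``min_baseq`` mask low-quality evidence on the alignment path only
    (the mapping-quality floor operationalises "uniquely mapped reads").
    """

    min_total: int = 20
    max_total: int = 200
    min_alt: int = 7
    min_ref: int | None = 7
    min_mapq: int = 20
    min_baseq: int = 13
    fraction_window: tuple[float, float] = (0.05, 0.95)
    max_third_allele_frac: float = 0.10

    def __post_init__(self) -> None:
        if not (0 < self.min_total <= self.max_total):
            raise ValueError("require 0 < min_total <= max_total")
        if self.min_alt < 0:
            raise ValueError("min_alt must be >= 0")
        lo, hi = self.fraction_window
        if not (0.0 <= lo < hi <= 1.0):
            raise ValueError("fraction_window must satisfy 0 <= lo < hi <= 1")


def apply_site_filter(
    site: SiteDepth, config: FilterConfig
) -> RejectReason | None:
    """Classify a site against the filter; ``None`` means retained.

    Total classification: exactly one enumerated cause is reported for a
    rejected site (bounds are checked in a fixed order).
    """
    total = site.total_depth
    if total < config.min_total:
        return RejectReason.TOTAL_BELOW_MIN
    if total > config.max_total:
        return RejectReason.TOTAL_ABOVE_MAX
    if site.alt_depth <= config.min_alt:
        return RejectReason.ALT_BELOW_MIN
    if config.min_ref is not None and site.ref_depth <= config.min_ref:
        return RejectReason.REF_BELOW_MIN
    lo, hi = config.fraction_window
    if not (lo <= site.fraction <= hi):
        return RejectReason.FRACTION_OUTSIDE_WINDOW
    return None


def filter_sites(
    sites: Iterable[SiteDepth], config: FilterConfig
) -> Iterator[SiteDepth]:
    """Yield only sites retained by :func:`apply_site_filter`. Idempotent."""
    for site in sites:
        if apply_site_filter(site, config) is None:
            yield site


def read_depths_from_alignment(
    alignment_path: str | Path,
    reference_path: str | Path,
    config: FilterConfig | None = None,
    *,
    exclude_contigs: Sequence[str] = (),
    region: str | None = None,
) -> Iterator[SiteDepth]:
    """Stream retained :class:`SiteDepth` from a coordinate-sorted alignment.

    At each pileup column, reads failing the MAPQ/base-quality floors are
    masked; the most frequent non-reference base is the alternative
    allele.  A column is emitted only when exactly two alleles remain —
    both reference and alternative support present, and any third allele
    below ``max_third_allele_frac`` of the column depth (a guard against
    collapsed paralogs).  Contigs named in ``exclude_contigs`` (e.g.
    organellar sequences, which are analysed separately) are skipped.

    Raises ``FileNotFoundError`` if the alignment index is missing and
    ``ValueError`` naming the first alignment contig absent from the
    reference.
    """
    config = config or FilterConfig()
    excluded = set(exclude_contigs)

    with pysam.FastaFile(str(reference_path)) as fasta:
        ref_contigs = set(fasta.references)
        with pysam.AlignmentFile(str(alignment_path)) as bam:
            if not bam.has_index():
                raise FileNotFoundError(
                    f"alignment {alignment_path} has no index; sort and "
                    "index it (samtools index) before depth extraction"
                )
            for contig in bam.references:
                if contig in excluded:
                    continue
                if contig not in ref_contigs:
                    raise ValueError(
                        f"alignment contig {contig!r} absent from reference "
                        f"{reference_path}"
                    )
            for column in bam.pileup(
                region=region,
                truncate=True,
                stepper="samtools",
                min_mapping_quality=config.min_mapq,
                min_base_quality=config.min_baseq,
                ignore_overlaps=False,
                max_depth=10 * config.max_total,
            ):
                contig = column.reference_name
                if contig in excluded:
                    continue
                ref_base = fasta.fetch(
                    contig, column.reference_pos, column.reference_pos + 1
                ).upper()
                counts: dict[str, int] = {}
                for base in column.get_query_sequences():
                    if not base:  # deletion/refskip
                        continue
                    b = base.upper()
                    counts[b] = counts.get(b, 0) + 1
                site = _column_to_site(
                    contig, column.reference_pos + 1, ref_base, counts, config
                )
                if site is not None and apply_site_filter(site, config) is None:
                    yield site


def _column_to_site(
    contig: str,
    pos: int,
    ref_base: str,
    counts: dict[str, int],
    config: FilterConfig,
) -> SiteDepth | None:
    """Reduce one pileup column's base counts to a biallelic SiteDepth."""
    ref_depth = counts.get(ref_base, 0)
    alt_counts = sorted(
        ((n, b) for b, n in counts.items() if b != ref_base and b in "ACGT"),
        reverse=True,
    )
    if ref_depth == 0 or not alt_counts:
        return None  # monoallelic column, not a variant
    alt_depth = alt_counts[0][0]
    depth = ref_depth + alt_depth
    if len(alt_counts) > 1:
        third = alt_counts[1][0]
        if third > config.max_third_allele_frac * (depth + third):
            return None  # triallelic — likely paralog collapse
    return SiteDepth(contig, pos, ref_depth, alt_depth)


def read_depths_from_variants(
    vcf_path: str | Path,
    sample_id: str,
    config: FilterConfig | None = None,
) -> Iterator[SiteDepth]:
    """Stream retained :class:`SiteDepth` from a VCF with per-sample AD.

    Only biallelic SNP records are considered; multiallelic and indel
    records are skipped with a logged count.  Raises ``KeyError`` listing
    the available samples if ``sample_id`` is absent, and ``ValueError``
    if a record lacks the allelic-depth FORMAT field.
    """
    config = config or FilterConfig()
    skipped = 0
    with pysam.VariantFile(str(vcf_path)) as vcf:
        samples = list(vcf.header.samples)
        if sample_id not in samples:
            raise KeyError(
                f"sample {sample_id!r} not in {vcf_path}; available samples: "
                f"{', '.join(samples)}"
            )
        for record in vcf:
            alts = record.alts or ()
            if (
                len(alts) != 1
                or len(record.ref) != 1
                or len(alts[0]) != 1
                or alts[0] not in "ACGT"
            ):
                skipped += 1
                continue
            call = record.samples[sample_id]
            ad = call.get("AD")
            if ad is None or ad[0] is None:
                raise ValueError(
                    f"record {record.chrom}:{record.pos} lacks the AD "
                    "(allelic depth) FORMAT field required for "
                    "allele-balance extraction"
                )
            site = SiteDepth(record.chrom, record.pos, int(ad[0]), int(ad[1]))
            if apply_site_filter(site, config) is None:
                yield site
    if skipped:
        logger.info("skipped %d multiallelic/indel records in %s", skipped, vcf_path)


def write_sites_tsv(sites: Iterable[SiteDepth], path: str | Path) -> int:
    """Export sites as TSV (contig, pos, ref_depth, alt_depth, fraction)."""
    n = 0
    with open(path, "w") as fh:
        fh.write("contig\tpos\tref_depth\talt_depth\tfraction\n")
        for s in sites:
            fh.write(
                f"{s.contig}\t{s.pos}\t{s.ref_depth}\t{s.alt_depth}\t"
                f"{s.fraction:.6f}\n"
            )
            n += 1
    return n


def read_sites_tsv(path: str | Path) -> list[SiteDepth]:
    """Load a site table written by :func:`write_sites_tsv`."""
    out: list[SiteDepth] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for line in fh:
            f = line.rstrip("\n").split("\t")
            out.append(
                SiteDepth(
                    f[idx["contig"]],
                    int(f[idx["pos"]]),
                    int(f[idx["ref_depth"]]),
                    int(f[idx["alt_depth"]]),
                )
            )
    return out
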