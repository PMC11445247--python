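"""Synthetic per-site allelic read depths with known effective copy number.

Each heterozygous site of a sample with effective copy number ``m``
carries an alternative-allele dosage ``d`` in ``1..m-1``; the per-read
probability of observing the alternative allele is the error-adjusted
dosage fraction ``p = (d/m)(1-e) + (1-d/m)e`` and the alternative depth
is binomial in the site's total depth.  This is the generative model the
caller inverts, so simulated samples provide ground truth for recovery
experiments without any sequencing data.

Reproducibility: one global seed governs a sample, and every site draws
from its own sub-stream keyed by ``(seed, site_index)``, so extending
``n_sites`` never reshuffles earlier sites and identical configurations
produce byte-identical exports.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .depth_io import FilterConfig, SiteDepth, filter_sites
from .ploidy_model import FractionProfile

__all__ = [
    "SimConfig",
    "simulate_sites",
    "simulate_sample",
    "simulate_admixed_sites",
    "simulate_admixed_sample",
    "profile_from_sites",
    "write_vcf",
]

SIM_CONTIG = "sim"


@dataclass(frozen=True)
class SimConfig:
    """Generative parameters for one simulated sample.

    ``depth_law`` is ``"uniform"`` (inclusive ``depth_min..depth_max``)
    or ``"nbinom"`` (mean ``depth_mean``, dispersion ``depth_dispersion``;
    variance mean + mean^2/dispersion).  ``dosage_weights`` is a
    probability vector over dosages ``1..m-1`` (uniform when omitted) and
    ``hom_fraction`` mixes in homozygous-alternative contaminant sites
    (dosage m).  Defaults put depths inside the 20–200 retention window
    at a mean of 30, matching typical reduced-representation coverage.
    """

    m: int = 2
    n_sites: int = 3000
    depth_law: str = "uniform"
    depth_min: int = 20
    depth_max: int = 40
    depth_mean: float = 30.0
    depth_dispersion: float = 10.0
    error_rate: float = 0.005
    dosage_weights: tuple[float, ...] | None = None
    hom_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 2:
            raise ValueError("effective copy number m must be >= 2")
        if not (0.0 <= self.error_rate < 0.5):
            raise ValueError("error_rate must lie in [0, 0.5)")
        if self.depth_law not in ("uniform", "nbinom"):
            raise ValueError(f"unknown depth_law {self.depth_law!r}")
        if self.dosage_weights is not None:
            w = np.asarray(self.dosage_weights, dtype=float)
            if w.size != self.m - 1 or (w < 0).any() or abs(w.sum() - 1.0) > 1e-9:
                raise ValueError(
                    "dosage_weights must be a probability vector over "
                    f"dosages 1..{self.m - 1}"
                )

    def dosage_probs(self) -> np.ndarray:
        if self.dosage_weights is None:
            return np.full(self.m - 1, 1.0 / (self.m - 1))
        return np.asarray(self.dosage_weights, dtype=float)


def _site_rng(seed: int, index: int) -> np.random.Generator:
    # sub-stream per site: stable under changes to n_sites
    return np.random.default_rng([seed, index])


def _draw_site(config: SimConfig, rng: np.random.Generator, pos: int) -> SiteDepth:
    if config.hom_fraction > 0.0 and rng.random() < config.hom_fraction:
        dosage = config.m
    else:
        dosage = 1 + rng.choice(config.m - 1, p=config.dosage_probs())
    if config.depth_law == "uniform":
        depth = int(rng.integers(config.depth_min, config.depth_max + 1))
    else:
        lam = rng.gamma(config.depth_dispersion,
                        config.depth_mean / config.depth_dispersion)
        depth = max(int(rng.poisson(lam)), 1)
    p = dosage / config.m
    p = p * (1.0 - config.error_rate) + (1.0 - p) * config.error_rate
    alt = int(rng.binomial(depth, p))
    return SiteDepth(SIM_CONTIG, pos, depth - alt, alt)


def simulate_sites(config: SimConfig) -> list[SiteDepth]:
    """Draw all sites of one sample, pre-filter."""
    return [
        _draw_site(config, _site_rng(config.seed, i), 10 * i + 1)
        for i in range(config.n_sites)
    ]


def profile_from_sites(
    sample_id: str,
    sites: Sequence[SiteDepth],
    filter_config: FilterConfig | None = None,
) -> FractionProfile:
    """Build a FractionProfile from sites, applying the retention filter.

    With ``filter_config=None`` only degenerate fractions (0 or 1, i.e.
    non-variant sites) are dropped.
    """
    if filter_config is None:
        kept = [s for s in sites if 0 < s.alt_depth < s.total_depth]
    else:
        kept = list(filter_sites(sites, filter_config))
    return FractionProfile(
        sample_id, tuple(s.fraction for s in kept), filter_config
    )


def simulate_sample(
    config: SimConfig,
    sample_id: str = "sim",
    filter_config: FilterConfig | None = None,
) -> FractionProfile:
    """Simulate one sample and return its fraction profile."""
    return profile_from_sites(sample_id, simulate_sites(config), filter_config)


def simulate_admixed_sites(
    parent_configs: Sequence[SimConfig],
    mixing: Sequence[float],
    n_sites: int | None = None,
    seed: int | None = None,
) -> list[SiteDepth]:
    """Sites drawn from several parental generative laws in proportion.

    Each site first picks a parent (a sub-stream independent of the
    parents' own draws, so ``mixing=(1.0, 0.0)`` reproduces the first
    parent's sample exactly) and then draws from that parent's law.
    """
    if len(parent_configs) < 2:
        raise ValueError("admixture requires at least two parent configs")
    mix = np.asarray(mixing, dtype=float)
    if mix.size != len(parent_configs) or (mix < 0).any() or abs(mix.sum() - 1.0) > 1e-9:
        raise ValueError("mixing proportions must be non-negative and sum to 1")
    n = n_sites if n_sites is not None else parent_configs[0].n_sites
    s = seed if seed is not None else parent_configs[0].seed
    sites = []
    for i in range(n):
        parent = int(_site_rng(s, i + 1_000_000).choice(len(parent_configs), p=mix))
        cfg = parent_configs[parent]
        sites.append(_draw_site(cfg, _site_rng(cfg.seed, i), 10 * i + 1))
    return sites


def simulate_admixed_sample(
    parent_configs: Sequence[SimConfig],
    mixing: Sequence[float],
    sample_id: str = "admixed",
    n_sites: int | None = None,
    seed: int | None = None,
    filter_config: FilterConfig | None = None,
) -> FractionProfile:
    """Fraction profile of an admixed individual (see simulate_admixed_sites)."""
    sites = simulate_admixed_sites(parent_configs, mixing, n_sites, seed)
    return profile_from_sites(sample_id, sites, filter_config)


def write_vcf(
    sites: Sequence[SiteDepth],
    path: str | Path,
    sample_id: str = "sim",
    contig_length: int | None = None,
) -> None:
    """Write sites as a minimal single-sample VCF with AD/DP fields.

    All records are biallelic SNPs (REF=A, ALT=C) on one synthetic
    contig, which is all the allele-balance pipeline consumes.
    """
    length = contig_length or (max((s.pos for s in sites), default=0) + 1)
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={SIM_CONTIG},length={length}>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample_id}",
    ]
    for s in sorted(sites):
        lines.append(
            f"{s.contig}\t{s.pos}\t.\tA\tC\t.\tPASS\t.\tGT:AD:DP\t"
            f"0/1:{s.ref_depth},{s.alt_depth}:{s.total_depth}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
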