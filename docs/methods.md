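# Methods

## Generative model

A sample with effective copy number *m* carries heterozygous biallelic
sites whose alternative allele occupies a dosage *d* ∈ {1, …, *m*−1} of
the *m* copies. Reads sample the two alleles binomially, with a per-read
miscall probability *e* toward the other allele, so the alternative
depth at a site of total depth *D* is Binomial(*D*, *p*) with

    p = (d/m)(1 − e) + (1 − d/m) e.

The alternative-allele fraction alt/(ref+alt) across many sites is then
a mixture with component means at the error-adjusted dosage fractions.
In an allopolyploid that has diploidized — subgenomes divergent enough
that most reduced-representation loci map to a single subgenome — the
segregating copy number at such loci is half the cytotype ploidy, so the
reported ploidy is `cytotype_factor × m` with `cytotype_factor = 2` by
default; set it to 1 for true autopolyploids, where every chromosome set
pairs.

Octoploids (m = 4) deserve a caveat: empirically their fraction
histograms often show a broad plateau between roughly 0.35 and 0.65
rather than three clean modes at 0.25/0.5/0.75 — uneven dosage usage and
residual inter-subgenome mapping smear the interior modes together. The
caller recognises both signatures (see below).

## Site filtering

Per-site allelic depths come from either a pileup over a
coordinate-sorted, indexed alignment (mapping-quality floor 20 as a
proxy for unique mapping; base-quality floor 13; the most frequent
non-reference base is the alternative allele; columns with a third
allele above 10% of depth are discarded as likely collapsed paralogs;
organellar contigs can be excluded by name) or from a VCF's per-sample
AD field (biallelic SNP records only). A site is retained when

* total depth ∈ [20, 200] (inclusive),
* alternative depth strictly greater than 7 reads,
* reference depth strictly greater than 7 reads (optional, default on),
* the fraction lies inside the window [0.05, 0.95].

The symmetric reference-depth requirement and the fraction window both
restrict the histogram to confidently heterozygous sites: the interior
modes, not the boundary mass of homozygotes and errors, carry the ploidy
signal. The strict `> 7` reading (at least 8 reads) applies to the
alternative allele and, by default, symmetrically to the reference
allele; disabling `min_ref` recovers the alternative-only behaviour.
Filtering is a total classification — each rejected site gets exactly
one enumerated cause — and is idempotent. Coordinates are 1-based
throughout; the alignment path converts internally. Whether fractions
are aggregated per SNP or per locus is an open choice; they are computed
per SNP here.

## Density estimation and mode detection

The retained fractions feed a Gaussian kernel density estimate with a
*fixed* absolute bandwidth of 0.02 on the fraction axis, evaluated on a
uniform 512-point grid over [0, 1] and renormalised to unit mass
(trapezoid rule, tolerance 1e-6). A fixed bandwidth (rather than a
data-driven rule) keeps the pipeline deterministic and exactly
mirror-symmetric under f → 1−f. Modes are local maxima whose topographic
prominence exceeds 10% of the global maximum, separated by at least
0.08. These defaults resolve the closest expected modes among the
candidate set (1/3 vs 1/4, gap 0.083) at depths of a few dozen reads;
at much lower depth the binomial noise widens the components and the
octoploid candidate degrades first. Density estimation requires at least
200 sites by default (an explicit error carrying both counts).

## Candidate scoring and the call

Each candidate *m* ∈ {2, 3, 4} receives two scores.

**Peak match.** Detected modes are greedily matched to the expected
positions {k/m} within a tolerance of 0.06; the score is
`matched − 0.5 × (unmatched expected + unmatched observed)`. A plateau
rule covers the empirical octoploid signature: when at least half the
density mass lies in [0.3, 0.7] and the density over [0.35, 0.65] is
flat (max/min ≤ 2.5), the largest candidate (m ≥ 4) is credited with a
full match.

**Mixture criterion.** A Gaussian mixture with component means pinned at
the error-adjusted dosage fractions (e = 0.005 by default), free weights
and one shared standard deviation is fitted by EM — uniform-weight
initialisation, closed-form M-steps, convergence tolerance 1e-6 on the
log-likelihood, cap 500 iterations, no randomness — and candidates are
compared by BIC with (m−2) free weights plus the shared width as the
parameter count. Gaussian components are an adequate symmetric unimodal
family here because all component means are interior and the binomial
sd at depth ≥ 20 is ≪ the distance to the boundary; the shared width
approximates the mild mean-dependence of the binomial variance.

The call is the candidate minimising BIC, with the peak score as a
deterministic tie-break; the two scores agree on clean profiles, and the
information criterion is the more statistically efficient discriminator
when modes are smeared. The call is flagged `ambiguous` when the BIC gap
between the top two candidates is below 10, and `low_sites` (still
emitted) below the 200-site minimum. Mixoploidy and aneuploidy are out
of scope; odd effective copies report odd × factor cytotypes (m = 3 →
"6x").

Invariants verified by the test suite: mirror symmetry of calls under
f → 1−f; bit-for-bit determinism of repeated calls; recovery
non-decreasing in site count under common random seeds; ≥ 95% recovery
per class at the reference simulation conditions.

## Admixture calculus and validation

The expected ploidy of an admixed individual with ancestry proportions
qᵢ from lineages of ploidy pᵢ is the weighted arithmetic mean Σ qᵢ pᵢ,
rounded half-away-from-zero to one decimal (0.77·8 + 0.23·4 = 7.08 →
7.1). Proportions are used as published, without renormalisation:
ancestry vectors rounded to two decimals may sum to slightly under 1 and
the residual carries no expectation (this choice reproduces every
published cell; renormalising would not). The F1 expectation of a cross
is the parental midpoint; for individuals with more than two source
lineages the packaged panel's printed F1 corresponds to the midpoint of
the extreme parental ploidies, which is what the evaluation computes.
Neoploidy is classified with a strict epsilon of 0.05 rather than a
±0.5 band — an individual predicted 8x against an expectation of 7.5
counts as increased, matching the published tally of 14 increased and
2 decreased.

Flow-cytometry classification assigns a 2C genome size (pg) to the
cytotype with the nearest reference mean — defaults 4x → 1.99, 6x →
3.09, 8x → 3.99 pg, the medians of the packaged panel's groups — with
ties broken toward the lower ploidy; it is monotone in genome size.
Concordance between two per-individual ploidy mappings is the matching
fraction over shared ids, with discrepant ids listed. On the packaged
panel (56 individuals with measured sizes surviving transcription) the
read-based predictions and flow classes agree at 98.2%; the single
discrepant row (I12: predicted 4x, 3.92 pg) is surfaced, not resolved.
The polyploid inbreeding coefficient is F = 1 − H·p/(p−1); it is ≤ 1,
strictly decreasing in H, and negative under excess heterozygosity.

## Simulator

The simulator draws, per site, a dosage from a configurable weight
vector (uniform over 1..m−1 by default, plus an optional
homozygous-alternative contaminant fraction), a depth from either a
uniform law (default 20–40, mean 30 — typical reduced-representation
coverage) or a gamma-Poisson (negative-binomial) law, and a binomial
alternative depth at the error-adjusted dosage fraction (default error
0.5%). Every site draws from a sub-stream keyed by (seed, site index),
so enlarging `n_sites` appends sites without reshuffling earlier ones
and identical configurations export byte-identical VCFs. What the
simulator deliberately omits: linkage between sites, locus dropout and
allele-specific amplification bias, mapping error and paralog collapse,
and inter-site depth correlation. Passing recovery tests therefore
demonstrates that the caller inverts the dosage-mixture model at
realistic depths and site counts — not that every artefact of real
reduced-representation data is handled; the alignment-path filters
(MAPQ, third-allele, organelle exclusion) exist precisely for the
artefacts the simulator does not emulate.

Reference experiment sizes used by the test suite and the acceptance
script: 50 replicates per cytotype class, 3000 sites per sample, uniform
depth 25–60, error 0.005 — the panel-realistic regime at which per-class
recovery is ≥ 95%. The synthetic alignment-path fixture is a 10 kb
contig at ~40× with planted heterozygous sites, checked against an exact
enumeration pileup oracle.

## Known limitations

* Candidates above m = 4 are not scored by default; dodecaploids or
  higher would need an extended candidate list and tighter bandwidth.
* A 50/50 mixture of two cytotype laws (contact-zone individuals,
  mixoploid tissue) yields an interior-mass profile that the caller may
  legitimately assign to an intermediate class or flag ambiguous; it is
  recorded, not resolved.
* The diploidization assumption (cytotype = 2m) fails for loci shared
  between subgenomes; a substantial shared-locus fraction biases calls
  toward higher m.
* Admixture proportions and heterozygosity statistics are consumed as
  inputs; estimating them is the job of dedicated structure/genotyping
  tools.
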