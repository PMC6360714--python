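# Methods

## Estimators

**Nucleotide diversity.** For one pool at one site with coverage C and
minor-allele read count x, π̂ = 2x(C−x)/(C(C−1)) — the unbiased
heterozygosity of the read sample. Sites with C < 2 are skipped (flagged,
not an error). Window π (non-overlapping, default 5,000 bp) is the sum of
site values over sites passing the coverage filters divided by the number
of covered sites, so it is a per-covered-site rate, robust to missing
positions. A window is reported only when covered sites fill at least a
configurable fraction of its span (default 0.5); the genome mean is the
unweighted mean over reported windows, quoted in percent. Only the F_ST
windows slide; π windows do not overlap.

**Karlsson-method F_ST.** Per biallelic SNP, with major/minor read counts
(aᵢ, bᵢ) and read depth nᵢ in each pool,

    hᵢ = aᵢbᵢ/(nᵢ(nᵢ−1)),
    N  = (a₁/n₁ − a₂/n₂)² − h₁/n₁ − h₂/n₂,
    D  = N + h₁ + h₂.

hᵢ is an unbiased estimator of pᵢqᵢ, N of (p₁−p₂)², and D of
(p₁−p₂)² + p₁q₁ + p₂q₂; the window estimate is the ratio of sums ΣN/ΣD,
not a mean of per-SNP ratios — the ratio-of-sums form is stable when
individual D values are small. Sites with depth < 2 in either pool are
excluded. Consequences used as test oracles: an all-fixed-difference
window gives exactly 1; identical-frequency pools average to 0; and under
pure drift for t generations at effective size Ne in both populations the
genome-wide estimate converges to 1 − (1 − 1/(2Ne))ᵗ, because
E[N] = 2p₀q₀(1 − λᵗ) and E[D] = 2p₀q₀ with λ = 1 − 1/(2Ne), independent of
the ancestral frequency distribution. Negative window values are reported
unclamped: the region caller works on empirical percentiles and clamping
would distort them.

A deliberate design choice worth stating: a frequently seen paraphrase of
this estimator computes a "total" heterozygosity from the two pools'
summed read counts, 2AB/(N(N−1)), and takes 1 − h_within/h_total. That
variant converges to (1 − λᵗ)/(1 + λᵗ) under drift — roughly half the
expected differentiation at recent splits — and is *not* what is
implemented here; the identity-by-state form above is the estimator as
used in pool-seq practice, and it is the form whose drift calibration the
test suite verifies.

## Site and window filters

Defaults mirror standard pool-seq settings: minimum combined allele count
3 (summed across pools, so a rare allele private to one pool still counts),
per-pool coverage within [10, 100], and coverage fraction 1.0 — every pool
must be covered for a site to be usable. Sites with more than two retained
alleles are dropped entirely rather than reduced to their top two, because
the F_ST estimator is defined for biallelic sites and silent reduction
would bias heterozygosity. Allele ties at the retention threshold are
broken toward the alphabetically earlier base, deterministically.

F_ST windows additionally require a minimum number of usable SNPs
(default 5) to have a defined value. This is the SNP-level analog of the
window-coverage-fraction requirement of the original windowed pool-seq
tools, adapted to inputs that carry only variant sites: with fewer SNPs the
ratio-of-sums estimate is noise-dominated and both tails of its
distribution fill with statistically empty windows, which would otherwise
drive the percentile thresholds (the control 5 % percentile goes negative)
and dominate the dual-contrast selection with false positives. Windows
below the minimum are reported with an undefined value and are never
selectable; percentiles are computed over each pair's defined windows.

## Region calling

A window is flagged iff focal-pair F_ST > the focal 95 % percentile AND
control-pair F_ST < the control 5 % percentile. Both inequalities, and the
clustering gap below, are strict: a window exactly at a cutoff, or two
windows exactly 0.1 Mb apart, fail. Thresholds may instead be pinned in
the configuration to reproduce published cutoffs exactly. Flagged windows
merge into a cluster while each new window starts less than 0.1 Mb after
the cluster's current end; clusters with fewer than two member windows or
fewer than two *distinct* SNP positions (overlap-deduplicated — 50 %
overlapping windows would otherwise double-count every interior SNP) are
discarded. "Fewer than two member windows" is applied to the window count
regardless of window size, so the rule generalizes when windows are
reconfigured. Region bookkeeping reports count, length statistics,
cumulative length and genome share (default genome size 2.442 Gb,
overridable), and per-chromosome counts both as share-of-regions and — when
chromosome sizes are supplied — regions per Mb, since "concentration" is
ambiguous between the two.

Coordinates: mpileup/sync/QTL-TSV input are 1-based; all internal window
and region arithmetic is 0-based half-open; BED output is 0-based
half-open; human-readable reports are 1-based inclusive.

## The simulator

The generator emulates the statistical structure the scan assumes, not
reads or haplotypes. Unlinked ancestral derived-allele frequencies are
drawn from Beta(θ, θ) (θ = 0.2: the U-shaped spectrum of standing
variation) at 80,000 positions of a 10 Mb chromosome (~8 sites/kb, the
density of cross-breed pooled resequencing; about half survive drift
absorption and the site filters). Frequencies drift by binomial
Wright–Fisher resampling of 2Ne gametes (Ne = 500) along a ((NSCT, NSD),
SB) topology with branch lengths t_deep = 80 and t_shallow = 70
generations, followed by a one-shot SB→NSCT admixture pulse
p' = (1−m)p_NSCT + m·p_SB with m = 0.15. These values were chosen so the
mean pairwise window F_ST reproduces the qualitative breed pattern
(NSCT–NSD < NSCT–SB < NSD–SB, magnitudes ≈ 0.07–0.12) expected from
1 − λᵗ at the corresponding divergence times.

Sweeps model introgressed favourable variants: inside each planted span
(20 spans of 20 kb by default) the SB frequency is pushed through a
deterministic logistic trajectory p_t = p₀eˢᵗ/(1−p₀+p₀eˢᵗ) with s = 0.06
for t = 100 generations (s·t = 6, near fixation from standing variation;
sites at frequency 0 are seeded at 1/(2Ne)), and NSCT *adopts the same
selected frequency* — the favourable haplotype originated in SB and was
co-selected after introgression. This creates the dual-contrast signature
the caller targets: high NSCT–NSD, near-zero NSCT–SB differentiation.
Selection is deterministic rather than conditioned-on-fixation stochastic,
for reproducible truth at desk scale.

Read data are two-stage samples: pool allele count ~ Binomial(2n, p) for a
pool of n diploids (defaults 18/25/22), coverage ~ Poisson(μ) (defaults
44/36/56), alt reads ~ Binomial(C, pool frequency), then each read flips
to a uniformly random other base with probability 0.001 (a quality-free,
strand-agnostic error model, matching the parser's ignoring of the quality
column). Output is mpileup, sync, a truth BED of sweep spans and a config
echo; everything is a deterministic function of one integer seed.

What the simulator does **not** emulate — and hence what passing tests do
not show about real data: linkage disequilibrium (sweeps are spans of
co-selected unlinked sites, not haplotype structure), mapping/reference
bias, indels, base-quality structure, GC-dependent coverage, and
chromosome-scale heterogeneity in recombination or diversity. Recovery
rates on simulated sweeps are therefore an upper bound on what identical
settings would achieve on real alignments.

## Problem sizes and numerical choices

The shipped validation runs use one 10 Mb chromosome (≈ 20,000 sliding
windows) for scan-level checks, 20,000 sites for the drift calibration at
t ∈ {10, 50, 200}, 10⁴ windows for the null-mean check, and a dense 500 kb
region for π (the default sparse design leaves π windows below the
covered-fraction rule, as it would for any SNP-only input). Quantiles use
linearly interpolated order statistics (the conventional default; no
method is canonical for the original analysis, which is why thresholds can
be pinned). Window F_ST with ΣD = 0 is undefined and excluded downstream.
The logistic sweep is evaluated in its decay form p₀/(p₀+(1−p₀)e^{−st}) so
large s·t underflows to fixation instead of overflowing. Monte-Carlo
assertions use three standard errors, with block-wise standard errors for
ratio-of-sums statistics.

## Known limitations

* Base qualities are parsed but ignored; any quality filtering must happen
  upstream.
* Percentile thresholds are computed over each pair's defined windows
  separately; selection then requires joint definedness. If the original
  analysis took percentiles over the jointly defined grid instead, cutoffs
  would shift slightly — pinned thresholds sidestep the ambiguity.
* The QTL TSV reader accepts one documented minimal dialect
  (`qtl_id chrom start end trait source`, 1-based inclusive) rather than
  guessing database export formats.
* Per-breed π ordering in the simulator follows branch lengths (SB,
  with the shortest total branch, is most diverse); matching a specific
  observed per-breed π ordering would require branch-specific Ne, which
  the generator does not model.
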