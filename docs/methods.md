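# Methods

## Scope and model

`tajscan` estimates, in non-overlapping genomic windows, the three
classical summaries of intraspecific variation — the number of
segregating sites S, the mean number of pairwise differences k̂, and
Tajima's D — and calls selection candidates from the percentile tails of
the observed genome-wide D distribution. The target setting is a small
panel of resequenced strains (the default assumes five diploid isolates,
n = 10 sequences) genotyped against a reference, with repeat/low-coverage
regions masked.

All estimators are computed from per-site allele counts, never from
phased haplotypes. S, k̂ and D depend only on allele frequencies, so
unphased diploid genotypes carry the full information; this is what makes
pooled or short-read-called strain panels usable. k̂ uses the unbiased
frequency form `Σ_sites n/(n−1)·(1 − Σ_a p_a²)`, which equals the
average Hamming distance over all C(n,2) sequence pairs (the test suite
checks this equivalence against an explicit pair loop). Multi-allelic
sites enter through the generalized heterozygosity; indels and symbolic
alleles are excluded by default because the statistics assume single-
nucleotide variation.

## Sample-size constants and the beta approximation

The constants a₁, a₂, b₁, b₂, c₁, c₂, e₁, e₂ follow the standard
normalization of D. Two degenerate corners are handled explicitly:
windows with S = 0 have no defined D (status INVARIABLE), and S = 1 with
n ≤ 3 makes the variance term vanish (e₁ = 0); both return `None` with
distinct reason codes rather than propagating non-finite values.

D is bounded: `D_min = (2/n − 1/a₁)/√e₂` (all singletons) and
`D_max = (n/(2(n−1)) − 1/a₁)/√e₂` (all sites at half frequency, S → ∞).
The theoretical null is approximated by a beta density on
`[D_min, D_max]` rescaled to mean 0 and variance 1. The two shape
parameters have a closed form under those constraints
(`α = −D_max(1 + D_min·D_max)/R`, `β = −D_min·(−D_min·D_max − 1)/R` with
`R = D_max − D_min`); quantiles come from `scipy.stats.beta.ppf`, and the
inversion is verified to 1e−8 by evaluating the CDF at the returned
points. For n = 10 at 95% coverage this yields (−1.733, 1.975).

## Window scan

Defaults: 1000-bp non-overlapping windows, 90% minimum callable
fraction, ploidy 2. Callable fraction subtracts masked bases and sites at
which *any* strain lacks a genotype (a completeness requirement across
the whole panel); a missing site inside a masked region is not double-
counted. Windows fall into exactly three states — discarded (low
coverage), invariable (covered, S = 0), analysed — and the bookkeeping
counts are emitted so that the three always sum to the total.

π per site divides k̂ by the window's callable sites rather than by the
nominal window size, so partially masked windows are not artificially
deflated. Watterson's θ is reported on the per-window scale (S/a₁); the
per-site value is recoverable by dividing by callable sites. A trailing
partial window at a chromosome end is computed and flagged but excluded
from the D distribution by default, because unequal window lengths
distort S-based statistics; a config flag includes them.

## Empirical confidence limits

Demography moves the whole genome's D distribution, so theoretical limits
misclassify under non-equilibrium histories. The correction implemented
is the empirical-percentile device: the upper significance region is the
largest block of extreme observed values whose mass does not exceed the
per-tail fraction (default 2%), and symmetrically below. Windowed D is
discrete, so tied runs can straddle the nominal percentile; ties are
treated as indivisible blocks. The default ("exclude") policy drops a
straddling block, guaranteeing achieved mass ≤ the request; the
alternative ("include") policy flags the whole straddling run, which can
overshoot. Both are exposed because either behaviour is defensible when
the discreteness forces a choice between recording less or more than the
nominal tail. The reported limit is the least extreme *flagged* value
(the cut D value); when even the most extreme tied run overshoots under
the exclude policy, no window is flagged and the limit is undefined.

Classification uses `D ≥ upper` / `D ≤ lower`, and decreasing the tail
fraction can only remove flags (checked property).

## Gene mapping

A gene is *analysed* when more than 50% of its span lies in analysed
windows — the denominator rule. Significance then requires any overlap
with a significant window: the span rule gates eligibility, overlap
decides the call. A gene overlapping significant windows of both signs
takes the sign of the window with maximal |D| (ties resolve positive);
the conflict is recorded on the classification and logged, so the
alternative both-counted tally can be audited. Every gene receives
exactly one class, so positive + negative = total significant genes.

## Contrast statistics

- χ² on 2×2 tables is the plain Pearson statistic with df = 1 and **no**
  continuity correction — the convention that matches published scan
  contrasts of this kind.
- Fisher's exact test is two-sided by probability summation (all tables
  with the same margins whose point probability does not exceed the
  observed one), computed through scipy's log-space hypergeometric
  machinery; the tail-doubling convention is available behind a flag. The
  test suite checks equivalence against a from-scratch log-factorial
  enumeration, exhaustively for small totals and on a sampled grid up to
  totals of 200.
- The rank-sum statistic is reported on the pair-count scale (number of
  (x, y) pairs with x > y plus half the ties), with a tie-corrected
  normal approximation — the scale common statistical software prints.
- The two-sample t defaults to pooled variance with df = n₁ + n₂ − 2.
  Published between-scan comparisons of this design sometimes print df
  that match neither pooled nor Welch bookkeeping exactly; the package
  reports its own df explicitly.
- The expression contrast emits, per selection category (significant,
  significant-positive, significant-negative), Fisher tests of the
  differential class against the non-differential class and against the
  global scan — six comparisons — plus the full count/percentage table.

## Synthetic-data generator

Each window receives an independent genealogy for the n = strains ×
ploidy lineages (free recombination between windows, none within — the
independence the windowed scan implicitly assumes), and infinite-sites
mutations at rate θ/2 per branch-length unit, so E[k̂] = θ and
E[S] = θ·a₁ per window. θ defaults to 5 per 1-kb window, a mid-range
value for strain panels of this kind; the masked fraction defaults to 5%
in random blocks of 200–800 bp, and diploid genotypes pair consecutive
haplotypes (no inbreeding parameter).

Selection regimes are engineered structurally rather than by forward
simulation:

- **balancing** multiplies the two root-adjacent branch lengths of a
  neutral genealogy by a stretch factor (default 5), emulating an
  anciently balanced split; at stretch 5 and θ = 5 this lifts mean D by
  ≈ 0.4 and puts roughly 10% of windows beyond the theoretical upper
  limit — a deliberately moderate, realistic signal;
- **sweep** uses a star genealogy at depth `1 − 1/n` (half the expected
  neutral tree height `2(1 − 1/n)`), making every variant a singleton and
  D strongly negative.

The generator emulates the statistical structure the scan consumes —
window-scale θ, masking, gene spans, regime mixtures — and is
byte-deterministic per seed. It does **not** emulate linkage within
windows beyond a single genealogy, relatedness structure among strains,
sequencing or genotype-calling error, coverage heterogeneity beyond the
binary mask, or realistic gene architecture (introns/exons). Passing
tests therefore demonstrate correctness of the estimators and of the
percentile machinery under the stated model, not robustness to
real-data artefacts upstream of the VCF.

An expression-class planter assigns DIFFERENTIAL labels at base rate 1/3
(typical of induced-protein panels), with the odds multiplied for genes
overlapping balancing windows, to exercise the contrast stage against a
known enrichment direction.

## Problem sizes and numerical choices

Monte-Carlo checks in the test suite use 2,000 neutral windows (three
seeds) for calibration — mean D within [−0.15, 0.10], mean θ̂_W within 5%
of truth, mean S within 3% of θ·a₁, beta-limit coverage 95% ± 2% — and a
2,000-window genome with 10% balancing for end-to-end enrichment
recovery (odds ratio of planted windows among significant-positive
calls > 1). These sizes put the Monte-Carlo error comfortably inside the
asserted bands while keeping the full suite under a minute. VCF records
failing FILTER are dropped by default (standard calling hygiene;
configurable). Internal coordinates are uniformly 0-based half-open;
GFF3 is converted at the boundary.

## Known limitations

- The empirical-percentile device fixes the flagged fraction by
  construction, so *between*-genome comparisons of significant-window
  counts are uninformative; compare distributions instead (the compare
  stage's K-S/rank-sum/t tests).
- With n ≤ 3 sequences the variance constants degenerate; the scan
  requires n ≥ 4 for defined D values.
- The simulator's balancing signature is a two-deep-clade caricature;
  real balanced polymorphisms with recombination produce narrower,
  messier peaks.
- No per-window p-values are attempted: the output is a ranked outlier
  set, which is what the percentile approach can honestly deliver.
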