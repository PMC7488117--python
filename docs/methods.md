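# Methods

## Harmonization model

Two call sets describing one individual are paired on (chromosome,
1-based position). Only sites genotyped — present and non-missing — on
both platforms enter any metric; a missing call on either side removes
the site. The VCF side anchors the allele vocabulary: A = REF, B = first
ALT, C = second ALT (ALT order as written in the record, which makes the
B/C assignment deterministic). Records with a FILTER value other than
`PASS`/`.` and records with more than two ALT alleles are dropped.

Array reports carry plus-strand allele letters with no reference
designation, so reconciliation proceeds in two steps: direct set
membership in {REF} ∪ ALTs, then reverse complement. For palindromic
biallelic SNVs (A/T and C/G), a strand flip is undetectable from the
alleles themselves; markers of this kind that fail the direct match are
counted as strand-ambiguous and excluded rather than guessed. All
exclusions (missing, unreconcilable, ambiguous, excluded chromosomes)
are tallied in a `HarmonizeReport` — harmonization never raises on bad
markers.

Indel alleles are compared through I/D symbols: at a biallelic indel
site the longer of REF/ALT is I (insertion allele), the shorter D,
matching the array convention for simple indels. Indel sites whose
alleles cannot be ordered by length (equal lengths, or two ALTs) are
excluded and counted. Haploid genotypes are treated as
homozygous-equivalent pairs; the sex and mitochondrial chromosomes are
normally excluded by the caller anyway (`exclude_chroms` is MT/X/Y for
males, MT for females).

## Metric definitions and numerical policy

Per-class reduction of the 6×6 matrix and the weighted/mean combination
rules are described in the README. Numerical conventions:

- A metric with an empty denominator is `None` ("undefined"), never 0.
- Per-class precision/sensitivity terms with zero denominator carry zero
  weight in the weighted sums (their weight is zero by construction).
- The accuracy/specificity means run, by default, over the classes with
  a nonzero row or column sum ("present" classes); `class_universe="all"`
  forces all six. Per-class accuracy is never NaN for a nonempty matrix,
  so the averaging convention — not NaN exclusion — is what decides the
  accuracy value; the present-classes default is the convention under
  which the package's validation-subset accuracy numbers are defined.
- Non-reference concordance = (trace − C\[AA,AA\]) / (N − C\[AA,AA\]);
  non-reference sensitivity = (trace − C\[AA,AA\]) / (sum of non-AA truth
  rows). These follow the operational definitions used throughout the
  package; other conventions exist in the literature.
- `symmetrize_metrics` averages the two role assignments element-wise; a
  symmetrized value is defined only when both directions define it.
  Genotype concordance, precision and sensitivity are transpose-invariant
  (micro-average identity), so symmetrization only affects the averaged
  metrics.

On the packaged validation table no external reference allele is
available, so class labels are assigned site-locally with A = the
allele most frequent in the Sanger (truth) genotype, ties broken by
frequency across all three genotypes, then lexicographically. The
micro-averaged precision is provably independent of this labeling (it
equals the fraction of exactly matching genotype pairs); the labeling
only decides which off-diagonal cell a disagreement occupies.

## Discordance mapping

Per-chromosome discordance is the share of paired sites whose classes
differ, reported per chromosome and pooled. Neighbor-distance pairs
(d_prev, d_next) are computed per concordance group and chromosome for
interior variants only; their Gaussian KDE is estimated in log10 space
(Scott's-rule bandwidth, overridable) on a grid padded 0.75 log units
beyond the data, which keeps the grid integral within a few percent of
1. There is no standard scalar for how evenly such a distance cloud
hugs the diagonal; the package exposes the KDE grid plus
`bisectrix_deviation` = mean |log10 d_prev − log10 d_next| as its own
summary construction.

Validation-region selection is a greedy maximal cover: repeatedly take
the window of span ≤ 500 bp (one Sanger read) holding the most
not-yet-covered discordant sites — ties resolved to the leftmost window
— and emit the tight span of the covered sites. Anchoring candidate
windows at uncovered site positions is exhaustive, since any window can
be slid right until its leftmost covered site is its start. Reported
region bounds are the tight discordant span; the published windows
include primer-design padding (one printed row spans 510 bp), so
padding is a separate `pad` parameter used only for attaching nearby
concordant sites and is excluded from the span constraint.

## Quality analysis

Group comparisons use Welch's unequal-variance t-test (two-sided,
α = 0.05). Groups with fewer than two finite values, or with zero
pooled variance, yield an undefined comparison instead of an exception.
Multiple testing across metrics is uncorrected by default, with an
optional Bonferroni flag — the uncorrected behaviour mirrors how such
exploratory metric scans are usually reported, and no hard-coded
expected values exist for this module's statistics.

Border scoring idealizes the Theta cluster centers at 0 (AA), 0.5 (AB)
and 1 (BB); true GenomeStudio cluster positions are per-marker and not
exported in final reports, a documented limitation. `theta_distance` is
the absolute distance from the called class's center (classes outside
the biallelic trio fall back to the nearest center), and `near_border`
flags distances above a quantile (default 0.9) of the concordant
group's distances.

## Synthetic data: what it emulates, and what it does not

The generator draws sites uniformly without replacement per chromosome
(counts proportional to chromosome length, GRCh38 autosomes by
default), assigns minor-allele frequencies uniform on \[0.05, 0.5\], and
draws diploid genotypes under Hardy–Weinberg equilibrium. Defaults:
100 000 sites (a desk-scale stand-in for a genotyping array's ~650 k
markers, keeping the full pipeline under a minute while binomial noise
stays well below the tested effect sizes), 4% indels, 0.2% triallelic
SNVs, platform miscall rates 0.002 (WGS-like) and 0.004
(BeadChip-like). Each platform call equals the truth with probability
1 − e and is otherwise a uniformly chosen *different* genotype class at
that site, independently across platforms — the simplest error model
that populates every confusion-matrix cell, including A/C and B/C. The
implied pairwise discordance, 1 − \[(1−e₁)(1−e₂) + e₁e₂/(k−1)\] ≈ 0.6%,
sits inside the 0.33–0.84% per-sample range the analysis targets.

Array intensities are generated as truncated Gaussians around the
called class's Theta center (sd 0.04); with border enrichment on,
discordant calls have their Theta mean shifted halfway toward the
nearest cluster border (0.25/0.75), reproducing the near-border excess
of discordant calls. GC score decreases deterministically with the
distance from the cluster center; R is log-normal; X/Y invert the polar
transform Theta = (2/π)·atan(Y/X) with R = X + Y; B allele frequency is
Theta interpolated against the canonical centers. All written floats
are quantized to the report's four printed decimals so file round trips
are bit-exact; VCF QUAL values are integral for the same reason.

All randomness derives from one seed through `numpy.random.SeedSequence`
children (separate streams for truth, each platform, annotations and
intensities), so a seed fixes every downstream number.

What the generator does **not** emulate: linkage disequilibrium and
realistic allele-frequency spectra, allele-dropout- or
cluster-misplacement-specific error modes, strand-flipped or
palindromic array manifests, genotype missingness, read-level artifacts
(alignment, repeats, low complexity) that plausibly drive real
discordance, and per-marker cluster geometry. Passing pipeline tests on
synthetic data therefore demonstrates correctness of the bookkeeping
and statistics, not that real platform discordance behaves like the
simulated miscall process.

## Known limitations

- The strand-reconciliation fallback (reverse complement, palindromic
  exclusion) is this package's design choice; array TOP/BOT manifests,
  where available, would resolve strand definitively.
- Site-local class labeling on the validation table is a convention;
  with a reference genome the labels could differ per site, though the
  micro-averaged precision cannot.
- Mean per-class accuracy depends on the class-universe convention (see
  above); values from other conventions are not comparable one-to-one.
- The border analysis inherits the canonical-center idealization and is
  qualitative for real data.
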