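# Methods

`recland` implements the two complementary views of a recombination
landscape used in avian population genomics — sex-specific genetic maps
from pedigree crossovers, and fine-scale per-bp rate tracks from
LD-based inference — together with the downstream statistics that relate
them: intrachromosomal shuffling, multi-scale windowed maps,
Lorenz/Gini landscape inequality, hotspot/coldspot annotation, and
cross-population comparison. Everything is exercised end to end on
synthetic data with known ground truth.

## Coordinates and units

All intervals are 0-based half-open (BED convention); crossover and
marker positions are 0-based bp points. Rates are per-bp per-generation
crossover probabilities (pyrho-style output after dividing rho by 4Ne):
1e-8 /bp = 1 cM/Mb. Map distances use Haldane's function,
d = −50 ln(1 − 2p) cM, which assumes no crossover interference.

## Genetic maps from crossover tables (`genetic_map`)

A crossover table records breakpoints observed in transmitted gametes
(one meiosis = one parent→offspring transmission). For each
adjacent-marker interval the recombination fraction is the proportion of
meioses with an **odd** number of crossovers in the interval — what
segregation data can detect; two crossovers between the same pair of
markers restore the parental phase. Interval distance is 100·c cM
(default, `direct`) or the Haldane correction −50 ln(1−2c); at the
marker densities used here the two differ negligibly, and the direct
mode makes the count-conservation identity (total cM = 100 × crossovers
per meiosis) exact.

End trimming removes markers within the terminal window whose separation
exceeds 2 cM, iteratively from the ends inward, re-anchoring positions
to zero. The window is expressed in markers (default 100, appropriate
for dense SNP maps); the analysis scripts use a 5-marker window on their
sparse 100 kb grids, since a 100-marker window would span entire
linkage groups there.

Pseudomarkers are placed every 10 kb from 0 and include the sequence
end; their cM position is the linear interpolation between flanking true
markers, clamping to the terminal values outside the marker span (no
segregation information exists beyond the outermost markers). The
sex-averaged map pools male and female meioses rather than averaging the
two maps, matching how pedigree mappers pool families.

## Intrachromosomal shuffling (`shuffling`)

r_intra for a chromosome is the mean over all pseudomarker pairs of the
probability that a crossover separates the pair, weighted by the squared
fraction of genome length the chromosome carries (L², the fraction of
locus pairs it holds). Two conventions are provided because "pairwise
map distance" is ambiguous for maps longer than 50 cM:

- `haldane_prob` (default): mean of haldane_p(|D_i − D_j|), a true
  probability bounded by 1/2;
- `morgan_linear`: mean of |D_i − D_j|/100 Morgans, the literal pairwise
  distance (for a uniform map of length T cM this equals T/300).

Both are O(n) per chromosome via prefix sums over sorted positions
(|ΔD| sums directly; for the Haldane mode, e^{−ΔD/50} factorises into
exponential prefix sums, centred to avoid overflow). Tests check both
against O(n²) brute force. Interchromosomal shuffling from independent
assortment is out of scope.

The two-sample KS statistic for placement comparison is the exact ECDF
sweep; its p-value is a label permutation (default 10⁴ permutations,
seeded) rather than the asymptotic formula, since placement samples are
bounded and heavily tied.

## Windowed maps and scaling (`landscape`)

Each rate-track interval is converted to cM once (p = r·len, Haldane),
and that cM mass is split pro-rata by bp at window boundaries. Applying
Haldane at the interval level — the resolution at which the rate was
estimated — makes window totals exactly additive across scales: a 1 Mb
window equals the sum of its 1 kb windows, and genome totals are
invariant to window size. An interval with r·len ≥ 0.5 is rejected as
pathological. Trailing partial windows are kept, with cM/Mb normalised
by their true length; they are flagged and excluded from Lorenz/Gini
(unequal support).

LD-based totals are confounded by Ne, so tracks are rescaled per
linkage group by f = (linkage cM)/(LD cM); per-interval cM are scaled
and converted back to rates, making per-lg totals match exactly. The
genome-average rate used by hotspot thresholds is total autosomal cM
over total autosomal Mb on the scaled track.

Window covariates: GC over unmasked bases; nucleotide diversity
π = Σ_sites 2p(1−p)·2n/(2n−1) divided by unmasked bp (the 2n/(2n−1)
factor is the unbiased correction for n diploids; fully masked windows
get π = NaN, flagged, never 0); gene counts, TSS presence, windows fully
contained in a CpG island, repeat and mask overlap bp.

## Inequality and hotspots (`hotspots`)

The Lorenz curve orders complete 10 kb windows by decreasing rate and
plots cumulative sequence fraction against cumulative cM fraction; the
Gini coefficient is twice the trapezoid area between the curve and the
diagonal, which tests verify equals the mean-absolute-difference form
Σ|x_i − x_j| / (2n²μ) to 1e-9. The sequence fraction holding 80% of the
genetic length is also reported. All-zero chromosomes get NaN.

Two hotspot definitions are deliberately separate:

- **Global (10 kb)**: hotspot if rate is strictly more than 5× the
  genome average, coldspot if strictly below 1/5×; a second set at
  ≥10× (inclusive) is reported separately. The strict/inclusive
  boundary choice mirrors the distinct "more than"/"at least" wordings
  of the two definitions.
- **Local (1 kb)**: RRR80 = focal rate / mean rate of the 40 kb flanks
  on each side, focal excluded. Near chromosome ends the statistic is
  computed when at least half the flank windows exist, otherwise left
  undefined (as when the flank mean is zero). Candidate windows need
  RRR80 ≥ 5 (a `strict` flag switches to >; the difference affects only
  boundary ties), a rate within 1–10 cM/Mb (LD-based hotspot inference
  has little power outside this band), and ≤500 bp of annotated
  repeats; runs of ≥2 consecutive candidates are emitted as hotspots,
  with both window and merged-run counts reported.

Element profiles divide the rate at every offset within ±40 kb of a
TSS-containing (or CGI-spanning) window by that element's own flank
mean and average across elements; a peak at offset 0 indicates
recombination concentrated on the elements.

## Population comparison (`popcompare`)

Populations are compared on window tables scaled to the same linkage
map. Pearson correlations are computed on log10(cM/Mb + 1e-6) because
per-window rates span orders of magnitude and are heavy-tailed; the
pseudocount keeps zero-rate windows. Subsampling pseudoreplicates are
emulated by independent noisy copies of the focal population's track;
the min–max of the five replicate sharing curves at offset 0 is used as
a heuristic noise envelope (matching the five subsets of the emulated
design), not a formal confidence interval.

## Synthetic data (`synthetic_data`)

The generator produces every input with the statistical structure the
analysis assumes, plus ground truth for recovery tests.

- **Genome**: 8 autosomal linkage groups of 90, 70, 50, 35, 25, 15, 10
  and 5 Mb — a desk-scale stand-in for a bird-like karyotype of ~40
  linkage groups spanning 5–90 Mb.
- **Background rates**: log-normal per 100 kb segment with arithmetic
  mean 2.33e-8 /bp (2.33 cM/Mb, the genome-average scale of the
  emulated system) and log-sd 0.7.
- **Hotspots**: 1 per Mb, 2 kb wide, multiplying the local background by
  Uniform(10, 50); 80% are centred on TSS/CGI elements (birds lack
  PRDM9, so hotspots concentrate at promoter-like features).
  Overlapping placements are dropped greedily.
- **Crossovers**: per meiosis and chromosome the tetrad receives one
  obligate crossover plus Poisson(0.5 × map Morgans) extras, giving the
  1–2 crossovers per chromosome of the emulated system. Positions are
  drawn from a per-sex mixture of a symmetric U-shaped Beta(1/2, 1/2)
  density on relative position (telomere bias; weight 0.7 male, 0.4
  female) and a uniform density, multiplied by the truth track and
  renormalised, so family crossovers and the LD landscape are mutually
  consistent. By default each tetrad crossover is recorded only if
  transmitted to the sampled gamete (probability 1/2) — this is what
  pedigree data observe, and it is why one obligate crossover produces
  a 50 cM map; `record="tetrad"` keeps all crossovers. No crossover
  interference is modelled (a known limitation); extra crossovers are
  independent.
- **Diversity**: window-level π = 0.030 + 0.0015·ln(rate) + noise,
  clipped at 0; segregating sites are Poisson with allele frequencies
  Uniform(0.05, 0.5), with the site count calibrated so the expected
  heterozygosity sum matches the target π.
- **Replicates**: multiplicative log-normal noise exp(N(0, sd)) applied
  on 10 kb segments (estimation error of LD inference is locally
  correlated), preserving the expected log-rate.

Everything is driven by `numpy.random.default_rng` seeded from
`SimParams.seed` with a distinct stream per generator, so identical
parameters and seed give identical outputs.

What the generator does **not** emulate: coalescent noise structure
(replicate noise is i.i.d. log-normal per segment, not genealogy
sampling), crossover interference, chromosome-size-dependent landscape
shape (all lgs share one background model, so per-lg Gini varies little
and its correlations with length and diversity are weak in the
synthetic study), GC-biased gene conversion, sequencing or genotyping
error, and real marker ascertainment. Passing tests therefore show the
statistics are computed correctly and recover planted structure under
realistic noise — not that the generator reproduces every property of
real data.

## Mappability mask

The exact mask re-implements aligner-based mappability for error-free
synthetic genomes: the genome is split into 150-mers every bp, a read is
unique when its sequence occurs exactly once genome-wide counting both
strands (canonical k-mer hashing; reads with ambiguous bases are never
unique), and 150 bp blocks where fewer than 90% of overlapping reads are
unique are masked. This is deterministic and dependency-free, and
agrees with alignment-based masking when reads contain no errors.

## Problem sizes and numerical choices

The test suite and analysis scripts run at desk scale: 8 lgs / 300 Mb
for the full pipeline, 10–100 Mb single chromosomes for recovery
experiments, 10⁴ meioses for map-rebuilding checks, and 10⁴
permutations only where the p-value matters. Recovery of planted
hotspots is evaluated on a 100 Mb chromosome with a 0.15 cM/Mb
background (log-sd 0.15) so that 10–50× hotspots fall inside the
1–10 cM/Mb band where the local-hotspot filter has power, with
replicate noise sd 0.2; sensitivity is the fraction of planted hotspots
overlapped by a called run and FDR the fraction of called runs
overlapping no planted hotspot. Floating-point tolerances in tests are
1e-9 for oracle equivalences, 1e-12 for closed forms, and 1e-6 cM for
additivity identities.
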