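# Methods

This package reimplements, as one tested toolchain, the analysis stages of
a conifer genome survey and its downstream SSR-marker diversity study:
genome-size estimation (flow cytometry and k-mer spectrum), microsatellite
mining and primer screening, codominant diversity statistics, distance
clustering, model-based structure inference with Evanno model selection,
and AMOVA-based differentiation and gene flow. Because the underlying raw
reads and genotype tables of such surveys are typically unavailable, every
stage is paired with a seeded synthetic-data generator that reproduces the
statistical structure the stage assumes; the generators' parameters are
the study conditions the estimators are validated against.

## Flow cytometry

Sample 2C DNA content is the intensity ratio of the sample's G0/1 peak to
a co-processed standard's, times the standard's known 2C value; base pairs
follow from 1 pg = 0.978×10⁹ bp, halved for the 1C genome size. Replicates
with a within-peak coefficient of variation above 5% (configurable) are
excluded — the instrument-side quality rule. When several standards are
run (e.g. barley, 2C = 10.43 pg, and *Populus trichocarpa*, 2C = 0.98 pg)
their surviving replicate estimates are pooled with equal weight; the
pooling rule is a package choice, as is interpreting the recorded CV as a
per-replicate peak property. The estimator is exactly linear in both the
intensity ratio and the standard value, which the tests assert directly.

## K-mer spectrum estimators

K-mers are counted with k = 17 by default; canonical counting (a window
and its reverse complement share a key) is on by default, the behavior of
standard counters on unstranded reads. Windows containing N are skipped.

Peak finding smooths the count-vs-depth curve with a centered moving
average (width 3 bins) and takes local maxima; between equal candidates
the higher depth wins. The *main* (homozygous) peak is the candidate
closest to an externally supplied prior depth when one exists — in a
survey the flow-cytometry size plays this role, discriminating the
half-depth heterozygous peak from the full-depth peak — otherwise the
candidate carrying the most k-mer mass.

Genome size is floor(total k-mer number / main peak depth). "Total"
excludes the sequencing-error spike: depths below max(3, peak/4) are
dropped before the division. The cutoff rule is a package choice; when
counting k-mers from assembled sequence rather than reads the pipeline
uses no cutoff, since an assembly has no error spike and depth-1 k-mers
are genuine single-copy sequence.

The heterozygous signal is the k-mer mass between the cutoff and the
midpoint of the half-depth and full-depth components (0.75 × peak),
minus the left tail that the homozygous Poisson component itself places
below that split (a Poisson at the peak depth, scaled to the observed
modal height). Without the subtraction a zero-heterozygosity spectrum
reports a spurious signal — the Poisson(30) left-tail mass below
0.75 × 30 is ~3.5% — which the tests require to stay below 2%. Converting the signal into a
per-base rate is done by *self-calibration*: spectra are simulated on a
grid of known rates at the same depth and k, the signal measured on each,
and the observed signal inverted by monotone interpolation. The
calibration grid is repeat-free; an estimated repeat fraction divides the
observed signal by (1 − repeat fraction) first. This calibration is a
stand-in for the reference-genome simulation the original workflow used;
it recovers a simulated rate of 0.02 to within ±0.005 in the tests but
has not been validated against real read sets.

The repeat fraction is the mass beyond a multiplier (default 2×) of the
main peak over non-error mass — a deliberate threshold heuristic in place
of a full mixture-model fit, documented as approximate.

GC content is (G+C)/(A+C+G+T) with N excluded, profiled in 10-kb
non-overlapping windows; a trailing window is kept only if it covers at
least half the window size.

## SSR mining

The scanner reports maximal perfect tandem repeats of primitive 2–6 bp
units with per-unit-size minimum repeat counts {2: 6, 3: 5, 4: 4, 5: 4,
6: 4}. Primitivity (the unit is not a repetition of a shorter unit)
guarantees each run is reported at its smallest period exactly once, and
excludes mononucleotide runs from being reported as dinucleotide loci.
Runs are broken at N. Coordinates are 0-based half-open internally and
1-based inclusive in reports. Two maximal runs of different period (or
adjacent equality stretches of the same period) can overlap by up to
unit−1 bases; detected loci are made non-overlapping with a deterministic
leftmost-wins rule. Compound or interrupted microsatellites are reported
as separate perfect loci. The scanner is validated against an independent
brute-force enumerator of every (start, period) maximal run on a thousand
random sequences, including N-containing ones.

Motif classes are strand- and phase-independent: the label "X/Y" takes X
as the lexicographically smallest rotation over the motif and its reverse
complement and Y as the smallest rotation of X's reverse complement
(e.g. CTT → AAG/CTT, GTT → AAC/GTT). Under this rule the AT class renders
as "AT/AT" (AT's reverse complement is a rotation of itself), where some
published tabulations write "AT/TA".

SSR density is reported the survey way: non-N bases per locus.

Primer screening scans all left-flank forward and right-flank reverse
windows around a locus and keeps pairs in which both primers satisfy
length 18–23 nt (optimum 21), GC 40–70% (optimum 50%) and Tm 50–70 °C
(optimum 55), with the product spanning the locus at 100–300 bp (optimum
150). Tm uses the basic GC formula 64.9 + 41·(GC−16.4)/len, the quick
mode of batch primer-design tools; nearest-neighbor thermodynamics,
dimer/hairpin screening and specificity checks are out of scope.
Candidates are ranked by the summed |value − optimum| penalties with GC
expressed in percent; ties break on coordinates.

## Diversity statistics

With allele frequencies p₁…pₙ at a locus (two observations per diploid
call; missing calls excluded locus-wise):

* Na = number of observed alleles; Ne = 1/Σp², tied to the raw expected
  heterozygosity by He_raw = 1 − 1/Ne exactly (asserted to machine
  precision);
* Ho = heterozygous calls / non-missing calls;
* He defaults to Nei's unbiased form (2n/(2n−1))(1 − Σp²) — consistent
  with the published per-locus table this package ships, whose He column
  sits closer to the corrected than the raw value at n = 199 — with the
  raw form behind a flag;
* I = −Σp ln p (natural log);
* PIC = 1 − Σp² − Σᵢ<ⱼ 2pᵢ²pⱼ², computed via the identity
  Σᵢ<ⱼ2pᵢ²pⱼ² = (Σp²)² − Σp⁴ and checked against the explicit double sum.
  PIC ≤ He_raw always.

Nei's (1983) Dₐ between frequency profiles is 1 − (1/L)ΣₗΣₐ√(xy).
Individual-level distances treat each individual as a population of two
alleles per locus; loci missing in either member of a pair are dropped
from L for that pair.

## Neighbor joining and bootstrap

Standard Saitou–Nei agglomeration with two deterministic conventions:
Q-matrix ties join the lowest-index pair, and a negative branch length is
clamped to zero with the deficit moved to its sister so the pair's summed
length is preserved. On additive matrices the generating topology and
branch lengths are recovered exactly (tested), and topologies agree with
an independent NJ implementation. Bootstrap resamples loci with
replacement; each internal edge of the reference tree is scored by the
fraction of replicate trees containing the same leaf bipartition.

## Admixture model and K selection

The structure stage is a Gibbs sampler over the standard admixture model:
individual ancestry vectors qᵢ (Dirichlet(α) prior, α fixed at 1.0 — no
α updating), group allele frequencies (symmetric Dirichlet(λ = 1.0)), and
a latent origin group per allele copy. Missing genotypes are skipped, not
imputed. The observed-data log likelihood is recorded every sweep;
reported Q and P are posterior means over post-burn-in sweeps. The
sampler's inner loop is a compiled (numba) kernel; a run is bit-identical
given its seed.

L(K) per run is mean(trace) − var(trace)/2. The Evanno statistic is
ΔK(K) = meanᵣ|Lᵣ(K+1) − 2Lᵣ(K) + Lᵣ(K−1)| / sdᵣ(L(K)) over replicate
runs, undefined at the grid endpoints; a zero standard deviation is
floored at 10⁻⁶ with a warning. Replicate Q matrices at the selected K
are aligned by exact search over column permutations (k ≤ 8) against an
incrementally built running mean, then averaged and renormalized — a
small-K stand-in for the full CLUMPP search. Individuals are assigned to
their argmax group when the top membership reaches 0.6 (inclusive), else
labeled mixed.

The default MCMC lengths are scaled down (burn-in 2,000 / 10,000 sweeps)
so that a six-point K grid with ten replicates completes in minutes on
one core; survey-scale settings (50,000 / 500,000) are available by flag.
At the scaled-down settings, model selection on the three-group reference
simulation is a stochastic property: ΔK at K=2 (driven by the large
L(1)→L(2) gain and the small replicate sd there) competes with ΔK at the
true K=3, and an occasional seed resolves the race toward K=2. The
acceptance-scale settings select K=3 in the large majority of seeds; this
variability is inherent to the second-difference statistic at desk scale,
not reduced by averaging in this implementation.

## AMOVA, Fst and gene flow

Variance is partitioned at the *allele-copy* level: each diploid
contributes two haploid units per locus, and the squared distance between
units is the number of loci at which their alleles differ. The classical
sums-of-squares decomposition over the unit-level distance matrix gives
the variance components for one-level (groups) or two-level (subgroups
nested in groups) designs, with negative components floored at zero for
percentage reporting (flagged). The allele-copy convention is what makes
ΦST a direct estimate of Fst: in a genotype-as-unit analysis the two
copies of an individual are independent draws given its group, so the
among-group variance doubles relative to the within spread and ΦST
estimates 2F/(1+F) (~0.33 at F = 0.2) rather than F. The unit-level
estimator recovers a Balding–Nichols F of 0.2 to within ±0.05 at 40 loci
and ±0.03 at 500 (tested). A genotype-level 0/1/2 allele-difference
matrix remains available for reporting.

Permutation tests (default 999, +1 smoothing so p ≥ 1/1000) keep each
individual's two copies together: the among-group test permutes whole
subgroups across groups when a nested design is present, else individuals
across groups; the among-subgroup test permutes individuals within their
group. Pairwise Fst runs each group pair as a two-group AMOVA and equals
the corresponding two-group ΦST exactly.

Gene flow uses the island-model formula Nm = ¼(1/Fst − 1), with the
among-group ΦST as the default input — the reading under which a 21.33%
among-group fraction yields Nm ≈ 0.92.

## Synthetic data

* **SSR genomes** — backgrounds are rejection-sampled until the scanner
  itself finds nothing, then motifs are planted at requested positions
  with one flanking base forced outside the motif alphabet so a planted
  run cannot extend; the planted list is therefore the complete truth.
  Planted motifs must be primitive.
* **K-mer spectra** — simulated directly as Poisson depth mixtures rather
  than via read simulation (the estimators only consume histograms): an
  error spike at depth 1–2, a heterozygous component of two distinct
  k-mers at half depth for a fraction 1 − (1−h)ᵏ of unique positions, the
  homozygous peak at the mean depth, and a repeat tail with copy numbers
  ≥ 4 (3 + geometric, mean 8) carrying the requested fraction of total
  mass. Total depth-weighted mass stays ≈ genome size × depth.
* **Genotypes** — the Balding–Nichols model: per-locus base frequencies
  from a flat Dirichlet over 5 alleles (the panel-typical allele count),
  group frequencies from Dirichlet(p₀(1−F)/F), so F is an explicit,
  recoverable parameter; two independent allele draws per individual per
  locus, optional Dirichlet-α admixture of group frequencies, and
  whole-genotype missingness at a configurable rate. Loci are unlinked
  and alleles are exchangeable labels — no mutation model, no LD.
* **Flow cytometry** — lognormal replicate peak intensities at a given
  CV around means with the requested ratio; the generating CV is recorded
  per replicate so quality filtering can be exercised.

The generators reproduce the *statistical* structure the estimators
assume, not real data's failure modes (allele dropout, stutter, linked
loci, GC-coverage bias, contaminant k-mers); passing tests demonstrate
correctness of the estimators under the stated models, not robustness to
those artifacts.

## Scale choices and determinism

All randomness flows through numpy `SeedSequence` splitting from a single
integer, so every experiment is reproducible bit-for-bit. Reference
problem sizes were chosen to exercise each method's operating regime on a
single core: megabase-scale spectra, ten-kilobase SSR genomes, panels of
~180 diploids × 40 loci, ten-replicate K grids. Printed numbers in
reports use four decimals except genome sizes (integers) and p-values.
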