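# Methods

## The model

A short-read dataset from a p-ploid genome is summarized by its k-mer
spectrum f(x): the number of distinct k-mers observed at coverage depth x.
`ploidyscope` models the spectrum as a mixture of 2p negative binomials
whose means sit at integer multiples of the per-homolog (monoploid) k-mer
coverage λ:

    f(x) = G · Σ_{i=1}^{2p} α_i · NB(x; mean = iλ, size = iλ/ρ)

- **G** — distinct k-mers in the monoploid genome (repeats counted once).
- **λ** — monoploid k-mer coverage. For reads of length R with per-base
  error rate e, λ ≈ fold · (R−k+1)/R · (1−e)^k; the i-th peak collects
  k-mers present in exactly i copies across the polyploid genome.
- **ρ** — overdispersion: the NB variance is mean·(1+ρ); ρ→0 recovers
  Poisson coverage. Default bounds (1e-6, 50), started at 0.5.
- **d** — the fraction of distinct monoploid k-mers occurring exactly twice.
  Repeats above two copies are not modeled as mixture components (their mass
  still counts toward genome length).
- **α_i** — the expected number of k-mer sequences at copy number i
  contributed by one distinct monoploid k-mer; determined exactly by the
  combinatorics below.

### Topologies and heterozygosity forms

The homologs of a polyploid are related by a *ranked* binary tree shape,
represented as a maximal refinement chain in the lattice of set partitions
of the homolog index set: each rank splits exactly one block. Ranked shapes
(not plain tree shapes) are the correct notion here — they count 1, 1, 2, 5,
16 for p = 2..6, matching the known tetraploid pair (autotetraploid
`(, (, (, )));` and allotetraploid `((, ), (, ));`).

Each chain partition induces one *heterozygosity form*: the pattern (aab,
aabb, aabc, …) of which homologs share a nucleotide at a locus. A topology
on p homologs carries p−1 forms; the homozygous pattern aa…a holds the
complementary probability. *Nucleotide divergence* is the sum of the form
rates — the fraction of loci at which the homologs are not all identical.

### α via Möbius inversion

With per-site forms drawn independently, the probability that all homologs
agree within every block of a partition υ across all k sites of a k-mer is
Q(υ)^k, where Q(υ) sums the rates of the forms whose partition υ refines
(plus the homozygous rate). Möbius inversion on the partition lattice turns
these "coarser-or-equal" probabilities into exact probabilities:

    P(identity partition = τ) = Σ_{υ ⪰ τ} μ(τ, υ) · Q(υ)^k

where μ is the product over blocks of υ of (−1)^(n−1)(n−1)! for n sub-blocks
of τ. Unique k-mers (weight 1−d) contribute E[#blocks of size i] to α_i.
Two-copy k-mers (weight d) occupy two loci with independent identity
partitions; the block containing homolog 0 at each locus carries the
ancestral sequence shared between the loci, so those two blocks merge into
one sequence at the summed copy number while every other block remains
distinct. This construction reproduces the published diploid four-term
closed form exactly (tested to 1e-12) and conserves copy mass:
Σ i·α_i = p(1+d).

Because a topology's site partitions are totally ordered by refinement, the
identity-partition distribution also has a cumulative-rate shortcut; the
implementation uses it for speed and the test suite verifies it against the
general Möbius formula and against a 10⁶-replicate Monte-Carlo simulation
of monoploid k-mers (agreement within 3 standard errors for p = 3, 4).

## Fitting

Fitting minimizes squared residuals on the *transformed* spectrum x·f(x)
(which amplifies higher-order peaks) over bins between the error valley (the
first local minimum of f scanning up from x = 1) and min(last bin,
20·p·peak). G is linear in the model and is profiled out in closed form at
every residual evaluation. The optimizer is scipy's bounded
trust-region-reflective damped least squares (bounds: rates and d in [0,1],
λ and ρ positive; convergence tolerances 1e-8, max 1000 evaluations).

Low-coverage spectra invite convergence to the wrong peak, so the fit is
restarted once per divisor m = 1..2p of the tallest transformed peak
(λ₀ = peak/m) and the lowest residual wins. Among residuals within 0.1% of
the best, the largest λ wins: a fully homozygous, non-repetitive spectrum
makes (λ, d=0) and (λ/2, d=1) *exactly* equivalent mixtures, and parsimony
resolves the tie toward the non-repetitive reading.

Genome length: polyploid length = Σ_{x ≥ valley} x·f(x) / λ̂ (total
non-error k-mer mass per unit of per-homolog coverage — repeat copies beyond
two are naturally included), monoploid length = polyploid/p. Lengths from
truncated histograms are flagged as lower bounds; the reader flags a final
bin more than 10× the median of the preceding ten as an overflow bin.

## Ploidy inference from k-mer pairs

Genomic k-mers above a coverage threshold (default: the error valley of the
count histogram) are scanned for pairs differing at exactly one nucleotide:
for each position, both orientations of every canonical k-mer are bucketed
with that position masked, and bucket collisions are the pairs. A k-mer in
more than one pair signals repeat structure; it is dropped with all its
pairs (a bucket of three or more mutually one-away k-mers is dropped
outright, which the ambiguity rule implies). The masked-bucket search is
exactly equivalent to brute-force all-pairs Hamming-1 comparison over both
orientations (property-tested on planted sets).

Writing CovA ≥ CovB, a structure with a major and b minor copies projects
onto ((a+b)λ, b/(a+b)) in (coverage-sum, minor-ratio) space. Structures are
annotated up to total copy number 8 (sufficient for an octoploid).

**λ estimation.** The initial estimate is the smoothed mode of CovB: the
minor allele of nearly every structure (AB, AAB, AAAB, AAABB, …) occurs
once, so CovB concentrates at λ regardless of ploidy. The estimate is then
refined by re-centering on the dominant smudge's median coverage sum. If
more than 10% of pairs then sit below the lowest predicted structure
(coverage sums < 1.55λ̂), the scale was read an octave high — the signature
of a repeat-dominated cloud whose CovB mode is 2λ — and λ̂ is halved and
re-refined. A coverage-sum-based grid search (mode/i scored by window
membership) was evaluated and rejected: halving λ maps every center set
onto a finer superset that always scores at least as well on the ~10-15% of
pair mass in inter-center coverage tails, making that scheme unidentifiable
at desk-scale coverage.

**Ploidy.** Pairs are assigned to the nearest center (coverage sums in units
of λ, ratios absolute); the ploidy is the total copy number of the smudge
with the most pairs. The call is flagged low-confidence when the dominant
smudge holds <10% of pairs or is a multiple of a smaller structure (AABB =
2×AB and the like admit a coarser reading at rescaled λ) — the latter is
exactly the failure mode reported for repeat-rich diploids being read as
tetraploid.

## The simulator

`simulate.run_design` generates: (1) a uniform random monoploid progenitor
of ~`size` bases in which a fraction d of distinct k-mers occurs twice
(exact extra copies of 5 kb segments of the unique part — so two-copy k-mers
arise from independent loci, matching the model's assumption); (2) p
homologs derived per site by drawing a heterozygosity form, with the block
containing homolog 0 keeping the progenitor base and the other blocks
receiving distinct substitutes (the model's ancestral-block convention);
(3) uniform single-end 100 bp reads at a chosen fold per homolog with
uniform substitution errors; (4) exact canonical k-mer counts (2-bit packed,
numpy) and the derived spectrum, plus the realized truth (divergence by site
census, repetitiveness by k-mer census of the progenitor).

Design choices worth noting:

- **Deterministic form embedding.** Each form uses exactly its chain
  partition. For caterpillar topologies the embedding is forced anyway; for
  the allotetraploid a randomized embedding would break the correspondence
  between simulator statistics and the fitted model.
- **Single-knob divergence.** Where a sweep specifies only a total
  divergence, the whole value goes to the coarsest form: one homolog group
  diverging is the first-order mode of heterozygosity, while finer forms
  require multiple hits at one site. Under an equal split, surviving pairs
  from the finest form would dominate at high divergence and collapse
  triploid calls near ~7% divergence, inconsistent with the reported
  behavior of this class of methods.
- **Alphabet limit.** Forms with more than four blocks (abcde and finer)
  cannot be realized at a single nucleotide site; the simulator rejects
  nonzero rates on them. Validation therefore uses p ≤ 4.

### What the simulator does and does not emulate

It reproduces uniform short-read coverage, substitution errors, two-copy
repeats, and form-structured heterozygosity — the data-generating process
the mixture model assumes. It does **not** emulate GC bias, PCR duplication
(ρ in real data), indels, paired ends, coverage waviness, or repeats copied
*after* divergence. That last omission matters for one reported phenomenon:
repeat pairs here land on paralog smudges (AAAB-like: ancestral three-copy
k-mer vs one variant), not on AABB, so the repeat-driven tetraploid overcall
of real repeat-rich diploids does not arise in-sweep; it is exercised
instead on a synthetic pair cloud (labelled synthetic in the tests). Passing
tests demonstrate correctness of the algorithms under the model's own
assumptions, not robustness to every artifact of real libraries.

## Problem sizes used in validation

Recovery and sweep tests use 1 Mbp monoploid progenitors (0.4 Mbp for some
unit tests), 15x per homolog for spectrum fitting and 25x per homolog for
pair analysis, 1% error, k = 21, and ≥10 random design points for the
recovery study — the same conditions as the full-scale study with the
genome scaled down, with acceptance tolerances widened threefold relative
to the full-scale mean absolute errors to account for the ~30x smaller
genome. Monte-Carlo oracle checks use 10⁶ replicates.

## Numerical notes and degenerate inputs

- Negative binomials are parameterized by (mean μ, size μ/ρ) so the variance
  is μ(1+ρ); the size→∞ (ρ→0) limit is Poisson.
- Histograms with strictly decreasing frequencies (no error valley) are
  rejected with advice that coverage is insufficient; an explicit
  `error_cutoff` override supports noiseless model-generated spectra.
- Rates are box-bounded to [0,1]; if a trial point's rates sum past 1 they
  are rescaled and a soft penalty pushes the optimizer back into the
  simplex.
- Empty fit ranges, empty pair sets, sub-minimum pair counts (<100), and
  unwritable outputs raise informative errors rather than guessing.
- All randomness flows from explicit integer seeds; identical seeds give
  byte-identical outputs.

## Known limitations

- Heterozygosity forms with >4 blocks cannot be simulated at nucleotide
  sites (model-side α computation has no such limit).
- The genome-length estimator counts k-mer mass above the error valley;
  genomic k-mers below the valley (a ~0.1-1% effect at 15x per homolog) are
  lost, and error k-mers above it are gained.
- λ and ploidy from pair analysis are only identifiable when at least one
  non-divisible structure (AB, AAB, AAAB…) carries appreciable signal; a
  genome whose only visible smudge is AABB-like is flagged, not resolved.
- Confidence intervals, GC-bias modeling, and >2-copy mixture components are
  out of scope.
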