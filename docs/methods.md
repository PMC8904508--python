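# Methods

This note documents the models, estimators, and numerical choices behind
adnakit, and what the synthetic-data generator does and does not emulate.

## The synthetic-data generator

**Allele frequencies on an admixture graph.** The root of a user-supplied
graph draws per-SNP frequencies i.i.d. Beta(a, b); the default a = b = 0.46
gives expected heterozygosity 2·E[p(1−p)] ≈ 0.2396, which puts
pseudo-haploid mismatch rates of unrelated pairs on the ~0.24 scale typical
of genome-wide capture panels in ancient-DNA work. Each drift edge of
length c applies a Balding–Nichols perturbation: the child draws from a
Beta with mean p and variance c·p(1−p) (shape k = (1−c)/c). For c ≥ 1 the
requested variance exceeds what any Beta on [0,1] supports and the draw
truncates to a Bernoulli(p) on {0,1}; such fixation/truncation events are
counted and reported on the frequency table. Admixture nodes mix their two
parents linearly, p = α·p_A + (1−α)·p_B, with drift accruing only on
drift edges below.

A consequence worth knowing: drift compounds multiplicatively
(E[p(1−p)] shrinks by (1−c) per edge), so the additive "sum of branch
lengths" reading of f2 is exact only to first order in c. All bundled
designs use c ≤ 0.1, where the second-order error is well below the block
jackknife SEs at the panel sizes used; the test suite's closed-form f2
oracle uses the exact compounded recursion.

**Genotypes and pedigrees.** Unrelated diploids draw Binomial(2, p) per
SNP (Hardy–Weinberg, no inbreeding, no linkage within populations — see
limitations). Pedigree links overwrite draws with Mendelian transmission:
duplicates copy the genotype vector; parent–offspring transmit one random
allele plus one population draw; full siblings share two simulated
parents; second-degree pairs are realized as half siblings (kinship 1/8).

**Pileups.** Read depth is Poisson(λ) per individual per site; each read
carries one of the individual's true alleles, a strand (fair coin), a
uniform position within a fixed read length, and base/mapping qualities of
which ~10% fall below the 30 threshold so quality gates have work to do.
Terminal deamination: with probability δ, a C within 5 bp of either read
end on a plus-strand read is emitted as T; on a minus-strand read the
read's own C→T appears as G→A in reference-strand representation. This is
the damage geometry that motivates the strand-restricted calling rule: at
C/T sites only minus-strand reads are damage-immune, at G/A sites only
plus-strand reads.

**Admixed chromosomes.** Each haplotype's local ancestry is a Markov
process along the genetic map: switch points arrive as a Poisson process
of rate g per Morgan and each switch redraws the source with probability
α/(1−α). Observed same-source tract lengths are therefore exponential
with mean 1/((1−α)·g) Morgans, and the ancestry autocorrelation at
distance d is exactly exp(−g·d). Alleles then draw from the local
source's frequency. The default map is uniform 1 cM/Mb.

**Reproducibility.** Every generator keys its RNG stream by
(seed, stage, group/individual/haplotype) through numpy `SeedSequence`
entropy pooling, so outputs are bit-identical for a given seed and
independent of evaluation order.

## Pseudo-haploid calling

Eligible reads satisfy base quality ≥ 30, mapping quality ≥ 30, base more
than `end_trim` (default 5) bp from both read ends, and base ∈ {ref, alt};
in single-strand mode, C/T sites accept only minus-strand reads and G/A
sites only plus-strand reads. One eligible read is drawn uniformly per
site per calling unit; no eligible read means missing. The draw's RNG is
keyed by (seed, chromosome, position, unit), so calls are invariant to
pileup row order and to SNP subsetting. Multiple libraries of one
individual are pooled before the draw by default (`unit="individual"`);
`unit="library"` calls each library separately, which is what duplicate
screening wants. End trimming is implemented as read-position filtering at
call time rather than rewriting stored reads.

## Relatedness from pairwise mismatch rates

For two pseudo-haploid call sets the expected mismatch rate is
(1−φ)·B, with φ the kinship coefficient and B the unrelated baseline
(≈ the population heterozygosity): duplicates ≈ B/2, first degree ≈ 0.75B,
second degree ≈ 0.875B. The baseline estimator single-linkage-clusters the
observed PMR values with a 0.03 merge gap (about half the duplicate/
first-degree separation at B ≈ 0.24) and takes the median of the most
populous cluster, on the assumption that most pairs are unrelated.
Classification assigns each pair to the nearest expected value —
equivalently, midpoint thresholds at {0.625, 0.8125, 0.9375}·B — and flags
pairs within 2 SE of two expected values as ambiguous. The binomial SE of
PMR at the default 3000-SNP overlap floor is ≤ ~0.008, small against the
0.03–0.06 class gaps. First-degree subtypes (parent–offspring vs full
siblings) are deliberately not distinguished: that requires genotype
likelihoods and IBD-state inference, for which the calls can be exported.

## f-statistics and the block jackknife

Per-SNP values follow the standard unbiased moment estimators
(f2 = (â−b̂)² minus â(1−â)/(n−1)-type corrections; f3 with the target's
correction only; f4 uncorrected). The f3 correction is disabled
automatically when the target population's counts come from pseudo-haploid
calls, where it is undefined. A SNP contributes to a statistic iff every
argument population has data there (n ≥ 2 where a correction needs it).
Aggregates are plain means over contributing SNPs; with unit SNP weights
this coincides exactly with ratio-of-sums aggregation, so no separate mode
is exposed.

Standard errors use the weighted delete-one-block jackknife (pseudovalue
form with h_j = n/m_j) over blocks of 5 cM in genetic distance, contiguous
within chromosomes; SNPs lacking a genetic position fall back to physical
position at 1 cM/Mb. With equal block sizes the formula reduces to the
ordinary delete-1 jackknife, which the tests exploit as a brute-force
oracle. A 200-replicate calibration keeps the jackknife SE within 25% of
the empirical SD of the estimator.

## qpWave and qpAdm

Both consume the matrix X_ij = f4(l0, l_i; r0, r_j) over left populations
L (target first) and right outgroups R, with a delete-one-block jackknife
covariance Q of vec(X). With `allsnps` each entry uses its own maximal SNP
set; otherwise the global intersection. Q is computed with the unweighted
vector jackknife — blocks are near-equal by construction — and inverted
with an escalating ridge (1e−6 to 1e−3 of the mean diagonal) before
erroring with the condition number.

The rank-r test minimizes vec(X−X̂)ᵀQ⁻¹vec(X−X̂) over rank-r matrices by
alternating generalized least squares on the factors, with 10 seeded
restarts (the exact minimizer has no closed form under a general Q); the
statistic is referred to χ² with (|L|−1−r)(|R|−1−r) degrees of freedom.
Under cladal simulations the rank-0 p-values are uniform (KS-checked over
200 replicates), which is the ground truth this package's df convention is
validated against.

qpAdm solves min_w d(w)ᵀQ_d(w)⁻¹d(w) with d_j(w) = Σ_i w_i X_ij and
Σw = 1 — the target-minus-mixture lineage must share no drift with any
right. Because the weighting matrix Q_d depends on w, the solve iterates a
fixed point from equal weights (converges in a handful of steps). SEs come
from leave-one-block-out re-solves against the full-data Q; the tail
p-value is the rank-(k−1) test of the full left set. Weights outside
[0, 1] are reported with `feasible=False`, never clamped — infeasibility is
itself the model-rejection signal. Rights that fail to differentiate the
sources show up as a collapsing precision diagnostic (the smallest
eigenvalue of the GLS normal matrix) and exploding SEs — reported, not
silent; exactly collinear sources raise an error naming the offending
pair.

## Admixture-graph fitting

The fitted model treats each leaf frequency as the root plus independent
increments on the drift edges its lineage traverses, an admixture node
routing the lineage to its first parent with probability α. Expected
f2(A,B) = Σ_e c_e (w_A(e) − w_B(e))², with edge-usage probabilities w
recomputed from the current α's during optimization; the root
heterozygosity scale is absorbed into the c's (f2 units). Fitting is
bounded nonlinear least squares of (expected − observed)/SE over the
leaf-pair f2 basis, c ≥ 0 and α ∈ [0, 1], with restarts over α starting
points. Residual z-scores use the observed SEs; the score is the count of
|z| > 2. Zero-length fitted branches are legitimate results, reported as
such. Non-identifiable parameterizations (e.g. the two root-adjacent edges,
identified only through their sum) are reported through the Jacobian's
null-space dimension rather than raised, and parameter SEs use the
pseudo-inverse of the Gauss–Newton Hessian.

Greedy leaf addition enumerates every single-edge attachment and every
two-edge admixed attachment (E + E(E−1)/2 candidates for E edges), refits
each, and ranks by (score, all-positive internal branches, number of
admixture events, residual sum). The admixture-count key is a parsimony
tie-break this package adds: at equal score an admixed attachment's extra
parameters otherwise always absorb enough noise to win on residual sum,
even when the truth is a plain edge. The search is greedy and its outcome
can depend on the order in which populations are added; the tests assert
this order dependence rather than hiding it.

## Admixture-LD dating

Per SNP k, the weight w_k = p1_k − p2_k and per-individual residual
r_k = g_k/2 − (p1_k+p2_k)/2 (pseudo-haploid calls scaled to {0, 2}). For
every same-chromosome SNP pair the across-individual covariance of
residuals, times w_k·w_l, is accumulated into genetic-distance bins; with
one individual the uncentered product substitutes. Under the generator's
pulse model the binned curve decays exactly as A·exp(−g·d) + c, so the
fitted rate is the admixture age in generations. Allele-sampling noise is
uncorrelated across SNPs and only inflates the (excluded) zero-distance
diagonal, leaving the fit unbiased.

Fitting is bounded least squares with multi-start over g ∈ {5, 20, 50,
200} (exponential fits are initialization-sensitive), bins below 0.05 cM
excluded (in real data short-range background LD contaminates them). The
SE of g is a weighted jackknife over leave-one-chromosome-out refits with
chromosome pair counts as weights. Defaults are 1 cM bins out to 1 Morgan,
the classic settings for ~1M-SNP panels expressed in cM; the bundled
recovery experiments (20 chromosomes × 1 Morgan, 800 SNPs each, 20
diploid targets) use 0.25 cM bins over the same 1 Morgan range, matched to
their 0.125 cM marker spacing. Fitting over a truncated range (a few decay
scales) is a known trap: for small g the offset and the rate confound and
the jackknife under-covers, which is why the full-Morgan range is kept
even for old admixture. Under these conditions the ±2 SE interval covers
the truth in ≈95% of replicates for g ∈ {10, 46, 100}. Conversion of
generations to calendar years requires an explicit generation time; none
is assumed.

## Selection scan

Windows tile each chromosome at multiples of the step (default 500 kb
windows, 10 kb step, half-open on 1-based coordinates). Per SNP, with c
the target frequency from n alleles: f3 = (c−a)(c−b) − c(1−c)/(n−1)
against the ancient (a) and outgroup (b) frequencies, and heterozygosity
2c(1−c)·n/(n−1). SNPs must be segregating in target or outgroup and
covered in strictly more than `min_ancient_individuals` (default 15)
ancient individuals — the coverage vector is supplied by the caller, so
either reading of "more than one read" (≥1 usable read per individual, or
>1) is a choice made when building it. Windows with fewer than 250
qualifying SNPs are emitted without statistics. The window statistic is
the mean f3 normalized by the mean heterozygosity, removing the
allele-frequency dependence (the normalized value is invariant to common
rescaling of both).

z-scores: each of 100 resamples draws one qualifying window per LD block
and takes the mean and SD of the normalized statistic; the averaged mean
and SD standardize all windows. Averaging over resamples stabilizes the
reference distribution at negligible cost relative to a single draw; a
single-draw mode is a matter of passing `n_resamples=1`. An all-constant
statistic yields SD 0 and a flagged degenerate result. Candidate regions
merge overlapping super-threshold windows (default z > 4) and annotate
them with overlapping gene intervals. Under null simulations the z-scores
are centered within ±0.1 with SD in [0.8, 1.2], and a +0.35
frequency-shifted window is recovered as the genome-wide top hit with
z > 4. Per-locus allele frequencies come with Wilson 95% intervals
(statsmodels).

## Y-haplogroup assignment

Reads passing the calling-quality gates are tallied as ancestral or
derived per branch of a user-supplied marker tree. A branch is supported
when derived reads outnumber ancestral reads over at least one covered
marker (ties unsupported) — a deliberately simple, auditable stand-in for
expert inspection of count tables. The call walks from the root while
exactly one child is supported; two supported siblings stop the call at
their parent with both flagged, and any supported branch off the called
path is a conflict. `transversions_only` drops C/T and G/A markers
entirely, removing the states deamination can mimic.

## What the generator does not emulate

No linkage disequilibrium within source populations (sources are in
exact linkage equilibrium, so the dating curve has no background-LD
contamination and the scan's LD blocks are conservative constructions);
no sequencing error beyond deamination; no reference bias or mapping
artifacts; damage confined to exactly the terminal 5 bp with a flat rate
rather than an exponential profile; a uniform recombination map. Passing
recovery tests therefore demonstrates correctness of the estimators under
their own model assumptions, not robustness to these real-data
complications.

## Problem sizes

The bundled validation experiments run at: 50,000 SNPs × 20 replicates
(mismatch-rate calibration); 20,000 SNPs × 200 replicates (qpWave null);
100,000 SNPs × 50 replicates (qpAdm recovery); 80,000 SNPs (graph fits,
20 leaf-addition replicates); 16,000 SNPs × 20 chromosomes × 150
replicates (dating); 60,000 SNPs × 20 replicates (scan null). These sizes
keep every calibration's Monte-Carlo error comfortably below the property
being asserted while the whole suite runs in minutes on one core.
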