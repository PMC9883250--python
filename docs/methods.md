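# Methods

## The model

Two populations (labelled south and north) split from an ancestral
population T generations ago. Backwards in time, each deme of diploid size
N holds a Kingman coalescent: a pair of lineages coalesces at rate
1/(2N) per generation. Under IM₁, which has forwards-in-time migration from
south to north at per-lineage per-generation probability m<sub>e</sub>,
lineages currently in the north jump to the south at rate m<sub>e</sub>
each; IM₂ is the mirror image. At T all lineages enter the ancestral deme
(size N<sub>anc</sub>, no growth). Time is continuous, in generations, with
exponential competition among coalescence and migration events.

For two diploids (one per population) the sample is four haplotypes. Each
branch is classified by its descendant set: a single southern haplotype, or
one southern plus both northern, maps to `hetA` (a mutation there makes the
southern sample heterozygous and the northern homozygous); the mirror maps
to `hetB`; one haplotype from each population maps to `hetAB`; both
haplotypes of one sample map to `fixed`; branches ancestral to everything
are invisible. At T = 0 (panmixia) the expected class lengths have the
closed form (8N/3, 8N/3, 4N/3, 2N/3), from E[L<sub>i</sub>] = 4N/i for
branches with i descendants distributed uniformly over labelled subsets;
this is the main analytic oracle for the sampler.

## Likelihood

The probability of a block's capped count 4-tuple given parameters is
estimated by Monte Carlo: draw n genealogies, evaluate the product over
types of Poisson(k; u·L<sub>type</sub>) with u = μ · 64, average, and take
logs. Counts above k<sub>max</sub> = 2 use the Poisson upper tail, so for
any fixed genealogy sample the capped configuration space has total
probability exactly 1 (verified to 10⁻⁶). A configuration with zero Monte
Carlo mass would make the composite likelihood −∞; inside likelihood
evaluations it receives the pseudo-floor log(1/(n+1)) and is flagged. The
floor is a regularization, not part of the probability model, which is why
the normalization check evaluates exact probabilities (structurally
impossible configurations, e.g. `hetAB` and `fixed` in one block, genuinely
have probability zero for a single genealogy).

The composite log-likelihood sums count × log-probability over the table,
treating blocks as independent — false under linkage, which is why all
uncertainty statements come from the parametric bootstrap rather than from
likelihood curvature.

### Optimization

Nelder–Mead on log₁₀ parameters within boxes (sizes and T in [10³, 10⁷],
m<sub>e</sub> in [10⁻⁹, 10⁻⁴]), at most 1000 iterations, terminating at a
relative CL change below 10⁻⁶. Common random numbers — one genealogy seed
reused by every evaluation in a fit — make the surface deterministic, so
two fits with identical seeds agree bit-for-bit.

Two practical devices were needed. First, a multi-start: the
method-of-moments start (N from mean singleton-type counts via
E[L] → 4N, T from the mean fixed count via E[L<sub>fixed</sub>] ≈ 2T,
N<sub>anc</sub> from the shared-het count) can land in a basin where a
too-small N<sub>anc</sub> is compensated by a too-large T; short probe runs
from three deterministic start variants choose the basin before the full
optimization. Second, a restart loop: when Nelder–Mead terminates with a
degenerate simplex, it is restarted from the incumbent with a fresh simplex
until the budget is exhausted or no improvement exceeds the tolerance. Both
stay within the overall iteration budget.

## Model test, intervals, bias

IM models nest SI, so their CL gain is judged against a null built by
simulating bSFS replicates (same block count as the data) under the fitted
SI parameters and refitting both models. The p-value uses the add-one
convention (1 + #{null ≥ observed})/(1 + n), never exactly zero; with 100
replicates the smallest attainable p is 1/101 ≈ 0.0099. Because observed
and null ΔCL are computed with identical Monte Carlo settings they are
exchangeable under the null, so the test's level survives rough settings —
the calibration experiment (20 repetitions × 25 replicates) checks exactly
this. Individual null ΔCL values can be slightly negative: the two fits use
independently seeded surfaces, and at the reduced calibration settings
(300 genealogies per evaluation) differences of a few tens of CL units are
Monte Carlo noise; the nesting property is asserted only above that bound
(ε = 50 at those settings).

Per-parameter 95% intervals are MCL ± 1.96 × sd of the replicate estimates.
Recombination bias is quantified by simulating blocks with intra-block
recombination at a given cM/Mb (1 cM/Mb = 10⁻⁸ crossovers/bp/generation),
refitting the recombination-free model, and reporting (estimate −
truth)/truth per parameter; it is reported, never subtracted.

### Intra-block recombination model

Blocks recombine internally in reality but the likelihood assumes one
genealogy per block. The simulator's recombination mode walks the 64
callable sites left to right and renews the genealogy with a fresh
independent draw between adjacent sites with probability
1 − exp(−r·d·E[L<sub>total</sub>]), d being the mean physical spacing.
Renewal at a constant rate is deliberate: redrawing at a rate proportional
to the current tree's own length — superficially more natural — culls long
trees faster than they are entered and visibly biases per-site marginals
(−7% at an exaggerated 50 cM/Mb in development testing). Constant-rate
renewal keeps the per-site marginal distribution exactly the single-site
coalescent while reproducing the decorrelation; what it forgoes is the
local (prune–regraft) correlation structure of a full ancestral
recombination graph, which the bias-quantification use case does not need.

## Synthetic data

The generator tiles a region into 128-bp non-recombining segments and
simulates, per segment, a genealogy for 2 diploids per population plus one
outgroup diploid whose lineages join the ancestral deme at a deeper split
(default 5T; outgroup deme size defaults to N<sub>anc</sub>). Mutations are
Poisson on branches under infinite sites; position collisions are redrawn,
except a configurable fraction (default 5%) kept as multiallelic records so
the biallelic filter has something to drop. The reference allele is the
ancestral base. The VCF holds in-group-variant sites; the outgroup table
holds pileup-style observations (alleles seen among coverage-many reads
drawn from the two outgroup haplotypes) at every mutated position,
including outgroup-only divergent sites, which downstream RND computation
counts as one difference per in-group haplotype (half for a heterozygous
outgroup row).

Coverage is drawn per 1-kb window from a gamma distribution
(CV 0.3 around a mean of 30×) with per-position Poisson jitter, so the
callable-mask rules (≥8×, ≤ mean + 0.75 sd, moments per sample over all
analysed positions) are exercised with realistic spatial structure. A
random exclusion BED (default 5% of the region in 200-bp intervals) stands
in for the gene/repeat annotation.

Default demography: strict isolation with
N<sub>anc</sub> = N<sub>south</sub> = N<sub>north</sub> = 2 × 10⁵ and
T = 7 × 10⁵ generations, μ = 4.6 × 10⁻⁹. Equal sizes are chosen because
E[d<sub>a</sub>] = 2μ(T + 2N<sub>anc</sub> − N<sub>south</sub> −
N<sub>north</sub>), which collapses to the clock value 2μT exactly when
2N<sub>anc</sub> = N<sub>south</sub> + N<sub>north</sub>; the manifest
records both the clock and the exact expectation. The
divergent-region-like scenario used in the recovery and bias experiments
(N<sub>anc</sub> = 2 × 10⁵, N<sub>south</sub> = 3 × 10⁵,
N<sub>north</sub> = 9 × 10⁵, T = 7 × 10⁵) deliberately violates that
equality — its clock age underestimates the true split, which is the
phenomenon motivating model-based estimation.

What the generator does not emulate: sequencing error and mapping artefacts
(all genotype calls are correct given coverage), linkage between segments
(segments are independent, so block configurations are less correlated than
on a real chromosome), indels and structural variation, and base-composition
effects. Passing tests therefore demonstrate correctness of the estimators
under the assumed statistical structure, not robustness to artefacts real
variant-calling pipelines must handle upstream.

## Statistics

π is the mean pairwise haplotype difference within a population per
callable site; d<sub>xy</sub> the mean cross-population haplotype
difference; d<sub>a</sub> = d<sub>xy</sub> − (π<sub>N</sub> + π<sub>S</sub>)/2;
the clock conversion is T = d<sub>a</sub>/(2μ) generations × 1.7
yr/generation. RND divides d<sub>xy</sub> by the mean of the two
population-to-outgroup divergences. F<sub>ST</sub> is Weir & Cockerham's
variance-component estimator; windowed values are the ratio of summed
components over sites passing a pooled-MAF ≥ 0.1 filter (per-site negative
estimates retained, windows without usable sites reported as missing, never
zero). Tajima's D uses the standard normalization; Fay & Wu's H is the
unnormalized θ<sub>π</sub> − θ<sub>H</sub> with
θ<sub>H</sub> = Σ 2 S<sub>i</sub> i² / (n(n−1)); D is explicitly undefined
(not zero) when S = 0.

Design resolutions where the conventions genuinely vary: the RND
denominator is the mean of the two outgroup distances; the d<sub>a</sub>
clock divides by 2μ; the MAF filter pools the two in-group populations;
window denominators count variant sites passing the filter, not all
callable sites; the bSFS sums configurations over all four inter-population
sample pairs on each pair's own joint callable mask (composite likelihood
tolerates the resulting non-independence); sites with a missing genotype in
a pair are treated as non-callable for that pair; outgroup sites showing a
third allele are excluded and counted separately.

## Problem sizes and numerical choices

Defaults balance resolution against desk-scale runtime: likelihood
evaluations use 4000 genealogies (6000 in the recovery experiment, 300 in
the bootstrap calibration, whose validity rests on exchangeability rather
than per-fit precision); the recovery experiment uses 3 × 10⁴ blocks; the
calibration 20 × 25 replicates on 3 × 10³-block datasets; synthetic regions
in tests span 20–300 kb. Degenerate inputs are defined rather than
accidental: an empty bSFS has CL 0; an all-empty-configuration bSFS drives
size parameters to the lower bound; masks and spectra round-trip through
their text formats exactly. All randomness flows from explicit
`numpy.random.Generator` seeds; replicate seeds derive from one master seed
via `SeedSequence`, and every experiment is bit-reproducible.

### End-to-end behavior of the tiled generator

Because the generator draws an independent genealogy per 128-bp tile while
blocks are cut from the callable mask, a 64-site block whose physical span
stretches over missing data routinely straddles a tile boundary and mixes
two genealogies. This is not an artefact to be engineered away: at these
split times the genealogical correlation length along a real chromosome
(~1/(r·T) at ~2 cM/Mb) is itself well under the block span, so real blocks
recombine internally in just the same way. The consequence, visible in the
end-to-end tests, is a split-time estimate biased upward by roughly 10–30%
at the default tiling, with bootstrap intervals — which are centred on the
biased estimate and simulate replicates without mixing — covering the true
T in only a majority (not ~95%) of repetitions. This mirrors the behaviour
of the real analysis, where the divergence-time bias from intra-block
recombination is quantified and reported but the intervals are not widened
for it. The recovery experiment proper simulates blocks directly from the
coalescent engine (one genealogy per block), isolating estimator
correctness from this data-model mismatch.

## Known limitations

The Monte Carlo likelihood is noisy at small n<sub>genealogies</sub>, and
although common random numbers make each surface deterministic, different
parameter points consume the random stream differently, so the surface is
deterministic but jagged; the multi-start and restart devices mitigate, not
eliminate, the resulting optimizer variance. m<sub>e</sub> is weakly
identified at realistic values (~10⁻⁷) — precisely why the bootstrap test
exists. The sampler handles exactly two populations and four in-group
haplotypes for inference; the generator, but not the likelihood, supports
larger samples. Exact bSFS probabilities via generating functions are out
of scope, as are phased configurations and folded spectra.
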