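# Methods

`peripagen` re-implements, as a tested pipeline, the multi-locus demographic
inference used to test a peripatric-speciation hypothesis in a two-variety
conifer system: per-locus diversity and neutrality statistics, a two-deme
structured-coalescent scenario family, ABC scenario choice, joint-SFS
composite-likelihood fitting, and mutation-rate/time scaling.

## The demographic model

Two demes are tracked backward in time: deme 1 (the widespread variety,
current diploid size `N1`) and deme 2 (the peripheral variety, size `N2`).
Scenario codes combine a topology family with a migration regime:

| family | history (backward) |
|---|---|
| A | deme 2 founded from deme 1 at `t3` at founder size `N2f`, recovering to `N2` at `t1` |
| B | A, plus a deme-1 expansion `N1b → N1` at `t0` |
| C | both demes split from an ancestor of size `NA` at `t3`; deme 2 at size `N2f` during the bottleneck window `(t1, t2)` |
| D | C, plus the deme-1 expansion at `t0` |

Migration suffixes: `1` none, `2` initial epoch only, `3` recent epoch only,
`4` both, `5` ongoing. The verbal epoch definitions are made concrete as
backward-time windows: initial = `[t1, t3]`, recent = `[0, t0]`, ongoing =
`[0, t3]`; these are configurable, and the defaults are what every test uses.
A and B with no/recent migration are tagged peripatric, C and D with
no/recent migration vicariant, A/B with initial migration parapatric, the
rest complex.

All size changes are instantaneous; an exponential-growth option was
considered and rejected because nothing in the inference surface requires it.
Times are generations throughout; conversion to years happens only at
reporting, via the generation time (default 25 years, standard for
long-lived conifers). The per-generation mutation rate defaults to
5.58 × 10⁻⁹/site (2.23 × 10⁻¹⁰/site/year × 25), itself derived from
silent-site divergence to a sister taxon via μ = K_S/(2T); `K_S` is always an
input, never estimated here.

## Simulator

The structured coalescent is simulated event by event: within a deme of
diploid size N (ploidy factor `pf`), k lineages coalesce at total rate
k(k−1)/(4·N·pf) per generation; lineages migrate at epoch-specific backward
rates; at `t3` all deme-2 lineages merge into deme 1. Mutations follow the
infinite-sites model, Poisson on branch lengths, mapped to distinct
positions. Two hot-path kernels are JIT-compiled (numba): one returns the
genealogy (node times + parent pointers), the other directly accumulates
branch lengths by joint descendant-count cell, which is the Monte-Carlo
estimator of the expected joint SFS. Correctness is pinned by closed forms
(E[T₂] = 2N, E[L] = 4NΣ1/i, E[S] = θΣ1/i, E[ξᵢ] = θ/i) and by agreement
with msprime configured to the identical demography (ploidy 1 with sizes 2N,
so the pair-coalescence rates match).

Reproducibility: a single master seed fans out through
`numpy.random.SeedSequence` spawn keys to per-locus/per-replicate 31-bit
substreams, so any locus or stage can be re-simulated in isolation.

## Statistics

Statistics operate on gap-masked alignments ('N' treated as missing
pairwise, the site still counted in L; indel columns removed, optionally
counted as single events for haplotype work). Implemented from first
principles (no SNP-library dependency): S, η, N_h, H_d (with the n/(n−1)
correction), π, Watterson's θ_w, Hudson–Kaplan R_m (greedy disjoint-interval
reduction, provably optimal for interval scheduling), Tajima's D, Fu & Li's
D*/F* (Simonsen-corrected variance constants, the DnaSP convention), Fu's
F_S via the exact Ewens distribution (log-space unsigned Stirling numbers),
and Fay & Wu's H in its original unnormalized form. Polarization requires a
unanimous outgroup allele present among exactly two ingroup alleles;
tri-allelic sites count in S but are excluded from SFS/H, and skipped-site
counts are reported. Undefined statistics are `None`, never 0 — except
inside the fixed ABC summary vector, where Tajima's D of a monomorphic locus
is imputed as 0 so the vector stays complete (documented trade-off).

ΦST is the AMOVA estimator on pairwise-difference distances (the Arlequin
default for sequence data), with haplotype-level permutation significance
p = (#perm ≥ obs + 1)/(n_perm + 1); individual-level permutation and
Hudson's 1 − H_w/H_b are available as cross-checks. Multi-locus ΦST pools
per-haplotype distance matrices across loci; multi-locus means of per-site
statistics are unweighted across loci (a length-weighted flag exists).

## HKA

One-taxon multilocus HKA (each variety against the outgroup separately;
df = L − 1 = 13 for 14 loci, consistent with back-calculating both published
p-values from their χ² statistics). Given T, the moment equations are linear
in the locus θ̂ᵢ, so fitting reduces to 1-D root finding (Brent) on the
divergence-moment identity, with a Nelder–Mead fallback for degenerate
brackets. Variances follow the classical 1987 forms, including the
divergence-time term. The moment solution conserves ΣS + ΣD exactly but is
not the exact numerical minimizer of the χ² objective (the variances depend
on the parameters); tests assert it is within 15% of the grid minimum.
D_i defaults to mean pairwise ingroup–outgroup differences (net-of-within
correction by flag; the source analysis does not state which was used).

## ABC

The summary-statistic set is fixed and versioned (`STAT_SET_V1`): per
population {S, π, N_h, Tajima's D, private S} and between populations
{ΦST, mean between-population difference, shared S}, each as mean and
variance across loci (26 statistics). Rejection standardizes by median/MAD
(zero-MAD statistics are dropped with a warning — under deep-divergence
priors the shared-S summaries routinely have MAD 0), retains
⌈tolerance·R⌉ rows by Euclidean distance with stable tie-breaking. The
"direct" posterior is the retained scenario frequency; the "logistic"
posterior is a ridge-regularized (λ = 10⁻⁶, escalated on separation)
multinomial logistic regression evaluated at the observed point, with
delta-method CIs from the intercept covariance. Parameter posteriors use
Beaumont local-linear adjustment with Epanechnikov weights, clipped to the
prior support. Pod-based confidence evaluation reports a hold-one-out
confusion matrix with per-scenario type-I/type-II rates.

Default priors (uniform, desk scale): N1 ∈ [10⁵, 10⁶], N2 ∈ [10⁴, 10⁵],
N2f ∈ [10², 10⁴], N1b ∈ [10⁴, 10⁵], NA ∈ [10⁵, 10⁶], t3 ∈ [5·10⁴, 3·10⁵],
t1 ∈ [10⁴, 1.2·10⁵], t2 ∈ [2·10⁴, 1.4·10⁵], t0 ∈ [10³, 5·10⁴] generations,
m ∈ [0, 2·10⁻⁶], with t0 < t1 ≤ t2 < t3. These brackets the study's point
estimates and were fixed before any recovery experiment was run; the
original analysis' prior table is unpublished, so these are declared
package defaults, not inferences.

## SFS composite likelihood

log₁₀ CL = Σ m_e log₁₀ p̂_e over polymorphic cells, monomorphic corners
excluded (loci are ascertained as sequenced alignments). Expected spectra
are branch-length Monte-Carlo estimates; zero cells are floored at 1/(10·Z)
(Z = simulated-SNP total) and renormalized. Optimization is Nelder–Mead in
log-parameter space with box constraints by sigmoid transform; each loop
re-estimates the spectrum under common random numbers (smooth surface within
a loop, fresh draws between loops — standing in for the ECM loops of SFS
fitting tools). AIC = 2k − 2·ln(10)·maxlog₁₀CL; parametric-bootstrap CIs
refit spectra simulated at the MLE. Desk defaults: 2,000 sims/evaluation,
10 loops, 5 restarts; production-scale values are config-only.

## Synthetic data

The study template: 14 nuclear loci totalling 6,077 bp (equal 433 bp × 13 +
448 bp, since per-locus lengths are unpublished), 112 + 63 diploids (224 +
126 phased haplotypes), one haploid 1,589 bp cpDNA locus, generated under
scenario B3 at the published point estimates (N1 = 5.17·10⁵, N2 = 3.63·10⁴,
t3 = 146,000 gen, t1 = 26,000, t0 = 24,400, m = 8.37·10⁻⁷/1.91·10⁻⁷).
Unpublished quantities fixed once as package choices: N1b = 5·10⁴
(pre-expansion size, an order below N1), N2f = 2·10³ (founder size), NA = N1,
cpDNA mutation rate 3·10⁻¹⁰/site/gen (chosen so the simulated cpDNA shows
the observed order of a handful of variants; conifer cpDNA is paternally
inherited, hence the configurable ploidy factor 0.5). The generator does not
emulate within-variety substructure (inference pools varieties), sequencing
error, indel evolution, or phasing uncertainty — a green end-to-end test
therefore certifies the inference machinery on the pooled two-deme world,
not robustness to those nuisances.

## Desk-scale acceptance properties

The heavy stochastic checks are scaled to a single CPU: ABC scenario
recovery uses 8 × 500 bp loci and 24 + 16 haplotypes with 5,000
simulations/scenario and 50 pods from B1 (≥ 60% direct-approach recovery);
SFS-fit recovery uses 16 + 10 haplotypes, 300 sims/evaluation, 3 loops,
3 restarts over 20 seeded replicates (generating model first by AIC in
≥ 70%; median fitted t3 within ±35% — the median because a single 8-locus
replicate's sampling noise exceeds 35%). The production-scale analysis
(2·10⁶ simulations/scenario, 100 independent runs) is reachable only through
configuration and is not exercised by the tests.

## Known limitations

- No recombination within loci (loci are treated as non-recombining blocks,
  matching the source analysis' use of largest non-recombining regions).
- Composite likelihood treats SNPs as independent; CIs from the parametric
  bootstrap inherit that assumption.
- The HKA χ² reference is asymptotic; the type-I calibration test tolerates
  ±2% around the nominal 5%.
- The logistic-posterior CI is a delta-method approximation and can be
  anti-conservative near probability 0 or 1.
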