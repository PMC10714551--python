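# peripagen

Two-deme coalescent demographic inference for peripatric-speciation studies.

When a small peripheral population is founded from a large widespread one and
diverges in isolation (peripatric speciation), the genetic signature differs
from a symmetric range split (vicariance): the derived population carries a
subset of the ancestral variation, lower diversity (π, θ_w), a founder
bottleneck, and often asymmetric late gene flow after secondary contact.
`peripagen` packages the full inference chain used to discriminate these
histories from multi-locus phased sequence data in two populations:

1. **Per-locus statistics** — S, η, N_h, H_d, π, θ_w, Hudson–Kaplan R_m,
   Tajima's D, Fu & Li's D*/F*, Fu's F_S (exact Ewens distribution), Fay &
   Wu's H (outgroup-polarized), AMOVA ΦST with permutation p-values.
2. **Multilocus HKA test** — polymorphism vs outgroup divergence across
   L loci, χ² with L − 1 df from the classical moment equations.
3. **Scenario simulation** — a structured-coalescent engine over 20 scenario
   codes (families A–D × migration regimes 1–5) encoding founder events,
   bottlenecks, expansions, and epoch-restricted migration.
4. **ABC scenario choice** — rejection on a versioned summary-statistic set,
   direct and logistic-regression posteriors, local-linear parameter
   adjustment, pod-based type-I/II confidence evaluation.
5. **Joint-SFS composite likelihood** — fastsimcoal-style fitting of the 2D
   site-frequency spectrum, AIC ranking, parametric-bootstrap CIs.
6. **Rate scaling** — μ = K_S/(2T) calibration, per-year ↔ per-generation
   rates (default 25-year generation time), 2Nm migrant scaling.

The model core: backward in time, k lineages in a deme of diploid size N
coalesce at rate k(k−1)/(4N) per generation, migrate between demes at
epoch-specific rates, and merge at the divergence time t₃; mutations are
infinite-sites with rate μ per site per generation (default 5.58 × 10⁻⁹).
See `docs/methods.md` for the complete model description and numerical
choices.

## Worked example

Generate a study-shaped dataset (14 nuclear loci, 6,077 bp, 224 + 126
phased haplotypes) under the default peripatric scenario B3 and analyze it:

```bash
peripagen synth --scenario B3 --seed 42 --out data/
peripagen stats --out run/
peripagen hka --out run/
peripagen scale --ks 0.00745 --t-years 16.7e6 --ne 5.17e5 --m 8.37e-7
```

The `scale` call prints

```json
{
  "mu_per_year": 2.2305389221556887e-10,
  "mu_per_gen": 5.576347305389222e-09,
  "2Nm": 0.865458
}
```

i.e. a silent-site divergence of 0.745% at a 16.7 Ma calibration gives
2.23 × 10⁻¹⁰ substitutions/site/year, 5.58 × 10⁻⁹ per 25-year generation,
and the fitted migration rate corresponds to ≈ 0.87 effective migrant
lineages per generation into the larger deme.

A full desk-scale pipeline run (`python scripts/acceptance.py --seed 1
--out results/acceptance.json`) prints, for the seed-1 synthetic dataset:

```
[stats] pooled PhiST = 0.8216 (perm p = 0.0010)
[hka] chi2 = 2.6615, df = 13, p = 0.99891
[abc] direct posteriors: {'A1': 0.125, 'B1': 0.344, 'C1': 0.188, 'D1': 0.344}; best = B1
[sfs] best by AIC: B1 (dAIC to runner-up = 113.69)
```

Reading: the two simulated populations are strongly differentiated
(ΦST = 0.82, no permutation reached the observed value); no locus deviates
from neutral polymorphism/divergence proportions (HKA p ≈ 1, as expected for
neutrally simulated data); ABC favors the founder-event-plus-expansion
family (B) over the vicariant alternatives, and the SFS comparison prefers
the no-migration variant B1 at these reduced optimization settings — the
generating scenario B3 differs from B1 only by weak migration
(2Nm ≈ 0.87/0.01), a signal this desk-scale run is not powered to resolve.

## Acceptance script

`scripts/acceptance.py --seed <int> --out <path>` regenerates the synthetic
dataset from scratch, runs the four analysis stages above at desk scale
(~20 s), writes the stats table and SFS ranking next to `<path>`, and emits
the results JSON to `<path>`.

## Layout

```
src/peripagen/
  alignments.py   FASTA/popmap I/O, indel masking, validation
  stats.py        diversity + neutrality statistics, SFS, PhiST
  hka.py          multilocus HKA test
  coalescent.py   scenario grammar + structured-coalescent engine
  _kernels.py     numba hot paths
  abc.py          ABC rejection, posteriors, confidence
  sfs_fit.py      composite-likelihood fitting, AIC, bootstrap
  scaling.py      rate and unit conversions
  synth.py        study template, dataset generator, micro-fixtures
  cli.py          `peripagen` command-line pipeline
```
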