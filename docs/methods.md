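# Methods

## Model

For a target/reference chromosome pair the coalescence time *T* follows a
piecewise-exponential distribution with hazard λ(t), the pairwise
coalescence rate, constant within the epochs of a discrete time grid and
constrained to *T* ≥ *t₀*, the older of the two sample ages. A derived
mutation of age *a* carried by a reference chromosome is shared by the
target iff *T* < *a* (infinite-sites assumption), so each observation is
Bernoulli with success probability p(a) = 1 − exp(−Λ(t₀, a)), where Λ is
the integrated rate. The likelihood is the product of these terms over
sites, chromosomes and (for read input) reads; no phasing is required
because carrier copies are simply counted. Mutation age is not known
exactly: it is uniform on the branch interval reported by the dating
genealogy, and is integrated out on the grid.

All internal times are generations; user-facing I/O is in years and is
converted with a configurable generation time (default 28 years/generation,
so that per-generation mutation rates and year-denominated epochs coexist).
Mutation ages are capped at the TMRCA to an outgroup (default 10 My,
human–chimpanzee): sites fixed and derived in all dating samples are
retained with age interval [sample TMRCA, cap], because external samples
can coalesce into the root branch.

## Estimation

Preprocessing reduces the data to fractional counts of shared and
not-shared observations per (genomic block × time bin), distributing each
mutation's uniform age mass over bins by interval overlap. From there the
fit is independent of genome length and sample size.

Because a bin's counts pool observations whose ages spread across the bin
(and shared observations skew older within a bin than not-shared ones),
the binned likelihood treats each bin as Bernoulli with the *bin-averaged*
sharing probability, evaluated by a midpoint quadrature over
`quadrature = 8` equal within-bin slices. Placing the whole bin mass at a
single representative age instead aliases rates across neighbouring epochs
(the likelihood then pins the cumulative hazard only at isolated points);
the quadrature removes the artefact at negligible cost. For grids whose
bins are much wider than the coalescence timescale (e.g. a single-bin
grid), raise `quadrature`.

The fit is an EM in which the missing data are the observation's age node
and the latent coalescence time. The E-step is in closed form per epoch:
for a shared observation of age *a*, expected events are the truncated
piecewise-exponential bin probabilities and expected exposure is
E[|bin ∩ [t₀, T]| given T < a]; a not-shared observation contributes
censored exposure |bin ∩ [t₀, a]|. The M-step is λₑ = eventsₑ/exposureₑ.
EM steps are monotone in the likelihood but converge only linearly — very
slowly when adjacent epochs are correlated — so after a short EM phase the
climb is finished by a bounded L-BFGS step (analytic gradient, log-rate
parameterization) on the same likelihood; the reported likelihood trace
remains non-decreasing. Rates are clipped to [0, `rate_cap`] (default 1.0
per generation, which bounds the M-step under degenerate all-shared
counts). Epochs with exposure below 1e-12 are unidentified and inherit the
previous epoch's rate, so curves remain defined through data-sparse
epochs. Convergence is declared when the relative log-likelihood change
falls below `tol` (default 1e-8).

Initialization is the single-epoch maximizer of the same likelihood
(`constant_rate_mle`, a bounded scalar search on log λ), which also serves
as an independent oracle in tests.

**Shared singletons.** A mutation carried by exactly one dating sample and
observed shared must be older than the coalescence of target, reference
and carrier, biasing its age upward relative to uniform. Their shared
weight is therefore kept un-binned and redistributed each EM iteration
with the uniform density tilted by the current sharing probability
(normalized on the branch interval); `drop_shared_singletons` excludes
them instead. With tilting active the likelihood trace is only
approximately monotone. This tilted scheme is a documented reconstruction;
the original empirical recipe is not published in detail.

**Uncertainty.** A genomic block bootstrap resamples blocks (default
20 Mb, 100 replicates) with replacement, refits per replicate, and reports
2.5/97.5 percentiles. The TCC/TTC proportion uses 10-Mb blocks; the NNLS
mixture bootstrap resamples panel entries (default 1000 replicates).

## Filters and input handling

Read input applies the ancient-DNA acceptance filter: mapping quality
strictly above 30, read length strictly above 34 bp, fewer than 3
mismatches, 2 bp trimmed at each read end, and at most two distinct
observed alleles per site. Accessibility masks keep sites with depth ≥ 5
and below twice the mean coverage (BED, 0-based half-open; variant and
pileup positions are 1-based). Alleles are polarized against an ancestral
base; sites where it matches neither allele (or is N) are rejected.
Transversion-only mode drops {A,G} and {C,T} pairs — the standard
mitigation for post-mortem deamination. Shared observations whose age
interval lies entirely below t₀ are impossible under the model; they are
dropped and counted in `SharingCounts.n_inconsistent`.

## Synthetic data

The pair simulator is self-contained (no coalescent engine needed): per
genomic segment it draws *T* from the piecewise-exponential (the last
epoch's rate extends beyond the grid cap), lays Poisson(μ·L·(T − t_ref))
not-shared mutations with ages uniform on [t_ref, T] on the
reference-private lineage, and Poisson(μ·L·(t_out − T)) shared mutations
with ages uniform on [T, t_out] on the ancestral lineage (none when
T ≥ t_out — the same rule used when augmenting real tables with fixed
sites, whose count is Poisson with mean μ·l·(t_out − t_sample), all times
in generations). Dating noise is emulated by reporting the interval
[a(1−h), a(1+h)] clipped to [0, t_out]; h = 0 reports exact ages.
Independent segments emulate free recombination; position collisions
within a segment are collapsed (two-state model). Read data are emulated
with Poisson depth at the requested mean coverage, uniform allele choice
from the genotype, and a uniform base-error rate; read geometry fields are
set to filter-passing values. Deamination-like asymmetric damage is not
modelled — transversion-only mode is the pipeline's mitigation, so passing
tests bound statistical, not damage-model, behaviour. A tree-sequence
adapter imports dated mutations (age interval = child/parent node times)
and span-weighted pairwise TMRCAs from msprime-style simulations for
cross-checks against the direct MLE.

What the generator does not emulate: linkage between neighbouring trees
(segments are independent, so bootstrap blocks are cleaner than real
20-Mb blocks), mutation-age error that is correlated along the genome,
reference bias, and contamination.

## Study designs used by the heavy tests

*Six-epoch recovery.* Alternating rates (1.3e-4, 4.4e-5, 6.7e-5, 1.8e-5,
3.6e-5, 9e-6 per generation) on epochs ending at 800, 2000, 5000, 12000,
25000 and 50000 generations, plus one deep scaffold epoch to 120000
generations at the last rate so that dating-interval noise near the cap
cannot leak into the scored range; 30000 segments of 300 kb at
μ = 1.25e-8 (≈6M dated mutations; every scored epoch carries ≥500 expected
observations, most far more). With exact ages every epoch is recovered
within 10%; with ±30% interval noise within 25% — the residual error under
noise is dominated by the mismatch between the reported interval and the
uniform-age assumption, exactly the regime the dating genealogy produces.

*Low-coverage consistency.* A 100-Mb genome (100 × 1 Mb segments, five
20-Mb bootstrap blocks) under a six-epoch history; the same haplotypes are
observed as genotype dosages and as simulated reads at 4x and 0.1x mean
coverage. Block-bootstrap intervals (100 replicates) from the read
pipelines overlap the genotype-based intervals in every epoch.

## Downstream conventions

Integrated rates over a window are ∫λ dt (expected coalescences), not
time-averaged rates; the choice rescales the NNLS design and response
jointly and leaves the mixture coefficients' meaning unchanged. Rate
matrices are directed (target→reference kept distinct from the reverse),
with an optional symmetrization for PCA; columns are standardized
(mean-imputed where missing, constant columns dropped) before a centered
SVD. The optional affine rescaling that matches sharing-based and
genealogy-based rate levels is left to the user (`MixtureProblem` accepts
any pre-transformed inputs).

## Mutation-spectrum conventions

Substitutions are strand-collapsed to 96 classes with a central pyrimidine.
The shipped CpG-context rule ("pulse20") excludes exactly 20 classes: the
ancestral triplet contains CG at the mutating site (central C with right
flank G, 12 classes), the derived allele creates CG (T>C with right flank
G, 4), or creates CG on the opposite strand (T>G with left flank C, 4).
This rule is a reconstruction constrained to the published exclusion
count; symmetric "ancestral-or-derived CG on either strand" definitions
enumerate 23–24 classes instead, so the rule is pluggable (`CPG_RULES`).
Relative rate curves divide the focal class's per-epoch mutation density
(counts over genomic opportunity) by the mean over the 76 retained
classes; the count-ratio form is exact for per-individual curves, where
all classes share the same branches. Singletons and terminal-branch
mutations are excluded (an `is_terminal` column when available, otherwise
carrier count 1 as a proxy, with a warning). Flanking context defaults to
the ancestral genome where it disagrees with the reference. The IMI scales
the curve to mean 1 over 1e5–1e6 years BP (predating the TCC/TTC pulse),
integrates (curve − 1) over 14 ky–1 My BP in log10 time (upweighting the
recent past), and extrapolates the earliest value back to 14 ky for
samples older than that; a constant curve yields exactly 0.

## Known limitations

- Counts compiled on a coarse grid lose within-bin age structure; use
  grids whose bins are narrow relative to the hazard timescale (the
  default is 1 linear + 28 log-spaced bins to the cap).
- Multiplying across reads treats overlapping reads as independent
  evidence; at high coverage this overweights single sites (an optional
  `max_reads_per_site` cap is provided; the default applies no cap).
- The within-individual mode's random allele split is seeded for
  reproducibility but remains a randomized estimator.
- The tilted shared-singleton scheme approximates, not reproduces, the
  original empirical age-sampling procedure.
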