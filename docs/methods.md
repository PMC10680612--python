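# Methods

`ratehet` studies how heterogeneity in mutation and recombination rates
distorts SFS-based two-step inference of demography and the
distribution of fitness effects (DFE). It contains a forward
Wright–Fisher simulator that generates the data, and coalescent- and
diffusion-style estimators that analyse them; biases are read off as
truth-scaled estimates.

## Chromosome model

A single chromosome of `n_genes` repeating units, each a gene (four
588-bp exons alternating with three 563-bp introns, 4,041 bp in total)
followed by a 3,811-bp intergenic spacer. These element sizes are
genome-wide averages for *D. melanogaster* protein-coding annotation
and are the package defaults; 127 genes give the full-scale 997,204-bp
chromosome. Within each exon every third site (1-based positions 3, 6,
9, …) is synonymous and evolves neutrally; the remaining two thirds are
directly selected. Introns and intergenic DNA are neutral. The
chromosome begins with a gene; coordinates are 0-based half-open, exon
masks are written as BED, rate maps as TSV.

Rate maps are per-1-kb-window. Fixed maps use the *D. melanogaster*
averages mu = 2.8e-9 /site/generation and 2.32 cM/Mb (1 cM/Mb =
1e-8 crossovers /bp/generation). Variable maps draw each window from
Uniform(a, b) — mu: (1e-9, 6.1e-9); recombination: (0.0127, 7.40)
cM/Mb — and then multiply all windows by one constant so that the
length-weighted chromosome mean equals the fixed rate exactly. The raw
uniform means do not equal the fixed rates, so this mean-matching
rescaling (which can push individual windows slightly outside [a, b])
is what makes fixed- and variable-rate replicates comparable. The final
shorter window carries its own draw, weighted by its length.

## Forward simulator

Discrete-generation diploid Wright–Fisher dynamics with multiplicative
fitness across sites and semi-dominance (genotype fitnesses 1, 1−s/2,
1−s; h = 0.5 throughout). Each generation: parents are sampled with
probability proportional to fitness (selfing allowed, as in standard WF
sampling); each gamete recombines the parent's two haplotypes with a
Poisson number of crossovers placed by the recombination map; new
mutations arrive as a Poisson draw with the mutation map's per-site
rates under an infinite-sites rule at finite coordinates (a hit on an
occupied or previously fixed site is redrawn). Mutations at directly
selected sites draw s from a discrete four-class DFE on
gamma = 2·N_ancestral·s with class boundaries 0, 1, 10, 100 and
gamma_max, uniform within each class; all other sites get s = 0.
gamma_max is not part of the published parameterisation; the default is
2·N_ancestral, i.e. the strongly deleterious class spans s from
100/(2N) to 1 (homozygous-lethal cap). Under rescaling this cap tracks
the simulated N, so the strong class's s-distribution differs between
scales — one of the known rescaling artifacts.

Populations start monomorphic and burn in for 16·N_ancestral
generations, pass through optional instantaneous size changes (each
epoch lasts `duration_N` times its own N, default 1), and are sampled
as both haplotypes of sample_n/2 distinct individuals (default 100
haplotypes); non-segregating columns are dropped. All parameters can be
rescaled by Q (N → N/Q; mu, r, s → ×Q), which preserves 2N·mu, 2N·r and
2N·s. Rescalings implying s > 1 or N < 10 are rejected; at severe desk-
scale contractions the current size is clamped at 10 diploids.

Internally, neutral mutations live in a bit-packed haplotype matrix
(crossovers are word-level segment copies), selected mutations in a
dense byte matrix consulted each generation for fitness, and mutations
younger than the last purge in a sparse carrier list. Fixed and lost
columns are removed on a fixed 25-generation purge schedule (they are
inert in between: fixed selected sites multiply every individual's
fitness by the same constant). A single seeded generator drives all
randomness; a fixed seed reproduces a replicate bit for bit.

## Spectra and summary statistics

Unfolded single-population SFS with bookkeeping bins 0 and n that are
masked in every likelihood. Spectra can be restricted by an interval
mask (e.g. exons) or by site class, pool additively across replicates
(span_bp accumulates), fold to minor-allele form, and round-trip
through a dadi-style `.fs` text format. Windowed pi, Watterson's
theta_W, S and Tajima's D (standard variance constants) use 5-kb
windows sliding by 2.5 kb; every window start below L is emitted, final
windows are truncated and flagged, and D is undefined (NaN) when
S = 0.

## Demographic inference

The expected SFS under a two-epoch history comes from E[T_k], the
expected time the sample genealogy spends with k lineages, via the
branch-subtending weights C(n−i−1, k−2)/C(n−1, k−1):
E[xi_i] = mu·L·Σ_k k·E[T_k]·w_{ik}. E[T_k] is computed two ways:

* quadrature — the pure-death lineage chain is linear within an epoch;
  p(tau) = expm(A·tau)·p0 by dense scaling-and-squaring (robust to the
  very stiff generators small-N proposals produce), occupancy integrals
  by bidiagonal back-substitution, and the infinite ancestral epoch in
  closed form;
* Monte Carlo — direct simulation of the inhomogeneous death chain,
  vectorised over replicates (default 1e5), with common random numbers
  across proposals within one fit.

The two routes agree within Monte-Carlo error and serve as mutual
oracles. Two fitting flavors mirror the two families of SFS tools: an
absolute Poisson composite likelihood over (N_ancestral, N_current,
tau) with mu fixed at the true mean simulated rate and box constraints
of 10–100,000 diploids and 10–10,000 generations, and a relative
multinomial likelihood over (nu, tau_rel) with the spectrum normalised
and log10 bounds of ±2. Both use multi-start Nelder–Mead on
sigmoid-boxed log parameters (relative log-likelihood tolerance 1e-8);
all starts are logged, ties go to the first-found optimum, and optima
within 0.1% of a bound are flagged as boundary-pinned. The equilibrium
model is a 1-D bounded search on log10 N.

A note on conventions: scaled parameters are quoted as theta = 4N·mu
per site with N the diploid count; writings that use theta = 2N·mu can
be reconciled by halving.

## DFE inference

Selected-site spectra come from two engines. The equilibrium
Poisson-random-field closed form uses the semi-dominant sojourn
density g(x; gamma) = (e^{gamma(1−x)} − 1)/((e^{gamma} − 1)·x·(1−x))
with gamma = 2N·s ≥ 0 a deleterious magnitude, integrated against
binomial sampling kernels by composite Gauss–Legendre quadrature (96
nodes on each of [0, .5, .9, .99, .999, 1]; the extra panels resolve
the 1/gamma boundary layer at x → 1; evaluation is in log space so
gamma up to ~1e5 cannot overflow). The Wright–Fisher transition-matrix
engine evolves the expected density of segregating sites over derived
counts 0..2N_ref (default N_ref = 100) with selection rescaled so
2·N_ref·s_ref = gamma: its stationary state under constant influx into
count 1 is an exact linear solve; size-change epochs re-bin the density
binomially, scale the influx with nu, rescale selection and the drift
clock to the current engine size, and either step generation by
generation or jump to the current-size stationary state when the epoch
exceeds 20·2N_ref generations; the final density is projected to the
sample by hypergeometric subsampling. Engine sizes are bounded
(current-epoch size at most 500; contraction-resolved sizes quantised
to {100, 150, 200, 300}, with a binomial-projection fallback when the
final population is smaller than the sample) so that extreme — e.g.
boundary-pinned — nuisance demographies stay tractable. The two engines agree to ~1.6%
per bin at gamma = 0 and converge to each other as 1/N_ref — the
residual at strong selection (s_ref up to 0.5 at N_ref = 100) is the
intrinsic diffusion-vs-finite-chain gap, so oracle comparisons at fixed
small N_ref must budget for it.

A gamma DFE (shape beta, mean gamma_bar of 2N·s over new mutations) is
discretised on a fixed 64-node log grid over [1e-4, 1e5]
(mass-weighted; tail mass folded into the end nodes; grid resolution
limits how sharply a very narrow DFE can be represented). Fitting
maximises a Poisson composite likelihood of the selected SFS with
theta_sel profiled in closed form and multi-start Nelder–Mead over
(beta, gamma_bar) in [0.01, 100] × [1e-3, 1e5]. Two-step conditioning
follows the standard tools: demography is first fitted to the
putatively neutral (synonymous) spectrum and the DFE engines run under
that fitted history. When the neutral spectrum is supplied to the fit,
both spectra are modelled jointly with shared per-bin distortion
factors r_i (neutral bin i expected as theta_neu·u0_i·r_i, selected as
theta_sel·u_i·r_i); the maximum-likelihood nuisances have the closed
form r_i = (n_i + s_i)/(theta_neu·u0_i + theta_sel·u_i) iterated with
the profiled thetas. Because synonymous and selected sites share their
mutation-rate and linked-selection environment, r_i absorbs shared
spectrum distortions; it is also the channel through which noisy,
rate-heterogeneous neutral spectra push DFE estimates around. Class proportions f0..f3 are gamma CDF masses on
[0,1), [1,10), [10,100), [100,∞) — comparisons across replicate sets
use the mean proportions over the fitted spectra. The neutral-vs-gamma
comparison reports 2·Δloglik against chi-square with 2 d.f.; with the
null on the boundary this is conservative, which the size check
accepts. polyDFE-style fragment handling profiles a separate theta_f
per fragment SFS (closed form; zero-SNP fragments contribute nothing)
under one shared gamma.

## Experiment harness

The factorial design crosses four rate regimes (fixed/variable mutation
× fixed/variable recombination; variable maps are redrawn per
replicate), four demographies (equilibrium; instantaneous 100%
expansion, nu = 2; 50% and 99% contractions, each 1·N_current
generations before sampling), and a strictly neutral model plus six
discrete DFEs. The six class-weight vectors (DFE1 (0.1,0.7,0.1,0.1),
DFE2 (0.1,0.1,0.7,0.1), DFE3 (0.1,0.1,0.1,0.7), DFE4 uniform, DFE5
(0.5,0,0,0.5), DFE6 (0.3,0,0,0.7)) are representative shapes — excess
weak / moderate / strong, uniform, and two bimodal forms — and are
configurable, not canonical. Per-scenario seeds derive deterministically
from a master seed.

Each scenario simulates n_reps replicates, pools them into
n_reps/pool_size spectra, and per pooled spectrum runs: the absolute
(equilibrium or size-change) fit and the relative two-epoch fit on the
exon-masked spectrum, and — for DFE scenarios — the two-step gamma-DFE
fit from the synonymous and selected spectra. Failures are recorded per
spectrum. Summaries report mean, SD and quartiles of truth-scaled
estimates (the mean of per-spectrum ratios).

Two profiles set problem sizes. The `paper` profile is the full-scale
study: 127 genes (997 kb), Q = 200 (N_ancestral = 7,000), 100
replicates pooled by 10. The `desk` profile is the package's
development/test scale: 7 genes (54,964 bp), Q = 5,600 (N_ancestral =
250), 20 replicates pooled by 5 — sizes chosen so a full scenario runs
in minutes on a laptop core while keeping the population-scaled
parameters (theta/site = 0.0157, rho/site, the 2Ns classes) identical
to the full scale. Desk-scale caveats: the strong-selection class is
compressed (gamma_max = 2N = 500), severe contractions clamp at 10
diploids, sample size (100) approaches 2N after contractions, and
per-spectrum mutation supply is ~36× smaller than at paper scale, so
stochastic checks use directional sign tests rather than magnitudes.

## What the generator does and does not emulate

The synthetic data reproduce the genic architecture, rate maps,
demographies and DFEs of the simulated study design — not real
*D. melanogaster* data. No gene conversion, no beneficial mutations, no
dominance variation, no GC-bias, no sequencing error or missing data;
mutation is strictly infinite-sites at finite coordinates. Passing
tests therefore demonstrate internal correctness of the simulator and
estimators and the direction of rate-heterogeneity biases under these
idealised conditions; they do not certify behaviour on empirical data.

## Numerical choices and degenerate inputs

Quadrature orders, grid sizes, purge interval and optimizer tolerances
are as above. Monomorphic SFS bins never enter likelihoods; expected
counts are floored at 1e-300 before logs. Zero-length chromosomes,
invalid class probabilities, a > b uniform limits, crossover
probabilities above 0.5/bp, rescaled s > 1 and rescaled N < 10 are all
rejected with errors. Ties in multi-start optimisation resolve to the
first-found optimum, making fits reproducible for a given seed.
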