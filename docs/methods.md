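# Methods

## Model

The unit of modelling is a *chromosome block*: the m mutations one MA line
carries on one chromosome.  A cross to the unmutated ancestor puts all m
mutant alleles in coupling on one parental chromosome; one round of meiosis
produces 2^m recombinant haplotypes whose expected frequencies follow from
the recombination fractions between adjacent mutations,

    f(h) = 0.5 * prod_k [ r_k if h switches parental origin across
                          interval k else 1 - r_k ],

so every mutation is marginally at frequency 0.5.  Recombination fractions
come from the Haldane map function r = (1 - e^{-2d})/2 applied to map
distances on a per-chromosome uniform map: the inverse recombination rate
y_i (bp/cM) grows linearly with chromosome length x_i, y_i = slope*x_i + k
with k chosen so the length-weighted mean of y_i equals the genome-wide
average.  Haldane is the natural choice given the model's assumption of
independent crossovers and the sparse marker density (~2 mutations per
chromosome per line); no interference model is offered.  Defaults:
genome average 87,000 bp/cM, slope 0.00616 bp/cM per bp (an alternative
ten-fold smaller slope circulates for the same regression and can be passed
explicitly).

The pool then competes asexually: haplotype fitness is multiplicative,
w_i = prod_j (1 + s_j)^{delta_ij}, and frequencies evolve deterministically
by pi' = pi w / wbar for t generations (default t = 60).  Iterating this
recursion is algebraically identical to pi_t ∝ pi_0 w^t; the likelihood
uses the closed form, the `evolve` operation iterates, and tests pin their
agreement to 1e-12.  Blocks evolve independently across chromosomes and
crosses.

### Likelihood

Three terms, summed over blocks:

1. **Reads.**  For mutation j, replicate k at the end timepoint, the
   replicate frequency v_jk = p_j + delta_jk is lognormal with median p_j
   and log-scale sd sigma_delta ("mean p_j" is read as the log-scale
   location, i.e. the median), truncated to (0, 1) and renormalised by the
   mass below 1, Phi(-ln p_j / sigma_delta); mutant reads x_jk are
   binomial(d_jk, v_jk).  A frequency cannot exceed 1, and for expected
   frequencies near 1 (strong positive effects) the truncated mass is
   substantial: dropping the normaliser and merely rejecting out-of-range
   states spuriously penalises large effects and measurably inflates the
   fitted shape.  v_jk must lie in (0, 1); states outside have log
   likelihood -inf.  Only
   end-timepoint replicates enter the likelihood: the model's initial
   condition is frequency 0.5 at the cross, so inferred effects absorb the
   whole frequency change, including any change before the time-0 sample.
   Time-0 counts feed diagnostics only.
2. **Effect magnitudes.**  |s_j| is gamma with the side's shape and rate
   (mean |s| = shape/rate; the rate is a *rate*, never a scale).  The
   positive-mass weight q is excluded here.
3. **Sign counts.**  The global number of positive effects is
   binomial(n, q), including the binomial coefficient, with n the total
   mutation count pooled over crosses.

Priors are uniform: s_j on (-1, 1), q on (0, 1), sigma_delta on (0, 10],
shapes on (0, 100], rates on (0, 1e4]; deviations are constrained only by
the (0, 1) support of v.  s_j = 0 has measure zero and proposals landing
exactly there are rejected.

### Sampling

Systematic-scan Metropolis-Hastings, one update per scalar parameter per
sweep, symmetric normal proposals.  During burn-in each parameter's
proposal scale is multiplied by 1.2^(accepted - 0.234) after its update
(clamped to [1e-8, 1e2]); at equilibrium the acceptance proportion is
0.234.  Scales freeze at the end of burn-in, so the sampling phase is a
fixed-kernel chain with the correct stationary distribution.

Internally the replicate deviations are carried non-centrally: the engine
samples z_jk = log(v_jk/p_j)/sigma_delta, whose target is a standard-normal
term plus the binomial read likelihood at v = p e^{sigma z}.  This is an
exact reparameterisation of the same posterior; it removes the funnel
between sigma_delta and the ~760 deviation parameters that otherwise makes
desk-scale chains under-estimate sigma_delta (and hence inflate the fitted
shape).  Reported deviations are always the additive delta_jk = v - p.

The replicate deviations are conditionally independent given everything
else and are updated as one vectorised elementwise Metropolis batch; all
other parameters update serially.

Two supplementary symmetric moves per chromosome block and sweep improve
mixing over linked mutations, whose individual effects are only jointly
identified: an exchange that shifts log(1+s) of a random adjacent pair by
+/-eps (preserving the pair's combined log fitness; the s-space Jacobian
of the paired translation is exactly 1) and a swap of two effects within
the block (an involution).  Both leave the posterior invariant; without
them, single-coordinate updates crawl along the near-degenerate ridge and
under-sample configurations in which one member of a tight pair is
near-neutral, which biases the fitted shape upward at desk-scale chain
lengths.  The moves can be disabled in the chain configuration.  "Iterations" are full sweeps; the
equivalent single-parameter-update count (sweeps x parameters) appears in
the run log.  Defaults (burn_in 2,000, total 10,000 sweeps, thin 10) fit a
seven-cross dataset in about two minutes on one CPU; arbitrarily longer
chains are a config knob.

Initialisation uses the naive single-locus estimate per mutation (the s
carrying 0.5 to the empirical mean frequency in t generations, clipped to
(-0.5, 0.5)), deviations matching the clipped empirical replicate
frequencies, sigma_delta = 0.05, and DFE moment estimates from the initial
effects.

### Summaries and model comparison

Point estimates are posterior modes via Gaussian KDE (Silverman bandwidth,
512-point grid spanning the sample range padded by one bandwidth; ties
resolve to the lowest grid value, and a mode outside the credible interval
is clipped in with a log entry).  Credible intervals are equal-tail 2.5/97.5
ranked quantiles (midpoint interpolation).  Variants are compared with
BIC = k ln(n) - 2 ln(L), L the modal (maximum sampled) log likelihood,
k the free gamma parameters (2/3/4 for shared / side-specific means /
side-specific means and shapes), and n the number of mutation x replicate
read observations (the reference analysis does not define n; this is our
choice).  Raw BIC and deltas to the best variant are reported; externally
published BIC values for this design appear rescaled and are not directly
comparable.  The evidence convention: a model is strongly preferred when it
beats an alternative by more than 10 BIC units.

## MA-phase selection-bias correction

Mutations arise during clonal colony growth between single-cell transfers
of the MA experiment; selection during those t doublings (t = 11 here)
biases which mutations are observed.  With deterministic doubling growth
from one cell, mutations arising at divisions in proportion to the number
of divisions per generation, and mutant lineage growth scaled by 1+s, a
mutation with effect s is represented in the final colony with relative
weight

    w(s, t) = (2^{st} - 1) / (t (2^s - 1)),    w(0, t) = 1,

which is the closed form of the generation-by-generation sum (an explicit
brute-force implementation of that sum ships as the validation oracle).
Dividing the observed DFE density by w and renormalising on a grid of
2,001 points over s in [-0.3, 0.3] (covering >99.99% of the fitted mass)
yields the corrected DFE; its positive mass q' is below the uncorrected q
because w increases in s.  For the fitted shared DFE (q 0.50, shape 0.53,
mean 0.022) and t = 11 the corrected value is q' = 0.46.

## Diagnostics

*Repeatability.*  End-timepoint frequencies decompose into among-cross
(V_MA), among-mutation-within-cross (V_M) and among-replicate residual
(V_E) components by method-of-moments nested ANOVA (balanced-design
coefficients evaluated with average group sizes; negative estimates
truncate to zero with a log entry).  Repeatability is V_M/(V_M+V_E),
excluding V_MA from the denominator.  Closed-form moments are used rather
than REML so the decomposition is dependency-free and exactly testable.

*Generations.*  Per-transfer generations are log2 of the regrowth factor,
summed over transfers; densities may be any proportional proxy (OD with a
pre-computed standard-curve multiplier).  The founding population size
inverts N_t = N_0 2^g as N_0 = N_t / 2^g (the algebraically consistent
form; a printed variant of this formula with the sign flipped on log N_t
is dimensionally inconsistent and not implemented).

*Annotation contrasts.*  Differences between annotation categories in mean
effect and mean squared effect are tested by bootstrap: mutations are
resampled with replacement from the pooled set and reallocated to the
original group sizes (10,000 draws by default), with the (1+k)/(B+1)
two-sided p-value correction.  P-values are exactly invariant to swapping
the group labels.

## Synthetic data generator

The generator emulates the study design end to end: 7 crosses with
(25, 15, 47, 52, 41, 36, 38) mutations (254 total), 17 synthetic
chromosomes with lengths evenly spanning 1-10 Mb, mutation classes in the
232:13:9 SNP/insertion/deletion ratio, uniform placement (chromosome chosen
uniformly, position uniform within it, ~2.1 mutations per chromosome per
cross), true effects drawn from a configurable two-sided gamma (default
q 0.5, shape 0.53, mean 0.022).  Each block's founding pool is a
multinomial draw of germinating zygotes (default 10,000; None = infinite,
i.e. the exact meiosis expectation), evolved deterministically or by
Wright-Fisher resampling (census 10^6 with nine 1/100 serial-transfer
bottlenecks in stochastic mode).  By default 5 pre-assay generations of
selection precede the time-0 sample, reproducing the observed dispersion of
initial frequencies around 0.5; the number of pre-assay generations in the
real experiment is unknowable, so t_pre is a knob, not an estimate.
Sequencing: depths are negative-binomial matched to the observed means
(520.7x at time 0, 221.6x per end replicate) and coefficient of variation
(~0.43); replicate frequencies get lognormal noise (sigma_delta 0.05,
chosen to reproduce the observed replicate repeatability of ~0.96) and
mutant reads are binomial.

What the generator does *not* emulate: sequencing error, mapping bias,
de-novo mutation during the experiment, epistasis, and inter-colony
selection during the MA phase.  Passing recovery tests therefore
demonstrate correctness of the estimator under its own assumptions plus
the modelled noise, not robustness to those unmodelled features.

With sigma_delta = 0, an infinite pool, deterministic mode and t_pre = 0
the generated expected frequencies equal the likelihood's predictions
bit-for-bit (generator and inference share the same selection core).

## Parameter-recovery conditions

The recovery acceptance test simulates at the inference model's own
conditions — infinite founding pool, no pre-assay generations — at full
design size (254 mutations, 3 replicates, depth ~222, t = 60) and checks
that posterior modes of q, shape and mean |s| land within the reference
credible-interval half-widths of the generating values in >= 9/10 seeded
runs.  Under the generator *defaults* (finite pool, t_pre = 5) the
un-modelled initial drift and extra generations inflate the fitted shape by
roughly +0.1 and the mean by a few percent; that misspecification is a
property of the experiment, not of the estimator, and is deliberately left
visible in the defaults.  Chains for these runs use burn-in 1,500 /
total 6,500 sweeps, thinning 5 (about a minute and a half per fit); the
Wright-Fisher cross-check uses 10^6 haploids and the MH kernel check a
10^5-step chain on a three-bin piecewise-constant target.

## Numerical notes

- Haplotypes are integer bitmasks in genome order; blocks are capped at 20
  mutations (2^20 haplotypes) with an explicit error.
- Binomial log-PMFs use log-gamma throughout; 0*log(0) is defined as 0 so
  degenerate frequencies at observed boundaries behave.
- The gamma DFE with shape < 1 has an integrable singularity at 0: log
  densities diverge as |s| -> 0, which is expected and harmless; exact
  zeros are excluded from the support.
- KDE modes on constant samples return that constant with a zero-width
  interval.
- All randomness flows through numpy Generators seeded from a single
  integer; identical seeds give byte-identical outputs.
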