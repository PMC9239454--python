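# linkdfe

Inference of the **distribution of fitness effects (DFE)** of spontaneous
mutations from allele-frequency changes of linked mutations in
experimentally evolved recombinant haploid pools.

## The problem

Mutation-accumulation (MA) lines of a haploid microbe (the motivating system
is *Chlamydomonas reinhardtii*) each carry a few dozen spontaneous
mutations.  Crossing an MA line to its unmutated ancestor produces a pool
of recombinant haplotypes carrying the mutations in all linkage-consistent
combinations, each mutation starting at frequency 0.5.  After ~60
generations of laboratory natural selection, pooled sequencing measures
each mutation's frequency.  Because mutations on the same chromosome are
linked, their frequency changes are not independent; the package models the
full haplotype dynamics.

For each cross x chromosome block of m linked mutations, one round of
meiosis yields 2^m haplotype frequencies (Haldane map function over a
length-dependent per-chromosome genetic map, genome average 87,000 bp/cM).
Haplotype i with fitness w_i = prod_j (1 + delta_ij s_j) then changes
deterministically:

    pi_{i,t+1} = pi_{i,t} w_i / wbar_t

The composite log likelihood sums three terms: (i) replicate read counts —
each replicate's frequency is lognormal around the expected frequency p_j
(log-sd sigma_delta) and mutant reads are binomial; (ii) effect magnitudes
|s_j| — gamma-distributed with side-specific shape and rate (a **two-sided
gamma** DFE); (iii) the number of positive effects — binomial(n, q).
Adaptive Metropolis-Hastings (normal proposals, multiplicative 1.2 scale
adaptation targeting 0.234 acceptance) samples the joint posterior over all
s_j, replicate deviations, sigma_delta, the gamma parameters and q.  Three
DFE constraint variants (shared; side-specific means; side-specific means
and shapes) are compared by BIC = k ln(n) - 2 ln(L).

The package also implements the pre-inference diagnostics (repeatability
variance components, serial-transfer generation counting, founding
population size), the colony-growth selection-bias correction of the DFE
for the MA phase, bootstrap contrasts between annotation categories, and a
full synthetic-data generator so every stage is testable without external
data.

## Worked example

```python
import tempfile
from pathlib import Path
from linkdfe import SimulationConfig, simulate_dataset, load_dataset
from linkdfe.mcmc_inference import ChainConfig, run_chain, summarize

# a two-cross experiment drawn from the model (q=0.5, shape 0.53, mean 0.022)
cfg = SimulationConfig(n_crosses=2, mutations_per_cross=(10, 10),
                       seed=3, t_pre=0)
with tempfile.TemporaryDirectory() as td:
    simulate_dataset(cfg).write(td)
    data = load_dataset(Path(td) / "reads.tsv", Path(td) / "chromosomes.tsv")

res = run_chain(data.blocks, data.reads,
                ChainConfig(burn_in=1000, total=5000, thin=10, seed=5))
summary = summarize(res.samples)
for name in ("q", "shape_pos", "mean_pos", "sigma_delta"):
    p = summary.params[name]
    print(f"{name:12s} mode {p.mode:.4f}  95% CI [{p.lower95:.4f}, {p.upper95:.4f}]")
```

Output of this exact script:

```
q            mode 0.4864  95% CI [0.2729, 0.7125]
shape_pos    mode 0.6897  95% CI [0.2609, 1.4184]
mean_pos     mode 0.0150  95% CI [0.0093, 0.0303]
sigma_delta  mode 0.0403  95% CI [0.0218, 0.0789]
```

With only 20 mutations the intervals are wide, but all four cover the
generating values (0.5, 0.53, 0.022, 0.05).  `q` is the posterior fraction
of fitness-increasing mutations; `mean_pos` the mean positive effect
(shape/rate); `sigma_delta` the between-replicate lognormal noise.

The same pipeline is available from a shell:

```sh
linkdfe simulate --out data --seed 1
linkdfe fit --reads data/reads.tsv --chromosomes data/chromosomes.tsv \
            --out fit --variants shared,shared_shape,full
linkdfe diagnose --reads data/reads.tsv --chromosomes data/chromosomes.tsv \
            --out diag --mutations data/mutations.tsv
```

`fit` writes thinned samples, posterior summaries (mode and ranked-quantile
95% credible intervals), a BIC table over the requested variants and the
fitted DFE density grid; `diagnose` writes the repeatability variance
components and annotation contrasts.

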