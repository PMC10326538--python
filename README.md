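# imcoal

Coalescent simulation and exact gene-tree inference for the two-population
**isolation-with-migration (IM) model**, built to study what intra-locus
recombination does to demographic parameter estimates when each locus is
analyzed through the true gene tree of one non-recombined block.

## The problem

The IM model describes two populations of scaled sizes θ₁ and θ₂ that
diverged from an ancestral population of size θ₃ at scaled time τ and since
exchange migrants at rates m₁ and m₂ (θᵢ = 4Nᵢu, τ = tu, mᵢ = Mᵢ/u, with u
the per-locus mutation rate; everything at run time is mutation-scaled).
Multilocus inference methods for this model standardly assume **no
recombination within a locus** and free recombination between loci. Genomic
data violate the first assumption: a recombining locus carries several
non-recombined blocks, each with its own marginal genealogy. `imcoal`
provides the machinery to measure what that does to the estimators:

* an ancestral-recombination-graph simulator for the 2-population IM model
  (Hudson-style, backwards in time, with migration, a population split, and
  recombination over a continuous unit-interval locus), emitting the true
  marginal gene tree of every non-recombined block;
* random-interval sampling of one block tree per locus;
* the **exact log-density of a labeled gene tree** under the IM model with
  all migration histories integrated out — a defective continuous-time
  Markov chain over the 2^k assignments of the k extant lineages to
  populations, propagated between coalescences by matrix exponentials, with
  coalescence operators of weight 2/θₚ and the plain single-population
  coalescent above the split;
* MAP estimation of (θ₁, θ₂, θ₃, m₁, m₂, τ) under uniform box priors
  (equivalently, box-constrained maximum likelihood) by seeded multi-start
  Nelder–Mead;
* an experiment driver that replicates the whole pipeline over a factorial
  grid of recombination rates and locus counts and reports bias, standard
  errors and trends.

## Worked example

```bash
python examples/map_estimation.py
```

```
fit of 300 loci in 11.8s (log-posterior -2724.39)
parameter    truth   estimate
   theta1    10.00    11.5708
   theta2    10.00     9.8237
   theta3    10.00     9.5970
       m1     0.10     0.0970
       m2     0.00     0.0000
      tau    10.00     9.9717
```

Three hundred non-recombining loci were simulated at the truth shown, one
gene tree taken per locus, and the joint gene-tree density maximized over
the prior box (0, 50)³ × (0, 0.2)² × (0, 20). All six estimates sit near the
generating values; the residual deviations are sampling noise.

With recombination switched on the picture changes
(`python examples/recombination_bias.py`):

```
rho = 0.0: mean theta3-hat 10.098  bias +0.098  SE 0.047
rho = 1.0: mean theta3-hat 11.535  bias +1.535  SE 0.174
```

Treating one randomly chosen block's tree as the locus' genealogy inflates
the ancestral population size estimate — the central effect the package is
designed to quantify. The other examples show the ARG simulator
(`simulate_recombining_locus.py`) and the density computation against closed
forms (`gene_tree_density.py`).

A thin CLI mirrors the library (`imcoal simulate | sample-blocks | loglik |
estimate | experiment | summarize`); run `imcoal --help`.

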