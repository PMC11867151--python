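# fossilbisse

Do fossils improve extinction-rate estimates under state-dependent
diversification models? `fossilbisse` is a simulation-study toolkit for
answering that question for the binary-state speciation and extinction
model (BiSSE) combined with the fossilized birth–death (FBD) process. It
is aimed at phylogenetic methods developers and macroevolution
researchers who want a transparent, fully scripted pipeline:

1. **Simulate** BiSSE trees (per-state speciation λᵢ, extinction μᵢ,
   transition rates q₀₁/q₁₀) to a fixed extant size, with neutral binary
   traits and Poisson(ψ) fossil records stamped with lineage states;
2. **Derive** the two observable views of each tree — the ultrametric
   *extant* tree and the *FBD* tree with fossil tips and sampled
   ancestors;
3. **Infer** posteriors under BiSSE / BiSSE+FBD with an ODE-based
   pruning likelihood and adaptive Metropolis–Hastings MCMC;
4. **Summarise** accuracy (relative error), 95%-interval coverage,
   posterior probabilities of rate inequalities such as P(λ₁ > λ₀),
   turnover/extinction-fraction transforms, and ROC curves for
   trait–rate association tests.

The likelihood is the standard state-dependent pruning construction: on
each branch, integrated backward in age,

    dEᵢ/da = μᵢ − (λᵢ+μᵢ+ψᵢ+q_ij)Eᵢ + λᵢEᵢ² + q_ij E_j
    dDᵢ/da = −(λᵢ+μᵢ+ψᵢ+q_ij)Dᵢ + 2λᵢEᵢDᵢ + q_ij D_j

with fossil tips entering as ψ·Eᵢ(t), sampled ancestors as ψ factors,
and a free root-state probability π₀. See `docs/methods.md` for the full
model description, priors and design choices.

## Worked example

```python
import numpy as np
import fossilbisse as fb
import fossilbisse.summarize as sz

rng = np.random.default_rng(7)
ds = fb.generate_replicate(fb.SCENARIOS["S1"], psi=0.1,
                           neutral_specs=[], n_extant_stop=100, rng=rng)
print(len(ds.extant.tips()), len(ds.occurrences))   # 100 124

settings = fb.MCMCSettings(iterations=2000, target_samples=500)
trace = fb.run_mcmc(ds.fbd, "bisse_fbd", settings=settings, seed=12)
print(sz.summarize_trace(trace).to_string(index=False))
```

```
parameter     mean  lower95  upper95
  lambda0 0.093478 0.072945 0.115334
  lambda1 0.120116 0.079218 0.171923
      mu0 0.021732 0.008017 0.042095
      mu1 0.034354 0.006412 0.076361
      q01 0.012946 0.006232 0.022885
      q10 0.009301 0.001386 0.023078
      psi 0.096142 0.077546 0.115457
      pi0 0.685684 0.202986 0.986674
```

The replicate was simulated under S1 (λ = 0.1, μ = 0.03, q = 0.01,
ψ = 0.1): with fossils, the posterior means recover the speciation,
extinction, transition and fossil-sampling rates; running the same
dataset's extant view (`fb.run_mcmc(ds.extant, "bisse", ...)`) shows
the extinction estimates degrade once fossils are removed. (Posterior
means shown here come from a short 2000-iteration illustration chain;
study-scale analyses default to 100 000 iterations.)

The `examples/` directory holds one short narrative script per
capability (simulation, fossil views, likelihood, MCMC recovery,
spurious associations); each prints its numbers and what they mean. A
thin CLI covers the same stages:

```sh
fossilbisse replicate-study --scale 0.02 --seed 1 --out scratch/study
```

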