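# lexiphylo

Bayesian phylogenetics for binary cognate data, built for the study of
language-family history from basic-vocabulary databases. Given a doculect ×
cognate-set presence/absence matrix (with cognates grouped into meanings),
`lexiphylo` infers a clocked, rooted time tree under a binary covarion model
with per-meaning ascertainment correction, and then interrogates the
posterior with the analyses a historical linguist actually wants:

* **consensus / MCC summaries** with clade posterior probabilities and a
  census of the induced topologies over named subgroups;
* **lexical-innovation reconstruction**: the posterior probability, per
  cognate set, that it was gained on the stem branch of a focal clade
  (absent at the origin node, present at the MRCA);
* **per-cognate topology tests**: which cognates' likelihoods discriminate
  between two constrained tree hypotheses (non-overlapping 50% HPD
  intervals);
* **language-switching analysis**: parsimony reconstruction of a binary
  population trait, dating of the switching branches, and a comparison of
  lexical rates on background / transition / within-group branches;
* a **synthetic-data generator** with known ground truth (Yule trees,
  covarion characters conditioned on observability, injected innovations,
  discrete borrowing events) used as the validation harness throughout.

## The model in brief

Each cognate set evolves on the tree under a 4-state covarion process with
states (absent/slow, present/slow, absent/fast, present/fast): gain/loss
runs at a fraction α of the fast rate in the slow category, and characters
toggle categories at rate s. With observed equilibrium frequencies
(f₀, f₁) and hidden frequencies (½, ½), the generator is normalized so one
unit of branch distance is one expected gain+loss per cognate. Because
all-absent characters are never recorded, each meaning's columns are
conditioned on observability:

    log L(column) ← log L(column) − log(1 − P(all covered doculects absent))

with the all-absent probability evaluated under that meaning's coverage
pattern. The tree prior is a root-conditioned (calibrated) Yule process with
a Normal(5200, 100) years-BP root calibration, LogNormal(−7.5, 2) birth-rate
and LogNormal(−10, 2) clock-mean hyperpriors, a Gamma(0.5396, 0.3819) prior
on the relaxed-clock standard deviation, and unit-mean lognormal branch-rate
multipliers. Meanings are binned by cognate count (1–10, 11–20, ...), each
bin receiving a relative rate multiplier constrained to weighted mean 1.
See `docs/methods.md` for the full account.

## Worked example

Simulate a small dataset with known truth, infer, and summarize:

```python
import numpy as np
from lexiphylo import (SimulationConfig, simulate_dataset,
                       partition_by_meaning_size, ChainConfig, run_chain,
                       combine_runs)
from lexiphylo.mcmc import ess

cfg = SimulationConfig(n_taxa=10, n_meanings=12,
                       mean_cognates_per_meaning=10, seed=7)
sim = simulate_dataset(cfg)
scheme = partition_by_meaning_size(sim.matrix)

runs = [run_chain(matrix=sim.matrix, scheme=scheme,
                  config=ChainConfig(generations=10_000, sample_every=20,
                                     seed=s))
        for s in (1, 2, 3)]
post = combine_runs(runs, burnin_fraction=0.1)

print(len(post), "posterior samples,",
      f"ESS(posterior) = {ess(post.params['posterior'].to_numpy()):.0f}")
print("root age: median "
      f"{np.median(post.params['root_age']):.0f} BP (true {cfg.root_age:.0f})")
```

Output from this exact script:

```
1350 posterior samples, ESS(posterior) = 557
root age: median 5199 BP (true 5200)
```

The 1350 samples are three chains of 500 samples each after 10% burn-in;
the root-age posterior sits on its calibration, as it should at this data
size. (Clade supports at this scale are honestly weak: with the realistic
rarity of cognates, most simulated columns are singletons and carry little
topological signal — a property of the data regime, not of the sampler.)
The same posterior objects feed the downstream modules
(`innovation_posterior`, `discriminating_cognates`, `fitch_asr`,
`weighted_mean_rates`).

A shell-first workflow is available through the `lexiphylo` CLI
(`simulate`, `data validate|filter|freqs|partition`, `infer`, `innovations`,
`topotest`, `contact`, `pipeline`); `lexiphylo pipeline config.yml` runs the
whole chain of stages from one YAML file and writes a manifest with
checksums, seeds, and per-stage timings.

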