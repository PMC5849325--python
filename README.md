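# lgpnet

Linear genetic programming (LGP) classifiers and synergy-network analysis for
case/control metabolomics studies.

Most single-marker association scans miss disease signals that live in
*combinations* of metabolites: a pair of concentrations can be jointly
predictive while each member shows no marginal effect at all. `lgpnet`
searches for such signals by evolving populations of small register-machine
programs that classify samples as case or control, then mining the ensemble of
best-of-run programs for which features — and which feature *pairs* — they
actually use.

## The method

**Classifier representation.** A model is an imperative program over a
register file: read-only feature registers (one per metabolite), writable
calculation registers `r[0..K-1]` initialized to 1, and integer constants
`{1,…,10}`. Instructions are assignments `r[d] = a op b` with
`op ∈ {+, −, ×, ÷, x^y}` (protected: division by ≈0 gives 1, powers are
`|a|^b` capped at 10⁶) or conditionals `if a < b` / `if a > b` that guard the
single following instruction; a chain of consecutive conditionals guards the
one instruction after the chain and requires every condition to hold. After
sequential execution the output register `r[0]` is mapped through the logistic
sigmoid `S(x) = 1/(1+e^{−x})`; a sample is called a case iff `S(r[0]) ≥ 0.5`.

**Search.** A (μ+λ) evolutionary algorithm (defaults μ = λ = 500, 500
generations) with tournament parent selection (size 16), segment
recombination, point mutation restricted to *effective* instructions, and
truncation survival. Fitness is the mean classification error (MCE) on the
training fold. Effective instructions are found by backward structural
reachability from `r[0]`; instructions that cannot influence `r[0]`
(introns) are provably removable — the effective subset reproduces the full
program's output exactly.

**Ensemble analysis.** Each run uses stratified 5-fold cross-validation, so
`n` seeds yield `5n` best models with held-out MCE / sensitivity /
specificity / AUC. Across the collection, each model contributes its set of
*effective features*; singleton occurrence and pairwise co-occurrence
frequencies are tabulated, and the top fraction (default 1%) of pairs forms a
weighted **synergy network** whose high-degree / high-closeness /
high-betweenness vertices are the candidate hub and bottleneck metabolites.
A second, restricted round re-runs the search using only the network's
vertices on both a discovery and a replication split; the intersection of the
two top-20 occurrence rankings is the replicated key-feature set. A logistic
regression on the same folds provides the linear baseline.

**Data preprocessing** (fixed order): mean-ratio batch correction → OLS
residualization on age/sex/BMI → stratified discovery/replication split →
per-split z-scoring. A synthetic-data generator emulates a case/control
metabolomics cohort (log-normal concentrations, batch effects, covariate
effects) with planted main effects and purely synergistic pairs (product or
XOR-threshold interactions), for validating the whole chain end to end.

## Worked example

Evolve a small batch on synthetic data with one planted XOR-threshold pair
(features `M002`/`M003`, no marginal effect) and inspect what the ensemble
used:

```python
import numpy as np
from lgpnet import (SyntheticConfig, EvolutionConfig, generate, batch_correct,
                    adjust_covariates, normalize, run_batch, summarize,
                    count_occurrences, top_k)
from lgpnet.synthetic_data import SynergySpec

cfg = SyntheticConfig(n_cases=60, n_controls=60, n_features=8, n_batches=2,
                      main_effects={}, synergies=(SynergySpec((2, 3), "xor", 4.0),))
data, truth = generate(cfg, np.random.default_rng(7))
data = normalize(adjust_covariates(batch_correct(data)))

ecfg = EvolutionConfig(population_size=60, n_parents=60, n_generations=40,
                       tournament_size=8, max_program_length=10, n_calc_registers=6)
models = run_batch(data, ecfg, n_seeds=3)     # 3 seeds x 5 folds = 15 models
print(summarize(models).round(3))
print(top_k(count_occurrences(models), 4).to_string(index=False))
```

prints

```
                  mce  sensitivity  specificity    auc
Mean            0.389        0.656        0.567  0.633
Median          0.375        0.667        0.583  0.653
Min             0.083        0.333        0.083  0.264
Max             0.667        0.917        1.000  0.868
Std dev         0.143        0.183        0.248  0.166
5% confidence   0.108        0.296        0.080  0.308
95% confidence  0.670        1.015        1.054  0.959
feature  count  frequency
   M002     11   0.733333
   M003     11   0.733333
   M005      8   0.533333
   M006      7   0.466667
```

The summary rows follow the mean ± 1.96·sd convention for the 5%/95% bounds.
Even at this tiny search budget the planted pair tops the occurrence ranking
(11 of 15 models each), while no single-feature statistic would flag it: both
members' point-biserial correlations with the label are near zero. The best
single model reaches a held-out AUC of 0.868.

The same workflow is scriptable from a shell via the `lgpnet` CLI
(`simulate`, `preprocess`, `evolve`, `analyze`, `network`, `pipeline`,
`report`); see `lgpnet --help`.

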