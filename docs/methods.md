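# Methods

## Program semantics

A classifier is a sequence of at most 500 instructions over a register file
with `n_features` read-only feature registers, `n_calc_registers` (default
150) writable calculation registers, and literal constants drawn at creation
from `{1,…,10}`. All calculation registers start at 1.0 on every execution;
`r[0]` is the output register. Two instruction kinds exist:

- assignment `r[d] = a op b`, `op ∈ {+, −, ×, ÷, ^}`, destination always a
  calculation register (features are never overwritten);
- conditional `if a < b` / `if a > b`, guarding the single next instruction.
  A run of consecutive conditionals guards the one instruction following the
  run, and executes it only if *every* condition holds: a false condition
  skips the next instruction, and if that instruction is itself a
  conditional, the instruction it guards is skipped too. A conditional as
  the final instruction guards nothing and is a no-op.

Arithmetic is protected so that every syntactically valid program is total on
finite inputs: division returns 1 when the denominator's magnitude is below
1e-9; the power operator computes `|a|^b`, caps the magnitude at 1e6, and
returns 1 on domain error or overflow. The neutral value 1 matches the
register initialization. Classification applies the standard logistic
`S(x) = 1/(1+e^{−x})` to the final `r[0]` and thresholds at 0.5 (so class one
iff final `r[0] ≥ 0`).

Two interpreters exist: a vectorized one that executes a program on a whole
sample matrix at once, tracking a per-sample skip mask for the conditional
chains, and a scalar tracing interpreter used for inspecting single-sample
executions. They are cross-checked for exact agreement in the test suite.

## Effective code (introns)

An instruction is *effective* if it can structurally influence the final
`r[0]`. The analysis scans backward maintaining a needed-register set
initialized to `{r[0]}`: an assignment is effective iff its destination is
needed; a conditional is effective iff the instruction its chain guards is
effective (its register operands then become needed). One conservative rule
matters: an assignment that sits under a conditional may not execute at run
time, so its destination stays in the needed set. Under this rule the
effective subset, executed alone, reproduces the full program's final `r[0]`
*exactly* on every input — the property is enforced bitwise over random
programs and inputs in the tests, and fitness evaluation exploits it by
executing only the effective subset. *Effective features* are the feature
operands (conditional operands included) of effective instructions; they are
the unit of all occurrence counting.

## Evolutionary search

A (μ+λ) generational scheme with μ = `population_size`, λ = `n_parents`
(defaults 500/500, 500 generations): each generation draws offspring by
tournament selection (size 16), applies segment recombination with
probability `recombination_rate` (default 0.7; both offspring are admitted,
configurable) and point mutation with probability `mutation_rate` (default
0.9), then truncates the pooled parents+offspring to the μ best. Mutation
changes exactly one element (destination, operator/comparator, or one
operand) of one randomly chosen *effective* instruction, falling back to any
instruction when nothing is effective. Recombination exchanges one uniformly
chosen contiguous segment per parent, resampling segment endpoints until both
offspring lengths are within `[1, max_program_length]`. Truncation sorts
stably by (MCE, number of effective instructions, insertion order) — the
second key exerts mild parsimony pressure and the stable order makes runs
fully deterministic given the seed. Pooling parents with offspring makes the
best-fitness trajectory monotone (elitism), which the tests assert.

Random programs draw their length uniformly on `[1, max_program_length]`;
each instruction is a conditional with probability `p_branch` (default 0.25),
and each operand is a feature register / calculation register / constant with
probabilities 0.4/0.4/0.2. These mixing ratios are config-exposed; the
defaults simply make features reachable early in the search.

## Experiment layer

Each random seed drives one stratified 5-fold cross-validated run (per-class
fold sizes differ by at most one): the program is evolved on four folds and
scored on the held-out fold, so `n` seeds produce `5n` best models whose
metrics (MCE, sensitivity, specificity, AUC by trapezoidal rule over the ROC,
the ROC itself) never touch training samples. Single-class folds flag
sensitivity/specificity/AUC as missing rather than guessing. Per-fold seeds
derive deterministically from the run seed, and all stage seeds derive from
one master seed by a fixed affine-modular schedule (every derived seed stays
below 2³¹), so an entire pipeline run is a pure function of (data, config,
master seed).

Summary tables report mean, median, min, max, sample standard deviation
(n−1), and mean ± 1.96·sd as the 5%/95% bounds — the normal-interval
convention the reported-statistics layout uses.

## Occurrence counting and the synergy network

Each model contributes *binary* membership: a feature (or unordered feature
pair) counts at most once per model regardless of how often it appears inside
the program, and introns never contribute. Pair frequency can therefore never
exceed either member's singleton frequency (anti-monotonicity, property-
tested). Rankings break frequency ties lexicographically by feature name so
they are deterministic.

The synergy network keeps the `ceil(top_fraction × D)` highest-count pairs as
edges, with all ties at the cutoff retained; vertices are the endpoints of
kept edges, weighted by singleton frequency. The denominator `D` is a policy
— `n²` (default), `n(n−1)/2`, or the number of nonzero pairs — because the
"top 1% of all pairs" convention does not uniquely determine the edge count
on real collections; the choice is exposed rather than hidden. Centralities
are computed on the unweighted simple graph: closeness as `(n−1)/Σd` within
each connected component (isolated vertices get 0) and pair-normalized
betweenness, both via networkx. Hub/bottleneck reports rank vertices by
(degree, closeness, betweenness) with a name tie-break and list vertices
above a degree threshold (default 10). Exports are GraphML (with
`occurrence_frequency` vertex and `cooccurrence_frequency` edge attributes)
and a TSV edge list; no rendering is done here.

## Synthetic data generator

The generator emulates a targeted-panel case/control study; defaults mirror a
cohort of 153 cases and 236 controls measured on 167 metabolites in 3
batches. Per feature, log-concentrations are normal (`μ_f ~ N(1, 0.5)`,
noise sd 0.3 — wide enough for realistic right-skewed concentration spreads);
observed values are `exp(latent) × batch factor + covariate terms`, with
multiplicative batch factors `exp(N(0, 0.15))` per (batch, feature) and
additive age/sex/BMI contributions whose coefficients scale with each
feature's own spread (scale 0.3) so nuisance variation is proportionate
rather than absolute. Labels are drawn from a logistic model over the
*standardized latent* values of the planted features: main-effect terms
(defaults 0.9, −0.7, 0.5 on three features), product interactions
(`γ·z_i·z_j`, default one pair at 1.5), and XOR-threshold interactions
(`+γ` iff exactly one member exceeds its median, else `−γ`; default one pair
at 2.0 — symmetric by construction, hence near-zero marginal effect per
member). The intercept is calibrated by bisection to the requested case
fraction and exact counts are met by drawing from a larger pool (bounded
retries, then an error). A truth record (planted features, forms,
coefficients) accompanies every dataset.

What the generator does *not* emulate: missing values and limits of
detection, heteroscedastic measurement error, metabolite-metabolite
correlation structure (non-planted features are independent noise), and any
real panel chemistry. Passing tests therefore demonstrate that the framework
recovers planted synergies under clean generative assumptions, not that it
would do so at real-data noise levels.

Preprocessing follows a fixed order — mean-ratio batch correction (each value
× overall mean / batch mean per feature), per-feature OLS residualization on
[1, age, sex, BMI], a stratified discovery/replication split (cases and
controls each halved as evenly as possible), then per-split z-scoring
(population mean, n−1 variance). Batch correction makes every
(feature, batch) mean equal the feature's overall pre-correction mean, an
identity the tests verify.

## Two-round pipeline and baseline

Round one runs the evolutionary batch on the full feature set of the
discovery split, counts occurrences, builds the network, and takes its vertex
set as the reduced feature set. Round two re-runs the batch on the reduced
columns of both splits and intersects the two top-20 occurrence rankings
(ordered by discovery rank) as the replicated key features. The logistic
baseline (scikit-learn, L2 default) is trained per fold on the same
stratified partition as the first round-2 run of each dataset (verifiable via
a fold hash); non-converging folds are flagged and skipped. Round-2 metric
superiority over round 1 is *not* asserted anywhere — it is data-dependent —
only the structural guarantees (subset relations, leakage-freedom,
reproducibility) are.

## Validation scales

All validation runs are sized for a single CPU core:

- collection-cardinality check: 200 seeds × 5 folds at population 10,
  3 generations, 40 samples × 6 features (the 1000-model count depends only
  on the design, not the search budget);
- intron-removal check: 100 random programs (length ≤ 40) × 100 random
  inputs, exact equality;
- planted-synergy recovery (`lgpnet.recovery`): 10 replicate worlds of 160
  cases + 160 controls × 10 features with a single XOR pair at coefficient 4
  (Bayes accuracy ≈ 0.98), population 100, 60 generations, tournament 8,
  program length ≤ 10, 6 registers; 6 evolutionary seeds in round 1 (stable
  occurrence statistics need restarts) and 4 in round 2 (restricted search
  space); network cutoff at the top 5% of n² pairs, since 1% of 10² would
  keep a single edge. Success means the pair enters the round-1 top-5
  occurrence ranking and survives the round-2 intersection; across
  replicates the evolved models' mean held-out AUC must exceed the logistic
  baseline's, which stays near 0.5 because a linear logit cannot express the
  XOR rule.

## Known limitations

- The intron analysis is structural and conservative: semantically dead code
  that is structurally connected to `r[0]` (e.g. multiplying by an expression
  that is always 1) counts as effective.
- Protected operators make the search space total but introduce flat regions
  (everything undefined maps to 1) that carry no gradient for selection.
- Occurrence statistics are only as good as the ensemble is diverse; with few
  seeds the top-k rankings are noisy, which is why the recovery experiment
  uses more restarts in round 1.
- The default full-scale settings (population 500 × 500 generations × 200
  seeds) are faithful to the published design but computationally heavy;
  the library is written so that all structural claims hold at any budget,
  and the validation suite exercises reduced budgets only.
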