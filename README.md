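# gtrel

Generalizability-theory (GT) reliability analysis for trial-level
psychophysiological scores: single-trial ERP amplitudes, per-split
heart-rate-variability measures, rectified EMG magnitudes, skin
conductance responses — any already-scored observation collected over
many trials, splits, occasions, or tasks.

Classical test theory lumps all measurement error into one number.
Psychophysiological data have many identifiable error sources at once:
trial-to-trial noise, session effects, task differences, unequal usable
trial counts after artifact rejection, and skewed, zero-bounded score
distributions.  GT handles this by decomposing observed-score variance
into components — a **G study** — and then projecting reliability for
any planned design — a **D study**.  `gtrel` implements both phases for
researchers who need to report defensible reliability for individual-
differences work, decide how many trials a paradigm needs, compare
reliability across tasks, or evaluate the reliability of difference
scores.

## The model

A score of person *p* on trial *i* is decomposed as

```
X_pi = μ + (μ_p − μ) + (μ_i − μ) + (X_pi − μ_p − μ_i + μ)
σ²_X = σ²_p + σ²_i + σ²_pi,e
```

where the person × trial interaction is confounded with residual error
(`pi,e`).  From the components, for n′ trials:

- generalizability  **Eρ² = σ²_p / (σ²_p + σ²_pi,e/n′)** — relative
  error only (rank-order consistency);
- dependability  **φ = σ²_p / (σ²_p + σ²_pi,e/n′ + σ²_i/n′)** —
  absolute error, counting trial mean differences;
- per-trial ICCs (the n′ = 1 structure), coefficients of equivalence /
  stability / both (CE, CS, CES) for trials × occasions designs,
  cut-score dependability (adds (μ − C)² to the signal), split designs
  (Persons × (Trials:Splits)), and difference-score reliability with
  concurrent or non-concurrent error covariances.

Two estimators produce the components: exact expected-mean-squares
ANOVA for balanced Gaussian designs, and a Bayesian multilevel Gibbs
sampler (half-t priors on component SDs; every variance draw strictly
positive) for unbalanced data, non-Gaussian families (lognormal,
chi-square-like via a square-root scale), per-condition components from
a single fixed-facet model, and heteroscedastic residuals.  See
`docs/methods.md` for the full account.

## Worked example

Three error-monitoring tasks (flanker, Stroop, go/no-go) with 420
trials each are simulated with *identical* per-trial signal quality,
but only commission-error trials are usable and error rates differ
(21%, 17%, 12%).  A single location-scale model with task as a fixed
facet yields per-task components:

```python
import gtrel

table, truth = gtrel.make_worked_example(seed=17)
design = gtrel.DesignSpec(facets=[gtrel.Facet("trial"),
                                  gtrel.Facet("task", "fixed")])
counts = table.data.groupby(["task", "person"]).size().groupby("task").mean()

fit = gtrel.estimate_bayes(table, design, seed=23,
                           mcmc=gtrel.MCMCConfig(thin=12, warmup=1200))
per = gtrel.components_by_fixed_level(fit, "task")
for task in ("flanker", "stroop", "gonogo"):
    vc = per[task]
    icc = gtrel.coefficient(vc, gtrel.DStudyScenario(n_trials=1, coefficient="ICC_rel"))
    phi = gtrel.coefficient(vc, gtrel.DStudyScenario(n_trials=float(counts[task]), coefficient="D"))
    print(task, round(icc.value, 3), round(phi.value, 3), phi.interval)
```

prints

```
task       n_trials    ICC    phi  95% CrI
flanker        88.4  0.085  0.886  [0.851, 0.917]
stroop         72.2  0.092  0.874  [0.834, 0.906]
gonogo         50.4  0.108  0.855  [0.811, 0.893]
```

Read it as: per-trial signal quality (ICC ≈ 0.09–0.11) is the same
across tasks, but dependability at the *observed* trial counts is
ordered by how many usable trials each task retains — the task with the
most errors wins, not the task with the cleanest signal.  Evaluating
all three at a common trial count makes the differences vanish
(`gtrel.contrast` quantifies each pairwise difference with a credible
interval).  A projection answers the planning question directly:

```python
proj = gtrel.project(per["gonogo"], None, "D", range(1, 201), 0.90)
print(proj.minimal_n)   # 77 trials for phi >= 0.90 on go/no-go
```

## Command line

```
gtrel simulate --config sim.yaml --seed 11 --out data/
gtrel gstudy --input data/data.csv --design design.yaml \
      --estimator bayes --seed 7 --out gstudy/
gtrel dstudy --components gstudy/components.json --design design.yaml \
      --coefficient D --n-trials 40 --n-trials-grid 1:200 --target 0.9 \
      --out dstudy/
gtrel diff --input pair.csv --design design.yaml --concurrent --out diff/
```

Inputs are long-format CSV/TSV (one row per person × trial × ...);
designs are small YAML files listing facets as random or fixed.  Every
run writes a manifest (config hash, seed, versions) sufficient to
reproduce its outputs.

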