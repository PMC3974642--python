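# otubench

A simulation benchmark of normalization strategies for microbiome OTU
count tables, for statisticians and bioinformaticians who need to decide
— or demonstrate — how library-size normalization affects downstream
analysis.  It compares **rarefying** (discard small samples, subsample
the rest without replacement to a common depth) and **proportions**
against **Negative Binomial mixture-model** machinery (median-of-ratios
size factors, a fitted mean-dispersion trend, variance-stabilizing
transformation, exact and Wald tests), on two tasks: unsupervised sample
clustering and differential-abundance detection.

## The model

Counts for OTU *i* in sample *j* are modeled as

    K_ij ~ NB(mean = s_j μ_i,  variance = s_j μ_i + φ_i (s_j μ_i)²)

with *s_j* a per-sample size factor, *μ_i* the OTU's common-scale mean,
and *φ_i* its dispersion (φ = 0 gives Poisson).  The benchmark's two
synthetic frameworks are:

- **Simulation A** — samples drawn from two multinomial templates with
  disjoint support, mixed at a controlled target:non-target ratio (the
  effect size).  Each normalization × distance pairing (Bray-Curtis,
  Euclidean, Poisson deviance, top-MSD, unweighted/weighted UniFrac) is
  clustered by PAM (k = 2) and scored by the fraction of all samples
  correctly clustered — discarded samples count as wrong.
- **Simulation B** — samples drawn from one template; a random 10% of
  OTUs is multiplied by the effect size in the test class only.  Welch
  t (raw / rarefied / proportions), the NB exact test, and the NB Wald
  test are compared by ROC AUC and false-positive rate at a
  Benjamini-Hochberg threshold of 0.05.

Everything is generated from explicit seeds; no external data is
required.  See `docs/methods.md` for the full model and design choices.

## Worked example

Simulate one differential-abundance experiment (200 OTUs, 10 samples per
class, median library 2000 reads, effect size 5) and compare three
test/normalization combinations:

```python
import otubench as ob
from otubench.nb_tests import run_da_experiment
from otubench.evaluate import auc_from_results

template = ob.make_template(200, decay=0.99, seed=0)
libs = ob.sample_library_sizes(20, 2000, log_sd=1.0, seed=1)
perturbed = ob.pick_perturbed_otus(template, 0.10, seed=2)
counts, design = ob.simulate_experiment_B(
    template, libs, 5.0, perturbed, n_per_class=10, seed=3
)

for test, norm in [("nb_exact", "none"), ("welch", "rarefied"), ("welch", "proportion")]:
    res = run_da_experiment(counts, design, test, norm, seed=7)
    det = res["p_adj"] <= 0.05
    fpr = (det & ~res.is_true_positive).sum() / (~res.is_true_positive).sum()
    tpr = (det & res.is_true_positive).sum() / res.is_true_positive.sum()
    print(f"{test:8s} + {norm:10s}  AUC={auc_from_results(res):.3f}  "
          f"TPR={tpr:.2f}  FPR={fpr:.3f}")
```

Output:

```
nb_exact + none        AUC=1.000  TPR=1.00  FPR=0.011
welch    + rarefied    AUC=0.973  TPR=1.00  FPR=0.167
welch    + proportion  AUC=0.967  TPR=1.00  FPR=0.383
```

All three combinations find every truly perturbed OTU at this strong
effect, but the t-test on proportions falsely flags 38% of the
unperturbed OTUs (and the rarefied variant 17%), because neither
accounts for overdispersion and library-size inflation in the test
class; the NB exact test on the original counts stays near the nominal
false-positive level.

A command-line shell wraps the same pipeline:

```sh
otubench simulate-b --effect-sizes 2,5,10 --replicates 10 --seed 1 --out runs/b
otubench simulate-a --effect-sizes 1.5,2,5 --replicates 10 --seed 1 --out runs/a
otubench sweep-threshold --seed 1 --out sweep.tsv
otubench summarize --summary runs/b/summary.tsv
```

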