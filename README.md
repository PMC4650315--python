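# clockminer

Multi-omics evidence integration for mining candidate circadian clock genes,
with a circular regression model of transcript peak phase on clock
transcription-factor binding.

## The problem

The mammalian circadian clock is a transcriptional–translational feedback
loop (TTFL) whose known members — CLOCK/BMAL1/NPAS2 activators, PER/CRY
repressors, REV-ERB/ROR nuclear receptors, the D-box repressor E4BP4 —
regulate thousands of transcripts.  Screens for *new* clock genes produce
long candidate lists (here, a master list of 1000 genes) that need filtering
before any gene is worth experimental follow-up.  `clockminer` implements a
meta-analysis that filters such a list with three independent classes of
gene-level evidence:

* **ChIP-seq** — circadian binding of clock transcription factors near the
  gene (14 datasets);
* **proteomics** — circadian oscillation of the gene's protein product
  (3 datasets);
* **protein–protein interaction** — physical interaction with core clock
  proteins (2 datasets).

## The method

**Scoring.**  Presence of gene *g* in dataset *l* is a binary hit
*I<sub>l</sub>(g)*.  The total score is the weighted hit count
Σ<sub>d</sub> w<sub>d</sub> I<sub>d</sub>(g), with unit weights except one
particularly thorough BMAL1 ChIP-seq study weighted 3; a gene present
everywhere scores 21.

**Significance.**  Each dataset's hit count is reassigned uniformly at
random across the master list (independently per dataset); pooling all
per-gene scores over many iterations yields an empirical null, with an exact
weighted-Bernoulli convolution as an analytic oracle.  Under the published
hit counts, a total score of 13 is the smallest significant at the 0.001
level.

**Robustness.**  Because ChIP-seq dominates the dataset count, class
pre-factors (α, β, γ), α+β+γ = 1, re-balance the three classes:
S(g) = α·[ChIP-seq score] + β·[proteomics score] + γ·[PPI score].
Pre-factors are drawn uniformly from the simplex slice
0.165 < α, β, γ < 0.5 (each class weight perturbed at most 50% around the
equal split); a gene is a *robust* candidate only if significant at the
0.001 level under every one of 100 draws, each with its own null.

**Phase model.**  ChIP-seq datasets are grouped into E-box activators,
D-box repressor and RRE regulators, giving each gene normalized group
scores S<sub>E</sub>, S<sub>D</sub>, S<sub>RRE</sub> ∈ [0, 1].  Peak phases
φ of significantly rhythmic transcripts (pooled across tissues) follow a
von Mises distribution with

> E(φ) = μ + 2·arctan(c<sub>E</sub>·S<sub>E</sub> + c<sub>D</sub>·S<sub>D</sub> + c<sub>RRE</sub>·S<sub>RRE</sub>),

fitted by maximum likelihood (`CircularPhaseGLM`, statsmodels-style
Model/Results objects).  E-box binding pulls peaks toward dusk, D-box/RRE
binding toward dawn.

A synthetic-data generator (`clockminer.simulate`) reproduces these study
conditions — 1000 genes, the 19 published hit counts, phases over 14
tissues from the phase model — with planted ground truth, so the whole
pipeline is testable without any downloads.

## Worked example

```python
import numpy as np
import clockminer as cm
from clockminer.simulate import HIGH_EVIDENCE_PLANT_PROFILE

reg = cm.paper_registry()                      # the 19 published datasets
cfg = cm.SimulationConfig(n_planted=12, plant_datasets=HIGH_EVIDENCE_PLANT_PROFILE, seed=42)
rng = np.random.default_rng(42)
hits, planted = cm.simulate_hit_matrix(cfg, rng=rng)

null = cm.shuffle_null(reg, n_iterations=1000, seed=42)
print(cm.significance_threshold(null, 0.001))  # 13.0
table = cm.attach_pvalues(cm.total_scores(hits, reg), null, level=0.001)
print(len(table.significant_genes()))          # 12

res = cm.robust_candidates(hits, reg, n_draws=100, seed=42, null_method="exact")
print(len(res.robust_genes & set(planted)))    # 12  (all planted genes recovered)

scores = cm.tf_group_scores(hits, reg)
pcfg = cm.SimulationConfig(seed=42, circadian_fraction=3000 / 14000)
pooled = cm.filter_and_pool_phases(cm.simulate_phase_table(pcfg, scores, rng=rng))
fit = cm.CircularPhaseGLM.from_dataframe(pooled, scores).fit()
print(fit.summary())
```

```
Circular phase regression (von Mises, 2*arctan link)
  observations: 2935    log-likelihood: -5207.3372
  converged: True    iterations: 17

  param         estimate     std err
  mu_ct          18.1388      0.5163
  s_e            -2.2785      0.1877
  s_d             0.7203      0.0714
  s_rre           0.3425      0.1316
  kappa           0.5171      0.0274
```

The threshold 13 is the score a gene needs before its evidence is unlikely
(p < 0.001) under random hit assignment; all 12 planted high-evidence genes
survive the 100-draw robustness screen.  The phase fit recovers the
generating parameters (μ = 17.97 CT, c = (−2.25, 0.67, 0.41), κ = 0.58)
within its standard errors: a pure E-box gene is predicted to peak at
CT ≈ 9.3 (dusk side), a D-box+RRE gene at CT ≈ 0.4 (dawn).

The same stages are available from a shell:

```sh
clockminer simulate --out-dir sim --planted 12 --seed 42
clockminer score --hits sim/hits.tsv --out scores.tsv
clockminer null --exact --out null.tsv
clockminer robust --hits sim/hits.tsv --exact --out-dir robust_out
clockminer phase-fit --phases sim/phases.tsv --hits sim/hits.tsv --out-dir fit_out
clockminer run --config pipeline.yaml     # all stages, with a run manifest
```

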