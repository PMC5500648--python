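# connectomdmr

Group-level comparison of structural brain connectomes by **multivariate
distance matrix regression** (MDMR) with permutation inference, plus a
synthetic connectome-cohort simulator for validating the full pipeline.

## Who this is for

Researchers comparing groups of subjects (e.g. control vs. disease-severity
grades) on streamline-count structural connectivity matrices derived from
diffusion tractography and an M-module brain parcellation. Instead of
testing every edge separately, the method asks per module: *is the pattern
of this module's connections to the rest of the brain more different
between groups than within them?*

## The statistic

For module *i*, each subject's connectivity profile is row *i* of their
M×M symmetric streamline-count matrix (diagonal removed). Subject pairs
(u, v) are compared by the correlation chord distance

d<sub>uv</sub> = √(2·(1 − r<sub>uv</sub>)),

with r<sub>uv</sub> the Pearson correlation of their profiles, yielding
one N×N subject-space distance matrix per module. With N subjects in m
groups of sizes n<sub>g</sub>:

- SS<sub>T</sub> = (1/N) Σ<sub>u&lt;v</sub> d²<sub>uv</sub>
- SS<sub>W</sub> = Σ<sub>g</sub> (1/n<sub>g</sub>) Σ<sub>u&lt;v∈g</sub> d²<sub>uv</sub>
- SS<sub>B</sub> = SS<sub>T</sub> − SS<sub>W</sub>
- pseudo-F = (SS<sub>B</sub>/(m−1)) / (SS<sub>W</sub>/(N−m))

The pseudo-F is not F-distributed for general dissimilarities, so its
p-value comes from shuffling group labels (default 10,000 permutations,
add-one convention p = (1+b)/(1+n_perm)); Benjamini–Hochberg FDR is
applied across the M module tests of each comparison. On univariate
Euclidean data the pseudo-F reduces exactly to the classical one-way
ANOVA F — one of the test suite's oracles. See `docs/methods.md` for the
full model and design decisions.

## Worked example

Simulate a two-group cohort (36 controls, 36 LMCI-like patients, 20
modules) with a planted effect: the patients' expected streamline counts
from module 18 to half of the other modules are attenuated to 0.6×.

```bash
cat > spec.yaml <<'YAML'
n_modules: 20
group_sizes: {Control: 36, LMCI: 36}
seed: 7
effects:
  - target_module: 18
    multiplier: 0.6
    applies_to_groups: [LMCI]
YAML
connectomdmr simulate --spec spec.yaml --out data

cat > cfg.yaml <<'YAML'
data_dir: data
out_dir: results
n_perm: 999
seed: 1
alpha: 0.05
YAML
connectomdmr run --config cfg.yaml
```

which prints

```
wrote 72 subjects to data
Control_vs_LMCI: significant modules at alpha=0.05: 18, 5, 9, 2
```

and `results/Control_vs_LMCI/results.tsv` contains one row per module
(abridged, values rounded):

```
module  ss_total  ss_within  ss_between  pseudo_f  p_raw  p_fdr
1       28.437    27.655     0.782       1.980     0.018  0.072
2       37.350    36.145     1.204       2.333     0.005  0.025
...
18      36.974    33.037     3.938       8.344     0.001  0.007
```

Module 18 — the planted module — ranks first (pseudo-F 8.3, FDR-adjusted
p 0.007, at the permutation resolution of 1/1000). A few of its partner
modules (2, 5, 9) are also significant: the SC matrix is symmetric, so
attenuating edge (18, j) necessarily alters one entry of module *j*'s
profile too. The per-comparison `report.json` also records the
demographic balance battery (here age t-test p = 0.768, sex χ² p = 1.0)
and the within-group homogeneity diagnostic for the top modules.

The same analysis is available as a library:

```python
import connectomdmr as cdm

cohort = cdm.read_cohort("data/cohort.tsv")
matrices = [cdm.read_sc_matrix(f"data/sc/{sid}.tsv") for sid in cohort.subject_ids]
results = cdm.run_mdmr(matrices, cohort, n_perm=999, seed=1)
top = cdm.rank_modules(results)[0]
print(top.module, top.pseudo_f, top.p_fdr)
```

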