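# ratpheno

Behavioral phenotyping of cocaine addiction-like behavior in large,
genetically heterogeneous rat cohorts.

Extended-access self-administration studies screen hundreds of outbred rats
through a standard protocol — 10 daily 2-h short-access (ShA) sessions,
14 daily 6-h long-access (LgA) sessions, progressive-ratio (PR) tests,
a footshock-punished session, and bottle-brush irritability assays — to
quantify four constructs: **escalation** of intake, **motivation**,
**compulsivity** (aversion-resistant responding), and withdrawal
**irritability**. `ratpheno` implements the full scoring pipeline for such
screens, plus a calibrated synthetic-cohort simulator so every stage can be
verified end to end without animal data.

## The scoring model

Each behavioral measure x is normalised within cohort-by-sex groups,

```
Z = (x − μ) / σ
```

with μ and σ the sample mean and SD (n−1 denominator) of the rat's cohort ×
sex group, removing batch and sex main effects. The four measures are:

| Index         | raw measure                                              |
|---------------|----------------------------------------------------------|
| Escalation    | mean daily infusions over the last 3 LgA sessions        |
| Motivation    | infusions earned in the PR test after LgA                |
| Compulsivity  | infusions earned despite contingent footshock (0.3 mA, 30%) |
| Irritability  | bottle-brush total score, withdrawal − baseline          |

The **Addiction Index** (AI) is the unweighted mean of the escalation,
motivation and compulsivity Z-scores — irritability is excluded because it
is empirically uncorrelated with the other three. Rats are classified
**resilient** when their mean last-3-day LgA intake is below 50 infusions
per session (≈ 8 infusions/h, short-access levels) and **vulnerable**
otherwise, and split into **Low / Mild / Moderate / Severe** quartiles of
the AI (cumulative cuts at `round_half_up(N·k/4)`, which reproduces a
128/128/127/128 split at N = 511).

Progressive-ratio breakpoints follow the requirement schedule
1, 2, 4, 6, 9, 12, 15, 20, 25, 32, 40, 50, 62, 77, 95, 118, 145, 178, …
(closed form `round(5·e^(0.2 j)) − 5`), with the session ended by the first
60-min period without a completed ratio.

The statistical battery provides pooled-SD Cohen's d with 95% CIs, Pearson
correlations, Student's t-tests, PCA of the standardized index battery
(correlation-matrix eigendecomposition with a fixed sign convention), and
exact noncentral-t power/sample-size calculations.

## Worked example

```python
from ratpheno import (GeneratorConfig, simulate_cohort, summarize_behavior,
                      build_indices, cohens_d, pearson_r, pca_indices)

config = GeneratorConfig()          # 567 cocaine rats + 49 naive, 12 cohorts
tables, truth = simulate_cohort(config, seed=42)
summaries = summarize_behavior(tables)
index_table = build_indices(summaries, tables.rats)
print(index_table.head(4).round(3))
```

```
  rat_id  escalation_z  motivation_z  compulsivity_z  irritability_z  addiction_index vulnerability severity
R4200000         0.103        -0.999          -0.021          -0.041           -0.306    vulnerable     Mild
R4200001         0.486         1.206          -0.196           0.103            0.499    vulnerable   Severe
R4200002         0.930        -0.170           1.190          -0.198            0.650    vulnerable   Severe
R4200003        -0.196         0.176          -0.941           0.206           -0.320    vulnerable     Mild
```

Each row is one rat: its four standardized indices, their three-way average
(the AI), and the two phenotype labels. Population-level statistics:

```python
merged = summaries.merge(tables.rats, on="rat_id")
d = cohens_d(merged.loc[merged.sex == "F", "shock_infusions"],
             merged.loc[merged.sex == "M", "shock_infusions"])
r = pearson_r(summaries.preshock_infusions, summaries.shock_infusions)
pca = pca_indices(index_table[["escalation_z", "motivation_z",
                               "compulsivity_z", "irritability_z"]].dropna())
```

prints, for this seed:

```
vulnerable fraction: 0.795
sex effect on shock infusions: d = 0.74 [0.57; 0.91]
preshock -> shock correlation: r = 0.59 (p = 1e-54)
PC1 loadings: escalation 0.43, motivation 0.64, compulsivity 0.64, irritability 0.03
```

i.e. ~80% of the cohort escalates intake, females out-respond males under
punishment at a medium effect size, pre-punishment responding strongly
predicts punished responding, and the first principal component aligns with
the three addiction indices while irritability is nearly orthogonal —
the structure the Addiction Index is built on.

The same run is available from the shell:

```bash
ratpheno run --seed 42 --out out/          # simulate + score + stats bundle
ratpheno simulate --seed 7 --out sim/      # just the synthetic cohort CSVs
```

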