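# bipolarnet

Symptom-network analysis of bipolar disorder **course types**.

Patients with bipolar disorder follow very different two-year
trajectories — some stay largely euthymic, some are chronically
depressed, some cycle between poles — and the past course is among the
best predictors of the future one. `bipolarnet` asks whether these
course types carry *typical symptom-network signatures*: it

1. classifies each patient into one of three longitudinal course groups
   (**mildly impaired / predominantly depressed / cycling**) from
   24 months of Life Chart Method ratings (monthly 0–4 impairment for
   depression and mania, mixed months counting toward both poles);
2. prepares QIDS-SR16 and YMRS raw item scores: published-rule scale
   totals, selection of each patient's most symptomatic of five
   assessments (argmax of summed pooled z-scores), merging of
   overlapping items into 14 symptom variables (max pooled z,
   back-transformed to the reference item's raw scale), and a 94%
   zero-fraction screen;
3. estimates a complete weighted network per group — nodes are the 14
   symptoms, edge weights are groupwise Spearman rank correlations
   ρ_ij — and computes
   * weighted **density** `D = (2/(k(k-1))) Σ_{i<j} ρ_ij`,
   * **node strength** `s_i = Σ_j ρ_ij` (weighted degree centrality),
   * **random-walk betweenness** (Newman's current-flow betweenness
     with conductance |ρ|, normalised by (k−1)(k−2)/2);
4. compares groups with percentile-bootstrap 95% CIs (patients resampled
   with replacement, 10,000 iterations), a CI-overlap rule (distinct if
   overlap < 50% of the mean CI width), top-5 centrality tables, and a
   sensitivity analysis that averages edge weights over all five
   timepoints.

A Gaussian-copula / Markov-chain **synthetic cohort generator**
(`bipolarnet.simulate`) produces study-shaped data — 125 patients split
47/42/36, type-specific mood dynamics, ordinal items with controlled
rank-correlation structure — so the whole pipeline is testable without
patient data. It is first-class, tested code, not a fixture.

The intended audience is researchers in psychopathology network
analysis and biostatisticians reproducing or extending course-type
network comparisons.

## Worked example

```python
from bipolarnet import (CohortSpec, simulate_cohort, classification_report,
                        RunConfig, run_full_pipeline)

charts, panel, truth = simulate_cohort(CohortSpec(seed=42))
print(classification_report(charts)["label"].value_counts().to_dict())

config = RunConfig(output_dir="out", seed=42, n_iter=2000)
bundle = run_full_pipeline(config, charts=charts, panel=panel)
print(f"mean QIDS at peak {bundle.mean_qids_at_peak:.1f}")
for group in ("mildly_impaired", "depressed", "cycling"):
    s = [x for x in bundle.bootstrap_summaries
         if x.group == group and x.metric == "density"][0]
    print(f"{group:16s} density {s.point_estimate:.3f} "
          f"(95% CI {s.lower:.3f}-{s.upper:.3f})  "
          f"top strength: {', '.join(bundle.top_strength[group][0][:3])}")
```

prints

```
{'mildly_impaired': 47, 'depressed': 41, 'cycling': 37}
mean QIDS at peak 11.1
mildly_impaired  density 0.201 (95% CI 0.117-0.282)  top strength: energy decrease, suicidality, interest
depressed        density 0.156 (95% CI 0.075-0.247)  top strength: appetite/weight, energy decrease, concentration
cycling          density 0.201 (95% CI 0.103-0.294)  top strength: sleep quality, appetite/weight, depressed mood
```

Reading this: the rule-based classifier recovered group sizes close to
the generating 47/42/36 split; each group's density is the mean of its
91 Spearman edges at the peak timepoint, with its percentile-bootstrap
CI; the wide, overlapping CIs at n ≈ 40/group are exactly why the
original comparison is descriptive. `run_full_pipeline` also writes all
artifacts (classification report, networks as matrix/edge-list/GraphML,
pruned display networks at |ρ| ≥ 0.2, node metrics, bootstrap summaries,
CI-overlap verdicts, top-5 tables, timepoint-averaged sensitivity
networks, a manifest and a deterministic run log) to `output_dir`.

## Command line

```bash
bipolarnet simulate --seed 3 --out-dir cohort
bipolarnet classify --lifecharts cohort/lifecharts.csv --out labels.csv
bipolarnet network  --lifecharts cohort/lifecharts.csv --symptoms cohort/symptoms.csv
bipolarnet bootstrap --lifecharts ... --symptoms ... --n-iter 10000 --out cis.csv
bipolarnet sensitivity --lifecharts ... --symptoms ...
bipolarnet run-all --config run.yaml
```

Input schemas: life charts as tidy CSV (`patient_id, month_index (1–24),
dep_severity, man_severity`); symptoms as tidy CSV (`patient_id,
timepoint (0–4)`, one column per raw item `q01..q16`, `y01..y11`). An
SPSS `.sav` can be ingested through an explicit column-binding map
(`bipolarnet.pipeline.read_spss_panel`).

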