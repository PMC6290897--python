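# irsigflow

Multivariate analysis of **inhibitory-receptor (IR) signatures** on gated
immune cell subsets from flow cytometry cohorts — built for studies that ask
whether combinational IR expression (PD-1, TIGIT, TIM-3, CD160, LAG-3) on
γδ T cells separates clinical groups such as ART-suppressed HIV+ vs
uninfected subjects, stratified by age.

The package is aimed at computational immunologists who have per-subject
event tables (cells × channels), a cohort design, per-batch
fluorescence-minus-five (FM5) background controls, and plasma/supernatant
analyte panels, and who want a reproducible, scriptable version of the
CITRUS + regression + PLS analysis stack usually spread across GUI tools.

## What it computes

* **Combinational signatures** — FM5-quantile IR gates per batch, γδ
  extraction (CD3+ γδTCR+), the abundance of every positivity pattern over a
  chosen IR set (the 3-IR set PD-1/TIGIT/CD160 gives the eight combinational
  subsets), ≥2/≥3/≥4-IR fractions over all five IRs, and median-intensity /
  FM5-ratio summaries.
* **CITRUS-style cluster association** — Ward/Euclidean clustering of pooled
  events on seven lineage channels (CD3, CD4, CD8, γδTCR, CD127, CD16, CD56);
  per-sample median IR intensities of every cluster ≥ 5% of the pool; then
  (a) a cross-validated **nearest shrunken centroid** (PAM) model reporting
  the minimal feature set that predicts the groups, and (b) **SAM**-style
  selection of all features significant at a target permutation-estimated FDR.
* **Beta regression with a permutation minP threshold** — each subset
  abundance y ∈ (0,1) is modeled as y ~ Beta(μφ, (1−μ)φ) with
  logit(μ) = β₀ + β_HIV·HIV + β_age·old; family-wise error over the eight
  subsets is controlled by permuting each subject's abundances across the
  subset labels, recording the minimum p per term per permutation, and taking
  the 5th percentile of the minima as the per-term significance threshold.
* **PLSR / PLS-DA** — NIPALS decomposition on z-scored blocks, latent-variable
  count chosen by one-third (3-fold) cross-validation, orthogonal rotation for
  maximal LV1 separation, VIP scores (mean-square normalized to 1, VIP > 1 =
  above-average contributor), and model confidence from Y-permutation with a
  one-sided Mann–Whitney U comparison of held-out errors.
* **Univariate layer** — Welch t-tests with Bonferroni correction (six
  four-group comparisons → displayed threshold 0.008), Pearson correlation
  matrices of the eight combination abundances per stratum, per-cell analyte
  normalization with a 45% responder cutoff, and analyte-on-TIGIT⁺-fraction
  regressions.
* **Synthetic cohort generator** — a fully parameterized simulator of the
  whole study (cohort design, event matrices with bimodal and non-bimodal IR
  expression, FM5 controls, plasma and supernatant panels) with known ground
  truth, so every stage is testable end to end without any external data.

## Worked example

```python
from irsigflow import (SyntheticConfig, generate_cohort, build_signature_table,
                       fit_all_subsets, minp_thresholds, apply_thresholds)

cfg = SyntheticConfig(group_sizes=(8, 8, 8, 8), events_per_subject=800,
                      n_batches=2, seed=42)
design, events, fm5, plasma = generate_cohort(cfg)
sig = build_signature_table(events, design, fm5)        # 8 combo columns + more
combos = sig[[c for c in sig.columns if c.startswith("combo_")]]

fits = fit_all_subsets(combos, design.reset_index(drop=True))
thresholds = minp_thresholds(combos, design, n_perm=100, seed=1)
print({t: round(thr.threshold, 4) for t, thr in thresholds.items()})
print(apply_thresholds(fits, thresholds)["hiv"])
```

prints

```
{'hiv': 0.0053, 'age': 0.005}
['combo_+--', 'combo_-++', 'combo_-+-', 'combo_---']
```

i.e. the permutation-derived per-term significance thresholds (far below the
nominal 0.05, as expected when the smallest of eight p-values is the test
statistic), and the combinational subsets whose HIV coefficient clears the
HIV-term threshold — here the TIGIT-containing subsets rise and the
TIGIT-negative “resting” subsets shrink, matching the generator's planted
HIV effects.

The same analysis runs from the shell:

```bash
irsigflow all --config config.yaml --seed 3 --out results/
```

writing TSV artifacts and JSON reports for every stage
(simulate → gate → signatures → citrus → betaperm → pls → plsda → report).

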