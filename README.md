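# hrdkit

Homologous-recombination deficiency (HRD) scoring linked to platinum
response in preclinical breast-cancer models.

Triple-negative breast cancers are frequently HR-deficient, which
sensitizes them to platinum salts; the clinical problem is predicting,
per tumour, who will respond. `hrdkit` implements the computational
chain used to study this question in patient-derived xenografts (PDX):

* **shallow-WGS HRD calling** — a binned copy-ratio profile (50 kb
  windows) is segmented per chromosome by penalized least-squares
  change-point detection; a per-profile minimal-CNA cutoff is estimated
  from the level-difference distribution of large segments; **LGAs**
  (large-scale genomic alterations) are counted as chromosome-arm breaks
  between adjacent (< 3 Mb apart) segments of more than 10 Mb.
  More than 20 LGAs ⇒ HRD, fewer than 18 ⇒ HRP, 18–20 ⇒ borderline
  (flagged for review, never auto-resolved).
* **allele-specific scar scores** — LOH (loss-of-heterozygosity regions
  ≥ 15 Mb, shorter than the chromosome), TAI (telomeric allelic
  imbalance over > 500 probes with a balanced centromere) and LST
  (state changes between adjacent ≥ 10 Mb segments after 3 Mb
  smoothing), summed to an HRD scar score.
* **tumour response metrics** — V = a·b²/2 from caliper diameters;
  ΔVol\_t = 100·(V\_t−V₀)/V₀; BestResponse = min ΔVol (t ≥ 14 d);
  BestAvgResponse = min running mean of ΔVol; CR/PR/SD/PD by the
  ordered strict rules (CR: < −95 and < −40; PR: < −50 and < −20;
  SD: < 35 and < 30; PD otherwise).
* **RAD51 functional assay scoring** — percent of geminin-positive
  cells with > 5 RAD51 foci; HR-deficient if the cisplatin-treated mean
  is below 10%.
* **somatic variant filter cascades** (WES cohort and targeted panel),
  gene-list restriction, and LOH inference from variant allele
  frequency.
* **fusion-derived deletion detection** — same-chromosome fusion
  transcripts spanning DNA-damage-response genes, confirmed by
  expression depletion (both region-sum and per-gene counts at or below
  the 10th percentile) on a median-of-ratios-normalized count matrix.
* **association statistics** — two-sided Fisher exact test by direct
  hypergeometric enumeration, sensitivity/specificity/PPV/NPV,
  Pearson correlation, Mann–Whitney, and Kaplan–Meier survival with the
  Gehan–Breslow–Wilcoxon test.
* **a ground-truthed synthetic-cohort generator** for every input the
  pipeline consumes (the original study data are access-restricted).

## Worked example

```python
import numpy as np
from hrdkit import synthetic, shallow_hrd
from hrdkit.genome import load_genome
from hrdkit.stats import ContingencyTable, fisher_exact_two_sided, diagnostic_metrics

# plant 25 qualifying arm breaks on the bundled toy genome and recover them
genome = load_genome("toy3")
breaks = synthetic.plan_lga_breaks(25, genome, np.random.default_rng(1))
profile, truth = synthetic.simulate_binned_profile(breaks, genome, noise_sd=0.05, seed=2)
segments, report = shallow_hrd.shallow_hrd_pipeline(profile, genome)
print(report.lga_total, report.classification)
# 25 HRD

# the published HRD-vs-response cross-tab: 29 responders (21 HRD), 26 PD (17 HRP)
table = ContingencyTable(21, 9, 8, 17)
print(round(fisher_exact_two_sided(table), 3))
# 0.007
m = diagnostic_metrics(table)
print(round(100 * m.sensitivity), round(100 * m.specificity))
# 72 65
```

The planted 25 breaks are recovered exactly even with bin noise at 10%
of the copy-level step, and the cross-tab reproduces the association
(p = 0.007) between genomic HRD and platinum response with 72%
sensitivity and 65% specificity.

A CLI mirrors the library (`hrdkit hrd-call`, `scars`, `response`,
`rad51`, `filter-variants`, `fusion-del`, `stats`, `survival`,
`simulate`, `run`); see `hrdkit --help`.

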