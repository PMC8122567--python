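# splicescreen

A toolkit for the computational side of a splicing-factor perturbation
study in cancer cells: given junction read counts for alternative-splicing
(AS) events under control and factor-knockdown conditions, it quantifies
Percent-Spliced-In (PSI), screens for factor-regulated events, discovers
position-dependent GA-rich binding motifs, quantifies minigene reporter
splice switching, and stratifies patients into survival risk groups from a
combined PSI + expression marker. A first-class synthetic-data generator
produces every input with the statistical structure the analysis assumes,
so the whole pipeline is testable end to end without any sequencing data.

It is aimed at computational biologists who want a small, reproducible,
fully tested reference implementation of this analysis pattern (the
screen → motif → validation → prognosis chain common in splicing-factor
studies), or a simulation bench for evaluating screen thresholds.

## The analysis

**PSI.** For an event with inclusion- and exclusion-supporting junction
reads \(I\) and \(E\), the default estimator is the raw junction ratio
\(\hat\psi = I/(I+E)\); an effective-length-normalized form
\((I/\ell_I)/(I/\ell_I + E/\ell_E)\) is available for skipped exons, where
inclusion is supported by two junctions.

**Differential screen.** Each event's 2×2 table
\([[I_c, E_c], [I_{kd}, E_{kd}]]\) is tested with a two-sided Fisher exact
test; Benjamini–Hochberg q-values are computed across events, and an event
is called regulated when \(q < 0.05\) and \(|\Delta\psi| \ge 0.1\) with
\(\Delta\psi = \hat\psi_{kd} - \hat\psi_c\). Negative \(\Delta\psi\) under
knockdown means the factor *activates* inclusion; positive means it
*represses* it.

**Motif discovery.** The candidate binding-site space is the 2,222 GA-rich
hexamers (≥1 G, ≥1 A, G+A ≥ 50% of positions). Overlapping occurrences are
counted in the cassette exon and flanking constitutive exons of the top
activated and repressed skipped-exon events; each word gets a binomial
z-score of its foreground rate against unchanged-event background regions,
and a positional profile compares hit densities across regions. A position
weight matrix is then elicited by EM under a one-occurrence-per-sequence
model with uniform background, seeded deterministically from the top
enriched word.

**Minigene In/Ex.** Gel band intensities give the inclusion/exclusion
index \((I+\varepsilon)/(E+\varepsilon)\); the fold-response of a
construct to knockdown or overexpression classifies it as responsive or
not, which localises the binding element across deletion mutants.

**Clinical scores and survival.** Closed forms: IHC H-score
\(\sum PI_i \times I_i\) (range 0–300), xenograft tumor volume
\(L \times W^2/2\), wound-healing migration \((W_0-W_t)/W_0 \times 100\%\).
Patients are split at the cohort medians of target-exon PSI and factor
expression — high risk = low PSI and high expression, low risk = the
reverse, mixed profiles excluded — and compared with Kaplan–Meier curves
and a log-rank test (asymptotic or permutation).

## Worked example

```python
from splicescreen import PipelineConfig, run_pipeline

cfg = PipelineConfig({"seed": 7, "simulate": {"n_events": 600, "cohort_n": 200}})
report = run_pipeline(cfg, "out")
print(report["screen"]["direction_counts"])
print(report["motif"]["top_kmers_activated"][0],
      report["motif"]["preference"])
print(round(report["survival"]["logrank_statistic"], 2))
```

prints

```
{'activated': 60, 'repressed': 64, 'unchanged': 476}
GCAGGG {'activated': 'cassette', 'repressed': 'flank'}
57.76
```

With 600 simulated events at 10% activated and 10% repressed (true
|ΔPSI| = 0.4, coverage 100), the screen calls 124 regulated events — the
planted 120 plus a handful of boundary cases. The planted activated-set
hexamer `GCAGGG` ranks first among all 2,222 GA-rich words in the cassette
exons, the repressed-set word ranks first in the flanks, and the
positional-preference calls match the planting. The log-rank chi-square of
57.8 (p ≈ 3e-14) separates the median-cutoff risk groups built from a
200-patient cohort simulated at hazard ratio 3.

The same run is available from the shell:

```
splicescreen --seed 7 --outdir out run-all
```

which writes each stage's artifact (`events.tsv`, `sequences.fasta`,
`counts.tsv`, `psi.tsv`, `differential.tsv`, enrichment and motif files,
`minigene_results.tsv`, risk/KM tables) plus an aggregated `report.json`.
Identical config and seed reproduce every artifact byte for byte.

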