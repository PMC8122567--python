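# Methods

## Scope and data model

The package implements the analysis chain of a splicing-factor knockdown
screen: PSI quantification → differential screen → motif discovery →
minigene quantification → clinical scoring and survival stratification,
plus the synthetic-data generator that feeds it. The unit of analysis is
a `SpliceEvent` in one of five categories (SE, RI, A5SS, A3SS, MXE), each
reduced to a two-count abstraction — inclusion- vs exclusion-supporting
junction reads — regardless of category; the categories differ only in
region geometry (the RI "cassette" is the retained intron and sits flush
against its flanks, the splice-site categories use shorter intron gaps).
Coordinates are 0-based half-open throughout; minus-strand events store
sense-strand sequences, and all motif scans run on the sense strand only,
since the events are stranded.

## Synthetic-data generator

The generator defines the study conditions; its defaults are held fixed.

| parameter | default | meaning |
|---|---|---|
| `n_events` | 2000 | catalog size for demo runs (10,000 for screen-calibration runs) |
| `category_mix` | (5038, 121, 354, 345, 841)/6699 | the five-category proportions of the screen being emulated |
| `frac_activated`, `frac_repressed` | 0.1, 0.1 | fraction of events whose inclusion the factor promotes / suppresses |
| `true_delta_psi` | 0.4 | PSI shift induced by knockdown in regulated events |
| `coverage` | 100 | mean junction reads per event and condition |
| `planted_motif`, `repressed_motif` | GCAGGG, GCTGGA | hexamers planted in cassette exons of activated events / flanking exons of repressed events |
| `exon_len`, `flank_len` | 120, 120 | region lengths (bp), typical internal-exon scale |
| `base_composition` | uniform | i.i.d. background base probabilities |
| `n_replicates` | 1 | libraries per condition (two-sample design) |
| `dispersion` | None | optional gamma-Poisson overdispersion of totals |

Category counts are allocated by largest-remainder rounding (ties broken
by category order), so stated per-category totals are reproduced exactly.
Regulation labels are allocated the same way and shuffled by seed.

True control PSI is uniform on [0.05, 0.95]; for regulated events the
interval is shrunk so the full knockdown shift fits inside [0, 1] without
clipping — this keeps the truth labels exact, which is what a calibration
dataset is for. Clipping still applies for configs where no such interval
exists. Knockdown PSI is control − ΔPSI for activated events and control
+ ΔPSI for repressed ones.

Counts are Poisson totals with binomial inclusion — the simplest model
consistent with a two-sample, no-replicate design; overdispersion is
available but off by default, since there are no replicates for it to
matter in.

Sequences are i.i.d. background with *rejection re-sampling* of any window
that spells either planted hexamer, after which exactly one motif copy is
inserted at a random position of the labelled region (activated → cassette
exon; repressed → one flanking constitutive exon, chosen uniformly); a
post-insertion verification catches seam artefacts and re-samples. The
planted copy is therefore the unique ground-truth signal, which makes
enrichment ranks and EM consensus exactly checkable.

The survival generator draws a latent 50/50 risk group, exponential event
times at the group hazard, and independent exponential censoring with rate
chosen so the expected censored fraction equals `censor_rate`. PSI and
expression markers are drawn on disjoint supports around 0.5 (high risk:
PSI in [0, 0.45], expression in [0.55, 1]; low risk reversed), so the
median-cutoff rule can recover the latent group; `label_noise` flips the
marker placement to degrade that separability when wanted.

**What the generator does not emulate:** mappability and length biases in
junction counting, correlated events within genes, realistic exon
composition (GC skew, splice-site consensus), motif degeneracy (a single
exact hexamer is planted, not a PWM sample), and non-proportional hazards.
Passing tests therefore demonstrate correctness of the statistics and
bookkeeping under the assumed model, not performance on real RNA-seq.

## PSI

Default is the raw junction ratio; the effective-length-normalized form
(counts divided by the number of supporting junction forms) is opt-in,
since conventions differ between pipelines and the raw ratio is the
minimal defensible default. Zero-total events get `NaN` PSI with the
low-coverage flag set — they are flagged, never silently zeroed, and
filtering is left to the screen (separation of concerns).

## Differential screen

Fisher's exact test on the pooled 2×2 table is the default engine: with
one library per condition there is no replicate variance to model, and the
exact test is assumption-light at low counts. A binomial likelihood-ratio
test (asymptotic χ², 1 df) is provided as an alternative. Replicates, when
simulated, are pooled by summation before testing. Multiple testing uses
Benjamini–Hochberg. The decision rule is q < 0.05 and |ΔPSI| ≥ 0.1, both
thresholds inclusive at the boundary; the sign convention
ΔPSI = knockdown − control makes factor-activated events negative. Events
with zero total reads in either condition are excluded with a logged
reason. The gene-level expression screen (log2 fold change of group means
with pseudocount 1, Welch t on log2 values, BH) supports the standard
|logFC|/FDR threshold filters.

## Motif discovery

The hexamer catalog is exhaustive enumeration of all 4096 words filtered
to ≥1 G, ≥1 A and G+A ≥ 50% of positions (2,222 words), sorted
lexicographically. Event sets are the top-50 activated and repressed
skipped exons ranked by q ascending, |ΔPSI| descending, event id — the
same evidence ordering used to pick validation candidates. Counting is
overlapping sliding-window (standard for short degenerate motifs);
windows containing non-ACGT characters are skipped.

Enrichment uses a binomial z of the foreground occurrence count against
the background per-window rate, two-sided normal p, BH q. The background
set is regions of unchanged skipped-exon events subsampled (by sorted
event id, deterministic) to the foreground sequence count — unregulated
events are the least biased internal control. A word absent from the
background gets a pseudo-rate of one occurrence over the background
windows; a word absent from both sets is scored z = 0, since it carries no
evidence in either direction. The repressed-set search space is the
flanking constitutive exons (introns scannable by passing those sequences
explicitly).

The EM elicitor implements the one-occurrence-per-sequence model with
uniform 0.25 background: E-step posteriors over start positions, M-step
PWM re-estimation with pseudocount 0.1 per cell, stop at 200 iterations or
log-likelihood gain < 1e-6. EM monotonicity is asserted in tests at every
iteration. Initialisation is deterministic — from the top enriched k-mer
in the pipeline, or the most frequent width-mer standalone — with no
random restarts, trading global-optimum guarantees for reproducibility;
with a planted signal the seeded start is inside the right basin.
Consensus ties (equal column probabilities) resolve to the
alphabetically first base via argmax order.

## Minigene quantification

In/Ex = (inclusion + ε)/(exclusion + ε) with ε = 1e-6 of the lane's
maximum intensity, making detection-limited zero bands finite without
materially moving non-degenerate ratios (scale invariance holds to <1%).
Fold-response is oriented so an exon the factor promotes yields values ≥ 1
under both perturbation directions (control/perturbed for knockdown,
perturbed/control for overexpression); `responsive` means fold ≥ 2.0,
an explicit reporting threshold — "slight response" has no standard
quantitative definition, so the cutoff is configurable and inclusive at
the boundary. No amplicon-length molar correction by default.

## Clinical scoring and survival

H-score uses the standard percent scale: PI ∈ [0, 100] per intensity grade
0–3, sum bounded by 300, with PI sums above 100 rejected. Tumor volume
warns and swaps when width exceeds length rather than failing, since
calliper conventions vary.

Risk groups: cutoffs are the medians of the analyzed cohort; only the two
concordant-extreme profiles are defined (low PSI + high expression = high
risk and vice versa); mixed profiles and exact median ties are excluded —
they have no stated home in the two-group design, and excluding them keeps
the groups disjoint by construction. The Kaplan–Meier estimator is
computed via lifelines and returned as an explicit (time, at-risk, events,
survival) table. The log-rank statistic is computed directly from its
definition (observed minus hypergeometric-expected events summed over
event times, squared over the summed variance) — this in-repo form is
cross-checked against lifelines in the tests and makes the permutation
option cheap; p-values come from χ²(1) by default or from label
permutation (default 10,000 resamples, add-one estimator) for small
cohorts where the asymptotic reference is doubtful.

## Pipeline

Stages communicate only through on-disk artifacts (schema-versioned
TSV/CSV, FASTA, minimal MEME text), so each stage can be rerun in
isolation and reproduces its output byte-identically from upstream
artifacts; the report JSON contains no timestamps for the same reason.
One YAML/JSON config with flat per-stage namespaces carries every
threshold; unknown keys are rejected to catch typos. Sub-seeds for the
stages are derived from the single global seed by fixed offsets.

## Problem sizes

Screen calibration (null false-call rate, direction recovery) uses 10,000
events at coverage 100 — large enough that the binomial standard error on
a 5% rate is ~0.2%. Motif recovery uses 800 events so both directions
clear 50 skipped exons. The demo pipeline uses 600 events and a
200-patient cohort; survival power checks use 500 patients at hazard
ratio 3.

## Known limitations

* The screen models a two-sample design; replicate-aware hierarchical
  tests are out of scope (replicates are pooled).
* The enrichment statistic is a normal-approximation z against an internal
  background; it is a documented stand-in, not a reimplementation of any
  particular published enrichment pipeline.
* The EM elicitor is single-width, single-motif, uniform-background
  (no ZOOPS/TCM variants, no Markov background).
* Median-cutoff risk stratification discards up to half the cohort by
  design; no Cox adjustment is provided.
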