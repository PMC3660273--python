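# Methods

`ffpetconcord` implements an FFPET-optimized microarray analysis workflow —
in-silico probe re-annotation, RMA-style expression indices, limit-of-blank
detection calls, and FF-vs-FFPET concordance scoring — together with a
synthetic matched-cohort generator that provides ground truth for every
stage. This note records the models, the parameters that matter, the
numerical conventions, and the places where the design was genuinely open.

## The synthetic cohort model

The generator emulates a matched-pair study: tumors are split into mirrored
fresh-frozen (FF) and formalin-fixed paraffin-embedded (FFPET) sections, so
both preparations measure the same latent tissue state. Sixteen tumors (8
estrogen-receptor-positive, 8 negative) form the default cohort; the ER
contrast drives all differential expression.

All quantities are log2 unless noted. For gene *g* in tumor *t*:

```
e_gt = b_g + delta_g * [t is ER+] + N(0, tissue_sd)
```

drawn once per tumor and shared by the tumor's FF and FFPET sections.
Baselines `b_g ~ U(baseline_log2_range)`; a fraction `frac_de_genes` of
genes carries a signed effect with `|delta_g| ~ U(effect_log2_range)`
(default 1.2–3.0, so every designed effect exceeds the 2-fold relevance
threshold), all other genes have `delta_g = 0`.

FF probe-level signal for probe *p* of gene *g*:

```
s_pt = e_gt + a_p + N(0, measurement_sd_ff),   a_p ~ N(0, probe_affinity_sd)
```

FFPET signal for amplification kit *k* reuses the FF draw (the mirrored
section measures the same RNA) and applies the kit's degradation profile:

```
s'_pt = s_pt - A_k - lambda_k * d_p + N(0, extra_noise_sd_k)
```

where `A_k` is a global attenuation, `lambda_k` a per-nucleotide 3' decay
applied to the probe's distance `d_p` from the transcript 3' end (the
simplest monotone model producing the 3' bias of degraded RNA, with a
closed-form 3'/5' ratio `2^(lambda * delta_d)`), and probes drop out to
background with probability `dropout_prob_k`. An all-zero profile therefore
reproduces the FF matrix byte for byte — the identity case the concordance
stage must score as 100% sensitivity and specificity.

Linear intensities add an optical background and are floored at 1 (so logs
stay finite after background handling):

```
I_pt = 2^s_pt + c_t * max(N(background_mean, background_sd), 0),  I >= 1
```

`c_t = 2^N(0, background_scale_sd)` is a per-array background level, shared
by the mirrored sections. Chips genuinely differ in overall nonspecific
background; omitting this term makes background-only probes implausibly
stable across arrays, which in turn makes flawed probe sets look more
precise than real ones.

Planted design flaws, recorded in the ground truth:

* **non-matching probes** — a fraction of probes replaced by random 25-mers
  verified absent from the reference at Hamming distance <= 3; they emit
  background only.
* **cross-hybridizing probes** — the probe's target window is copied into a
  second gene's transcript (the returned reference is mutated accordingly);
  such probes emit the sum of both genes' linear signals.
* **complete-mismatch control sets** — whole probe sets of verified-absent
  probes; the blank distribution for the limit of blank.
* a **densely tiled control transcript** (600 nt, one probe per position by
  default) is appended for the in-silico 3'/5' integrity assay, the analog
  of the beta-actin 3'/5' rtPCR assay used on real samples. Dense tiling
  keeps the probe-affinity sampling error of the ratio below a few percent,
  so the intact-RNA expectation (ratio ≈ 1) is testable at any seed.

Randomness derives from one seed through fixed named PCG64 streams
(`SeedSequence([seed, stream_id, ...])`), so outputs are byte-identical
across runs, call orders, and platforms.

What the generator does **not** emulate: probe GC/thermodynamic affinity
structure (affinities are i.i.d. normal), spliced transcripts and isoform
mixtures, spatial artifacts beyond what the zone-masking contract needs,
chemical base modification (degradation is purely signal attenuation), and
correlated gene modules. Passing tests therefore demonstrate that the
*analysis machinery* is correct under the stated statistical model, not
that the workflow's wet-lab performance claims transfer to real arrays.

## Probe re-annotation and probe-set revision

Every probe is re-mapped against the (mutated) reference on both
orientations. The matcher is pigeonhole seed-and-verify: a probe within
*k* mismatches of a window must contain one of *k*+1 disjoint exact
segments, so candidates come from exact k-mer lookup and are verified by a
vectorized Hamming count. The contract — exhaustive equivalence to a
sliding-window Hamming scan for k in 0..3 — is enforced by an oracle test
at 1,000 probes against 50 kb.

At zero mismatches each probe is `MATCH_UNIQUE` (all hits in one gene),
`MATCH_MULTI`, or `NO_MATCH`. Each probe set becomes:

* `unique` — at least `min_retained` (default 3) uniquely matching probes;
  only those probes are retained for summarization. The floor is a design
  choice: median polish needs at least two rows and three adds robustness.
* `nonunique` — not unique but containing a multi-gene probe;
* `mismatched` — everything else.

A set with both unique and flawed probes is treated as "unique with the
flawed probes dropped" rather than discarded — dropping bad probes from an
otherwise usable set is the whole point of the revision. Sets whose probes
all miss the reference even at Hamming <= 3 form the complete-mismatch
(blank) collection.

## Expression index

The classic RMA triplet, applied per amplification cohort (each method is
summarized separately), behind one `expression_index` entry point so
variants can be swapped:

1. **Spatial QC.** The chip is split into `zone_grid x zone_grid` zones;
   per zone and sample, probes deviating from the zone median by more than
   `k_mad` normal-consistent MADs are masked. The threshold is floored at
   `min_log2_dev` (default 6 log2, 64-fold) whenever the zone has any
   spread: on chips dominated by background-level probes the zone MAD
   collapses and a raw MAD rule would mask genuine signal. A zero-MAD
   (constant) zone still masks any deviation, so single-spot artifacts are
   caught. Per-sample optical noise (SD of the lowest 2% of log2 values)
   and the zone-median background surface are reported.
2. **Convolution background correction.** Per sample, observed intensity is
   modeled as exponential signal (rate `alpha`) plus normal background
   (`mu`, `sigma`), estimated in the classic way (kernel-density mode;
   half-normal spread below the mode times sqrt(2); mean excess above the
   mode). Each value is replaced by the exact posterior mean of the signal:
   the posterior is N(a, sigma^2) truncated to [0, inf) with
   `a = x - mu - sigma^2 * alpha`, giving
   `E[S|x] = a + sigma * phi(a/sigma) / Phi(a/sigma)` — strictly positive,
   and verified against numerical integration of the posterior. A constant
   sample falls back to subtracting (min - 1) with a warning. A
   `background="none"` variant (log2 of raw intensities) exists for
   analyses of the additive-background compression itself, whose closed
   form the correction would deliberately undo.
3. **Quantile normalization.** Each column's sorted values are replaced by
   the across-column mean of order statistics; ties within a column receive
   the mean of the reference values their positions span (so `[1,1,3]`
   against `[2,4,6]` yields `[2,2,4.5]`). Masked entries are excluded from
   the reference and filled by rank interpolation. Without masks or ties
   the columns share one value multiset exactly.
4. **Median polish.** Per probe set, Tukey's row/column median sweeps on
   the log2 submatrix (relative tolerance 1e-6 on the total absolute
   residual, at most 100 sweeps; rows first). Expression per sample is the
   overall plus column effect; the probe affinity profile is the row
   effects re-centered to sum to zero (the center moves into the overall
   term). Unique sets use their retained probes; blank sets use all probes;
   a set with no unmasked probe in a sample gets missing expression there.

## QC metrics

* **Limit of blank**: per sample, the 95th percentile of the blank sets'
  expression, linear interpolation between closest order statistics (so
  blanks 1..20 give exactly 19.05). At least ~20 blank sets are needed for
  the percentile to be meaningful; an empty blank list is a hard error.
* **Present calls**: percent of non-blank probe sets with expression above
  the LOB, per sample; the pooled variant compares each set's median
  expression across samples with the median LOB (a single pooled number
  per cohort needs *a* pooling rule; this one is symmetric and monotone).
* **Probe-set consistency**: for genes measured by >= 2 retained probe
  sets, the median pairwise Pearson correlation across samples; a gene is
  inconsistent when it does not exceed 0.5. The median reduces to the
  single pairwise r for two-set genes and is robust for three-set genes.
  Pearson r is invariant to per-probe-set affine changes, not to common
  per-sample shifts (those are shared signal by definition).
* **Matched-pair correlation**: Pearson r of log2 expression between the
  FF and FFPET member of each pair over shared probe sets, summarized by
  median and quartiles.
* **3'/5' ratio**: mean linear intensity of control-transcript probes in
  the 3'-most third over the 5'-most third, per sample. Intact RNA gives
  ~1; the degradation model predicts `2^(lambda * delta_d)` for probe
  groups `delta_d` apart. Under strong attenuation the observed ratio is
  capped below this prediction because both termini sink into the additive
  background — a real property of the model, so the ratio is not monotone
  across heavily degraded kits.

## Concordance scoring

Per probe set, effect size = mean log2 expression (ER+) − mean (ER−).
With the 2-fold threshold (1.0 log2) on |effect|, FF-vs-FFPET pairs fall
into TP / TN / FN / FP / WP quadrants (WP: relevant in both but the
direction flips). With FF as the gold standard:

```
sensitivity = 100 * TP / (TP + FN + WP)      specificity = 100 * TN / (TN + FP)
```

WP counts against sensitivity by default (a sign-flipped finding is not a
recovery); the alternative convention is a flag, and the two coincide
whenever no WP occurs. Specificity is the standard true-negative rate:
that is the only reading under which a perfect workflow scores 100%.
Empty denominators report missing values, never zero. Binned estimates
stratify by |FF effect| (default bins (1,1.5], (1.5,2.5], (2.5,inf), plus
the nonrelevant stratum below 1); bins under 10 records are flagged.

Because attenuation and 3' decay are additive in log2, they cancel in
group differences; what actually destroys sensitivity is signal-to-
background compression: observed log2 intensity is `log2(2^(s-A) + B)`,
so a true effect `delta` at baseline `b` is observed as

```
log2( (2^(b+delta-A) + B) / (2^(b-A) + B) )
```

(`predicted_ffpet_effect`). This closed form is the analytic oracle for
the false-negative set under attenuation and predicts which genes each kit
loses; it applies to the raw scale, hence the `background="none"` variant
for that analysis.

Per-probe-set group comparisons use the pooled-variance two-sample t test
(Welch available by flag); `power_simulation` Monte-Carlos its power at
user-supplied effect, noise sigma, alpha, and group size — the sigma is
deliberately a required argument, since no single variance describes all
genes.

## PCA

Samples are projected onto principal components of the probe-set
expression matrix: rows centered across samples, no variance scaling by
default (the common expression-PCA practice; scaling available by flag),
full SVD, and a deterministic sign convention (the largest-magnitude
loading of each component is positive) so scores are reproducible.

## Pipeline and problem sizes

`run_pipeline` (or `ffpetconcord all`) chains simulate → revise →
preprocess (per cohort) → qc → concordance → pca, writes every stage
artifact under fixed names, and emits a single report JSON whose bytes are
a pure function of config and seed. The bundled example
(`examples/config.yaml`) uses 200 genes, ~330 unique probe sets, 25 blank
sets, 16 tumor pairs, and four kit profiles, and runs in well under a
minute on one core; the test suite and the acceptance script use cohorts
of 10–300 genes, chosen so every recovery property is measured with
comfortable statistical margin at interactive runtimes.

## Known limitations

* The probe-set revision keeps a set whose unique probes split across two
  genes (possible only through pathological designs); a majority-gene
  filter would be a natural extension.
* The background model is additive-normal per array; real optical
  backgrounds have spatial structure beyond zone medians.
* Present calls implement the LOB rule only; vendor-style P/M/A detection
  calls are a different statistic and are not reproduced.
* Degradation parameters are free knobs ordered to mirror the observed
  kit quality ranking; they are not inferences about any real kit.
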