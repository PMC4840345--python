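# Methods

## The analysis model

The package compares two sets of stranded RNA sequences — a *test* set
(transcripts enriched in exosomes) and a *control* set (transcripts
enriched in, or at least resident in, the parent cells) — and asks
whether the test set over-represents short sequence elements with a
plausible regulatory reading: miRNA seed complements and RBP binding
motifs. Three modelling commitments run through everything:

1. **RNA is single-stranded and already oriented.** Only the given
   (sense) strand is scanned; reverse complementation is used solely to
   relate a target motif to a miRNA seed.
2. **Counts, not presence.** Motif frequency is the raw total
   occurrence count over a set. Two transcripts each containing a motif
   once and one transcript containing it twice contribute equally. An
   optional `normalize_counts` mode divides by the total window count
   per set for grossly unequal set sizes; it is off by default because
   the equal-frequency filter below is defined on integer counts.
3. **Ambiguity never creates signal.** Characters outside {A,C,G,U}
   become N on input, and any k-mer or PWM window containing an N is
   skipped, on both the counting and the scanning paths.

## Sequence preprocessing

Input FASTA sequences are uppercased, T→U, other characters→N.
Poly-A tails — a library artefact, not genomic signal — are removed: a
terminal run of ≥ `min_run` consecutive A (default 8) at the 3' end is
deleted entirely. The run length is a design choice: 8 is long enough
that genuine A-rich 3' sequence survives, short enough to catch
truncated tails; it is exposed as a parameter. Trimming is idempotent
and may empty a pure-poly-A sequence (logged as a warning).
Coordinates are 0-based half-open internally; every written report is
1-based inclusive.

## Expression selection

Fold changes use a signed encoding: +x means x-fold up in the exosome,
−x means x-fold up in the cell, so no finite value lies in (−1, 1);
tables of raw ratios convert explicitly via `assume_ratios=True`. The
selection predicate is **inclusive** (value ≥ fc_min, default 2.0):
printed fold-change tables are rounded to one decimal, and an entry
printed exactly at the threshold is treated as passing. An optional
second filter requires the feature's z-score — computed with the
sample (n−1) standard deviation within the chosen cell line's
distribution — to reach `z_cut` (default 3.0); per-line is the default
scope, with pooled scoring available by stacking columns beforehand.

Over-expressed miRNAs are flagged with the Tukey boxplot rule on
signed log₁₀ fold change (sign(v)·log₁₀|v|): values strictly above
Q3 + 1.5·IQR with linear-interpolation quartiles, the same fence the
major point-and-click statistics packages use for boxplot outliers; the
3·IQR "extreme" fence is available via the `whisker` parameter.

Hierarchical clustering of samples uses Euclidean distance with
average linkage (configurable: single/complete/average) — the common
default for expression heatmaps — and serialises the dendrogram as
newick with merge heights as branch lengths. Leaf order is
deterministic given input order.

## The 6-mer enrichment cascade

With k = 6 (the length of a miRNA seed), every overlapping window of
every sequence is counted per set, then four filters run in order:

1. **Singleton filter** (per set): a motif counted exactly once in a
   set is deleted from that set's map *before* any cross-set
   comparison, so a motif at 5 (test) vs 1 (control) is subsequently
   compared as 5 vs 0.
2. **Equal-frequency filter**: motifs with identical counts in both
   sets are discarded.
3. **Direction filter**: only motifs with test count > control count
   survive.
4. **z-score filter**: each survivor's count difference is z-scored
   (sample sd) against the distribution of all survivors' differences;
   motifs at z ≥ 3 are reported, sorted by z descending with
   lexicographic tie-break.

z = 3 corresponds to one-sided normal coverage Φ(3) = 0.99865 ≈ 0.999.
Degenerate cases: zero survivors (e.g. identical sets) yield an empty
result; one or two survivors raise an error, because a difference
distribution that small cannot be z-scored honestly.

Note the z-score is computed within the *surviving-motif* difference
distribution, not against a background model: it identifies motifs
extreme relative to their peers, which is the intended reading of the
cascade, and it is why the singleton and equality filters run first.

## Seed matching with G:U wobble

The seed region is mature positions 2–7 (1-based, 6 nt), the standard
convention for seed-mediated targeting; `seed_start`/`seed_len` are
configurable. A motif (on the target strand) matches a miRNA when,
aligned antiparallel (motif position i against seed position 7−i),
every position pairs Watson–Crick or G:U wobble. Both wobble
orientations — target G : miRNA U and target U : miRNA G — are
accepted, since the pair is chemically identical either way. Wobble
count per match is unlimited but reported, so a stricter post-filter
(e.g. ≤ 1 wobble) can be applied without re-matching. Motifs matching
no seed are removed from the enriched list and reported separately.
Duplicate mature sequences under distinct ids are matched and reported
per id, with a distinct-sequence count available separately.

## PWM scanning

PWMs are 4×L position frequency matrices; count matrices and
DNA-alphabet (T-row) matrices are accepted and normalised. Columns are
normalised to sum 1 *before* a pseudocount of 0.01 is added and the
column renormalised — this order makes the relative score exactly
invariant under any column-wise rescaling of the input matrix. A
window scores S = Σⱼ log p(baseⱼ, j), reported as the relative score
(S − S_min)/(S_max − S_min) where S_min/S_max are the per-column
min/max attainable sums; a uniform (degenerate) matrix scores every
window 1.0 by convention. The hit threshold defaults to relative score
0.8, the web default of the RBP binding-site databases this format
models. The comparative statistic treats per-RBP site totals as
Poisson counts with the number of transcripts as exposure and tests
the rate ratio two-sided (score test).

For relating 6-mers to an RBP, a motif "is a binding site" when some
placement of the motif within the PWM achieves relative score ≥
threshold on the overlapped columns, each placement min-max normalised
on its own columns. This is the package's own construction; databases
do not document a canonical rule for sub-window matching.

## Supporting statistics

* **Kendall tau-b** (tie-corrected) for length-vs-frequency
  diagnostics, with exact-enumeration p-values for small untied
  samples and the tie-corrected normal approximation otherwise.
  Strength labels use |τ| < 0.3 negligible, < 0.6 weak, < 0.8
  moderate, else strong; the 0.3/0.6/0.8 boundaries are an inference
  from the qualitative labels this field attaches to such
  coefficients, not a universal standard.
* **One-way ANOVA** on transcript lengths, with group means and the
  max–min mean difference reported.
* **Φ(z)** for converting a z cutoff to a one-sided confidence level.

## The synthetic-data generator

The generator emulates the statistical structure of the real inputs:

* **Transcripts**: lengths log-normal with median 1500 nt (σ = 0.5 in
  log space), the scale of lncRNAs on expression arrays; uniform base
  composition by default, with composition configurable to stress-test
  enrichment against skewed backgrounds. Motifs are planted per
  transcript at a Bernoulli rate by *overwriting* bases at a uniform
  position — never inserting — so the length law is exactly preserved
  and length diagnostics can be validated under a known null.
* **Expression tables**: four cell-line columns; a planted subset of
  26 features (the scale of the real common set) at 8-fold effect with
  lognormal noise over a background of |fold change| in [1, 1.5];
  a cross-line agreement probability tunes how sharply the Venn
  intersection recovers the subset.
* **miRNA panels**: 2578 random 22-nt matures by default (the size of
  a full mature-miRNA catalogue), plus constructed responders whose
  positions 2–7 are the reverse complement of chosen motifs, optionally
  wobble-substituted.

What the generator does **not** emulate: array probe noise and
normalisation artefacts, real lncRNA base composition and repeat
structure, correlated motif co-occurrence, isoform redundancy, or any
exosome biology. Passing the planted-recovery tests therefore shows
the pipeline's machinery is correct and calibrated on clean signal; it
does not by itself validate conclusions on real transcriptomes.

## Problem sizes and numerical choices

The test-suite simulations use 150–300 transcripts per set at median
lengths 500–1500 nt, panel sizes 60–10000 and 2000 ANOVA calibration
repeats — sizes chosen so each property is measured with comfortable
statistical margin (e.g. planted-motif z lands above 15 against a
cutoff of 3, binomial checks use 3σ bands). All simulations are seeded
and deterministic; enrichment output ordering is fully specified
(z descending, then lexicographic), so reruns are byte-identical.

## Known limitations

* The bundled mature-miRNA panel mixes well-known mature sequences
  with synthetic-flank stand-ins for recently annotated miRNAs (see
  the FASTA header); only seed hexamers are load-bearing there.
* The enrichment z-score is descriptive (distance within the observed
  difference distribution), not an error-controlled test; no
  multiple-testing correction is applied, by design.
* PWM scanning scores each window independently; overlapping hits are
  all counted, which inflates site totals for low-complexity motifs on
  low-complexity sequence. The rate-ratio comparison is unaffected as
  long as both sets are scanned identically.
* `compare_rbp_counts` conditions on transcript counts as exposure;
  using total sequence length as exposure instead would be preferable
  when the two sets have very different length distributions.
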