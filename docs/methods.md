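# Methods

## The analysis model

Four cDNA libraries — oocyte, 1–2 cell, blastula, gastrula — are sampled by
single-pass 3'-end sequencing, so each EST is a draw from the stage's
transcript pool and ends at a cleavage/polyadenylation site followed by a
poly-A tail. The package treats the per-gene, per-stage EST counts as a
multinomial sample of the underlying stage-abundance profile, and treats
the position where the poly-A tail begins (after mapping the read to its
gene) as a direct observation of the cleavage site. Three consequences
drive the design:

1. **Counting is only as good as assignment.** An EST contributes to the
   matrix only if its tail is detected and a qualifying alignment exists
   (>0.85 identity to an EST contig, or >0.75 within a gene or ≤2000 bp
   downstream, read as strict inequalities). Every non-contributing read is
   logged with a reason (`no_tail`, `no_hit`, `no_qualifying_hit`,
   `ambiguous`), and assigned + discarded always reconciles with the input
   per stage.
2. **Low-copy profiles are unreliable.** A gene observed n times has
   multinomial noise of order 1/sqrt(n) on each stage proportion; the
   package quantifies this through the EST-vs-qPCR concordance experiment
   and gates downstream analysis at ≥9 total ESTs by default.
3. **Classification is a deterministic function of proportions.**
   Degrading: maternal (oocyte+1–2 cell+blastula) proportion ≥ 0.95;
   activating: blastula+gastrula ≥ 0.95; stable: all four counts positive
   and every proportion in [0.10, 0.40]. The 95% and 10/40% bounds are
   inclusive. Profiles meeting both directional criteria (only possible
   when blastula dominates) are flagged `ambiguous` rather than resolved by
   precedence. Relaxed mode adds >0.70 oocyte+1–2 cell (degrading), >0.70
   gastrula (activating) — strict inequalities, matching their "above 70%"
   definition — and widens the stable band to [0.05, 0.45]; a directional
   class outranks a coincidental fit of the widened band, which mirrors how
   the relaxed criteria were deliberately built around the unambiguous
   stages (oocyte/1–2 cell and gastrula) to avoid double assignment.

## Statistics

Kruskal–Wallis uses mid-ranks with the tie correction
1 − Σ(t³−t)/(N³−N) and an asymptotic χ² p-value (k−1 df); an all-tied
input is reported as H = 0, p = 1. Dunn's post test uses
z = Δmeanrank / sqrt[(N(N+1)/12 − Σ(t³−t)/(12(N−1)))(1/nᵢ+1/nⱼ)] with
two-sided normal p-values, Bonferroni-adjusted by default (Holm and
unadjusted available), and a compact letter display constructed by
insert-and-absorb so that two groups share a letter exactly when their
pair is not significant. D'Agostino–Pearson K² combines the D'Agostino
skewness and Anscombe–Glynn kurtosis transforms (χ², 2 df); samples with
n < 8 are flagged `insufficient n` instead of tested — the regime of
triplicate qPCR measurements. Normality is always reported before the
rank tests, but the nonparametric path is always taken: neither UTR
lengths nor small qPCR replicate sets support a Gaussian assumption.

qPCR quantification is comparative-Ct against a foreign spiked reference
added to each RNA sample before cDNA synthesis: ΔCt is formed per
replicate (pairing gene and spike by replicate index, since the spike is
physically present in the same tube), the calibrator is the stage with the
lowest mean ΔCt (ties broken by stage order), and quantities are
2^−(meanΔCt − calibratorΔCt), so the calibrator is exactly 1. The quantity
SEM is delta-method propagated: sem(q) = q·ln2·sem(ΔCt). Efficiency from a
dilution series is E = 10^(−1/slope) − 1 (slope of Ct on log₁₀ amount);
equality of efficiencies is reported, not enforced. EST/qPCR concordance is
Spearman's ρ over the four stages (Pearson optional); with four points the
coefficient is coarse — it is used for group comparisons (above vs below a
copy-number threshold), not per-gene inference — and constant profiles are
reported as undefined rather than zero.

## The synthetic generator

The generator emulates the statistical structure the analysis assumes, with
full ground truth. Defaults describe the reference experiment: 300 genes
(10 mitochondrial), four libraries of 1000 ESTs, 0.5% per-base substitution
error.

- **Classes**: degrading 0.18, stable 0.14, activating 0.20, unclassified
  0.48 (largest-remainder allocation, then shuffled). Stage profiles are
  rejection-sampled from class-specific Dirichlet priors until the strict
  rule for the class holds *uniquely* — blastula-dominated draws satisfying
  both directional rules are rejected so every labelled gene is
  recoverable in principle; after 1000 rejections the concentration
  parameters are scaled up and sampling continues. Unclassified genes draw
  from a flat Dirichlet. Mitochondrial genes are always degrading or
  stable: mitochondrial transcripts are maternally deposited, which
  reproduces the characteristic high mitochondrial share of maternal-stage
  libraries and its drop at gastrula.
- **Abundance**: per-gene weights are LogNormal(0, σ=2.0) — EST libraries
  are heavily skewed, with roughly half of detected genes observed once and
  single transcripts reaching several percent of a library — and
  mitochondrial genes carry a 25× multiplier. Per-stage counts are
  multinomial with probability ∝ weight × stage proportion.
- **3'UTRs**: lengths are log-normal per class with medians 180 (degrading),
  210 (stable), 75 (activating), 150 bp (unclassified) and σ = 0.45 (0.50
  unclassified), floored at 20 bp; a gene has a second cleavage site with
  class probability 0.457/0.346/0.154/0.25, at least 30 nt from the first
  (above the 10 nt clustering tolerance, so distinct truth sites never
  merge).
- **Motifs**: insertion probabilities per class — AATAAA 0.688/0.829/0.956
  (degrading/stable/activating; 0.80 unclassified), each of the 11
  alternative hexamers 0.06/0.09/0.025/0.05. Motif truth is *per gene*: the
  sampled motif set is placed inside the proximal isoform's exclusive
  region, because a longer isoform's sequence contains the shorter one's —
  per-isoform independent insertion would make observed prevalence exceed
  the configured probability. Background UTR sequence is scrubbed of
  accidental catalogue hexamers before and after insertion (edits are
  verified not to recreate a catalogue variant, e.g. the AATAxA family),
  so scanned presence equals inserted truth exactly.
- **Reads**: each EST covers up to 400 nt of transcript upstream of a
  uniformly chosen cleavage site, takes substitutions at the error rate
  (tails stay error-free unless `tail_errors` is set — keeping
  tail-detection testing orthogonal to the error model), and ends in a
  15–60 nt poly-A tail. The three bases immediately upstream of every
  cleavage site are forced non-A so that tail detection (max one mismatch)
  stops exactly at the site; no catalogue motif can be created by this
  (all twelve end in A, and none contains three consecutive non-A bases).
- **qPCR emulation**: gene Ct = 22 − log₂(stage proportion, floored at
  10⁻³) + N(0, 0.25) per replicate; spike Ct = 18 + N(0, 0.15).

What the generator does **not** emulate: indels and chimeric reads, vector
contamination, quality scores, internal priming on genomic A-runs,
cross-gene sequence homology (each gene gets its own contig), library-
construction biases, and correlation between abundance and transcript
class. Passing recovery tests therefore shows the inference chain is
correct under the stated sampling model, not that it is robust to every
artifact of real libraries.

## Numerical and design choices

- Coordinates are 0-based half-open in transcript orientation throughout;
  GFF3 output converts to 1-based inclusive contig coordinates.
- Poly-A detection scans from the 3' terminus, extends while the non-A
  count stays within the mismatch budget (default min length 8, max
  mismatch 1), trims non-A bases at the run's 5' edge, and tries the
  reverse complement when the given orientation has no tail.
- Isoform clustering is single-linkage with a 10 nt tolerance; isoform
  position is the support-weighted mean, rounded half-up; minimum isoform
  support defaults to 1. Both are configurable and recorded in output.
- UTR sequences for motif scanning come from the gene model's transcript,
  not from individual error-bearing reads.
- Assignment ties at equal identity prefer the longer aligned span, then
  the lexicographically smallest target id; equal-best hits on two
  different genes are discarded as `ambiguous`.
- The bundled aligner (exact 16-mer seed from the 3' end, ungapped
  extension) exists for the synthetic path only; real data should provide
  alignments from a dedicated aligner as TSV.
- Top-abundance tables break total-count ties alphabetically. Presence
  categories and composition fractions are computed on the filtered matrix
  by default; both modes are available since the threshold materially
  changes presence-category proportions.

## Validation problem sizes

The reference recovery experiment is 300 genes with 4 × 1000 ESTs. Because
per-class mean-length estimates need about 200 isoform records per class to
separate estimation noise from bias, the UTR-length recovery check runs on
a proportionally identical configuration scaled to 2400 genes and 4 × 6000
ESTs. The concordance experiment uses 100 independent replicates of 150
genes with 4 × 400 ESTs, large enough that both the low-copy (≤5) and
high-copy (≥12) groups carry stable medians.

## Known limitations

- **Classification at the copy-number threshold is intrinsically noisy.**
  With 12 total ESTs, a perfectly uniform stable gene yields counts inside
  the 10–40% band with probability 0.294 (only permutations of (3,3,3,3),
  (2,3,3,4), (2,2,4,4) qualify); at 24 ESTs roughly 0.55–0.75, at 48 about
  0.8–0.9. Overall recovery of true classes among genes passing the ≥9
  filter therefore plateaus near 80–85% under realistic abundance skew,
  dominated by stable-class genes near the threshold; degrading and
  activating genes recover at 94–99%. A practitioner wanting reliable
  *stable* calls should require substantially more than 9 ESTs.
- Dunn's test is implemented with a Bonferroni-style adjustment; the exact
  historical variant used by common GUI statistics packages is not
  documented, so the adjustment is configurable.
- Spearman over four stages takes few distinct values; concordance results
  are meaningful in aggregate only.
- The relaxed-rule precedence of directional classes over the widened
  stable band is a documented operationalization of an underspecified
  procedure, as is the 10 nt isoform tolerance.
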