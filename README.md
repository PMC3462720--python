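# estmzt

Analysis of the maternal-to-zygotic transition (MZT) from staged 3'-end EST
libraries, as produced by sequencing cDNA from unfertilized eggs and early
embryos (oocyte, 1–2 cell, blastula and gastrula stages in a teleost such
as Atlantic cod).

Early development runs on maternally deposited RNA until zygotic
transcription activates around the midblastula transition. Libraries of
3'-anchored ESTs — single-pass cDNA reads ending in a poly-A tail — capture
both *how much* of each transcript is present at each stage and *where* each
transcript is cleaved and polyadenylated. This package implements the full
analysis path from raw reads to biology:

- **EST processing** — poly-A tail detection/trimming with orientation
  resolution, identity-threshold gene assignment (>85% vs an EST contig, or
  >75% within a gene or ≤2000 bp downstream), and a genes × stages count
  matrix with a per-read discard log.
- **Copy-number reliability filtering** — genes with fewer than 9 total
  ESTs are excluded: low-copy stage profiles are noise-dominated, which the
  package demonstrates by comparing EST profiles against spike-in qPCR of
  the same genes.
- **Transcript classification** — *degrading* when ≥95% of a gene's
  transcripts sit in the maternal stages (oocyte–blastula), *activating*
  when ≥95% sit in blastula+gastrula, *stable* when present in all four
  stages with each holding 10–40%; a relaxed variant admits >70%
  oocyte+1–2-cell (degrading), >70% gastrula (activating) and a widened
  25±20% stable band.
- **3'UTR inference** — the tail start of each assigned EST, mapped through
  its alignment, is a cleavage site; UTR length = site − CDS end; sites
  within 10 nt cluster (single linkage) into isoforms; per-class length
  summaries with Kruskal–Wallis + Dunn's post test (D'Agostino–Pearson
  normality reported first).
- **Polyadenylation motifs** — exact scan for AATAAA and 11 alternative
  hexamers; per-class presence proportions and multi-motif prevalence.
- **qPCR** — comparative-Ct quantification normalized to a foreign spiked
  reference (rabbit *hba*), calibrated to the lowest mean ΔCt; standard-curve
  amplification efficiency E = 10^(−1/slope) − 1; Spearman concordance
  between EST and qPCR stage profiles and a copy-number threshold report.
- **Synthetic data** — a ground-truth generator emulating four stage
  libraries with class-conditional stage profiles, log-normal UTR lengths,
  alternative cleavage sites, controlled motif insertion, poly-A tails and
  substitution errors, so every inference step can be scored exactly.

## Worked example

```python
from estmzt.simulate import SimConfig, simulate_dataset
from estmzt.pipeline import run_pipeline
from estmzt.utr import utr_length_summary

dataset = simulate_dataset(SimConfig(seed=1))   # 300 genes, 4 x 1000 ESTs
result = run_pipeline(dataset)

print(result.census)
print(utr_length_summary(result.utr_records).to_string(index=False))
```

prints

```
{'degrading': 11, 'stable': 9, 'activating': 8, 'ambiguous': 0, 'unclassified': 24}
       class   n  mean_length       sem
  activating   8    93.375000 10.236380
   degrading  10   193.600000 29.745289
      stable   6   157.666667 24.385333
unclassified 188   176.031915  8.107579
```

Of the 52 genes surviving the ≥9-EST filter, 11 classify as degrading, 9
stable and 8 activating (24 match no rule); activating transcripts carry
clearly shorter 3'UTRs (mean ≈ 93 bp) than degrading ones (≈ 194 bp), the
hallmark of post-MZT transcripts. UTR isoform records for genes below the
filter are reported under `unclassified`. The same pipeline is available
from the shell via the `estmzt` console script (`simulate`, `process`,
`classify`, `utr`, `motifs`, `qpcr`, `report` subcommands).

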