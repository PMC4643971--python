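# negsel

Detection of **essential cancer proteins**: protein-coding genes whose intact
sequence a tumor appears to depend on. The reasoning is survivorship-based —
if cells carrying damaging mutations in a gene die, those mutations are
missing from the sequenced tumor cohort, so the gene looks *hypomutated* for
high-impact changes even though neutral mutations accumulate normally.

A gene is called essential when all four of the following hold:

1. **Enough data** — at least `min_variants` (default 11) variants in *both*
   the somatic cohort and the germline cohort;
2. **Negative selection** — somatic dN/dS (ω) below a threshold (default
   0.25, or detected as the local minimum of the genome-wide ω histogram);
3. **Expression** — mean expression above the lowest `expression_quantile`
   (default 20%) of genes;
4. **Impact depletion** — the fraction of high-functional-impact mutations
   f = #(high-impact) / #(all mutations), computed per cohort, satisfies
   f_germline > f_somatic (strict).

ω is estimated per gene by Nei–Gojobori (1986) site counting,
ω = (n/N) / (s/S), where n and s are observed missense and synonymous SNV
counts and N, S the corresponding expected site counts of the coding
sequence. A variant is *high-impact* if it is an indel, stop gain/loss or
splice-site change, or a missense SNV whose ensemble impact score (either of
two channels, MetaSVM/MetaLR-style) exceeds the empirical 70th percentile
strictly. Downstream, the essential set is tested for gene-set
over-representation (exact hypergeometric upper tail, Benjamini–Hochberg
correction) and summarized against a high-confidence interaction network
(combined score > 0.9).

Because results on real cohorts depend on specific data snapshots, the
package ships a first-class synthetic-study generator (`negsel.simulate`)
that emits every input format with planted ground truth — genes with known
true ω, depleted somatic impact, known expression class — so the whole
cascade is testable and calibratable offline.

## Worked example

```sh
negsel simulate --out example --seed 3 --n-genes 60
negsel select \
  --cds example/cds.fasta --somatic-maf example/somatic.maf \
  --germline-vcf example/germline.vcf --expression example/expression.tsv \
  --scores example/impact_scores.tsv --out example/run
```

or equivalently through the library:

```python
from negsel import EssentialGeneScreen, SimulationConfig, simulate_study

study = simulate_study(SimulationConfig(n_genes=60, random_seed=3))
results = EssentialGeneScreen(study.somatic, study.germline,
                              study.transcripts, study.expression).fit()
print(results.summary())
```

prints

```
Essential-gene screen
======================================================
genes in both cohorts                         60
pass min-variant filter (>= 11/11)            60
... and dN/dS < 0.25                           3
... and expressed (rank > 0.2)                 3
essential (all four filters)                   3
------------------------------------------------------
impact cutoffs (p70): score_a > 1.287, score_b > 1.253
expression universe size: 48
essential genes: G0034, G0047, G0058
```

All 60 genes clear the 11-variant floor; the dN/dS filter keeps the three
genes under strong purifying selection (this small study plants 5% essential
genes at true ω = 0.1), all of which are expressed and depleted of somatic
high-impact mutations — the three called genes are exactly the planted ones
(`example/ground_truth.tsv` has the truth; the pipeline never reads it).
`results.frame` holds the full per-gene report (ω, expression rank, the
germline/somatic neutral and high-impact counts, each filter's verdict);
`results.enrich(...)` and `results.summarize_network(...)` take the essential
set downstream.

## Layout

| module | contents |
|---|---|
| `negsel.reference` | transcript model, NG86 site counting, SNV consequences |
| `negsel.variants` | MAF/VCF readers, score joins, min-variant filter |
| `negsel.dnds` | per-gene ω, genome-wide histogram, threshold detection |
| `negsel.impact` | high-impact classification, per-gene fraction f |
| `negsel.screen` | the cascade; `EssentialGeneScreen` / `ScreenResults` |
| `negsel.enrich` | exact hypergeometric ORA, BH correction, GMT |
| `negsel.network` | edge loading, bait/prey and common-partner summaries |
| `negsel.simulate` | synthetic studies with planted ground truth |
| `negsel.report` | run manifests and the report bundle |

See `docs/methods.md` for the model, its assumptions and the numerical
choices.
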