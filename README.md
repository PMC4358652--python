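# rankvar

`rankvar` annotates, scores and ranks single-nucleotide variants and small
indels from cohort VCFs, for geneticists and molecular diagnosticians hunting
the causal mutation of a Mendelian disease among the thousands of rare
variants every individual carries. It ingests any combination of
multi-sample and single-sample VCFs (plain or gzip), annotates the
non-redundant union of variants once, and writes per-sample ranked
tab-separated reports that a biologist can open in a spreadsheet.

## The scoring scheme

Each variant is summarized into a single integer score
`S = S_category + adjustments`, with default category scores

| category | score | | category | score |
|---|---|---|---|---|
| known mutation | 110 | | intron–exon boundary | 70 |
| nonsense | 100 | | missense | 50 |
| frameshift | 100 | | in-frame indel | 40 |
| essential splice site | 90 | | deep intronic | 25 |
| start / stop loss | 80 | | synonymous | 10 |

plus **+5** when phastCons > 0.95 (not for frameshift, in-frame or known
mutations) and **+5 per deleterious protein prediction** (SIFT,
PolyPhen-2) for missense variants. A variant is considered to affect
splicing when at least two of the three splice-site predictors
(MaxEntScan, NNSplice, SpliceSiteFinder) report a significant score loss
(≤ −10%, −5%, −15% respectively); the two canonical intronic bases of a
splice site are *essential* regardless of predictor support. Every variant
is scored on all transcripts and through both the coding and the splice
pathway, and the most pathogenic effect is retained. Known mutations
(dbSNP clinical significance pathogenic/probable-pathogenic, or a
user-supplied list) score 110 unadjusted.

A per-variant **barcode** — one zygosity digit (0/1/2) per sample in a
fixed order — gives an immediate view of recurrence across the cohort,
and a user-ordered **family barcode** expresses inheritance hypotheses as
patterns (`121` = homozygous proband with heterozygous parents, `010` =
de novo heterozygous proband). Default filters remove calls with total
depth ≤ 10, supporting reads ≤ 10 or supporting-read ratio ≤ 15%, and
variants that are dbSNP-validated benign (≥ 2 evidences) or above 1%
population frequency; known mutations are exempt from the two
knowledge-based rules.

Two rankings are written per sample, each in `AllVariants` and prefiltered
`filteredVariants` versions: `rankingByVar` (variants by descending score;
the dominant-hypothesis view) and `rankingByGene` (genes ranked by
`max(best homozygous score, second-best heterozygous score)` — the
limiting allele under a recessive/compound-heterozygote model).

## Worked example

```python
from rankvar import SimulationConfig, Spike, generate_cohort, run_pipeline
from rankvar.ranking_output import rank_by_variant

sim = generate_cohort(SimulationConfig(
    n_samples=30, n_background_variants=1000, seed=42,
    spikes=[Spike(sample="S001", category="nonsense", zygosity=2)]))
vcf, ann, truth = sim.write("scratch/demo")
res = run_pipeline([vcf], annotation_table=ann, outdir="scratch/demo/reports")
top = rank_by_variant("S001", res.cohort, res.scored, res.decisions, filtered=True)
print(len(res.cohort.variants), res.scored[top[0]].final_score, top[0])
```

prints

```
1001 100 1_5000000_G_T
```

— a 30-sample cohort with 1,001 non-redundant variants in which the
planted homozygous nonsense mutation (score 100) ranks first in sample
S001's filtered by-variant report, while the 1,000 common background
polymorphisms (population frequency > 1%) are filtered away. The same
workflow runs from the shell via `rankvar -vcf cohort.vcf -ann
annotations.tsv -out reports/` and `rankvar-sim --seed 42 --out sim/`.

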