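# Methods

## Model

`rankvar` implements a rule-based prioritization of SNVs and short indels.
The premise is the standard one for Mendelian disease: the causal variant
is rare, has a strong predicted functional impact, and segregates in the
family. The score is not a calibrated pathogenicity probability; it is a
presentation order encoding the interpretation rules a molecular
geneticist applies by hand, so that the causal candidate surfaces in the
first lines of the report.

The score of a variant is `base(category) + adjustment`, computed per
transcript and per pathway:

* **coding pathway** — the category is the annotated coding effect
  (nonsense 100, frameshift 100, start/stop loss 80, missense 50,
  in-frame 40, synonymous 10);
* **splice pathway** — the category derives from the signed distance to
  the nearest splice site and a 2-of-3 predictor consensus (essential 90,
  close boundary 70, deep intronic 25).

Each transcript contributes `max(coding, splice)` after adjustments (a
tie is attributed to the coding effect), and the variant score is the
maximum over transcripts, so an SNV at an exon's last base is scored as
the more pathogenic of missense and splice-disruption readings, and a
variant that is intronic on one isoform but exonic on another is never
underestimated. Known-mutation evidence (dbSNP clinical significance
containing the tokens `pathogenic` or `probable-pathogenic`, or a
user-supplied variant-id list standing in for a licensed mutation
database) short-circuits everything at 110, unadjusted.

### Adjustments

+5 when phastCons > 0.95 (strict), applied to nonsense, start/stop loss,
missense, synonymous and all three splice categories; never to
frameshift, in-frame or known mutations. Missense additionally gains +5
per deleterious protein prediction: SIFT (prediction string containing
"deleterious"/"damaging", falling back to weight ≤ 0.05 when only the
numeric score is present) and PolyPhen-2 (prediction containing
"damaging" or "deleterious"). Under the default table every reachable
score lies in the 19-value set {0, 10, 15, 25, 30, 40, 50, 55, 60, 65,
70, 75, 80, 85, 90, 95, 100, 105, 110}, which the suite asserts by
enumeration.

### Splice rule

A predictor votes when its percent score change between wild-type and
mutated sequence is at or below its threshold — MaxEntScan −10%,
NNSplice −5%, SpliceSiteFinder −15%. The boundary is inclusive: a delta
of exactly −10% counts as a MaxEntScan vote (the thresholds are stated
without boundary semantics anywhere we could find; we chose the
inclusive reading and test it explicitly). Deltas are recomputed as
`100·(var−wt)/wt` whenever both raw scores are present; a supplied delta
column is trusted only when they are not. Absent predictors abstain, so
a variant annotated by no splice program can never reach the
consensus-gated categories (close, deep); essential-site positions score
90 without consensus, since disruption of a canonical GT/AG dinucleotide
is assumed significant.

Distance convention: `DistNearestSS > 0` is the intronic side of the
site, ≤ 0 the exonic side, for donors and acceptors alike. The close
windows are donor −3..+6 and acceptor −12..+2 in splice-site
nomenclature, i.e. in our convention donor dist ∈ [−3, 6] and acceptor
dist ∈ [−2, 12], minus the essential positions {+1, +2}. Intronic
positions beyond the window are deep; exonic positions beyond it fall
back to the coding pathway alone.

## Cohort handling

VCFs (plain or gzip, any mix of multi-sample and single-sample files)
are parsed with cyvcf2. Multi-allelic records are split per ALT —
genotype 1/2 is heterozygous for each alternate — and alleles are
reduced to the minimal anchored representation (shared suffix trimmed
first, then prefix, one base always retained), so differently padded
indel calls collapse to one key `chrom_pos_ref_alt`. Symbolic alleles
(`<DEL>`, breakends, `*`) are skipped with a warning; structural
variation is out of scope. Depths are read from DP/AD with an AO/RO
fallback; calls lacking depth fields simply make the depth filters
inapplicable rather than being discarded.

Sample order is lexicographic by sample id, fixed at load time and
reused by every barcode and report header, so outputs are byte-stable
across runs and input orderings. Duplicate sample ids across files keep
the first occurrence with a warning. No-call genotypes (./.) render as
"0" in the barcode — the barcode alphabet is deliberately {0,1,2} — and
are tallied separately in the load log; we preferred a small loss of
information over a fourth symbol that every downstream pattern would
have to handle.

The union of variant keys is annotated exactly once
(`annotate_non_redundant`); per-sample views are joins against that map,
and a test asserts row-identity with brute-force per-sample annotation.
The representative transcript is the gene's longest unless the variant
scores strictly higher on another transcript; ties prefer the longer
transcript, then the smaller transcript id, making the choice a pure
function of the annotation set.

## Filters

Default removals, boundaries exactly as stated: total depth ≤ 10,
supporting reads ≤ 10, supporting-read ratio ≤ 15%, dbSNP-validated
(≥ 2 evidences) and not pathogenic, any available population frequency
strictly above 1% (the maximum over all frequency columns is compared —
the conservative choice when several populations are reported). Rules
whose inputs are missing do not fire. Known mutations are exempt from
the dbSNP and frequency rules; this reproduces the documented failure
mode where a pathogenic-flagged but too-frequent variant persists in
every report and is best removed by the optional cohort-count rule
(keep when het count < N and hom count < M), which is off by default.
The depth-count and ratio rules share the threshold value 10 as printed;
with typical exome depths the read-count rule subsumes the depth rule,
a redundancy we implement literally rather than second-guess.

## Ranking

byVar sorts by descending final score, then ascending maximum population
frequency with absent frequency treated as 0 (a variant never seen in
any database is at least as interesting as one seen rarely), then
chromosome/position/alleles for full determinism. byGene ranks each gene
by `max(best homozygous score, second-best heterozygous score)` — the
recessive-model limiting allele; a gene with a single heterozygous
variant has no second allele and keys at 0 — with the best heterozygous
score, then the gene symbol, as tie-breaks. All of a gene's variants are
listed inside its block so nothing is hidden by the summary. The
category-count report tallies hom/het/total per sample and for the whole
dataset over a fixed 14-category list (UTRs, up/downstream, the coding
categories, splice site, intronic, not annotated).

## Synthetic cohorts

`rankvar.simulate` generates the structure the tool is designed around:
a pool of common background polymorphisms (allele frequency uniform on
(1%, 50%], Hardy–Weinberg genotypes independently per sample, dbSNP-
validated benign annotations) shared across the cohort — so the
non-redundant union grows sublinearly as samples are added — plus
private spiked mutations of any scoring category, annotated to land
exactly in that category. Read depths are negative-binomial (mean 50,
dispersion 10, a typical targeted-sequencing profile); heterozygous alt
depths are Binomial(depth, 0.5). The truth table's expected scores come
from a literal score-table lookup inside the simulator, independent of
the scoring module, so end-to-end tests compare against external
arithmetic. Everything is a deterministic function of the seed.

What the simulator does *not* model: sequence context, alignment or
calling artifacts, linkage between variants, population structure,
relatedness (outside the explicit trio fixture), or realistic gene
lengths. Passing the recovery test (a spiked nonsense/known mutation
ranks first in the filtered report in ≥ 95 of 100 seeded 30 × 1,000
cohorts) therefore demonstrates the engine's filtering and ordering
logic, not performance on real patient data, where annotation quality
and call quality dominate.

## Numerical and degenerate-input choices

Scores and adjustments are exact integer arithmetic; the only floating
comparisons are the strict phastCons cutoff, the inclusive splice
thresholds, and the inclusive 15.0% read-ratio boundary, all tested at
their boundaries. Zero total depth makes the supporting-read ratio
undefined (absent), not 0; alt depth exceeding total depth clamps the
ratio to 100 with a warning. Variants with no annotation score 0, are
reported with `AnnotationAnalysis = No`, and count as "not annotated".
Unscored locations (UTR, up/downstream, intronic without consensus)
score 0 and sort last but remain in all reports. Ref/alt strings are
truncated to 50 bases in report cells only; variant identifiers keep
the full alleles.

## Problem sizes

The test suite runs its end-to-end statistics at 30 samples × 1,000
background variants × 100 seeds (about a minute) and its equivalence
checks at 20 samples × 300 variants; these sizes give stable pass/fail
behaviour for rule-based (non-stochastic) logic while keeping the suite
quick to iterate on. Larger cohorts scale linearly in variants × samples.

## Known limitations

Splice categories depend entirely on upstream annotation quality
(distance and predictor deltas are consumed, never computed). The SnpEff
term map covers the common sequence-ontology terms; unmapped terms score
0 rather than guessing. Local splice effects (new/cryptic sites) are
passed through as annotation but never scored. Haploid genotypes are
folded to the diploid codes (1 → hom, 0 → ref). CNVs and other symbolic
records are skipped.
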