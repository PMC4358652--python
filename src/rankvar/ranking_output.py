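"""Ranked tab-separated reports.

For each sample four files are written: ``rankingByVar`` (one variant
per line, most to least likely pathogenic) and ``rankingByGene`` (genes
from most to least likely causative, each gene block listing all of the
sample's variants in that gene), each in an ``AllVariants`` and a
prefiltered ``filteredVariants`` version. A gene is ranked along two
criteria — its most pathogenic homozygous variant, or its first two most
pathogenic heterozygous variants (the compound-heterozygote case) — and
the rank key is the limiting allele under a recessive model:
``max(best hom score, second-best het score)``.

A per-sample and whole-dataset category-count report is produced as
well.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

from .annotation import GeneExternalAnnotation, TranscriptAnnotation
from .cohort_analysis import Barcode, FilterDecision, build_barcode, family_barcode
from .cohort_io import HET, HOM_ALT, REPORT_ALLELE_MAX, Cohort
from .scoring import Category, ScoredVariant

#: Report column layout; names follow the standard clinical
#: annotation-export column set.
REPORT_COLUMNS = [
    "VariantID",
    "Gene",
    "omimId",
    "TranscriptID",
    "TranscriptLength",
    "Chr",
    "Start",
    "Ref",
    "Mut",
    "Phred_QUAL",
    "HomHet",
    "TotalReadDepth",
    "VarReadDepth",
    "%Reads_variation",
    "CodingEffect",
    "VarLocation",
    "Exon",
    "Intron",
    "gNomen",
    "cNomen",
    "pNomen",
    "rsID",
    "rsValidation",
    "rsClinicalSignificance",
    "rsMAF",
    "espAllMAF",
    "espEAMAF",
    "espAAMAF",
    "1000g_AF",
    "delta MESscore (%)",
    "wtMEScore",
    "varMEScore",
    "delta SSFscore (%)",
    "wtSSFScore",
    "varSSFScore",
    "delta NNSscore (%)",
    "wtNNSScore",
    "varNNSScore",
    "DistNearestSS",
    "NearestSS",
    "localSpliceEffect",
    "SiftPred",
    "SiftWeight",
    "SiftMedian",
    "PPH2pred",
    "phyloP",
    "PhastCons",
    "GranthamDist",
    "VarScore",
    "AnnotationAnalysis",
    "familyBarcode",
    "Barcode",
    "Hom_Count",
    "Het_Count",
    "Allele_Count",
    "Sample_Count",
]

#: Fixed category list of the count report.
COUNT_CATEGORIES = [
    "5'UTR",
    "3'UTR",
    "upstream",
    "downstream",
    "frameshift",
    "in-frame",
    "nonsense",
    "splice site",
    "start loss",
    "stop loss",
    "missense",
    "synonymous",
    "intronic",
    "not annotated",
]


@dataclass
class GeneBlock:
    gene: str
    hom_best: Optional[int]
    het_top2: list[int]
    members: list[str]  # variant ids ordered by descending score

    @property
    def rank_key(self) -> int:
        hom = self.hom_best if self.hom_best is not None else 0
        het2 = self.het_top2[1] if len(self.het_top2) > 1 else 0
        return max(hom, het2)


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, float):
        return f"{value:g}"
    return str(value)


def _sort_key(scored: ScoredVariant, cohort: Cohort):
    """Descending score, then rarest (absent frequency = 0), then coords."""
    key = cohort.variants[scored.variant_id]
    ann = scored.representative
    freq = ann.max_frequency() if ann is not None else None
    return (-scored.final_score, freq if freq is not None else 0.0, key.chrom, key.pos, key.ref, key.alt)


def rank_by_variant(
    sample: str,
    cohort: Cohort,
    scored: Mapping[str, ScoredVariant],
    decisions: Optional[Mapping[tuple[str, str], FilterDecision]] = None,
    filtered: bool = False,
) -> list[str]:
    """Ordered variant ids of one sample's byVar ranking.

    Only variants the sample carries appear; the filtered view drops
    variants whose filter decision for this sample was negative.
    """
    vids = cohort.sample_variant_ids(sample)
    if filtered:
        if decisions is None:
            raise ValueError("filtered ranking requires filter decisions")
        vids = [v for v in vids if decisions[(v, sample)].keep]
    return sorted(vids, key=lambda v: _sort_key(scored[v], cohort))


def rank_by_gene(
    sample: str,
    cohort: Cohort,
    scored: Mapping[str, ScoredVariant],
    decisions: Optional[Mapping[tuple[str, str], FilterDecision]] = None,
    filtered: bool = False,
) -> list[GeneBlock]:
    """Ordered gene blocks of one sample's byGene ranking."""
    vids = rank_by_variant(sample, cohort, scored, decisions, filtered)
    by_gene: dict[str, list[str]] = {}
    for vid in vids:
        ann = scored[vid].representative
        gene = ann.gene if ann is not None and ann.gene else "(no gene)"
        by_gene.setdefault(gene, []).append(vid)

    blocks = []
    for gene, members in by_gene.items():
        hom_scores = []
        het_scores = []
        for vid in members:
            z = cohort.get_call(vid, sample).zygosity
            s = scored[vid].final_score
            if z == HOM_ALT:
                hom_scores.append(s)
            elif z == HET:
                het_scores.append(s)
        het_scores.sort(reverse=True)
        blocks.append(
            GeneBlock(
                gene=gene,
                hom_best=max(hom_scores) if hom_scores else None,
                het_top2=het_scores[:2],
                members=members,
            )
        )
    best_het = lambda b: b.het_top2[0] if b.het_top2 else 0
    blocks.sort(key=lambda b: (-b.rank_key, -best_het(b), b.gene))
    return blocks


def report_row(
    vid: str,
    sample: str,
    cohort: Cohort,
    scored: Mapping[str, ScoredVariant],
    barcode: Barcode,
    family: Optional[Sequence[str]] = None,
) -> list[str]:
    sv = scored[vid]
    ann = sv.representative or TranscriptAnnotation(variant_id=vid)
    key = cohort.variants[vid]
    call = cohort.get_call(vid, sample)
    hom_het = {HOM_ALT: "hom", HET: "het"}.get(call.zygosity, "")
    fam = family_barcode(barcode, family) if family else ""
    values = {
        "VariantID": vid,
        "Gene": ann.gene,
        "omimId": ann.omim_id,
        "TranscriptID": ann.transcript_id,
        "TranscriptLength": ann.transcript_length,
        "Chr": key.chrom,
        "Start": key.pos,
        "Ref": key.ref[:REPORT_ALLELE_MAX],
        "Mut": key.alt[:REPORT_ALLELE_MAX],
        "Phred_QUAL": call.phred_qual,
        "HomHet": hom_het,
        "TotalReadDepth": call.total_depth,
        "VarReadDepth": call.alt_depth,
        "%Reads_variation": call.percent_alt,
        "CodingEffect": ann.coding_effect if ann.coding_effect != "none" else "",
        "VarLocation": ann.location if ann.location != "none" else "",
        "Exon": ann.exon,
        "Intron": ann.intron,
        "gNomen": ann.g_nomen,
        "cNomen": ann.c_nomen,
        "pNomen": ann.p_nomen,
        "rsID": ann.rs_id,
        "rsValidation": ann.rs_validation_evidence,
        "rsClinicalSignificance": ann.rs_clinical_significance,
        "rsMAF": ann.frequencies.get("rsMAF"),
        "espAllMAF": ann.frequencies.get("espAllMAF"),
        "espEAMAF": ann.frequencies.get("espEAMAF"),
        "espAAMAF": ann.frequencies.get("espAAMAF"),
        "1000g_AF": ann.frequencies.get("1000g_AF"),
        "delta MESscore (%)": ann.mes.effective_delta(),
        "wtMEScore": ann.mes.wt,
        "varMEScore": ann.mes.var,
        "delta SSFscore (%)": ann.ssf.effective_delta(),
        "wtSSFScore": ann.ssf.wt,
        "varSSFScore": ann.ssf.var,
        "delta NNSscore (%)": ann.nns.effective_delta(),
        "wtNNSScore": ann.nns.wt,
        "varNNSScore": ann.nns.var,
        "DistNearestSS": ann.dist_nearest_ss,
        "NearestSS": ann.nearest_ss,
        "localSpliceEffect": ann.local_splice_effect,
        "SiftPred": ann.sift_pred,
        "SiftWeight": ann.sift_weight,
        "SiftMedian": ann.sift_median,
        "PPH2pred": ann.pph2_pred,
        "phyloP": ann.phylop,
        "PhastCons": ann.phastcons,
        "GranthamDist": ann.grantham,
        "VarScore": sv.final_score,
        "AnnotationAnalysis": sv.annotation_analysis,
        "familyBarcode": fam,
        "Barcode": barcode.digits,
        "Hom_Count": barcode.hom_count,
        "Het_Count": barcode.het_count,
        "Allele_Count": barcode.allele_count,
        "Sample_Count": barcode.sample_count,
    }
    return [_fmt(values[c]) for c in REPORT_COLUMNS]


def _write_tsv(path: Path, header_comment: str, columns: Sequence[str], rows) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(header_comment + "\n")
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            fh.write("\t".join(row) + "\n")


def write_reports(
    cohort: Cohort,
    scored: Mapping[str, ScoredVariant],
    decisions: Mapping[tuple[str, str], FilterDecision],
    outdir: str | Path,
    families: Optional[Mapping[str, Sequence[str]]] = None,
    extann: Optional[GeneExternalAnnotation] = None,
    write_filtered: bool = True,
) -> list[Path]:
    """Write the four per-sample report files; returns the paths written.

    Files: ``<sample>.<AllVariants|filteredVariants>.rankingBy<Var|Gene>.tsv``
    with a ``## Barcode`` first line naming the cohort sample order.
    """
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
        if not outdir.is_dir():
            raise OSError("not a directory")
    except OSError as exc:
        raise OSError(f"cannot write reports to {outdir}: {exc}") from exc

    barcodes = {vid: build_barcode(cohort, vid) for vid in cohort.variants}
    columns = list(REPORT_COLUMNS) + (list(extann.columns) if extann else [])
    header_comment = "## Barcode: " + " ".join(cohort.samples)
    families = families or {}
    written: list[Path] = []

    def rows_for(vids, sample):
        out = []
        for vid in vids:
            row = report_row(vid, sample, cohort, scored, barcodes[vid], families.get(sample))
            if extann:
                ann = scored[vid].representative
                gene = ann.gene if ann is not None else ""
                row += extann.values_for(gene)
            out.append(row)
        return out

    versions = [("AllVariants", False)] + ([("filteredVariants", True)] if write_filtered else [])
    for sample in cohort.samples:
        for label, filtered in versions:
            vids = rank_by_variant(sample, cohort, scored, decisions, filtered)
            path = outdir / f"{sample}.{label}.rankingByVar.tsv"
            _write_tsv(path, header_comment, columns, rows_for(vids, sample))
            written.append(path)

            blocks = rank_by_gene(sample, cohort, scored, decisions, filtered)
            gene_vids = [vid for block in blocks for vid in block.members]
            path = outdir / f"{sample}.{label}.rankingByGene.tsv"
            _write_tsv(path, header_comment, columns, rows_for(gene_vids, sample))
            written.append(path)
    return written


def variant_count_category(scored: ScoredVariant) -> str:
    """Map a scored variant to its row of the count report."""
    if scored.annotation_analysis == "No" or scored.representative is None:
        return "not annotated"
    if scored.effect_provenance == "splice" or scored.category in (
        Category.ESSENTIAL_SPLICE,
        Category.CLOSE_SPLICE,
        Category.DEEP_SPLICE,
    ):
        return "splice site"
    ann = scored.representative
    effect = ann.coding_effect
    if effect in ("frameshift", "in-frame", "nonsense", "start loss", "stop loss", "missense", "synonymous"):
        return effect
    if ann.location in ("5'UTR", "3'UTR", "upstream", "downstream"):
        return ann.location
    if ann.location == "intron":
        return "intronic"
    if ann.location in ("", "none"):
        return "not annotated"
    return "intronic"


def category_report(
    cohort: Cohort, scored: Mapping[str, ScoredVariant]
) -> "pd.DataFrame":
    """Hom/het/total counts per category, per sample plus a dataset row."""
    import pandas as pd

    rows = []
    totals = {c: [0, 0] for c in COUNT_CATEGORIES}
    for sample in cohort.samples:
        counts = {c: [0, 0] for c in COUNT_CATEGORIES}  # [hom, het]
        for vid in cohort.sample_variant_ids(sample):
            cat = variant_count_category(scored[vid])
            z = cohort.get_call(vid, sample).zygosity
            idx = 0 if z == HOM_ALT else 1
            counts[cat][idx] += 1
            totals[cat][idx] += 1
        for cat in COUNT_CATEGORIES:
            hom, het = counts[cat]
            rows.append({"Sample": sample, "Category": cat, "Hom": hom, "Het": het, "Total": hom + het})
    for cat in COUNT_CATEGORIES:
        hom, het = totals[cat]
        rows.append({"Sample": "ALL", "Category": cat, "Hom": hom, "Het": het, "Total": hom + het})
    return pd.DataFrame(rows, columns=["Sample", "Category", "Hom", "Het", "Total"])
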