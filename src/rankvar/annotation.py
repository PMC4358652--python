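"""Per-transcript variant annotation layer.

Annotations arrive either as SnpEff-style ``ANN`` strings inside the VCF
INFO column or as a generic tab-separated table (one row per
variant × transcript, column names following the standard clinical
annotation-export layout). Both are normalized into
:class:`TranscriptAnnotation` records: coding effect, genic location,
splice-site predictor deltas (MaxEntScan / NNSplice / SpliceSiteFinder),
population frequencies, dbSNP evidence, conservation and protein-level
predictions.

The cohort is annotated non-redundantly: the union of variant keys across
all samples is looked up once, and per-sample views are joins against
that map.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .cohort_io import Cohort

logger = logging.getLogger(__name__)

CODING_EFFECTS = {
    "synonymous",
    "missense",
    "nonsense",
    "in-frame",
    "frameshift",
    "start loss",
    "stop loss",
    "none",
}
LOCATIONS = {"upstream", "5'UTR", "exon", "intron", "3'UTR", "downstream", "none"}

#: Names of the optional population-frequency fields (all on a 0..1 scale).
FREQUENCY_FIELDS = (
    "rsMAF",
    "espAllMAF",
    "espEAMAF",
    "espAAMAF",
    "1000g_AF",
    "1000g_AFR_AF",
    "1000g_SAS_AF",
    "1000g_EAS_AF",
    "1000g_EUR_AF",
)


@dataclass
class SpliceScores:
    """Wild-type/variant scores and percent delta for one splice predictor."""

    wt: Optional[float] = None
    var: Optional[float] = None
    delta_percent: Optional[float] = None

    def effective_delta(self) -> Optional[float]:
        """Percent change, recomputed from wt/var when both are present."""
        if self.wt is not None and self.var is not None and self.wt > 0:
            return 100.0 * (self.var - self.wt) / self.wt
        return self.delta_percent


@dataclass
class TranscriptAnnotation:
    """One (variant, transcript) annotation record."""

    variant_id: str
    gene: str = ""
    transcript_id: str = ""
    transcript_length: Optional[int] = None
    coding_effect: str = "none"
    location: str = "none"
    omim_id: Optional[str] = None
    exon: Optional[str] = None
    intron: Optional[str] = None
    g_nomen: Optional[str] = None
    c_nomen: Optional[str] = None
    p_nomen: Optional[str] = None
    rs_id: Optional[str] = None
    rs_validation_evidence: Optional[int] = None
    rs_clinical_significance: str = ""
    frequencies: dict[str, float] = field(default_factory=dict)
    mes: SpliceScores = field(default_factory=SpliceScores)
    nns: SpliceScores = field(default_factory=SpliceScores)
    ssf: SpliceScores = field(default_factory=SpliceScores)
    dist_nearest_ss: Optional[int] = None
    nearest_ss: Optional[str] = None  # "donor" | "acceptor"
    local_splice_effect: Optional[str] = None
    sift_pred: Optional[str] = None
    sift_weight: Optional[float] = None
    sift_median: Optional[float] = None
    pph2_pred: Optional[str] = None
    phastcons: Optional[float] = None
    phylop: Optional[float] = None
    grantham: Optional[float] = None
    extra: dict[str, str] = field(default_factory=dict)

    def max_frequency(self) -> Optional[float]:
        """Maximum over all available population frequencies."""
        if not self.frequencies:
            return None
        return max(self.frequencies.values())

    def is_known_pathogenic(self) -> bool:
        """dbSNP clinical-significance evidence of a reported mutation."""
        tokens = (
            self.rs_clinical_significance.lower()
            .replace(";", ",")
            .replace("/", ",")
            .split(",")
        )
        tokens = [t.strip() for t in tokens]
        return any(
            t in ("pathogenic", "probable-pathogenic", "probably-pathogenic")
            for t in tokens
        )


@dataclass
class GeneExternalAnnotation:
    """User-supplied gene-level annotation columns (the -extann table)."""

    columns: list[str]
    rows: dict[str, dict[str, str]]  # gene -> column -> value

    def values_for(self, gene: str) -> list[str]:
        row = self.rows.get(gene, {})
        return [row.get(c, "") for c in self.columns]


# --- SnpEff ANN parsing -----------------------------------------------------

# SnpEff sequence-ontology terms -> (coding effect, location), ordered from
# most to least severe; composite terms map to their first (most severe)
# mappable component.
_SNPEFF_TERM_MAP: list[tuple[str, str, str]] = [
    ("stop_gained", "nonsense", "exon"),
    ("frameshift_variant", "frameshift", "exon"),
    ("start_lost", "start loss", "exon"),
    ("initiator_codon_variant", "start loss", "exon"),
    ("stop_lost", "stop loss", "exon"),
    ("disruptive_inframe_insertion", "in-frame", "exon"),
    ("disruptive_inframe_deletion", "in-frame", "exon"),
    ("inframe_insertion", "in-frame", "exon"),
    ("inframe_deletion", "in-frame", "exon"),
    ("missense_variant", "missense", "exon"),
    ("synonymous_variant", "synonymous", "exon"),
    ("stop_retained_variant", "synonymous", "exon"),
    ("splice_acceptor_variant", "none", "intron"),
    ("splice_donor_variant", "none", "intron"),
    ("splice_region_variant", "none", "intron"),
    ("5_prime_UTR_premature_start_codon_gain_variant", "none", "5'UTR"),
    ("5_prime_UTR_variant", "none", "5'UTR"),
    ("3_prime_UTR_variant", "none", "3'UTR"),
    ("intron_variant", "none", "intron"),
    ("upstream_gene_variant", "none", "upstream"),
    ("downstream_gene_variant", "none", "downstream"),
    ("intergenic_region", "none", "none"),
]


def map_snpeff_terms(annotation_field: str) -> tuple[str, str]:
    """Map a SnpEff annotation term (possibly ``&``-composite) to
    (coding_effect, location); the most severe mappable component wins."""
    terms = annotation_field.split("&")
    for known, effect, location in _SNPEFF_TERM_MAP:
        if known in terms:
            return effect, location
    return "none", "none"


def parse_snpeff_ann(
    ann_field: str, variant_id: str = "", alt: Optional[str] = None
) -> list[TranscriptAnnotation]:
    """Parse a SnpEff ``ANN`` INFO field into annotation records.

    One record per comma-separated entry, input order preserved (SnpEff
    sorts entries from most to least pathogenic). Entries with fewer than
    10 pipe-delimited fields are skipped with a warning. When ``alt`` is
    given, entries for other alternate alleles are dropped.
    """
    out: list[TranscriptAnnotation] = []
    for entry in ann_field.split(","):
        fields = entry.split("|")
        if len(fields) < 10:
            logger.warning("skipping malformed ANN entry (%d fields)", len(fields))
            continue
        if alt is not None and fields[0] and fields[0] != alt:
            continue
        effect, location = map_snpeff_terms(fields[1])
        cdna = fields[11] if len(fields) > 11 else ""
        tx_len = None
        if "/" in cdna:
            try:
                tx_len = int(cdna.split("/")[1])
            except ValueError:
                tx_len = None
        out.append(
            TranscriptAnnotation(
                variant_id=variant_id,
                gene=fields[3],
                transcript_id=fields[6],
                transcript_length=tx_len,
                coding_effect=effect,
                location=location,
                c_nomen=fields[9] or None,
                p_nomen=(fields[10] or None) if len(fields) > 10 else None,
            )
        )
    return out


# --- generic annotation table ----------------------------------------------

MANDATORY_COLUMNS = ("VariantID", "Gene", "CodingEffect", "VarLocation")

_COLUMN_TO_FIELD = {
    "Gene": "gene",
    "omimId": "omim_id",
    "TranscriptID": "transcript_id",
    "TranscriptLength": "transcript_length",
    "CodingEffect": "coding_effect",
    "VarLocation": "location",
    "Exon": "exon",
    "Intron": "intron",
    "gNomen": "g_nomen",
    "cNomen": "c_nomen",
    "pNomen": "p_nomen",
    "rsID": "rs_id",
    "rsValidation": "rs_validation_evidence",
    "rsClinicalSignificance": "rs_clinical_significance",
    "DistNearestSS": "dist_nearest_ss",
    "NearestSS": "nearest_ss",
    "localSpliceEffect": "local_splice_effect",
    "SiftPred": "sift_pred",
    "SiftWeight": "sift_weight",
    "SiftMedian": "sift_median",
    "PPH2pred": "pph2_pred",
    "PhastCons": "phastcons",
    "phyloP": "phylop",
    "GranthamDist": "grantham",
}

_INT_FIELDS = {"transcript_length", "rs_validation_evidence", "dist_nearest_ss"}
_FLOAT_FIELDS = {"sift_weight", "sift_median", "phastcons", "phylop", "grantham"}

_SPLICE_COLUMNS = {
    "mes": ("delta MESscore (%)", "wtMEScore", "varMEScore"),
    "ssf": ("delta SSFscore (%)", "wtSSFScore", "varSSFScore"),
    "nns": ("delta NNSscore (%)", "wtNNSScore", "varNNSScore"),
}


def _cell(row, column) -> Optional[str]:
    if column not in row or pd.isna(row[column]):
        return None
    text = str(row[column]).strip()
    return text or None


def _row_to_annotation(row: pd.Series, columns: Sequence[str]) -> TranscriptAnnotation:
    ann = TranscriptAnnotation(variant_id=str(row["VariantID"]))
    for column, attr in _COLUMN_TO_FIELD.items():
        raw = _cell(row, column)
        if raw is None:
            continue
        if attr in _INT_FIELDS:
            value: object = int(float(raw))
        elif attr in _FLOAT_FIELDS:
            value = float(raw)
        else:
            value = raw
        setattr(ann, attr, value)
    for freq in FREQUENCY_FIELDS:
        raw = _cell(row, freq)
        if raw is not None:
            ann.frequencies[freq] = float(raw)
    for attr, (delta_col, wt_col, var_col) in _SPLICE_COLUMNS.items():
        scores = SpliceScores()
        raw = _cell(row, delta_col)
        if raw is not None:
            scores.delta_percent = float(raw)
        raw = _cell(row, wt_col)
        if raw is not None:
            scores.wt = float(raw)
        raw = _cell(row, var_col)
        if raw is not None:
            scores.var = float(raw)
        setattr(ann, attr, scores)
    handled = (
        set(_COLUMN_TO_FIELD)
        | set(FREQUENCY_FIELDS)
        | {c for cols in _SPLICE_COLUMNS.values() for c in cols}
        | {"VariantID"}
    )
    for column in columns:
        if column not in handled:
            ann.extra[column] = _cell(row, column) or ""
    return ann


def load_annotation_table(path: str | Path) -> dict[str, list[TranscriptAnnotation]]:
    """Load a tab-separated per-transcript annotation table.

    Rows are grouped by VariantID; duplicated (VariantID, TranscriptID)
    rows keep the first occurrence. Unknown columns are preserved in
    ``TranscriptAnnotation.extra`` so report writers can pass them
    through.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=True)
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(
            f"annotation table {path} lacks mandatory column(s): {', '.join(missing)}"
        )
    result: dict[str, list[TranscriptAnnotation]] = {}
    seen: set[tuple[str, str]] = set()
    for _, row in df.iterrows():
        ann = _row_to_annotation(row, df.columns)
        dedup_key = (ann.variant_id, ann.transcript_id)
        if dedup_key in seen:
            logger.warning(
                "duplicate annotation row for %s / %s ignored", *dedup_key
            )
            continue
        seen.add(dedup_key)
        result.setdefault(ann.variant_id, []).append(ann)
    return result


def annotations_from_vcf(paths: Iterable[str | Path]) -> dict[str, list[TranscriptAnnotation]]:
    """Collect SnpEff ANN annotations keyed by normalized variant id."""
    from cyvcf2 import VCF

    from .cohort_io import split_multiallelic, trim_alleles

    result: dict[str, list[TranscriptAnnotation]] = {}
    for path in paths:
        vcf = VCF(str(path))
        for record in vcf:
            ann_field = record.INFO.get("ANN")
            if ann_field is None:
                continue
            single_alt = len(record.ALT) == 1
            for alt in record.ALT:
                pos, ref, alt_trim = trim_alleles(record.POS, record.REF, alt)
                vid = f"{record.CHROM}_{pos}_{ref}_{alt_trim}"
                if vid in result:
                    continue
                entries = parse_snpeff_ann(
                    ann_field, variant_id=vid, alt=None if single_alt else alt
                )
                if entries:
                    result[vid] = entries
        vcf.close()
    return result


# --- representative transcript & non-redundant annotation -------------------

def select_representative(
    annotations: Sequence[TranscriptAnnotation],
    scores: Sequence[float],
) -> TranscriptAnnotation:
    """Choose the transcript whose annotation the reports show.

    The longest transcript is reported unless the variant is more
    pathogenic (strictly higher score) on another transcript; score ties
    prefer the longer transcript, then the lexicographically smallest
    transcript id, so the choice is order-independent.
    """
    if not annotations:
        raise ValueError("variant has no annotations")
    if len(annotations) != len(scores):
        raise ValueError("annotations and scores length mismatch")
    best = max(scores)

    def sort_key(i: int):
        ann = annotations[i]
        length = ann.transcript_length if ann.transcript_length is not None else -1
        return (-length, ann.transcript_id)

    candidates = [i for i, s in enumerate(scores) if s == best]
    return annotations[min(candidates, key=sort_key)]


def annotate_non_redundant(
    cohort: Cohort,
    source: Mapping[str, list[TranscriptAnnotation]],
) -> dict[str, list[TranscriptAnnotation]]:
    """Annotate the union of cohort variants exactly once.

    Per-sample annotation views are joins against this map, so annotating
    per sample and annotating the union give identical results while
    paying each lookup once.
    """
    return {vid: list(source.get(vid, [])) for vid in cohort.variants}


def load_external_annotation(path: str | Path) -> GeneExternalAnnotation:
    """Load a gene-level external annotation table (first column = gene)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise ValueError(f"external annotation {path} needs a gene column plus data")
    gene_col = df.columns[0]
    columns = list(df.columns[1:])
    rows: dict[str, dict[str, str]] = {}
    for _, row in df.iterrows():
        gene = str(row[gene_col])
        if gene in rows:
            logger.warning("duplicate gene %r in external annotation; keeping first", gene)
            continue
        rows[gene] = {c: str(row[c]) for c in columns}
    return GeneExternalAnnotation(columns=columns, rows=rows)


def merge_external(
    rows: Iterable[tuple[str, list[str]]],
    extann: GeneExternalAnnotation,
) -> list[list[str]]:
    """Append external annotation cells to (gene, row-cells) pairs."""
    return [cells + extann.values_for(gene) for gene, cells in rows]
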