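"""End-to-end orchestration: load → annotate → score → filter → report."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import yaml

from . import annotation, cohort_analysis, cohort_io, ranking_output, scoring
from .annotation import GeneExternalAnnotation, TranscriptAnnotation
from .cohort_analysis import Barcode, FilterConfig, FilterDecision
from .cohort_io import Cohort
from .scoring import ScoredVariant, ScoringConfig


@dataclass
class PipelineResult:
    cohort: Cohort
    annotations: dict[str, list[TranscriptAnnotation]]
    scored: dict[str, ScoredVariant]
    barcodes: dict[str, Barcode]
    decisions: dict[tuple[str, str], FilterDecision]
    report_paths: list[Path]


def load_config_file(path: str | Path) -> tuple[dict, dict]:
    """Read a YAML config file; returns (scoring overrides, filter overrides).

    Recognized top-level keys are ``scoring`` and ``filters``, each a
    mapping of option name (e.g. ``S_Nonsense``, ``max_af``) to value.
    """
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return data.get("scoring", {}) or {}, data.get("filters", {}) or {}


def run_pipeline(
    vcf_paths: Sequence[str | Path],
    annotation_table: Optional[str | Path] = None,
    extann_path: Optional[str | Path] = None,
    sample_selection: Optional[Sequence[str]] = None,
    families: Optional[Mapping[str, Sequence[str]]] = None,
    scoring_config: Optional[ScoringConfig] = None,
    filter_config: Optional[FilterConfig] = None,
    known_variants: Optional[set[str]] = None,
    outdir: Optional[str | Path] = None,
    write_filtered: bool = True,
) -> PipelineResult:
    """Run the full prioritization workflow.

    Annotations come from ``annotation_table`` when given, otherwise from
    SnpEff-style ANN fields inside the VCFs. When ``outdir`` is set, the
    per-sample ranked reports and the category-count report are written
    there.
    """
    scoring_config = scoring_config or ScoringConfig()
    filter_config = filter_config or FilterConfig()

    cohort = cohort_io.load_cohort(vcf_paths, sample_selection)

    if annotation_table is not None:
        source = annotation.load_annotation_table(annotation_table)
    else:
        source = annotation.annotations_from_vcf(vcf_paths)
    ann_map = annotation.annotate_non_redundant(cohort, source)

    scored = scoring.score_all(ann_map, scoring_config, known_variants)
    barcodes = {vid: cohort_analysis.build_barcode(cohort, vid) for vid in cohort.variants}

    decisions: dict[tuple[str, str], FilterDecision] = {}
    for vid in cohort.variants:
        for sample in cohort.samples:
            call = cohort.get_call(vid, sample)
            decisions[(vid, sample)] = cohort_analysis.apply_filters(
                call, scored[vid], filter_config, barcodes[vid]
            )

    report_paths: list[Path] = []
    if outdir is not None:
        extann = (
            annotation.load_external_annotation(extann_path) if extann_path else None
        )
        report_paths = ranking_output.write_reports(
            cohort,
            scored,
            decisions,
            outdir,
            families=families,
            extann=extann,
            write_filtered=write_filtered,
        )
        counts = ranking_output.category_report(cohort, scored)
        counts_path = Path(outdir) / "category_counts.tsv"
        counts.to_csv(counts_path, sep="\t", index=False)
        report_paths.append(counts_path)

    return PipelineResult(
        cohort=cohort,
        annotations=ann_map,
        scored=scored,
        barcodes=barcodes,
        decisions=decisions,
        report_paths=report_paths,
    )
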