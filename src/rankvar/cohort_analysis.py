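"""Cohort barcodes, zygosity counts, inheritance patterns and filters.

The *barcode* is an ordered string of zygosity digits across all cohort
samples for one variant ("0" homozygous reference, "1" heterozygous,
"2" homozygous alternate); a *family barcode* restricts it to a
user-ordered sample subset so trio hypotheses can be expressed as digit
patterns ("121" = homozygous proband with heterozygous parents, "010" =
de novo heterozygous proband). No-call genotypes render as "0" in the
barcode; they are counted separately in QC logs.

The default filter cascade removes likely false positives and common
polymorphisms: low total depth, low supporting-read count, low
supporting-read ratio, dbSNP-validated non-pathogenic variants, and
variants above 1% population frequency. Rules without the data they need
do not fire, and known-mutation variants are exempt from the two
knowledge-based rules.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Optional, Sequence

from .cohort_io import Cohort, HET, HOM_ALT, MISSING, SampleCall
from .scoring import Category, ScoredVariant


@dataclass
class Barcode:
    """Per-variant zygosity digits over the cohort plus derived counts."""

    sample_order: tuple[str, ...]
    digits: str
    hom_count: int
    het_count: int
    allele_count: int
    sample_count: int


@dataclass
class FilterConfig:
    """Thresholds of the default filter cascade (all removals)."""

    min_total_depth: int = 10  # remove when total depth <= this
    min_alt_reads: int = 10  # remove when supporting reads <= this
    min_percent_alt: float = 15.0  # remove when supporting ratio <= this (%)
    max_af: float = 0.01  # remove when any population frequency > this
    dbsnp_min_validation_evidence: int = 2
    #: optional cohort-count filter (keep when het/hom counts are below
    #: these); None disables it
    max_het_count: Optional[int] = None
    max_hom_count: Optional[int] = None

    def override(self, **kwargs) -> "FilterConfig":
        known = {f.name for f in fields(self)}
        unknown = set(kwargs) - known
        if unknown:
            raise ValueError(f"unknown filter option(s): {', '.join(sorted(unknown))}")
        return replace(self, **kwargs)


@dataclass
class FilterDecision:
    keep: bool
    reasons: list[str] = field(default_factory=list)


def build_barcode(cohort: Cohort, variant_id: str) -> Barcode:
    """Zygosity barcode of one variant over the whole cohort."""
    if variant_id not in cohort.variants:
        raise KeyError(f"variant {variant_id} not in cohort")
    digits = []
    hom = het = 0
    for sample in cohort.samples:
        z = cohort.get_call(variant_id, sample).zygosity
        if z == HOM_ALT:
            hom += 1
            digits.append("2")
        elif z == HET:
            het += 1
            digits.append("1")
        else:  # hom-ref and no-call both render as "0"
            digits.append("0")
    return Barcode(
        sample_order=cohort.samples,
        digits="".join(digits),
        hom_count=hom,
        het_count=het,
        allele_count=2 * hom + het,
        sample_count=len(cohort.samples),
    )


def family_barcode(barcode: Barcode, family: Sequence[str]) -> str:
    """Barcode digits restricted to ``family``, in the user's order."""
    index = {s: i for i, s in enumerate(barcode.sample_order)}
    missing = [s for s in family if s not in index]
    if missing:
        raise ValueError(f"sample(s) not in cohort: {', '.join(missing)}")
    return "".join(barcode.digits[index[s]] for s in family)


def match_pattern(digits: str, pattern: str) -> bool:
    """Positionwise barcode match; '?' in the pattern matches any digit."""
    if len(digits) != len(pattern):
        raise ValueError(
            f"pattern length {len(pattern)} != barcode length {len(digits)}"
        )
    return all(p == "?" or p == d for d, p in zip(digits, pattern))


def cohort_frequency_filter(barcode: Barcode, max_het: int, max_hom: int) -> bool:
    """Keep variants seen fewer than ``max_het`` times heterozygous and
    fewer than ``max_hom`` times homozygous in the cohort."""
    return barcode.het_count < max_het and barcode.hom_count < max_hom


def apply_filters(
    call: Optional[SampleCall],
    scored: ScoredVariant,
    config: FilterConfig | None = None,
    barcode: Optional[Barcode] = None,
) -> FilterDecision:
    """Run the default cascade on one (sample call, scored variant) pair.

    Rule ids: ``low_total_depth``, ``low_alt_reads``, ``low_alt_ratio``,
    ``dbsnp_validated_benign``, ``frequent`` (plus ``cohort_count`` when
    the optional cohort-count filter is enabled and a barcode is given).
    Rules lacking their inputs do not fire; known mutations are exempt
    from the dbSNP and frequency rules.
    """
    config = config or FilterConfig()
    reasons: list[str] = []

    if call is not None:
        if call.total_depth is not None and call.total_depth <= config.min_total_depth:
            reasons.append("low_total_depth")
        if call.alt_depth is not None and call.alt_depth <= config.min_alt_reads:
            reasons.append("low_alt_reads")
        if call.percent_alt is not None and call.percent_alt <= config.min_percent_alt:
            reasons.append("low_alt_ratio")

    ann = scored.representative
    known = scored.category == Category.KNOWN
    if ann is not None and not known:
        validated = (
            ann.rs_validation_evidence is not None
            and ann.rs_validation_evidence >= config.dbsnp_min_validation_evidence
        )
        if validated and not ann.is_known_pathogenic():
            reasons.append("dbsnp_validated_benign")
        max_freq = ann.max_frequency()
        if max_freq is not None and max_freq > config.max_af:
            reasons.append("frequent")

    if (
        barcode is not None
        and config.max_het_count is not None
        and config.max_hom_count is not None
        and not cohort_frequency_filter(
            barcode, config.max_het_count, config.max_hom_count
        )
    ):
        reasons.append("cohort_count")

    return FilterDecision(keep=not reasons, reasons=reasons)
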