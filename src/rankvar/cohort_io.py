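"""Cohort ingestion from VCF files.

Reads one multi-sample VCF and/or several single-sample VCFs (optionally
gzip-compressed) into a unified :class:`Cohort`: the union of normalized
variant keys, per-sample genotype calls with read-depth QC fields, and a
deterministic (lexicographic) sample order that every downstream barcode
and report reuses.

Multi-allelic records are split into one key per ALT allele; indels are
normalized to the minimal anchored representation (shared suffix then
prefix trimmed, one anchor base retained) so the same event called with
different padding collapses to one key.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from cyvcf2 import VCF

logger = logging.getLogger(__name__)

#: Zygosity codes: 0 hom-ref, 1 het, 2 hom-alt; -1 marks a no-call (./.).
HOM_REF, HET, HOM_ALT, MISSING = 0, 1, 2, -1

#: Ref/alt sequences longer than this are truncated in report columns.
REPORT_ALLELE_MAX = 50


@dataclass(frozen=True, order=True)
class VariantKey:
    """A normalized genomic variant (1-based position, explicit alleles)."""

    chrom: str
    pos: int
    ref: str
    alt: str

    @property
    def id(self) -> str:
        return f"{self.chrom}_{self.pos}_{self.ref}_{self.alt}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.id


@dataclass
class SampleCall:
    """One sample's genotype at one variant plus call-quality fields."""

    sample_id: str
    zygosity: int
    total_depth: Optional[int] = None
    alt_depth: Optional[int] = None
    percent_alt: Optional[float] = None
    phred_qual: Optional[float] = None


@dataclass
class Cohort:
    """Merged view of one or more VCFs.

    ``calls`` holds only carrier and no-call genotypes; an absent
    (variant, sample) pair means homozygous reference.
    """

    samples: tuple[str, ...]
    variants: dict[str, VariantKey]
    calls: dict[tuple[str, str], SampleCall]
    provenance: dict[str, str] = field(default_factory=dict)

    def get_call(self, variant_id: str, sample_id: str) -> SampleCall:
        try:
            return self.calls[(variant_id, sample_id)]
        except KeyError:
            return SampleCall(sample_id=sample_id, zygosity=HOM_REF)

    def sample_variant_ids(self, sample_id: str) -> list[str]:
        """Variant ids the sample actually carries (zygosity 1 or 2)."""
        return [
            vid
            for (vid, sid), call in self.calls.items()
            if sid == sample_id and call.zygosity in (HET, HOM_ALT)
        ]

    @property
    def variant_ids(self) -> list[str]:
        return list(self.variants)


def trim_alleles(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Minimal anchored representation of (pos, ref, alt).

    Shared suffix is removed first, then the shared prefix (advancing
    ``pos``), always leaving at least one base on each allele — the VCF
    anchored-indel convention.
    """
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def zygosity(genotype_field: str) -> int:
    """Zygosity code for a GT string with respect to allele 1.

    ``0/0`` -> 0, ``0/1``/``1/0`` -> 1, ``1/1`` -> 2, ``./.`` -> MISSING.
    Phasing separators are ignored; haploid "1" counts as homozygous.
    """
    alleles = genotype_field.replace("|", "/").split("/")
    if all(a == "." for a in alleles):
        return MISSING
    n_alt = sum(1 for a in alleles if a == "1")
    if len(alleles) == 1:  # haploid (e.g. X in males)
        return HOM_ALT if n_alt else HOM_REF
    return min(n_alt, 2)


def zygosity_from_alleles(alleles: Sequence[int], alt_index: int) -> int:
    """Zygosity with respect to one ALT of a (possibly multi-allelic) call.

    ``alleles`` are integer allele indices (-1 for '.'); ``alt_index`` is
    1-based as in the GT field. A 1/2 genotype is heterozygous for each of
    the two alternates.
    """
    if not alleles or all(a < 0 for a in alleles):
        return MISSING
    n = sum(1 for a in alleles if a == alt_index)
    if len(alleles) == 1:
        return HOM_ALT if n else HOM_REF
    return min(n, 2)


def support_ratio(alt_depth: Optional[int], total_depth: Optional[int]) -> Optional[float]:
    """Percent of reads supporting the variant; None when undefined."""
    if alt_depth is None or total_depth is None or total_depth <= 0:
        return None
    if alt_depth > total_depth:
        logger.warning(
            "alt depth %d exceeds total depth %d; clamping ratio to 100%%",
            alt_depth,
            total_depth,
        )
        return 100.0
    return 100.0 * alt_depth / total_depth


def _is_symbolic(alt: str) -> bool:
    return alt.startswith("<") or alt == "*" or "[" in alt or "]" in alt


def split_multiallelic(record, samples: Sequence[str]):
    """Split one cyvcf2 record into per-ALT (VariantKey, calls) pairs.

    Returns a list of ``(VariantKey, {sample_id: SampleCall})``; only
    carrier and no-call samples are included. Symbolic alternates are
    skipped with a warning.
    """
    out = []
    genotypes = record.genotypes  # [[a0, a1, phased], ...]
    dp = _format_int_column(record, "DP")
    ad = _format_matrix(record, "AD")
    ao = _format_matrix(record, "AO") if ad is None else None
    ro = _format_int_column(record, "RO") if ad is None else None
    qual = record.QUAL

    for alt_index, alt in enumerate(record.ALT, start=1):
        if _is_symbolic(alt):
            logger.warning(
                "skipping symbolic allele %s at %s:%d", alt, record.CHROM, record.POS
            )
            continue
        pos, ref, alt_trim = trim_alleles(record.POS, record.REF, alt)
        key = VariantKey(chrom=record.CHROM, pos=pos, ref=ref, alt=alt_trim)
        calls: dict[str, SampleCall] = {}
        for i, sample in enumerate(samples):
            gt = genotypes[i]
            alleles = [a for a in gt[:-1]] if len(gt) > 1 else [gt[0]]
            z = zygosity_from_alleles(alleles, alt_index)
            if z == HOM_REF:
                continue
            total = dp[i] if dp is not None else None
            alt_reads = None
            if ad is not None and ad.shape[1] > alt_index:
                v = int(ad[i, alt_index])
                alt_reads = v if v >= 0 else None
            elif ao is not None:
                v = int(ao[i, alt_index - 1])
                alt_reads = v if v >= 0 else None
                if total is None and ro is not None and alt_reads is not None:
                    r = ro[i]
                    total = r + alt_reads if r is not None else None
            calls[sample] = SampleCall(
                sample_id=sample,
                zygosity=z,
                total_depth=total,
                alt_depth=alt_reads,
                percent_alt=support_ratio(alt_reads, total),
                phred_qual=qual,
            )
        out.append((key, calls))
    return out


def _format_matrix(record, name):
    try:
        arr = record.format(name)
    except KeyError:
        return None
    if arr is None:
        return None
    return arr


def _format_int_column(record, name):
    arr = _format_matrix(record, name)
    if arr is None:
        return None
    col = arr[:, 0] if arr.ndim > 1 else arr
    return [int(v) if int(v) >= 0 else None for v in col]


def load_cohort(
    paths: Iterable[str | Path],
    sample_selection: Optional[Sequence[str]] = None,
) -> Cohort:
    """Read and merge VCF files into one cohort.

    Sample order in the result is lexicographic regardless of input order,
    so barcodes are reproducible across runs. Duplicate sample ids across
    files are de-duplicated by first occurrence with a warning.
    """
    paths = [str(p) for p in paths]
    seen: dict[str, str] = {}  # sample -> source path
    variants: dict[str, VariantKey] = {}
    calls: dict[tuple[str, str], SampleCall] = {}
    n_records = 0

    for path in paths:
        if not Path(path).exists():
            raise FileNotFoundError(f"VCF file not found: {path}")
        try:
            vcf = VCF(path)
        except Exception as exc:  # cyvcf2 raises on missing #CHROM header
            raise ValueError(f"cannot parse VCF {path}: {exc}") from exc
        file_samples = list(vcf.samples)
        kept = []
        for s in file_samples:
            if s in seen:
                logger.warning(
                    "sample %r in %s already loaded from %s; keeping first",
                    s,
                    path,
                    seen[s],
                )
            else:
                seen[s] = path
                kept.append(s)
        for record in vcf:
            n_records += 1
            for key, per_sample in split_multiallelic(record, file_samples):
                if key.id not in variants:
                    variants[key.id] = key
                for sample, call in per_sample.items():
                    if sample in kept:
                        calls[(key.id, sample)] = call
        vcf.close()

    samples = sorted(seen)
    if sample_selection is not None:
        unknown = [s for s in sample_selection if s not in seen]
        if unknown:
            raise ValueError(f"unknown sample(s) in selection: {', '.join(unknown)}")
        selected = set(sample_selection)
        samples = [s for s in samples if s in selected]
        calls = {k: v for k, v in calls.items() if k[1] in selected}
        carried = {vid for (vid, _s) in calls}
        variants = {vid: k for vid, k in variants.items() if vid in carried}

    n_missing = sum(1 for c in calls.values() if c.zygosity == MISSING)
    logger.info(
        "loaded %d VCF record(s) from %d file(s): %d variant(s), %d sample(s), %d no-call genotype(s)",
        n_records,
        len(paths),
        len(variants),
        len(samples),
        n_missing,
    )
    return Cohort(
        samples=tuple(samples),
        variants=variants,
        calls=calls,
        provenance=seen,
    )


def write_vcf(cohort: Cohort, path: str | Path) -> None:
    """Write the cohort back out as a minimal multi-sample VCF.

    Used for round-trip checks and for exporting merged cohorts; carries
    GT, DP and AD only.
    """
    lines = [
        "##fileformat=VCFv4.2",
        *(
            f"##contig=<ID={c}>"
            for c in sorted({k.chrom for k in cohort.variants.values()})
        ),
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(cohort.samples),
    ]
    gt_for = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}

    def _sort_key(key: VariantKey):
        return (key.chrom, key.pos, key.ref, key.alt)

    for key in sorted(cohort.variants.values(), key=_sort_key):
        cols = []
        qual = "."
        for sample in cohort.samples:
            call = cohort.get_call(key.id, sample)
            if call.phred_qual is not None:
                qual = f"{call.phred_qual:g}"
            dp = call.total_depth if call.total_depth is not None else "."
            if call.alt_depth is not None and call.total_depth is not None:
                ad = f"{call.total_depth - call.alt_depth},{call.alt_depth}"
            else:
                ad = "."
            cols.append(f"{gt_for[call.zygosity]}:{dp}:{ad}")
        lines.append(
            f"{key.chrom}\t{key.pos}\t.\t{key.ref}\t{key.alt}\t{qual}\tPASS\t.\tGT:DP:AD\t"
            + "\t".join(cols)
        )
    Path(path).write_text("\n".join(lines) + "\n")
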