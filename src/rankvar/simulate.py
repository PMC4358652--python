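"""Synthetic cohort generation with known ground truth.

Emulates the structure the ranking engine is designed for: a cohort of
samples sharing a pool of common background polymorphisms (population
allele frequency above 1%, Hardy–Weinberg genotypes, so each new sample
adds few new variants) plus private, rare, spiked causal mutations whose
category — and therefore expected final score under the default
configuration — is known in advance.

The expected scores in the truth table are computed from a literal
score-table lookup inside this module, independent of the scoring
module, so end-to-end tests check the pipeline against an external
arithmetic oracle rather than against itself.

Everything is a pure function of the seed: two runs with the same
configuration produce byte-identical VCF and annotation text.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

#: Published default score table, restated literally as the simulation oracle.
_BASE_SCORE = {
    "known": 110,
    "nonsense": 100,
    "frameshift": 100,
    "essential splice": 90,
    "start loss": 80,
    "stop loss": 80,
    "close splice": 70,
    "missense": 50,
    "in-frame": 40,
    "deep splice": 25,
    "synonymous": 10,
}
_CONSERVATION_ELIGIBLE = {
    "nonsense",
    "essential splice",
    "start loss",
    "stop loss",
    "close splice",
    "missense",
    "deep splice",
    "synonymous",
}

ANNOTATION_COLUMNS = [
    "VariantID",
    "Gene",
    "TranscriptID",
    "TranscriptLength",
    "CodingEffect",
    "VarLocation",
    "cNomen",
    "rsID",
    "rsValidation",
    "rsClinicalSignificance",
    "rsMAF",
    "delta MESscore (%)",
    "delta NNSscore (%)",
    "delta SSFscore (%)",
    "DistNearestSS",
    "NearestSS",
    "SiftPred",
    "PPH2pred",
    "PhastCons",
]


@dataclass
class Spike:
    """One private causal mutation planted into one sample."""

    sample: str
    category: str
    zygosity: int = 2  # 1 het, 2 hom
    gene: Optional[str] = None
    phastcons: float = 0.5
    sift_deleterious: bool = False
    pph2_deleterious: bool = False

    def expected_score(self) -> int:
        """Final score under default configuration (independent lookup)."""
        if self.category not in _BASE_SCORE:
            raise ValueError(f"unknown spike category {self.category!r}")
        score = _BASE_SCORE[self.category]
        if self.category == "known":
            return score
        if self.category in _CONSERVATION_ELIGIBLE and self.phastcons > 0.95:
            score += 5
        if self.category == "missense":
            score += 5 * (int(self.sift_deleterious) + int(self.pph2_deleterious))
        return score


@dataclass
class SimulationConfig:
    n_samples: int = 30
    n_background_variants: int = 1000
    background_af_range: tuple[float, float] = (0.01, 0.5)
    spikes: list[Spike] = field(default_factory=list)
    depth_mean: float = 50.0
    depth_dispersion: float = 10.0
    seed: int = 0


@dataclass
class SimulatedCohort:
    vcf_text: str
    annotation_text: str
    truth: pd.DataFrame

    def write(self, outdir: str | Path) -> tuple[Path, Path, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        vcf = outdir / "cohort.vcf"
        ann = outdir / "annotations.tsv"
        truth = outdir / "truth.tsv"
        vcf.write_text(self.vcf_text)
        ann.write_text(self.annotation_text)
        self.truth.to_csv(truth, sep="\t", index=False)
        return vcf, ann, truth


_BG_EFFECTS = [  # (CodingEffect, VarLocation) cycle for background variants
    ("synonymous", "exon"),
    ("", "intron"),
    ("missense", "exon"),
    ("", "intron"),
]
_BASES = ["A", "C", "G", "T"]


def _vcf_text(samples, records) -> str:
    lines = [
        "##fileformat=VCFv4.2",
        *(f"##contig=<ID={c}>" for c in sorted({r[0] for r in records})),
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples),
    ]
    for chrom, pos, ref, alt, sample_fields in records:
        lines.append(
            f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t100\tPASS\t.\tGT:DP:AD\t"
            + "\t".join(sample_fields)
        )
    return "\n".join(lines) + "\n"


def _depths(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    p = dispersion / (dispersion + mean)
    return int(max(1, rng.negative_binomial(dispersion, p)))


def _genotype_field(rng, zyg, mean, dispersion) -> str:
    dp = _depths(rng, mean, dispersion)
    if zyg == 2:
        alt = int(rng.binomial(dp, 0.98))
        gt = "1/1"
    elif zyg == 1:
        alt = int(rng.binomial(dp, 0.5))
        gt = "0/1"
    else:
        alt = 0
        gt = "0/0"
    return f"{gt}:{dp}:{dp - alt},{alt}"


def _spike_annotation(vid: str, gene: str, spike: Spike) -> dict:
    row = {c: "" for c in ANNOTATION_COLUMNS}
    row.update(
        VariantID=vid,
        Gene=gene,
        TranscriptID=f"NM_{abs(hash(gene)) % 900000 + 100000}.1",
        TranscriptLength=2000,
        PhastCons=spike.phastcons,
    )
    cat = spike.category
    if cat == "known":
        row.update(
            CodingEffect="missense",
            VarLocation="exon",
            rsID="rs" + vid.split("_")[1],
            rsValidation=2,
            rsClinicalSignificance="pathogenic",
        )
    elif cat == "essential splice":
        row.update(
            VarLocation="intron",
            DistNearestSS=1,
            NearestSS="donor",
            **{"delta MESscore (%)": -20, "delta NNSscore (%)": -20, "delta SSFscore (%)": -20},
        )
    elif cat == "close splice":
        row.update(
            VarLocation="intron",
            DistNearestSS=4,
            NearestSS="donor",
            **{"delta MESscore (%)": -12, "delta NNSscore (%)": -6, "delta SSFscore (%)": -3},
        )
    elif cat == "deep splice":
        row.update(
            VarLocation="intron",
            DistNearestSS=87,
            NearestSS="acceptor",
            **{"delta MESscore (%)": -20, "delta NNSscore (%)": -20, "delta SSFscore (%)": -20},
        )
    else:
        row.update(CodingEffect=cat, VarLocation="exon")
    if cat == "missense":
        row.update(
            SiftPred="Deleterious" if spike.sift_deleterious else "Tolerated",
            PPH2pred="probably damaging" if spike.pph2_deleterious else "neutral",
        )
    return row


def generate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Generate the VCF, annotation table and truth table of one cohort.

    Background variants are drawn with allele frequencies above 1% and
    shared across samples (each sample's genotype is a Hardy–Weinberg
    draw); they carry dbSNP-validated benign annotations. Spiked variants
    are private to their sample, unobserved in population databases, and
    annotated so that their category is exactly the one requested.
    """
    if config.n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    samples = [f"S{i:03d}" for i in range(1, config.n_samples + 1)]
    sample_set = set(samples)
    for spike in config.spikes:
        if spike.sample not in sample_set:
            raise ValueError(f"spike sample {spike.sample!r} not in cohort")
        if spike.zygosity not in (1, 2):
            raise ValueError("spike zygosity must be 1 (het) or 2 (hom)")

    rng = np.random.default_rng(config.seed)
    lo, hi = config.background_af_range
    records = []
    ann_rows = []

    for i in range(config.n_background_variants):
        af = float(rng.uniform(lo, hi))
        pos = 10_000 + i * 100
        ref = _BASES[i % 4]
        alt = _BASES[(i + 1) % 4]
        vid = f"1_{pos}_{ref}_{alt}"
        gene = f"BGENE{i // 20 + 1:03d}"
        fields = []
        for sample in samples:
            r = rng.random()
            zyg = 2 if r < af * af else (1 if r < af * af + 2 * af * (1 - af) else 0)
            fields.append(
                _genotype_field(rng, zyg, config.depth_mean, config.depth_dispersion)
            )
        records.append(("1", pos, ref, alt, fields))
        effect, location = _BG_EFFECTS[i % len(_BG_EFFECTS)]
        row = {c: "" for c in ANNOTATION_COLUMNS}
        row.update(
            VariantID=vid,
            Gene=gene,
            TranscriptID=f"NM_{100000 + i}.1",
            TranscriptLength=1500,
            CodingEffect=effect,
            VarLocation=location,
            rsID=f"rs{900000 + i}",
            rsValidation=2,
            rsClinicalSignificance="",
            rsMAF=round(af, 4),
            PhastCons=round(float(rng.uniform(0.0, 0.9)), 3),
        )
        if effect == "missense":
            row.update(SiftPred="Tolerated", PPH2pred="neutral")
        ann_rows.append(row)

    truth_rows = []
    for j, spike in enumerate(config.spikes):
        pos = 5_000_000 + j * 1_000
        ref, alt = "G", "T"
        vid = f"1_{pos}_{ref}_{alt}"
        gene = spike.gene or f"SPIKEG{j + 1:02d}"
        fields = [
            _genotype_field(
                rng,
                spike.zygosity if sample == spike.sample else 0,
                config.depth_mean,
                config.depth_dispersion,
            )
            for sample in samples
        ]
        records.append(("1", pos, ref, alt, fields))
        ann_rows.append(_spike_annotation(vid, gene, spike))
        truth_rows.append(
            {
                "VariantID": vid,
                "Sample": spike.sample,
                "Gene": gene,
                "Category": spike.category,
                "Zygosity": spike.zygosity,
                "ExpectedScore": spike.expected_score(),
            }
        )

    records.sort(key=lambda r: (r[0], r[1]))
    truth = pd.DataFrame(
        truth_rows,
        columns=["VariantID", "Sample", "Gene", "Category", "Zygosity", "ExpectedScore"],
    )
    ann_text = pd.DataFrame(ann_rows, columns=ANNOTATION_COLUMNS).to_csv(
        sep="\t", index=False
    )
    return SimulatedCohort(
        vcf_text=_vcf_text(samples, records),
        annotation_text=ann_text,
        truth=truth,
    )


@dataclass
class TrioFixture:
    vcf_text: str
    annotation_text: str
    family: list[str]  # user barcode order: father, proband, mother
    variant_id: str
    pattern: str


def trio_fixture(pattern: str, seed: int = 0) -> TrioFixture:
    """A 3-sample cohort with one variant whose family barcode is ``pattern``.

    The family order is (father, proband, mother): "121" plants a
    homozygous variant in the proband inherited from heterozygous
    parents; "010" plants a de novo heterozygous variant in the proband.
    """
    if len(pattern) != 3 or any(c not in "012" for c in pattern):
        raise ValueError(f"unsupported trio pattern {pattern!r}")
    family = ["FATHER", "PROBAND", "MOTHER"]
    zygosities = dict(zip(family, (int(c) for c in pattern)))

    config = SimulationConfig(n_samples=1, n_background_variants=20, seed=seed)
    rng = np.random.default_rng(seed + 1)
    samples = sorted(family)
    records = []
    ann_rows = []
    for i in range(20):  # shared background polymorphisms
        pos = 10_000 + i * 100
        ref, alt = _BASES[i % 4], _BASES[(i + 1) % 4]
        af = float(rng.uniform(0.05, 0.5))
        fields = []
        for sample in samples:
            r = rng.random()
            zyg = 2 if r < af * af else (1 if r < af * af + 2 * af * (1 - af) else 0)
            fields.append(_genotype_field(rng, zyg, 50.0, 10.0))
        records.append(("1", pos, ref, alt, fields))
        row = {c: "" for c in ANNOTATION_COLUMNS}
        row.update(
            VariantID=f"1_{pos}_{ref}_{alt}",
            Gene=f"BGENE{i + 1:03d}",
            TranscriptID=f"NM_{200000 + i}.1",
            TranscriptLength=1500,
            CodingEffect="synonymous",
            VarLocation="exon",
            rsMAF=round(af, 4),
            rsValidation=2,
        )
        ann_rows.append(row)

    pos = 5_000_000
    vid = f"1_{pos}_G_T"
    fields = [_genotype_field(rng, zygosities[s], 50.0, 10.0) for s in samples]
    records.append(("1", pos, "G", "T", fields))
    spike = Spike(sample="PROBAND", category="missense", zygosity=max(int(c) for c in pattern))
    ann_rows.append(_spike_annotation(vid, "TRIOG1", spike))

    ann_text = pd.DataFrame(ann_rows, columns=ANNOTATION_COLUMNS).to_csv(
        sep="\t", index=False
    )
    return TrioFixture(
        vcf_text=_vcf_text(samples, records),
        annotation_text=ann_text,
        family=family,
        variant_id=vid,
        pattern=pattern,
    )
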