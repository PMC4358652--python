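"""Shared fixtures and builders for the test suite."""

from __future__ import annotations

from pathlib import Path

import pytest

from rankvar.annotation import SpliceScores, TranscriptAnnotation


def make_ann(
    variant_id="1_100_A_G",
    gene="GENE1",
    transcript_id="NM_000001.1",
    transcript_length=2000,
    coding_effect="none",
    location="exon",
    deltas=(None, None, None),  # (MES, NNS, SSF) percent deltas
    dist=None,
    nearest=None,
    phastcons=None,
    sift=None,
    pph2=None,
    clinsig="",
    rs_evidence=None,
    frequencies=None,
    **kwargs,
) -> TranscriptAnnotation:
    """Concise TranscriptAnnotation builder for scoring/filtering tests."""
    mes, nns, ssf = deltas
    return TranscriptAnnotation(
        variant_id=variant_id,
        gene=gene,
        transcript_id=transcript_id,
        transcript_length=transcript_length,
        coding_effect=coding_effect,
        location=location,
        mes=SpliceScores(delta_percent=mes),
        nns=SpliceScores(delta_percent=nns),
        ssf=SpliceScores(delta_percent=ssf),
        dist_nearest_ss=dist,
        nearest_ss=nearest,
        phastcons=phastcons,
        sift_pred=sift,
        pph2_pred=pph2,
        rs_clinical_significance=clinsig,
        rs_validation_evidence=rs_evidence,
        frequencies=dict(frequencies or {}),
        **kwargs,
    )


VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    "##contig=<ID=1>\n"
    "##contig=<ID=X>\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n'
    '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n'
)


def write_vcf_text(path: Path, samples, records) -> Path:
    """Write a small VCF; records are raw data-line strings."""
    header = VCF_HEADER + "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
    path.write_text(header + "\t".join(samples) + "\n" + "".join(r + "\n" for r in records))
    return path


@pytest.fixture
def vcf_writer(tmp_path):
    def _write(name, samples, records):
        return write_vcf_text(tmp_path / name, samples, records)

    return _write
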