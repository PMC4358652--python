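"""Ranked by-variant / by-gene reports and the category-count table."""

import random

import pytest

from rankvar.cohort_analysis import FilterConfig, apply_filters
from rankvar.cohort_io import Cohort, SampleCall, VariantKey
from rankvar.ranking_output import (
    COUNT_CATEGORIES,
    REPORT_COLUMNS,
    category_report,
    rank_by_gene,
    rank_by_variant,
    write_reports,
)
from rankvar.scoring import score_variant

from conftest import make_ann


def build_cohort(entries):
    """entries: list of (vid_tuple, {sample: zygosity})."""
    samples = sorted({s for _, z in entries for s in z})
    variants, calls = {}, {}
    for (chrom, pos, ref, alt), zyg in entries:
        key = VariantKey(chrom, pos, ref, alt)
        variants[key.id] = key
        for sample, z in zyg.items():
            calls[(key.id, sample)] = SampleCall(
                sample_id=sample, zygosity=z, total_depth=50, alt_depth=25, percent_alt=50.0
            )
    return Cohort(samples=tuple(samples), variants=variants, calls=calls)


def scored_map(cohort, spec):
    """spec: vid -> make_ann kwargs; annotation variant_id/gene from spec."""
    out = {}
    for vid in cohort.variants:
        kwargs = dict(spec.get(vid, {}))
        out[vid] = score_variant([make_ann(variant_id=vid, **kwargs)])
    return out


def all_decisions(cohort, scored, config=None):
    return {
        (vid, s): apply_filters(cohort.get_call(vid, s), scored[vid], config)
        for vid in cohort.variants
        for s in cohort.samples
    }


class TestRankByVariant:
    def test_descending_score_order(self):
        cohort = build_cohort(
            [
                (("1", 100, "A", "G"), {"P1": 1}),
                (("1", 200, "A", "G"), {"P1": 1}),
                (("1", 300, "A", "G"), {"P1": 2}),
            ]
        )
        scored = scored_map(
            cohort,
            {
                "1_100_A_G": dict(coding_effect="synonymous"),
                "1_200_A_G": dict(clinsig="pathogenic"),
                "1_300_A_G": dict(coding_effect="nonsense"),
            },
        )
        order = rank_by_variant("P1", cohort, scored)
        assert [scored[v].final_score for v in order] == [110, 100, 10]

    def test_tie_break_matches_documented_sort_key(self):
        """Oracle: exhaustive comparison using the documented key
        (score desc, max frequency asc with absent=0, coordinates)."""
        rng = random.Random(7)
        entries = []
        spec = {}
        for i in range(12):
            key = ("1", 100 + i, "A", "G")
            entries.append((key, {"P1": 1}))
            freq = rng.choice([None, 0.0001, 0.005, 0.009])
            spec[f"1_{100 + i}_A_G"] = dict(
                coding_effect=rng.choice(["nonsense", "missense"]),
                frequencies={} if freq is None else {"rsMAF": freq},
            )
        cohort = build_cohort(entries)
        scored = scored_map(cohort, spec)

        def oracle_key(vid):
            sv = scored[vid]
            f = sv.representative.max_frequency()
            k = cohort.variants[vid]
            return (-sv.final_score, 0.0 if f is None else f, k.chrom, k.pos, k.ref, k.alt)

        assert rank_by_variant("P1", cohort, scored) == sorted(spec, key=oracle_key)

    def test_absent_frequency_ranks_before_known_rare(self):
        cohort = build_cohort(
            [(("1", 100, "A", "G"), {"P1": 1}), (("1", 50, "A", "G"), {"P1": 1})]
        )
        scored = scored_map(
            cohort,
            {
                "1_100_A_G": dict(coding_effect="nonsense"),  # no frequency
                "1_50_A_G": dict(coding_effect="nonsense", frequencies={"rsMAF": 0.0001}),
            },
        )
        assert rank_by_variant("P1", cohort, scored) == ["1_100_A_G", "1_50_A_G"]

    def test_only_carried_variants_appear(self):
        cohort = build_cohort(
            [(("1", 100, "A", "G"), {"P1": 1, "P2": 0}), (("1", 200, "A", "G"), {"P2": 2})]
        )
        scored = scored_map(cohort, {})
        assert rank_by_variant("P1", cohort, scored) == ["1_100_A_G"]
        assert rank_by_variant("P2", cohort, scored) == ["1_200_A_G"]

    def test_filtered_view_drops_failing_variant_but_not_all(self):
        """A top variant failing a quality rule disappears from the
        filtered ranking while remaining in the AllVariants one."""
        cohort = build_cohort(
            [(("1", 100, "A", "G"), {"P1": 1}), (("1", 200, "A", "G"), {"P1": 1})]
        )
        # top variant has only 7 supporting reads
        cohort.calls[("1_100_A_G", "P1")] = SampleCall(
            "P1", zygosity=1, total_depth=50, alt_depth=7, percent_alt=14.0
        )
        scored = scored_map(
            cohort,
            {
                "1_100_A_G": dict(coding_effect="nonsense"),
                "1_200_A_G": dict(coding_effect="missense"),
            },
        )
        decisions = all_decisions(cohort, scored)
        full = rank_by_variant("P1", cohort, scored)
        filtered = rank_by_variant("P1", cohort, scored, decisions, filtered=True)
        assert full == ["1_100_A_G", "1_200_A_G"]
        assert filtered == ["1_200_A_G"]
        assert set(filtered) <= set(full)


class TestRankByGene:
    def _rank(self, gene_variants):
        """gene_variants: gene -> list of (zygosity, score-producing kwargs)."""
        entries, spec = [], {}
        pos = 100
        for gene, members in gene_variants.items():
            for zyg, kwargs in members:
                key = ("1", pos, "A", "G")
                entries.append((key, {"P1": zyg}))
                spec[f"1_{pos}_A_G"] = dict(gene=gene, **kwargs)
                pos += 100
        cohort = build_cohort(entries)
        scored = scored_map(cohort, spec)
        return rank_by_gene("P1", cohort, scored), scored

    def test_hom_beats_single_strong_het_plus_weak(self):
        blocks, _ = self._rank(
            {
                "HOMG": [(2, dict(coding_effect="nonsense"))],  # hom 100
                "HETG": [
                    (1, dict(coding_effect="nonsense")),  # het 100
                    (1, dict(coding_effect="synonymous")),  # het 10
                ],
            }
        )
        assert [b.gene for b in blocks] == ["HOMG", "HETG"]
        assert blocks[0].rank_key == 100 and blocks[1].rank_key == 10

    def test_compound_het_beats_single_het(self):
        blocks, _ = self._rank(
            {
                "SINGLE": [(1, dict(clinsig="pathogenic"))],  # het 110, no partner
                "COMPOUND": [
                    (1, dict(coding_effect="nonsense", phastcons=0.99)),  # 105 -> use 90/80 pair
                    (1, dict(coding_effect="start loss")),  # 80
                ],
            }
        )
        assert [b.gene for b in blocks] == ["COMPOUND", "SINGLE"]
        assert blocks[0].rank_key == 80  # the limiting second allele
        assert blocks[1].rank_key == 0

    def test_rank_key_matches_documented_oracle(self):
        rng = random.Random(11)
        effects = ["nonsense", "missense", "synonymous", "start loss", "in-frame"]
        gene_variants = {
            f"G{i}": [
                (rng.choice([1, 1, 2]), dict(coding_effect=rng.choice(effects)))
                for _ in range(rng.randint(1, 4))
            ]
            for i in range(8)
        }
        blocks, scored = self._rank(gene_variants)

        def oracle(block):
            hom = block.hom_best if block.hom_best is not None else 0
            het2 = block.het_top2[1] if len(block.het_top2) > 1 else 0
            return max(hom, het2)

        keys = [oracle(b) for b in blocks]
        assert keys == sorted(keys, reverse=True)
        assert [b.rank_key for b in blocks] == keys

    def test_block_contains_every_gene_variant(self):
        blocks, scored = self._rank(
            {
                "G1": [
                    (1, dict(coding_effect="nonsense")),
                    (1, dict(coding_effect="synonymous")),
                    (2, dict(coding_effect="missense")),
                ]
            }
        )
        assert len(blocks) == 1
        assert len(blocks[0].members) == 3
        member_scores = [scored[v].final_score for v in blocks[0].members]
        assert member_scores == sorted(member_scores, reverse=True)


class TestWriteReports:
    @pytest.fixture
    def simple_setup(self):
        cohort = build_cohort(
            [(("1", 100, "A", "G"), {"P1": 1, "P2": 0}), (("1", 200, "C", "T"), {"P2": 2})]
        )
        scored = scored_map(
            cohort,
            {
                "1_100_A_G": dict(coding_effect="missense"),
                "1_200_C_T": dict(coding_effect="nonsense"),
            },
        )
        return cohort, scored, all_decisions(cohort, scored)

    def test_four_files_per_sample(self, simple_setup, tmp_path):
        cohort, scored, decisions = simple_setup
        paths = write_reports(cohort, scored, decisions, tmp_path)
        assert len(paths) == 8  # 2 samples x (byVar, byGene) x (All, filtered)
        names = {p.name for p in paths}
        assert "P1.AllVariants.rankingByVar.tsv" in names
        assert "P2.filteredVariants.rankingByGene.tsv" in names

    def test_header_and_column_structure(self, simple_setup, tmp_path):
        cohort, scored, decisions = simple_setup
        write_reports(cohort, scored, decisions, tmp_path)
        lines = (tmp_path / "P1.AllVariants.rankingByVar.tsv").read_text().splitlines()
        assert lines[0] == "## Barcode: P1 P2"
        assert lines[1].split("\t") == REPORT_COLUMNS
        for row in lines[2:]:
            assert len(row.split("\t")) == len(REPORT_COLUMNS)

    def test_reruns_are_byte_identical(self, simple_setup, tmp_path):
        cohort, scored, decisions = simple_setup
        write_reports(cohort, scored, decisions, tmp_path / "a")
        write_reports(cohort, scored, decisions, tmp_path / "b")
        for path in sorted((tmp_path / "a").iterdir()):
            assert path.read_bytes() == (tmp_path / "b" / path.name).read_bytes()

    def test_empty_filtered_set_writes_header_only(self, tmp_path):
        cohort = build_cohort([(("1", 100, "A", "G"), {"P1": 1})])
        scored = scored_map(cohort, {"1_100_A_G": dict(frequencies={"rsMAF": 0.2})})
        decisions = all_decisions(cohort, scored)
        write_reports(cohort, scored, decisions, tmp_path)
        lines = (tmp_path / "P1.filteredVariants.rankingByVar.tsv").read_text().splitlines()
        assert len(lines) == 2  # barcode comment + header

    def test_barcode_columns_in_rows(self, simple_setup, tmp_path):
        cohort, scored, decisions = simple_setup
        write_reports(cohort, scored, decisions, tmp_path)
        lines = (tmp_path / "P2.AllVariants.rankingByVar.tsv").read_text().splitlines()
        row = dict(zip(REPORT_COLUMNS, lines[2].split("\t")))
        assert row["VariantID"] == "1_200_C_T"
        assert row["Barcode"] == "02"
        assert row["Hom_Count"] == "1" and row["Allele_Count"] == "2"
        assert row["VarScore"] == "100"


class TestCategoryReport:
    def test_counts_and_dataset_additivity(self):
        cohort = build_cohort(
            [
                (("1", 100, "A", "G"), {"P1": 1, "P2": 2}),
                (("1", 200, "C", "T"), {"P1": 2}),
                (("1", 300, "G", "A"), {"P2": 1}),
            ]
        )
        scored = scored_map(
            cohort,
            {
                "1_100_A_G": dict(coding_effect="missense"),
                "1_200_C_T": dict(location="intron", coding_effect="none"),
                # splice-site category via essential splice position
                "1_300_G_A": dict(
                    location="intron", coding_effect="none", dist=1, nearest="donor"
                ),
            },
        )
        report = category_report(cohort, scored)
        assert set(report["Category"]) == set(COUNT_CATEGORIES)

        def cell(sample, cat, col):
            row = report[(report.Sample == sample) & (report.Category == cat)]
            return int(row[col].iloc[0])

        assert cell("P1", "missense", "Het") == 1
        assert cell("P2", "missense", "Hom") == 1
        assert cell("P1", "intronic", "Hom") == 1
        assert cell("P2", "splice site", "Het") == 1
        assert cell("P1", "missense", "Total") == 1
        # whole-dataset row is the column-wise sum over samples
        for cat in COUNT_CATEGORIES:
            for col in ("Hom", "Het"):
                assert cell("ALL", cat, col) == cell("P1", cat, col) + cell("P2", cat, col)

    def test_unannotated_variant_counted(self):
        cohort = build_cohort([(("1", 100, "A", "G"), {"P1": 1})])
        scored = {"1_100_A_G": score_variant([])}
        scored["1_100_A_G"].variant_id = "1_100_A_G"
        report = category_report(cohort, scored)
        row = report[(report.Sample == "P1") & (report.Category == "not annotated")]
        assert int(row["Total"].iloc[0]) == 1
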