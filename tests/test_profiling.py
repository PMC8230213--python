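"""Incidence matrices, gene summaries, stratification, cohort descriptives."""

import numpy as np
import pandas as pd
import pytest

import oncopanel as op
from oncopanel.profiling import (cohort_summary, dichotomize, gene_sample_matrix,
                                 gene_summary, select_recurrent_genes, stratify)


@pytest.fixture(scope="module")
def matrices(demo_classified, demo_cohort):
    return {c: gene_sample_matrix(demo_classified, demo_cohort.calls, c)
            for c in ("any", "somatic", "pathogenic", "tissue_specific_pathogenic")}


class TestMatrix:
    def test_row_sums_match_brute_force_recount(self, demo_classified, demo_cohort, matrices):
        matrix = matrices["pathogenic"]
        flags = demo_classified.set_index(["chrom", "pos", "ref", "alt"])
        from oncopanel.filtration import quality_filter
        passing = quality_filter(demo_cohort.calls)
        brute: dict[str, set] = {}
        for row in passing.itertuples(index=False):
            key = (row.chrom, row.pos, row.ref, row.alt)
            rec = flags.loc[key]
            if rec["pathogenic"] and not rec["excluded_common"]:
                brute.setdefault(rec["gene"], set()).add(row.sample_id)
        for gene in matrix.index:
            assert matrix.loc[gene].sum() == len(brute.get(gene, set()))

    def test_tissue_specific_excludes_first_time_variants(self, demo_classified, demo_cohort):
        matrix = gene_sample_matrix(demo_classified, demo_cohort.calls,
                                    "tissue_specific_pathogenic")
        novel_only_genes = set(
            demo_classified.loc[demo_classified["novel_in_target_tissue"]
                                & ~demo_classified["tissue_specific_pathogenic"], "gene"]
        ) - set(demo_classified.loc[demo_classified["tissue_specific_pathogenic"], "gene"])
        assert not novel_only_genes & set(matrix.index)

    def test_duplicate_call_rows_do_not_change_matrix(self, demo_classified, demo_cohort):
        doubled = pd.concat([demo_cohort.calls, demo_cohort.calls], ignore_index=True)
        a = gene_sample_matrix(demo_classified, demo_cohort.calls, "any")
        b = gene_sample_matrix(demo_classified, doubled, "any")
        pd.testing.assert_frame_equal(a, b)

    def test_unknown_criterion_rejected(self, demo_classified, demo_cohort):
        with pytest.raises(ValueError, match="criterion"):
            gene_sample_matrix(demo_classified, demo_cohort.calls, "bogus")

    def test_cells_are_binary(self, matrices):
        for matrix in matrices.values():
            assert set(np.unique(matrix.to_numpy())) <= {0, 1}


class TestRecurrentSelection:
    def test_threshold_scan(self):
        matrix = pd.DataFrame([[1, 1, 0, 0], [1, 1, 1, 0], [1, 1, 1, 1]],
                              index=["g2", "g3", "g4"],
                              columns=["s1", "s2", "s3", "s4"])
        assert select_recurrent_genes(matrix, 3) == ["g3", "g4"]
        assert select_recurrent_genes(matrix, 1) == ["g2", "g3", "g4"]

    def test_matches_brute_force(self, matrices):
        matrix = matrices["tissue_specific_pathogenic"]
        brute = sorted(g for g in matrix.index if int(matrix.loc[g].sum()) >= 3)
        assert select_recurrent_genes(matrix, 3) == brute


class TestGeneSummary:
    def test_reference_gene_row_composition(self):
        """A gene built like the top cohort gene: 38 variants of which 5 novel,
        23 confirmed somatic, 15 pathogenic, 12 with a prior large-intestine
        report, carried by 24/25 samples."""
        rows = []
        for i in range(38):
            rows.append({
                "chrom": "chr5", "pos": 1000 + i, "ref": "A", "alt": "T",
                "gene": "APC", "consequence": "missense", "sift": None, "polyphen": None,
                "n_carriers": 1, "passed_quality": True, "excluded_common": False,
                "novel_vs_cosmic": i < 5, "in_icgc": False, "novel_vs_both": i < 5,
                "confirmed_somatic": 5 <= i < 28, "pathogenic": 5 <= i < 20,
                "tissue_specific_pathogenic": 5 <= i < 17,
                "novel_in_target_tissue": 17 <= i < 20,
                "germline_suspect_vaf": False, "germline_suspect_maf_support": False,
                "damaging_included": False,
            })
        classified = pd.DataFrame(rows)
        samples = [f"s{j:02d}" for j in range(25)]
        calls = pd.DataFrame([
            {"sample_id": s, "chrom": "chr5", "pos": 1000 + 6, "ref": "A", "alt": "T",
             "qual": 60.0, "depth": 500, "alt_depth": 100, "vaf_percent": 20.0}
            for s in samples[:24]
        ] + [  # last sample carries only a non-pathogenic variant
            {"sample_id": samples[24], "chrom": "chr5", "pos": 1000 + 30, "ref": "A",
             "alt": "T", "qual": 60.0, "depth": 500, "alt_depth": 100, "vaf_percent": 20.0}
        ])
        m_all = gene_sample_matrix(classified, calls, "any")
        m_som = gene_sample_matrix(classified, calls, "somatic")
        m_path = gene_sample_matrix(classified, calls, "pathogenic")
        summary = gene_summary(classified, m_all, m_som, m_path).set_index("gene")
        row = summary.loc["APC"]
        assert row["total_variants"] == 38
        assert row["novel_variants"] == 5
        assert row["pathogenic_variants"] == 15
        assert row["somatic_variants"] == 23
        assert row["tissue_specific_variants"] == 12
        assert row["pct_samples_pathogenic_all_tissue"] == pytest.approx(24 / 25)

    def test_fully_mutated_gene_ranks_first_with_proportion_one(
            self, demo_classified, matrices):
        m_path = matrices["pathogenic"].copy()
        m_path.loc[m_path.index[0], :] = 1
        summary = gene_summary(demo_classified, matrices["any"], matrices["somatic"], m_path)
        assert summary.iloc[0]["gene"] == m_path.index[0]
        assert summary.iloc[0]["pct_samples_pathogenic_all_tissue"] == pytest.approx(1.0)

    def test_ordering_stable_under_input_permutation(self, demo_classified, matrices):
        shuffled = demo_classified.sample(frac=1.0, random_state=3)
        a = gene_summary(demo_classified, matrices["any"], matrices["somatic"],
                         matrices["pathogenic"])
        b = gene_summary(shuffled, matrices["any"], matrices["somatic"],
                         matrices["pathogenic"])
        assert list(a["gene"]) == list(b["gene"])


class TestStratify:
    def test_age_and_stage_boundaries(self):
        patients = pd.DataFrame({
            "patient_id": ["p1", "p2", "p3", "p4"],
            "age_years": [49.9, 50.0, 30.0, 70.0],
            "gender": ["male"] * 4, "t_stage": ["T2"] * 4, "n_stage": ["N0"] * 4,
            "m_stage": ["M0"] * 4,
            "overall_stage": ["II", "III", "I", "IV"],
            "site": ["left_colon", "right_colon", "rectum", "other"],
        })
        ages = dichotomize(patients, "age_group")
        assert bool(ages["p1"]) and not bool(ages["p2"])
        stages = dichotomize(patients, "stage_group")  # True = late
        assert not bool(stages["p1"]) and bool(stages["p2"])
        sites = dichotomize(patients, "site")
        assert bool(sites["p1"]) and not bool(sites["p2"])
        assert pd.isna(sites["p3"]) and pd.isna(sites["p4"])  # rectum/other dropped

    @pytest.mark.parametrize("axis", ["gender", "age_group", "stage_group",
                                      "site", "lymph_node", "metastasis"])
    def test_strata_partition_row_sums(self, matrices, demo_cohort, axis):
        matrix = matrices["tissue_specific_pathogenic"]
        strata = stratify(matrix, demo_cohort.patients, axis)
        assert (strata.sum(axis=1) == matrix.sum(axis=1)).all()

    def test_sample_without_patient_record_raises(self, matrices, demo_cohort):
        truncated = demo_cohort.patients.iloc[:-5]
        with pytest.raises(ValueError, match="without patient records"):
            stratify(matrices["any"], truncated, "gender")


class TestCohortSummary:
    def test_reference_percentages(self):
        summary = cohort_summary(op.table1_patients(seed=0)).set_index(["field", "category"])
        male = summary.loc[("gender", "male")]
        assert male["n"] == 58 and male["denominator"] == 95 and male["pct"] == 61
        left = summary.loc[("site", "left_colon")]
        assert left["n"] == 47 and left["denominator"] == 90 and left["pct"] == 52

    def test_numerators_bounded_by_reported_denominators(self, demo_cohort):
        summary = cohort_summary(demo_cohort.patients)
        cat = summary[summary["pct"].notna()]
        assert (cat["n"] <= cat["denominator"]).all()

    def test_all_missing_field_gets_annotated_row(self):
        patients = op.table1_patients(seed=0).assign(site=None)
        summary = cohort_summary(patients)
        row = summary[(summary["field"] == "site")]
        assert len(row) == 1 and "missing" in row.iloc[0]["value"]

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            cohort_summary(pd.DataFrame(columns=["patient_id", "age_years", "gender",
                                                 "t_stage", "n_stage", "m_stage",
                                                 "overall_stage", "site"]))
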