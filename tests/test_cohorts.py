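"""Cohort filter chains, audits, merging and summaries."""

import datetime

import pytest

from varbench import (
    CohortDataset,
    FilterRuleSet,
    build_gnomad_benign,
    exclude_training_overlap,
    filter_clinvar,
    filter_recent,
    import_external_list,
    merge_cohorts,
    select_missense,
    summarize_distribution,
)
from varbench.cohorts import CohortError
from conftest import make_record

import pandas as pd

HCM_RULES = FilterRuleSet(
    ontology_ids=frozenset({"MedGen:C3495498", "MedGen:C0949658"}),
    min_review_stars=1,
)


def assert_telescoping(cohort):
    trail = cohort.audit_trail
    for (_, _, kept), (_, n_in, _) in zip(trail, trail[1:]):
        assert kept == n_in


class TestFilterClinvar:
    def test_hand_enumerated_six_records(self, clinvar_six_records):
        cohort = filter_clinvar(clinvar_six_records, HCM_RULES)
        assert len(cohort) == 3
        assert cohort.n_pathogenic == 2
        assert cohort.n_benign == 1
        assert_telescoping(cohort)

    def test_zero_star_removed(self, clinvar_six_records):
        cohort = filter_clinvar(clinvar_six_records, HCM_RULES)
        kept = {r.pos for r in cohort.records}
        assert 1003 not in kept  # the zero-star record

    def test_uncertain_significance_removed(self):
        recs = [
            make_record(0, significance="Uncertain_significance", review_stars=2,
                        ontology_ids=frozenset({"MedGen:C3495498"})),
            make_record(1, significance="Pathogenic", review_stars=2,
                        ontology_ids=frozenset({"MedGen:C3495498"})),
        ]
        cohort = filter_clinvar(recs, HCM_RULES)
        assert len(cohort) == 1 and cohort.n_pathogenic == 1

    def test_missing_metadata_is_an_error(self):
        recs = [make_record(0, significance="Pathogenic", review_stars=None)]
        with pytest.raises(CohortError, match="review_stars"):
            filter_clinvar(recs, HCM_RULES)

    def test_idempotent(self, clinvar_six_records):
        once = filter_clinvar(clinvar_six_records, HCM_RULES)
        twice = filter_clinvar(once.records, HCM_RULES)
        assert [r.key for r in twice.records] == [r.key for r in once.records]


class TestSelectMissense:
    @pytest.mark.parametrize(
        "consequence, kept",
        [
            ("missense_variant", True),
            ("synonymous_variant", False),
            ("missense_variant&splice_region_variant", True),
            ("intron_variant", False),
        ],
    )
    def test_substring_rule(self, consequence, kept):
        recs = [make_record(0, consequence=consequence)]
        assert (len(select_missense(recs)) == 1) is kept

    def test_order_preserved_and_idempotent(self):
        recs = [
            make_record(i, consequence=c)
            for i, c in enumerate(
                ["missense_variant", "synonymous_variant", "missense_variant"]
            )
        ]
        out = select_missense(recs)
        assert [r.pos for r in out] == [1000, 1002]
        assert select_missense(out) == out


class TestGnomadBenign:
    def build_records(self):
        panel_genes = ["MYH7", "MYBPC3", "TNNT2"]
        recs = []
        i = 0
        # 6 clean survivors
        for _ in range(6):
            recs.append(make_record(i, gene=panel_genes[i % 3],
                                    allele_frequency=0.01))
            i += 1
        # rare variant: fails strict AF > 0.001
        recs.append(make_record(i, gene="MYH7", allele_frequency=0.0005)); i += 1
        # AF exactly at the threshold: strict comparison removes it
        recs.append(make_record(i, gene="MYH7", allele_frequency=0.001)); i += 1
        # off-panel gene
        recs.append(make_record(i, gene="BRCA1", allele_frequency=0.01)); i += 1
        # non-missense
        recs.append(make_record(i, gene="MYH7", allele_frequency=0.01,
                                consequence="synonymous_variant")); i += 1
        # excluded gene (single-gene over-representation control)
        recs.append(make_record(i, gene="TTN", allele_frequency=0.01)); i += 1
        return recs

    def rules(self, exclusion=()):
        return FilterRuleSet(
            maf_threshold=0.001,
            gene_panel=frozenset({"MYH7", "MYBPC3", "TNNT2", "TTN"}),
            excluded_genes=frozenset({"TTN"}),
            exclusion_variant_sets=tuple(exclusion),
        )

    def test_filter_chain_counts(self):
        recs = self.build_records()
        cohort, _ = build_gnomad_benign(recs, self.rules(), seed=0)
        assert len(cohort) == 6
        assert cohort.n_benign == 6
        names = [step[0] for step in cohort.audit_trail]
        assert names == ["af>0.001", "gene_panel", "missense", "excluded_genes"]
        assert_telescoping(cohort)

    def test_exclusion_set_step(self):
        recs = self.build_records()
        excl = {recs[0].key}
        cohort, _ = build_gnomad_benign(recs, self.rules([excl]), seed=0)
        assert len(cohort) == 5
        assert cohort.audit_trail[-1][0] == "exclusion_set_1"

    def test_seeded_split_reproducible_and_disjoint(self):
        recs = [make_record(i, gene="MYH7", allele_frequency=0.01)
                for i in range(10)]
        rules = FilterRuleSet(maf_threshold=0.001)
        _, splits_a = build_gnomad_benign(recs, rules, split_sizes=(4, 4), seed=5)
        _, splits_b = build_gnomad_benign(recs, rules, split_sizes=(4, 4), seed=5)
        keys_a = [frozenset(s.keys) for s in splits_a]
        keys_b = [frozenset(s.keys) for s in splits_b]
        assert keys_a == keys_b
        assert not keys_a[0] & keys_a[1]
        assert len(keys_a[0]) == len(keys_a[1]) == 4

    def test_oversized_split_is_an_error(self):
        recs = [make_record(i, gene="MYH7", allele_frequency=0.01)
                for i in range(3)]
        with pytest.raises(CohortError, match="split"):
            build_gnomad_benign(recs, FilterRuleSet(), split_sizes=(2, 2), seed=0)

    def test_conjunctive_filters_commute(self):
        # permuting AF / panel / missense yields the same final key set
        recs = self.build_records()
        base, _ = build_gnomad_benign(recs, self.rules(), seed=0)
        af_first = [r for r in recs if r.allele_frequency > 0.001]
        panel_first = [r for r in recs if r.gene in self.rules().gene_panel]
        manual = {
            r.key
            for r in select_missense(panel_first)
            if r.allele_frequency > 0.001 and r.gene != "TTN"
        }
        assert base.keys == manual


class TestImportExternalList:
    def frame(self):
        return pd.DataFrame(
            {
                "chrom": ["chr1"] * 4,
                "pos": [1, 2, 3, 4],
                "ref": ["A"] * 4,
                "alt": ["C"] * 4,
                "gene": ["MYH7"] * 4,
                "consequence": ["missense_variant"] * 3 + ["synonymous_variant"],
                "assignment": ["Pathogenic", "Pathogenic", "Benign", "Pathogenic"],
                "allele_mismatch": [False, True, False, False],
            }
        )

    def test_chain(self):
        cohort = import_external_list(self.frame())
        # row2 mismatch, row3 not whitelisted, row4 not missense
        assert len(cohort) == 1
        assert cohort.records[0].pos == 1
        assert cohort.n_pathogenic == 1
        assert_telescoping(cohort)

    def test_exclusion_of_known_keys(self):
        cohort = import_external_list(
            self.frame(), exclusion_keys={("chr1", 1, "A", "C")}
        )
        assert len(cohort) == 0

    def test_empty_input(self):
        cohort = import_external_list(self.frame().iloc[0:0])
        assert len(cohort) == 0
        assert all(n_in == 0 and kept == 0 for _, n_in, kept in cohort.audit_trail)

    def test_missing_columns_are_an_error(self):
        with pytest.raises(CohortError, match="assignment"):
            import_external_list(self.frame().drop(columns=["assignment"]))


class TestMergeCohorts:
    def cohort(self, name, n, label="pathogenic", start=0):
        return CohortDataset(
            name=name,
            records=[make_record(start + i, label=label) for i in range(n)],
        )

    def test_disjoint_union(self):
        merged = merge_cohorts([self.cohort("a", 3), self.cohort("b", 4, start=10)])
        assert len(merged) == 7

    def test_merge_with_self_is_idempotent(self):
        a = self.cohort("a", 5)
        merged = merge_cohorts([a, a], dedupe=True)
        assert merged.keys == a.keys

    def test_shared_keys_counted_once(self):
        a = self.cohort("a", 4)  # positions 1000..1003
        b = self.cohort("b", 4, start=2)  # positions 1002..1005
        merged = merge_cohorts([a, b], dedupe=True)
        assert len(merged) == 4 + 4 - 2

    def test_conflicting_labels_error_without_dedupe(self):
        a = self.cohort("a", 2, label="pathogenic")
        b = self.cohort("b", 2, label="benign")
        with pytest.raises(CohortError, match="conflicting"):
            merge_cohorts([a, b], dedupe=False)

    def test_first_cohort_wins_on_conflict_with_dedupe(self):
        a = self.cohort("a", 2, label="pathogenic")
        b = self.cohort("b", 2, label="benign")
        merged = merge_cohorts([a, b], dedupe=True)
        assert merged.n_pathogenic == 2 and merged.n_benign == 0


class TestSummarizeDistribution:
    def test_small_genes_pool_into_other(self):
        recs = [make_record(i, gene="MYH7") for i in range(6)] + [
            make_record(10 + i, gene=f"RARE{i}") for i in range(4)
        ]
        gene_table, _, _ = summarize_distribution(recs, min_gene_count=5)
        assert set(gene_table["gene"]) == {"MYH7", "Other"}
        other = gene_table.set_index("gene").loc["Other", "count"]
        assert other == 4

    def test_category_generalization(self):
        recs = [
            make_record(0, molecular_consequence="inframe_insertion"),
            make_record(1, molecular_consequence="inframe_deletion"),
            make_record(2, molecular_consequence="splice_donor_variant"),
            make_record(3, molecular_consequence="intron_variant"),
            make_record(4, molecular_consequence=None,
                        consequence="missense_variant"),
        ]
        _, cats, _ = summarize_distribution(recs, min_gene_count=1)
        lookup = dict(zip(cats["category"], cats["count"]))
        assert lookup["Inframe indel"] == 2
        assert lookup["Splice site/Intron"] == 2
        assert lookup["missense_variant"] == 1

    def test_proportions_sum_to_one(self):
        recs = [make_record(i, gene=f"G{i % 3}") for i in range(11)]
        gene_table, cats, per_gene = summarize_distribution(recs, min_gene_count=2)
        assert gene_table["proportion"].sum() == pytest.approx(1.0, abs=1e-12)
        assert cats["proportion"].sum() == pytest.approx(1.0, abs=1e-12)
        for t in per_gene.values():
            assert t["proportion"].sum() == pytest.approx(1.0, abs=1e-12)


class TestCircularityAndRecency:
    def test_training_overlap_union_arithmetic(self):
        records = [make_record(i, label="pathogenic") for i in range(10)]
        cohort = CohortDataset(name="c", records=records)
        sets = {
            "toolA": {records[0].key, records[1].key},
            "toolB": {records[1].key, records[2].key},  # one shared key
        }
        out = exclude_training_overlap(cohort, sets)
        assert len(out) == 7
        step_names = [s[0] for s in out.audit_trail]
        assert step_names == [
            "training_overlap:toolA",
            "training_overlap:toolB",
            "training_overlap:union",
        ]
        assert_telescoping(out)

    def test_empty_training_sets_is_identity(self):
        cohort = CohortDataset(name="c", records=[make_record(0)])
        out = exclude_training_overlap(cohort, {})
        assert out.keys == cohort.keys

    def test_recency_cutoff_strict(self):
        cutoff = datetime.date(2020, 6, 1)
        recs = [
            make_record(0, first_reported=cutoff),
            make_record(1, first_reported=cutoff + datetime.timedelta(days=1)),
            make_record(2, first_reported=datetime.date(2019, 1, 1)),
            make_record(3, first_reported=datetime.date(2021, 1, 1)),
            make_record(4, first_reported=datetime.date(2022, 5, 5)),
            make_record(5, first_reported=None),  # undated: dropped
        ]
        out = filter_recent(recs, cutoff)
        assert {r.pos for r in out.records} == {1001, 1003, 1004}
        assert out.audit_trail[0] == ("has_first_reported", 6, 5)
        assert_telescoping(out)
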