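"""Drug matching, event queries, pair construction and contingency tables."""

import pandas as pd
import pytest

import pvsignal as pv
from pvsignal.cohort import build_contingency, build_pairs, match_drug, normalize_drug_name
from pvsignal.reference import load_reference_screen
from conftest import small_clean_set

TZP = "piperacillin\\tazobactam"


class TestDrugMatching:
    @pytest.mark.parametrize(
        "verbatim,expected",
        [
            ("PIPERACILLIN/TAZOBACTAM", TZP),
            ("Zosyn 4.5 g", TZP),
            ("  tazocin ", TZP),
            ("Amoxicillin 500 mg", "amoxicillin"),
            ("AUGMENTIN", "amoxicillin\\clavulanic acid"),
            ("penicillin vk", "penicillin V"),
            ("benzylpenicillin", "penicillin G"),
            ("vancomycin", "other"),
            ("piperacillin sodium", "piperacillin"),
        ],
    )
    def test_exact_match_after_normalization(self, verbatim, expected, drug_dictionary):
        assert match_drug(verbatim, drug_dictionary) == expected

    def test_no_substring_matching(self, drug_dictionary):
        # a name merely containing a synonym must not match
        assert match_drug("not really amoxicillin compound", drug_dictionary) == "other"

    @pytest.mark.parametrize(
        "raw,normalized",
        [
            ("Zosyn 4.5 g", "zosyn"),
            ("DRUG  NAME   100mg", "drug name"),
            ("plain", "plain"),
        ],
    )
    def test_dosage_token_stripping(self, raw, normalized):
        assert normalize_drug_name(raw) == normalized

    def test_all_twelve_penicillins_present(self, drug_dictionary):
        screen = load_reference_screen("pcn_hypokalemia_within_class")
        assert set(screen["label"]) <= set(drug_dictionary.drugs)

    def test_synonym_sets_disjoint(self, drug_dictionary):
        all_syns = [s for syns in drug_dictionary.synonyms.values() for s in syns]
        assert len(all_syns) == len(set(all_syns))


class TestEventQueries:
    def test_ten_disorders_with_two_pts_each(self, event_queries):
        assert len(event_queries) == 10
        assert all(len(pts) == 2 for pts in event_queries.values())
        all_pts = [pt for pts in event_queries.values() for pt in pts]
        assert len(all_pts) == 20 and len(set(all_pts)) == 20

    def test_each_disorder_pairs_clinical_and_laboratory_terms(self, event_queries):
        assert event_queries["hypokalemia"] == {"hypokalaemia", "blood potassium decreased"}
        assert event_queries["hypermagnesemia"] == {"hypermagnesaemia", "blood magnesium increased"}


class TestBuildPairs:
    def test_cartesian_product_of_drugs_and_events(self):
        clean = small_clean_set(
            demo_rows=[{"report_id": "1", "case_id": "c1"}],
            drug_rows=[("1", "Zosyn", "PS"), ("1", "vancomycin", "SS")],
            reac_rows=[("1", "hypokalaemia"), ("1", "nausea"), ("1", "rash")],
        )
        pairs = build_pairs(clean, pv.load_drug_dictionary())
        assert len(pairs) == 6
        assert set(pairs["drug"]) == {TZP, "vancomycin"}

    def test_within_report_duplicates_collapse(self):
        clean = small_clean_set(
            demo_rows=[{"report_id": "1", "case_id": "c1"}],
            drug_rows=[("1", "Zosyn", "PS"), ("1", "piperacillin/tazobactam", "SS")],
            reac_rows=[("1", "nausea"), ("1", "nausea")],
        )
        pairs = build_pairs(clean, pv.load_drug_dictionary())
        assert len(pairs) == 1  # both names standardize to the same drug

    def test_pair_totals_match_planted_truth(self, e2e_runs):
        for run in e2e_runs:
            assert len(run["pairs"]) == int(run["truth"].pair_counts.values.sum())

    def test_per_cell_counts_match_planted_truth(self, e2e_runs):
        run = e2e_runs[0]
        truth = run["truth"]
        got = run["pairs"].groupby(["drug", "pt"]).size()
        for drug in truth.pair_counts.index:
            for event in truth.pair_counts.columns:
                assert got.get((drug, event), 0) == truth.pair_counts.loc[drug, event]


class TestContingency:
    def pair_frame(self):
        rows = [
            ("1", TZP, True, "hypokalaemia"),
            ("2", TZP, True, "hypokalaemia"),
            ("3", TZP, True, "nausea"),
            ("4", "amoxicillin", True, "hypokalaemia"),
            ("5", "amoxicillin", True, "rash"),
            ("6", "vancomycin", False, "nausea"),
            ("7", "vancomycin", False, "hypokalaemia"),
            ("8", "vancomycin", False, "rash"),
            ("9", "amoxicillin", True, "nausea"),
            ("10", TZP, True, "rash"),
        ]
        return pd.DataFrame(rows, columns=["report_id", "drug", "matched", "pt"])

    def test_cell_conservation(self):
        t = build_contingency(self.pair_frame(), TZP, {"hypokalaemia"})
        assert t.a == 2 and t.n == 10

    def test_brute_force_recount(self):
        pairs = self.pair_frame()
        query = {"hypokalaemia"}
        t = build_contingency(pairs, TZP, query)
        a = sum((r.drug == TZP) and (r.pt in query) for r in pairs.itertuples())
        b = sum((r.drug == TZP) and (r.pt not in query) for r in pairs.itertuples())
        c = sum((r.drug != TZP) and (r.pt in query) for r in pairs.itertuples())
        d = sum((r.drug != TZP) and (r.pt not in query) for r in pairs.itertuples())
        assert (t.a, t.b, t.c, t.d) == (a, b, c, d)

    def test_restriction_commutes_with_building(self):
        pairs = self.pair_frame()
        universe = [TZP, "amoxicillin"]
        t1 = build_contingency(pairs, TZP, {"hypokalaemia"}, comparator=universe)
        t2 = build_contingency(
            pairs[pairs["drug"].isin(universe)], TZP, {"hypokalaemia"}, comparator="all_other_drugs"
        )
        assert (t1.a, t1.b, t1.c, t1.d) == (t2.a, t2.b, t2.c, t2.d)

    def test_target_absent_from_universe_errors(self):
        with pytest.raises(ValueError):
            build_contingency(self.pair_frame(), "nafcillin", {"hypokalaemia"}, comparator=["nafcillin"])

    def test_target_not_in_drug_list_errors(self):
        with pytest.raises(ValueError):
            build_contingency(self.pair_frame(), TZP, {"hypokalaemia"}, comparator=["amoxicillin"])

    def test_empty_universe_errors(self):
        empty = self.pair_frame().iloc[0:0]
        with pytest.raises(ValueError):
            build_contingency(empty, TZP, {"hypokalaemia"})


class TestWithinClassUniverse:
    def test_row_sums_partition_the_class_universe(self):
        """In the within-class screen every row shares one pair universe:
        each row's a+b+c+d equals it, and the twelve (a+b) row sums add up
        to it."""
        screen = load_reference_screen("pcn_hypokalemia_within_class")
        n_universe = int((screen["a"] + screen["b"] + screen["c"] + screen["d"]).iloc[0])
        assert (screen["a"] + screen["b"] + screen["c"] + screen["d"] == n_universe).all()
        assert int((screen["a"] + screen["b"]).sum()) == n_universe
        assert n_universe == 204_403
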