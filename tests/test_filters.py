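"""PSM retention, protein acceptance and SAP acceptance rules."""

import pandas as pd
import pytest

from paleosap.filters import (
    FilterCriteria,
    SAPCall,
    accept_proteins,
    accept_saps,
    accepted_psm_ids,
    filter_psms,
    position_coverage,
)


def psm_row(dataset="d1", scan="s1", acc="P1", start=1, end=12, score=30.0,
            peptide=None, subs=""):
    peptide = peptide or "A" * (end - start + 1)
    return dict(
        dataset_id=dataset, scan_id=scan, search_label="Pan", accession=acc,
        start=start, end=end, peptide=peptide, modifications="", score=score,
        substitutions=subs,
    )


@pytest.fixture
def planted_table():
    """One violation of each retention rule plus two clean PSMs."""
    rows = [
        psm_row(scan="short", end=9),                      # length 9 < 10
        psm_row(scan="orphan"),                            # not in search 1
        psm_row(scan="cont", acc="CONT1"),                 # contaminant
        psm_row(scan="dropped", acc="GONE1"),              # excluded protein
        psm_row(scan="region", acc="P2", start=95, end=110),  # excluded region
        psm_row(scan="lowscore", score=2.0),               # below score floor
        psm_row(scan="ok1"),
        psm_row(scan="ok2", acc="P2", start=1, end=15),
        # violates both length and contaminant: precedence says "length"
        psm_row(scan="both", acc="CONT1", end=8),
    ]
    table = pd.DataFrame(rows)
    keys = {("d1", s) for s in table["scan_id"]} - {("d1", "orphan")}
    criteria = FilterCriteria(
        min_peptide_length=10,
        score_min=10.0,
        contaminant_accessions=frozenset({"CONT1"}),
        excluded_accessions=frozenset({"GONE1"}),
        excluded_regions=(("P2", 100, 200),),
    )
    return table, criteria, keys


class TestFilterPsms:
    def test_reasons_match_plan_exactly(self, planted_table):
        table, criteria, keys = planted_table
        retained, log = filter_psms(table, criteria, search1_keys=keys)
        got = dict(zip(log["scan_id"], log["reason"]))
        assert got == {
            "short": "length",
            "orphan": "no_search1_match",
            "cont": "contaminant",
            "dropped": "excluded_protein",
            "region": "excluded_region",
            "lowscore": "score",
            "both": "length",
        }
        assert sorted(retained["scan_id"]) == ["ok1", "ok2"]

    def test_conservation_and_idempotence(self, planted_table):
        table, criteria, keys = planted_table
        retained, log = filter_psms(table, criteria, search1_keys=keys)
        assert len(retained) + len(log) == len(table)
        again, log2 = filter_psms(retained, criteria, search1_keys=keys)
        pd.testing.assert_frame_equal(again, retained)
        assert log2.empty

    def test_identity_filter_with_permissive_criteria(self, planted_table):
        table, _, _ = planted_table
        criteria = FilterCriteria(
            min_peptide_length=1, score_min=-1.0, require_search1_match=False
        )
        retained, log = filter_psms(table, criteria)
        assert log.empty and len(retained) == len(table)

    def test_malformed_rows_error_lists_lines(self):
        table = pd.DataFrame([psm_row(), psm_row(scan="bad", peptide="AAA")])
        criteria = FilterCriteria(score_min=0.0, require_search1_match=False)
        with pytest.raises(ValueError, match=r"lines \[1\]"):
            filter_psms(table, criteria)

    def test_criteria_require_exactly_one_threshold(self):
        with pytest.raises(ValueError):
            FilterCriteria()
        with pytest.raises(ValueError):
            FilterCriteria(fdr_max=0.01, score_min=10.0)

    def test_fdr_column_mode(self):
        table = pd.DataFrame([psm_row(scan="a"), psm_row(scan="b")])
        table["fdr"] = [0.005, 0.05]
        criteria = FilterCriteria(fdr_max=0.01, require_search1_match=False)
        retained, log = filter_psms(table, criteria)
        assert list(retained["scan_id"]) == ["a"]
        assert list(log["reason"]) == ["score"]


class TestAcceptProteins:
    def test_two_identical_peptides_rejected(self):
        table = pd.DataFrame([
            psm_row(scan="a", peptide="AAAAKAAAAKAA"),
            psm_row(scan="b", peptide="AAAAKAAAAKAA"),
        ])
        assert accept_proteins(table) == []

    def test_il_swapped_peptides_are_not_distinct(self):
        table = pd.DataFrame([
            psm_row(scan="a", peptide="AAAAKAAAAKAI"),
            psm_row(scan="b", peptide="AAAAKAAAAKAL"),
        ])
        assert accept_proteins(table) == []

    def test_two_distinct_peptides_accepted(self):
        table = pd.DataFrame([
            psm_row(scan="a", peptide="AAAAKAAAAKAA"),
            psm_row(scan="b", peptide="CCAAKAAAAKAA"),
        ])
        assert accept_proteins(table) == ["P1"]

    def test_empty_table(self):
        assert accept_proteins(pd.DataFrame(columns=["accession", "peptide"])) == []


def obs_frame(rows):
    return pd.DataFrame(
        rows, columns=["psm_id", "accession", "position", "db_aa", "observed_aa"]
    )


class TestAcceptSaps:
    @pytest.mark.parametrize(
        "n_mutated, n_total, accepted",
        [
            (1, 1, False),  # singleton: fails the two-PSM minimum
            (2, 3, True),   # 2/3 is a strict majority
            (2, 4, False),  # 2/4 is a tie: reject
            (2, 2, True),
            (3, 6, False),
            (4, 6, True),
        ],
    )
    def test_two_psm_majority_rule(self, n_mutated, n_total, accepted):
        rows = [(f"p{i}", "P1", 10, "A", "S") for i in range(n_mutated)]
        calls = accept_saps(obs_frame(rows), {("P1", 10): n_total})
        assert len(calls) == 1
        assert calls[0].accepted is accepted
        assert calls[0].n_mutated_psms == n_mutated

    def test_distinct_substitutions_at_one_position_judged_separately(self):
        rows = [
            ("p1", "P1", 10, "A", "S"),
            ("p2", "P1", 10, "A", "S"),
            ("p3", "P1", 10, "A", "G"),
        ]
        calls = {c.observed_aa: c for c in accept_saps(obs_frame(rows), {("P1", 10): 3})}
        assert calls["S"].accepted  # 2 of 3 covering
        assert not calls["G"].accepted  # singleton

    def test_sapcall_invariant_enforced(self):
        with pytest.raises(ValueError):
            SAPCall("P1", 1, "A", "S", n_mutated_psms=1,
                    n_total_psms_at_position=1, accepted=True)
        with pytest.raises(ValueError):
            SAPCall("P1", 1, "A", "S", n_mutated_psms=5,
                    n_total_psms_at_position=3, accepted=True)

    def test_accepted_psms_require_all_substitutions_accepted(self):
        rows = [
            ("p1", "P1", 10, "A", "S"),
            ("p1", "P1", 20, "G", "W"),
            ("p2", "P1", 10, "A", "S"),
        ]
        calls = accept_saps(obs_frame(rows), {("P1", 10): 2, ("P1", 20): 5})
        kept = accepted_psm_ids(obs_frame(rows), calls)
        # position 10 accepted (2/2); position 20 rejected (1/5): p1 falls
        assert kept == {"p2"}

    def test_position_coverage_counts_spans(self):
        table = pd.DataFrame([
            psm_row(scan="a", start=1, end=12),
            psm_row(scan="b", start=10, end=21),
            psm_row(scan="c", acc="P2", start=1, end=12),
        ])
        cov = position_coverage(table, [("P1", 10), ("P1", 15), ("P2", 30)])
        assert cov == {("P1", 10): 2, ("P1", 15): 1, ("P2", 30): 0}


class TestTighteningShrinksAcceptedSet:
    def test_accepted_saps_shrink_as_criteria_tighten(self, small_experiment):
        sr = next(iter(small_experiment.searches.values()))
        table = sr.psms
        loose = FilterCriteria(
            min_peptide_length=10, score_min=15.0, require_search1_match=False
        )
        tight = FilterCriteria(
            min_peptide_length=13, score_min=25.0, require_search1_match=False
        )

        def accepted_keys(criteria):
            retained, _ = filter_psms(table, criteria)
            obs = sr.sap_observations
            obs = obs.merge(
                retained[["dataset_id", "scan_id"]],
                on=["dataset_id", "scan_id"],
            )
            if obs.empty:
                return set()
            cov = position_coverage(
                retained, set(zip(obs["accession"], obs["position"]))
            )
            return {
                (c.accession, c.position, c.observed_aa)
                for c in accept_saps(obs, cov)
                if c.accepted
            }

        assert accepted_keys(tight) <= accepted_keys(loose)
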