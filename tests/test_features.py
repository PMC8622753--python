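"""Claims feature engine: LBP filter, windows, Charlson, linkage."""

import numpy as np
import pandas as pd
import pytest

from hurdlebss import features
from hurdlebss.features import (MalformedCodeError, build_design,
                                compute_charlson, compute_outcome,
                                derive_candidates, is_lbp_code, levenshtein,
                                link_records)
from hurdlebss.synthetic import corrupt_identifiers


@pytest.mark.parametrize("code,expected", [
    ("M54.5", True),       # low back pain, the canonical inclusion
    ("M51.2", True),
    ("M40.0", True),
    ("M54.02", False),     # cervical site digit
    ("M54.04", False),     # thoracic site digit
    ("M54.16", True),      # lumbar site digit retained
    ("M54.2", False),      # cervicalgia rubric
    ("M50.1", False),      # cervical disc category
    ("M99.0", False),      # outside M40-M54
    ("M39.9", False),
    ("M55.0", False),
    ("I21.0", False),
    ("m54.5", True),       # case-normalised
])
def test_lbp_filter(code, expected):
    assert is_lbp_code(code) is expected


@pytest.mark.parametrize("bad", ["", "M5", "54.5", "M545", "M54.567", "LBP"])
def test_lbp_filter_rejects_malformed(bad):
    with pytest.raises(MalformedCodeError):
        is_lbp_code(bad)


def test_filter_monotone_in_exclusions(synth_small):
    """Enlarging the exclusion list can only reduce the outcome count."""
    d = synth_small
    base = features.compute_outcomes(d.claims, d.cohort["subject_id"])
    bigger = features.DEFAULT_LBP_EXCLUSIONS + ("M54.5", "M51")
    reduced = features.compute_outcomes(d.claims, d.cohort["subject_id"],
                                        exclusions=bigger)
    assert (reduced["y"] <= base["y"]).all()
    assert reduced["y"].sum() < base["y"].sum()


class TestDeriveCandidates:
    COHORT_ROW = {"subject_id": "S1", "age_years": 53}

    def test_no_events(self, events_frame):
        row = derive_candidates(events_frame(), self.COHORT_ROW)
        assert row["history_lbp"] is False
        assert row["n_codes_2q"] == 0
        assert row["acute_codes"] == 0
        assert row["visited_specialties"] == "none"
        assert row["charlson_index"] == 0

    def test_history_and_acute_windows(self, events_frame):
        ev = events_frame((-5, "M54.5", "general_practitioner", "diagnosis"),
                          (0, "M54.5", "general_practitioner", "diagnosis"))
        row = derive_candidates(ev, self.COHORT_ROW)
        assert row["history_lbp"] is True
        assert row["acute_codes"] == 1          # baseline codes confined to Q0
        assert row["n_codes_2q"] == 0           # only one distinct baseline quarter

    def test_two_quarter_rule(self, events_frame):
        ev = events_frame((-2, "M54.5", "general_practitioner", "diagnosis"),
                          (-1, "M51.2", "orthopedist", "diagnosis"),
                          (-1, "M54.4", "orthopedist", "diagnosis"))
        row = derive_candidates(ev, self.COHORT_ROW)
        assert row["n_codes_2q"] == 3           # count form once >=2 quarters hit
        assert row["acute_codes"] == 0
        assert row["visited_specialties"] == "gp_and_specialist"

    def test_age_category(self):
        assert features.age_category(53) == "40-69"
        assert features.age_category(39) == "<40"
        assert features.age_category(70) == ">69"

    def test_excluded_codes_do_not_count(self, events_frame):
        ev = events_frame((-1, "M54.02", "general_practitioner", "diagnosis"))
        row = derive_candidates(ev, self.COHORT_ROW)
        assert row["n_codes_2q"] == 0 and row["acute_codes"] == 0
        assert row["any_baseline_lbp"] is np.False_ or row["any_baseline_lbp"] is False

    def test_out_of_range_quarter_errors(self, events_frame):
        ev = events_frame((5, "M54.5", "general_practitioner", "diagnosis"))
        with pytest.raises(ValueError, match="quarters outside"):
            derive_candidates(ev, self.COHORT_ROW)


@pytest.mark.parametrize("rows,expected_y", [
    ([], 0),
    ([(1, "M54.5"), (3, "M51.2"), (2, "M54.02")], 2),   # cervical site excluded
    ([(0, "M54.5")], 0),                                # baseline quarter not counted
    ([(1, "M54.5"), (1, "M54.5"), (4, "M48.0")], 3),
    ([(2, "J06.9")], 0),
])
def test_compute_outcome(events_frame, rows, expected_y):
    ev = events_frame(*[(q, c, "general_practitioner", "diagnosis") for q, c in rows])
    assert compute_outcome(ev) == expected_y


@pytest.mark.parametrize("codes,expected", [
    ([], 0),
    (["I21.0"], 1),                          # myocardial infarction
    (["I21.0", "I21.1", "C50.9"], 3),        # MI once (1) + malignancy (2)
    (["C50.9", "C78.0"], 6),                 # metastatic supersedes malignancy
    (["E11.9", "E11.2"], 2),                 # complicated diabetes supersedes
    (["B21", "N18.4", "J44.9"], 9),          # 6 + 2 + 1
    (["M54.5", "J06.9"], 0),                 # non-Charlson codes score nothing
])
def test_charlson(codes, expected):
    assert compute_charlson(codes) == expected


def test_no_followup_leakage(synth_small):
    """Permuting or dropping follow-up events never changes any predictor."""
    d = synth_small
    design = build_design(d.claims, d.cohort)
    rng = np.random.default_rng(0)
    claims2 = d.claims.copy()
    fu = claims2["quarter"] >= 1
    claims2.loc[fu, "quarter"] = rng.integers(1, 5, int(fu.sum()))
    design2 = build_design(claims2, d.cohort)
    pd.testing.assert_frame_equal(design, design2)
    design3 = build_design(d.claims[~fu], d.cohort)
    pd.testing.assert_frame_equal(design, design3)


def test_derive_candidates_pure(events_frame):
    ev = events_frame((-5, "M54.5", "general_practitioner", "diagnosis"),
                      (0, "M51.2", "orthopedist", "diagnosis"))
    snapshot = ev.copy()
    r1 = derive_candidates(ev, {"subject_id": "S1", "age_years": 30})
    r2 = derive_candidates(ev, {"subject_id": "S1", "age_years": 30})
    assert r1 == r2
    pd.testing.assert_frame_equal(ev, snapshot)


class TestLinkage:
    @staticmethod
    def ids(rows):
        return pd.DataFrame(rows, columns=["subject_id", "surname", "name",
                                           "birth_date", "sex"])

    def test_case_insensitive_exact_match(self):
        co = self.ids([("C1", "Schmidt", "Anna", "1970-01-01", "female")])
        cl = self.ids([("K1", "SCHMIDT", "ANNA", "1970-01-01", "female")])
        res = link_records(co, cl)
        assert res.pairs.status.tolist() == ["exact_match"]

    def test_birth_date_blocking(self):
        co = self.ids([("C1", "SCHMIDT", "ANNA", "1970-01-01", "female")])
        cl = self.ids([("K1", "SCHMIDT", "ANNA", "1970-01-02", "female")])
        assert len(link_records(co, cl).pairs) == 0

    def test_typo_goes_to_review(self):
        co = self.ids([("C1", "SCHMIDT", "ANNA", "1970-01-01", "female")])
        cl = self.ids([("K1", "SCHMIDD", "ANNA", "1970-01-01", "female")])
        res = link_records(co, cl)
        assert res.pairs.status.tolist() == ["possible_match_review"]
        assert res.pairs.distance.tolist() == [1]

    def test_missing_birth_date_skipped_with_warning(self):
        co = self.ids([("C1", "SCHMIDT", "ANNA", None, "female"),
                       ("C2", "KRAUSE", "HANS", "1960-05-05", "male")])
        cl = self.ids([("K2", "KRAUSE", "HANS", "1960-05-05", "male")])
        with pytest.warns(UserWarning, match="missing birth date"):
            res = link_records(co, cl)
        assert res.n_skipped_missing_birth_date == 1
        assert res.pairs.status.tolist() == ["exact_match"]

    def test_recall_on_corrupted_fixture(self, synth_small):
        """Unique birth dates + <=1 typo per record: recall of exact+review = 1."""
        cohort = synth_small.cohort.head(120).copy()
        cohort = cohort.drop_duplicates("birth_date")
        claims_side = corrupt_identifiers(cohort, typo_rate=0.2, seed=3)
        res = link_records(cohort, claims_side, max_review_distance=2)
        linked = res.pairs[res.pairs.status != "non_match"]
        found = set(zip(linked.cohort_id, linked.claims_id))
        assert {(s, s) for s in cohort.subject_id} <= found


def test_levenshtein_matches_bruteforce():
    def dp(a, b):
        m, n = len(a), len(b)
        D = np.arange(n + 1)[None, :].repeat(m + 1, 0).astype(int)
        D[:, 0] = np.arange(m + 1)
        for i in range(1, m + 1):
            for j in range(1, n + 1):
                D[i, j] = min(D[i - 1, j] + 1, D[i, j - 1] + 1,
                              D[i - 1, j - 1] + (a[i - 1] != b[j - 1]))
        return D[m, n]
    pairs = [("SCHMIDT", "SCHMIDD"), ("ANNA", "ANA"), ("KRAUSE", "KRAUSE"),
             ("ABC", "XYZ"), ("", "AB"), ("MEYER", "MAIER")]
    for a, b in pairs:
        assert levenshtein(a, b) == dp(a, b)
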