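"""Delphi consensus statistics, classification, and round bookkeeping."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pedpip.delphi import (
    ConservationError, RatingSet, RoundResult, classify_consensus,
    compute_stats, panel_share_percent, preliminary_count, read_ratings,
    stats_table, tally_rounds,
)


def _stats(ratings, **kw):
    return compute_stats(RatingSet("p", 1, tuple(ratings)), **kw)


class TestStats:
    def test_unanimous_full_scores(self):
        s = _stats([5] * 16)
        assert (s.mean, s.sd, s.cv, s.full_score_rate) == (5.0, 0.0, 0.0, 1.0)
        assert s.q1 == s.median == s.q3 == 5.0

    def test_spread_vector_hand_computed(self):
        # mean 3, sample sd sqrt(2.5) = 1.5811, cv = 0.527
        s = _stats([5, 4, 3, 2, 1])
        assert s.mean == 3.0
        assert s.sd == pytest.approx(1.5811, abs=1e-4)
        assert s.cv == pytest.approx(0.527, abs=1e-3)
        assert s.median == 3.0 and s.q1 == 2.0 and s.q3 == 4.0 and s.iqr == 2.0

    def test_full_score_rate_counts_only_fives(self):
        assert _stats([4, 4, 4, 4]).full_score_rate == 0.0
        assert _stats([5, 5, 4, 4]).full_score_rate == 0.5

    def test_population_sd_option(self):
        s = _stats([5, 4, 3, 2, 1], sd_ddof=0)
        assert s.sd == pytest.approx(np.sqrt(2.0))

    def test_quartiles_linear_interpolation(self):
        # spreadsheet-style inclusive quartiles on n=16
        s = _stats([5, 5, 5, 5, 5, 5, 5, 5, 4, 4, 4, 4, 4, 4, 3, 3])
        assert s.q1 == 4.0 and s.q3 == 5.0

    def test_invalid_ratings_rejected(self):
        with pytest.raises(ValueError):
            RatingSet("p", 1, ())
        with pytest.raises(ValueError):
            RatingSet("p", 1, (5, 6))
        with pytest.raises(ValueError):
            RatingSet("p", 1, (0, 3))


class TestClassification:
    def test_unanimous_accept_and_reject(self):
        assert classify_consensus(_stats([5] * 16)) == "accept"
        assert classify_consensus(_stats([1] * 16)) == "reject"

    def test_spread_vector_no_consensus(self):
        assert classify_consensus(_stats([5, 4, 3, 2, 1])) == "no_consensus"

    def test_cv_boundary_is_strict(self):
        # mean 4.55, sd such that cv crosses 0.20: craft via mixed ratings
        high_spread = _stats([5] * 10 + [2] * 4)  # cv > 0.20
        assert high_spread.cv >= 0.20
        assert classify_consensus(high_spread) == "no_consensus"

    @pytest.mark.parametrize("constant,expected", [
        (5, "accept"), (4, "no_consensus"), (3, "no_consensus"),
        (2, "no_consensus"), (1, "reject"),
    ])
    def test_constant_vectors_on_integer_grid(self, constant, expected):
        # mean > 4 and mean < 2 are strict: constant 4 and 2 do not qualify
        assert classify_consensus(_stats([constant] * 8)) == expected

    @given(st.lists(st.integers(1, 5), min_size=1, max_size=30))
    @settings(max_examples=300, deadline=None)
    def test_accept_reject_mutually_exclusive(self, ratings):
        s = _stats(ratings)
        accept = s.q1 >= 4 and s.mean > 4 and s.cv < 0.20
        reject = s.q3 <= 2 and s.mean < 2 and s.cv < 0.20
        assert not (accept and reject)
        assert classify_consensus(s) in {"accept", "reject", "no_consensus"}

    @given(st.lists(st.integers(1, 5), min_size=2, max_size=20),
           st.randoms(use_true_random=False))
    @settings(max_examples=200, deadline=None)
    def test_classification_permutation_invariant(self, ratings, rnd):
        shuffled = list(ratings)
        rnd.shuffle(shuffled)
        assert classify_consensus(_stats(ratings)) == \
            classify_consensus(_stats(shuffled))


class TestRoundLedger:
    def test_two_round_survey_arithmetic(self):
        ledger = tally_rounds([
            RoundResult(entered=149, accepted=94, rejected=0, carried=55,
                        new_next_round=1),
            RoundResult(entered=56, adjudicated_retained=42),
        ])
        assert ledger.final_retained == 136

    def test_single_round_all_accepted(self):
        ledger = tally_rounds([RoundResult(entered=10, accepted=10)])
        assert ledger.final_retained == 10

    def test_conservation_violation_rejected(self):
        with pytest.raises(ConservationError):
            tally_rounds([RoundResult(entered=10, accepted=5, rejected=1,
                                      carried=3)])

    def test_next_round_entry_mismatch_rejected(self):
        with pytest.raises(ConservationError):
            tally_rounds([
                RoundResult(entered=10, accepted=5, carried=5, new_next_round=0),
                RoundResult(entered=7, adjudicated_retained=3),
            ])

    @given(st.integers(0, 50), st.integers(0, 50), st.integers(0, 50),
           st.integers(0, 5), st.integers(0, 50))
    @settings(max_examples=200, deadline=None)
    def test_ledger_conservation_property(self, accepted, rejected, carried,
                                          new, retained2):
        entered = accepted + rejected + carried
        retained2 = min(retained2, carried + new)
        ledger = tally_rounds([
            RoundResult(entered=entered, accepted=accepted, rejected=rejected,
                        carried=carried, new_next_round=new),
            RoundResult(entered=carried + new, adjudicated_retained=retained2),
        ])
        assert ledger.final_retained == accepted + retained2


class TestPrintedArithmetic:
    def test_preliminary_criteria_count(self):
        assert preliminary_count(515, 366) == 149

    def test_panel_experience_share(self):
        assert panel_share_percent(11, 16) == 69


class TestRatingsIO:
    def test_read_and_tabulate(self, tmp_path):
        path = tmp_path / "ratings.csv"
        rows = ["proposition_id,round,panelist_id,rating"]
        rows += [f"prop1,1,e{i},5" for i in range(16)]
        rows += [f"prop2,1,e{i},{r}" for i, r in enumerate([5, 4, 3, 2, 1])]
        path.write_text("\n".join(rows) + "\n")
        table = stats_table(read_ratings(path))
        by_id = table.set_index("proposition_id")
        assert by_id.loc["prop1", "status"] == "accept"
        assert by_id.loc["prop2", "status"] == "no_consensus"

    def test_out_of_scale_rating_names_row(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("proposition_id,round,panelist_id,rating\np,1,e1,6\n")
        with pytest.raises(ValueError, match="row"):
            read_ratings(path)
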