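import datetime as dt

import pytest

import gardenset as gs
from gardenset.errors import ConfigurationError
from gardenset.participation import (
    PARTICIPATION_TYPES,
    challenge_contingency,
    code_comments,
    detect_long_break,
    load_lexicon,
    participation_profile,
)

from conftest import make_series


def series_on_days(days, plant_id="P1", comments=None):
    n = len(days)
    base = dt.date(2021, 6, 1)
    return make_series(
        O=[1] * n, F=[0] * n, R=[0] * n, H=[0] * n,
        dates=[base + dt.timedelta(days=d) for d in days],
        plant_id=plant_id, comments=comments,
    )


class TestTypology:
    def test_single_observation_is_once(self):
        p = participation_profile(series_on_days([0]))
        assert (p.type, p.duration_days, p.frequency) == ("once", 0, 0.0)

    def test_duration_boundary_56_is_long(self):
        # two visits 56 days apart: D=56 -> long; freq 28 -> low
        p = participation_profile(series_on_days([0, 56]))
        assert p.duration_days == 56
        assert p.frequency == 28.0
        assert p.type == "long-low"

    def test_eleven_visits_over_40_days_is_short_high(self):
        p = participation_profile(series_on_days(list(range(0, 44, 4))))
        assert p.n_measurements == 11
        assert p.duration_days == 40
        assert p.frequency == pytest.approx(40 / 11)
        assert p.type == "short-high"

    def test_frequency_boundary_exactly_four_is_high(self):
        # D=40, n=10 -> 4.0 days per measurement counts as high
        p = participation_profile(series_on_days([0, 5, 10, 15, 20, 25, 30, 33, 36, 40]))
        assert p.frequency == 4.0
        assert p.type.endswith("high")

    def test_interval_divisor_variant(self):
        p = participation_profile(series_on_days([0, 4, 8]), interval_divisor=True)
        assert p.frequency == 4.0  # 8 / (3 - 1)

    def test_partition_over_simulated_study(self):
        study = gs.simulate_study(gs.SimulationConfig(n_gardens=10, plants_per_garden=6, seed=9))
        profiles = [participation_profile(s) for s in study.sheets]
        n_once = sum(p.type == "once" for p in profiles)
        typed = [p for p in profiles if p.type != "once"]
        assert all(p.type in PARTICIPATION_TYPES for p in typed)
        assert len(typed) == len(profiles) - n_once
        assert all((p.n_measurements == 1) == (p.type == "once") for p in profiles)


class TestBreaks:
    def test_gaps_up_to_ten_days_are_not_breaks(self):
        assert not detect_long_break(series_on_days([0, 10, 20]))

    def test_eleven_day_gap_is_a_break(self):
        assert detect_long_break(series_on_days([0, 11, 15]))

    def test_boundary_is_strict(self):
        assert not detect_long_break(series_on_days([0, 3, 13]))


class TestCommentCoding:
    def test_plant_death_quote(self):
        s = series_on_days([0, 4], comments={1: "Plant is dead."})
        codes = code_comments(s)
        assert codes.flags["plant_death"]
        assert not codes.other

    def test_harvest_loss_quote(self):
        s = series_on_days([0, 4], comments={0: "1 rotten fruit removed"})
        assert code_comments(s).flags["harvest_loss"]

    def test_protocol_quote(self):
        s = series_on_days([0, 4], comments={1: "The last measurement must be 22 buds (not 9)."})
        assert code_comments(s).flags["protocol"]

    def test_no_comments_all_false(self):
        codes = code_comments(series_on_days([0, 4]))
        assert not any(codes.flags.values())
        assert not codes.has_comment and not codes.other

    def test_unmatched_comment_is_other(self):
        codes = code_comments(series_on_days([0, 4], comments={0: "cold and rainy weather"}))
        assert not any(codes.flags.values())
        assert codes.other

    def test_multiple_categories_allowed(self):
        s = series_on_days([0, 4], comments={0: "Plant is dead.", 1: "1 rotten fruit removed"})
        flags = code_comments(s).flags
        assert flags["plant_death"] and flags["harvest_loss"]

    def test_empty_lexicon_rejected(self):
        with pytest.raises(ConfigurationError, match="lexicon"):
            code_comments(series_on_days([0, 4]), lexicon={})

    def test_lexicon_file_round_trip(self, tmp_path):
        path = tmp_path / "lexicon.txt"
        path.write_text("plant_death: dead, tot\nharvest_loss: rotten\n")
        lex = load_lexicon(path)
        assert lex == {"plant_death": ["dead", "tot"], "harvest_loss": ["rotten"]}


class TestContingency:
    def _fixture(self):
        """12 contributions: 3 per type; within each type the first carries a
        plant-health comment and the others do not."""
        days_by_type = {
            "short-low": [0, 6, 12, 18, 24, 30],          # D=30, freq 5
            "short-high": [0, 3, 6, 9, 12, 15, 18, 21],   # D=21, freq 2.6
            "long-low": list(range(0, 66, 6)),            # D=60, freq 5.45
            "long-high": list(range(0, 60, 3)),           # D=57, freq 2.85
        }
        profiles, codes = [], []
        for t, days in days_by_type.items():
            for i in range(3):
                pid = f"{t}-{i}"
                comment = {0: "mildew on the leaves"} if i == 0 else None
                s = series_on_days(days, plant_id=pid, comments=comment)
                p = participation_profile(s)
                assert p.type == t, (t, p.type, p.duration_days, p.frequency)
                profiles.append(p)
                codes.append(code_comments(s))
        return profiles, codes

    def test_counts_match_hand_tally(self):
        profiles, codes = self._fixture()
        table = challenge_contingency(profiles, codes, "plant_health")
        assert (table["with_comment"] == 1).all()
        assert (table["without_comment"] == 2).all()
        assert table.to_numpy().sum() == 12

    def test_all_flagged_gives_zero_complement(self):
        profiles, codes = self._fixture()
        for c in codes:
            c.flags["plant_health"] = True
        table = challenge_contingency(profiles, codes, "plant_health")
        assert (table["without_comment"] == 0).all()

    def test_empty_input_zero_table(self):
        table = challenge_contingency([], [], "plant_health")
        assert table.to_numpy().sum() == 0
        assert list(table.index) == list(PARTICIPATION_TYPES)

    def test_once_contributions_excluded(self):
        s = series_on_days([0], plant_id="solo", comments={0: "Plant is dead."})
        table = challenge_contingency(
            [participation_profile(s)], [code_comments(s)], "plant_death"
        )
        assert table.to_numpy().sum() == 0
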