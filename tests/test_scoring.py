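"""Response normalization, four-category scoring, and table construction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ned_mcgurk import (
    build_fusion_table,
    congruent_accuracy,
    filter_participants,
    make_congruent_spec,
    make_stimulus_spec,
    normalize_response,
    score_response,
)


@pytest.mark.parametrize(
    "raw,expected",
    [
        ("DADA", "dada"),
        ("た", "ta"),  # hiragana mora
        ("タ", "ta"),  # katakana mora
        ("ばば", "baba"),
        ("ダダ", "dada"),
        ("ba-da", "bada"),
        (" Ba Da ", "bada"),
        ("da.", "da"),
        ("ガ", "ga"),
        ("ヴァ", "va"),
        ("は", "ha"),
        ("ばー", "ba"),  # long-vowel mark stripped
        ("!?.", ""),  # nothing survives -> flagged-invalid upstream
        ("xyz", "xyz"),  # unmapped Latin preserved
        ("だ私", "da私"),  # unmapped kanji preserved verbatim
    ],
)
def test_normalize_response(raw, expected):
    assert normalize_response(raw) == expected


@given(st.text(max_size=20))
@settings(max_examples=200, derandomize=True)
def test_normalize_is_idempotent(raw):
    once = normalize_response(raw)
    assert normalize_response(once) == once


class TestScoreResponse:
    @pytest.mark.parametrize(
        "resp,expected",
        [
            ("dada", {"fusion": 1.0}),
            ("tata", {"fusion": 1.0}),
            ("bada", {"auditory": 0.5, "fusion": 0.5}),
            ("baba", {"auditory": 1.0}),
            ("gaga", {"visual": 1.0}),
            ("baga", {"auditory": 0.5, "visual": 0.5}),
            ("thada", {"fusion": 1.0}),
            ("da", {"fusion": 1.0}),  # single mora vs doubled stimulus
            ("ba", {"auditory": 1.0}),
            ("haha", {"other": 1.0}),  # unsplittable -> whole unit -> other
            ("badaba", {"other": 1.0}),  # three morae route to other
        ],
    )
    def test_double_syllable(self, spec_double, resp, expected):
        score = score_response(resp, spec_double)
        for cat in ("auditory", "visual", "fusion", "other"):
            assert getattr(score, cat) == expected.get(cat, 0.0)

    @pytest.mark.parametrize(
        "resp,expected",
        [
            ("da", {"fusion": 1.0}),
            ("ta", {"fusion": 1.0}),
            ("tha", {"fusion": 1.0}),
            ("ba", {"auditory": 1.0}),
            ("ga", {"visual": 1.0}),
            ("ha", {"other": 1.0}),
            ("va", {"other": 1.0}),
            ("bada", {"other": 1.0}),  # two morae vs single stimulus
        ],
    )
    def test_single_syllable(self, spec_single, resp, expected):
        score = score_response(resp, spec_single)
        for cat in ("auditory", "visual", "fusion", "other"):
            assert getattr(score, cat) == expected.get(cat, 0.0)

    @given(st.text(alphabet="bdgkpthva", max_size=8))
    @settings(max_examples=300, derandomize=True)
    def test_fractions_sum_to_one_and_quantized(self, raw):
        for spec in (
            make_stimulus_spec("x1", "ba", "ga", "voiced"),
            make_stimulus_spec("x2", "papa", "kaka", "unvoiced"),
        ):
            s = score_response(normalize_response(raw), spec)
            total = s.auditory + s.visual + s.fusion + s.other
            assert total == pytest.approx(1.0)
            allowed = {0.0, 1.0} if spec.n_syllables == 1 else {0.0, 0.5, 1.0}
            assert {s.auditory, s.visual, s.fusion, s.other} <= allowed

    def test_scoring_idempotent_under_renormalization(self, spec_single):
        raw = "Da!"
        once = normalize_response(raw)
        assert score_response(once, spec_single) == score_response(
            normalize_response(once), spec_single
        )


def _congruent_trials(pid, n, n_correct, syllable="ba"):
    spec = make_congruent_spec("c01", syllable)
    rows = [
        {
            "participant_id": pid,
            "stimulus_id": "c01",
            "repetition": r + 1,
            "stimulus_kind": "congruent",
            "raw_response": syllable if r < n_correct else "ga",
        }
        for r in range(n)
    ]
    return pd.DataFrame(rows), {"c01": spec}


class TestCongruentAccuracy:
    def test_fraction(self):
        trials, specs = _congruent_trials("p1", 90, 88)
        assert congruent_accuracy(trials, specs)["p1"] == pytest.approx(88 / 90)

    def test_all_correct(self):
        trials, specs = _congruent_trials("p1", 30, 30)
        assert congruent_accuracy(trials, specs)["p1"] == 1.0

    def test_kana_responses_count_as_correct(self):
        trials, specs = _congruent_trials("p1", 4, 4)
        trials["raw_response"] = "ば"  # kana for the target syllable
        assert congruent_accuracy(trials, specs)["p1"] == 1.0

    def test_no_congruent_trials_is_nan(self):
        trials, specs = _congruent_trials("p1", 10, 10)
        trials["stimulus_kind"] = "mcgurk"
        trials2, _ = _congruent_trials("p2", 10, 10)
        acc = congruent_accuracy(pd.concat([trials, trials2]), specs)
        assert "p1" not in acc and acc["p2"] == 1.0

    def test_invalid_trials_excluded_from_denominator(self):
        trials, specs = _congruent_trials("p1", 10, 10)
        trials.loc[0, "raw_response"] = "?!"
        assert congruent_accuracy(trials, specs)["p1"] == 1.0


class TestFilterParticipants:
    def test_threshold_boundary(self):
        included, excluded = filter_participants({"a": 0.90, "b": 0.899, "c": 1.0})
        assert included == {"a", "c"}
        assert excluded == [("b", 0.899)]

    def test_nan_always_excluded(self):
        included, excluded = filter_participants({"a": float("nan"), "b": 0.95})
        assert included == {"b"} and excluded[0][0] == "a"

    def test_empty_survivors_aborts(self):
        with pytest.raises(ValueError, match="no participants"):
            filter_participants({"a": 0.5})


class TestBuildFusionTable:
    def _trials(self, scores, pid="p1", sid="s3"):
        return pd.DataFrame(
            [
                {
                    "participant_id": pid,
                    "stimulus_id": sid,
                    "repetition": r + 1,
                    "stimulus_kind": "mcgurk",
                    "raw_response": resp,
                }
                for r, resp in enumerate(scores)
            ]
        )

    def test_mean_fusion(self, spec_single):
        trials = self._trials(["da"] * 6 + ["ba"] * 4)
        extra = self._trials(["ba"] * 10, pid="p2")
        table = build_fusion_table(
            pd.concat([trials, extra]), {"s3": spec_single}, {"p1", "p2"}
        )
        j = table.participants.index("p1")
        assert table.fusion_prop[j, 0] == pytest.approx(0.6)
        assert table.n_reps[j, 0] == 10

    def test_half_point_average(self, spec_double):
        trials = self._trials(["bada", "bada"] + ["baba"] * 8, sid="s1")
        extra = self._trials(["baba"] * 10, pid="p2", sid="s1")
        table = build_fusion_table(
            pd.concat([trials, extra]), {"s1": spec_double}, {"p1", "p2"}
        )
        j = table.participants.index("p1")
        assert table.fusion_prop[j, 0] == pytest.approx(0.1)

    def test_duplicate_triple_raises(self, spec_single):
        trials = self._trials(["da", "ba"])
        trials.loc[1, "repetition"] = 1
        with pytest.raises(ValueError, match=r"\(p1, s3, 1\)"):
            build_fusion_table(trials, {"s3": spec_single}, {"p1"})

    def test_order_invariance(self, small_cohort):
        trials, _, specs = small_cohort
        included = set(trials["participant_id"])
        t1 = build_fusion_table(trials, specs, included)
        shuffled = trials.sample(frac=1.0, random_state=99)
        t2 = build_fusion_table(shuffled, specs, included)
        assert t1.participants == t2.participants
        assert t1.stimuli == t2.stimuli
        np.testing.assert_array_equal(t1.fusion_prop, t2.fusion_prop)

    def test_missing_cells_are_nan_not_zero(self, spec_single):
        spec2 = make_stimulus_spec("s4", "ba", "ga", "voiced")
        trials = pd.concat(
            [
                self._trials(["da"] * 3, pid="p1", sid="s3"),
                self._trials(["ba"] * 3, pid="p2", sid="s3"),
                self._trials(["ba"] * 3, pid="p2", sid="s4"),
            ]
        )
        table = build_fusion_table(
            trials, {"s3": spec_single, "s4": spec2}, {"p1", "p2"}
        )
        j1, i4 = table.participants.index("p1"), table.stimuli.index("s4")
        assert np.isnan(table.fusion_prop[j1, i4])
        assert table.n_reps[j1, i4] == 0

    def test_zero_lapse_cohort_has_perfect_congruent_accuracy(self, small_cohort):
        trials, _, specs = small_cohort
        acc = congruent_accuracy(trials, specs)
        assert all(a == 1.0 for a in acc.values())
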