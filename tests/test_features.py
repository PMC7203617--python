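"""Feature families: confusion matrices, correctness, gaze, metadata."""

import numpy as np
import pandas as pd
import pytest

from gazephen import EMOTIONS
from gazephen.features import (
    assemble,
    confusion_detail_features,
    confusion_matrix_features,
    expected_trial_width,
    gaze_features,
    gaze_features_for_stimulus,
    metadata_features,
    select_columns,
)
from tests.conftest import make_participant


def resp_frame(pairs):
    return pd.DataFrame(
        [{"true_emotion": t, "response": r} for t, r in pairs]
    )


class TestConfusionMatrix:
    def test_all_correct_is_identity(self):
        resp = resp_frame([(e, e) for e in EMOTIONS])
        cm = confusion_matrix_features(resp)
        mat = cm.to_numpy().reshape(7, 7)
        np.testing.assert_allclose(mat, np.eye(7))
        assert len(cm) == 49

    def test_absent_emotion_row_zero_and_flagged(self):
        resp = resp_frame([("happy", "happy")])
        cm = confusion_matrix_features(resp)
        assert cm[[f"cm_sad_{c}" for c in EMOTIONS]].sum() == 0
        assert "sad" in cm.attrs["zero_rows"]

    def test_hand_counted_row(self):
        resp = resp_frame([("happy", "happy"), ("happy", "happy"),
                           ("happy", "calm")])
        cm = confusion_matrix_features(resp)
        assert cm["cm_happy_happy"] == pytest.approx(2 / 3)
        assert cm["cm_happy_calm"] == pytest.approx(1 / 3)

    def test_unknown_response_rejected(self):
        with pytest.raises(ValueError, match="bored"):
            confusion_matrix_features(resp_frame([("happy", "bored")]))

    def test_rows_sum_to_one_or_zero(self):
        rng = np.random.default_rng(0)
        pairs = [(EMOTIONS[rng.integers(7)], EMOTIONS[rng.integers(7)])
                 for _ in range(42)]
        cm = confusion_matrix_features(resp_frame(pairs)).to_numpy().reshape(7, 7)
        sums = cm.sum(axis=1)
        assert all(s == pytest.approx(1, abs=1e-9) or s == 0 for s in sums)


class TestConfusionDetail:
    def test_length_and_order(self):
        pairs = [("happy", "happy"), ("sad", "angry"), ("calm", "calm")]
        conf = confusion_detail_features(resp_frame(pairs))
        np.testing.assert_array_equal(conf.to_numpy(), [1, 0, 1])

    def test_missing_response_rejected(self):
        df = resp_frame([("happy", "happy")])
        df.loc[0, "response"] = None
        with pytest.raises(ValueError, match="missing"):
            confusion_detail_features(df)


class TestGazeFeatures:
    def test_hand_traced_sequence(self):
        """L,L,F,F,R,F: face_frac 0.5, toward-face 2/3, latency 2."""
        ff, tf, lat = gaze_features_for_stimulus(
            np.array(list("LLFFRF")), window_frames=6
        )
        assert ff == pytest.approx(0.5)
        assert tf == pytest.approx(2 / 3)
        assert lat == 2

    def test_all_face_frames(self):
        ff, tf, lat = gaze_features_for_stimulus(np.array(list("FFFF")), 4)
        assert ff == 1.0 and lat == 0
        assert np.isnan(tf)  # no transitions -> undefined, imputed later

    def test_face_never_fixated_latency_is_window(self):
        ff, tf, lat = gaze_features_for_stimulus(np.array(list("NN")), 180)
        assert lat == 180

    def test_transitions_include_n(self):
        # N->F counts toward the face; F->N counts as a transition away
        ff, tf, lat = gaze_features_for_stimulus(np.array(list("NFNF")), 4)
        assert tf == pytest.approx(2 / 3)

    def test_names_and_width(self):
        s = gaze_features([np.array(list("F"))] * 3, 1)
        assert len(s) == 9
        assert s.index[0] == "gaze_s01_facefrac"


class TestMetadata:
    def test_codings(self):
        assert metadata_features(make_participant(age=12, gender="male")).tolist() == [12.0, 0.0]
        assert metadata_features(make_participant(age=8, gender="female")).tolist() == [8.0, 1.0]


def fake_blocks(participants, trials, n_stimuli, seed=0):
    rng = np.random.default_rng(seed)
    blocks, groups = {}, {}
    for pid, group in participants:
        groups[pid] = group
        by_trial = {}
        for t in trials:
            by_trial[t] = {
                "cm": pd.Series(rng.random(49),
                                index=[f"cm_{r}_{c}" for r in EMOTIONS for c in EMOTIONS]),
                "conf": pd.Series(rng.integers(0, 2, n_stimuli).astype(float),
                                  index=[f"conf_s{i+1:02d}" for i in range(n_stimuli)]),
                "gaze": pd.Series(rng.random(3 * n_stimuli),
                                  index=[f"gaze_s{i+1:02d}_{k}" for i in range(n_stimuli)
                                         for k in ("facefrac", "toward", "latency")]),
                "pat": pd.Series({"pat_age": 10.0, "pat_gender": 0.0}),
            }
        blocks[pid] = by_trial
    return blocks, groups


class TestAssemble:
    participants = [("a1", "ASD"), ("a2", "ASD"), ("n1", "NC"), ("n2", "NC")]

    def test_printed_dimensions_for_42_stimuli(self):
        blocks, groups = fake_blocks(self.participants, [1], 42)
        table = assemble(blocks, groups)
        assert table.shape[1] - 1 == 219 == expected_trial_width(42)

    def test_dimensions_for_41_stimuli(self):
        blocks, groups = fake_blocks(self.participants, [1], 41)
        table = assemble(blocks, groups)
        assert table.shape[1] - 1 == 215

    def test_pat_only_selection(self):
        blocks, groups = fake_blocks(self.participants, [1, 2], 10)
        table = assemble(blocks, groups)
        sub = select_columns(table, ["pat"], "all")
        assert list(sub.columns) == ["group", "pat_age", "pat_gender"]

    def test_pat_included_once_across_trials(self):
        blocks, groups = fake_blocks(self.participants, [1, 2, 3], 8)
        table = assemble(blocks, groups)
        per_trial = expected_trial_width(8)
        assert table.shape[1] - 1 == 3 * per_trial - 2 * 2

    def test_idempotent_and_order_stable(self):
        blocks, groups = fake_blocks(self.participants, [1, 2], 12)
        t1 = assemble(blocks, groups)
        t2 = assemble(blocks, groups)
        pd.testing.assert_frame_equal(t1, t2)

    def test_missing_trial_is_nan_not_dropped(self):
        blocks, groups = fake_blocks(self.participants, [1, 2], 6)
        del blocks["a2"][2]
        table = assemble(blocks, groups)
        assert "a2" in table.index
        t2_cols = [c for c in table.columns if c.startswith("t2_")]
        assert table.loc["a2", t2_cols].isna().all()
        assert not table.loc["a1", t2_cols].isna().any()

    def test_participant_missing_all_trials_dropped(self):
        blocks, groups = fake_blocks(self.participants, [1], 6)
        blocks["n2"] = {}
        with pytest.warns(UserWarning, match="n2"):
            table = assemble(blocks, groups)
        assert "n2" not in table.index
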