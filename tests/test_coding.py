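"""F/L/R/N coding, outlier exclusion, and distraction-ratio statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from gazephen.calibration import EpochAssignment
from gazephen.coding import (
    aggregate_participant,
    code_frame,
    code_session,
    distraction_ratio,
    exclude_outliers,
    group_ttest,
    per_emotion_flr,
)
from gazephen.synth import make_schedule, simulate_gaze
from tests.conftest import make_participant


class TestCodeFrame:
    def test_region_centers(self, geometry):
        assert code_frame(0.5, 0.5, geometry)[0] == "F"
        assert code_frame(geometry.left.cx, 0.5, geometry)[0] == "L"
        assert code_frame(geometry.right.cx, 0.5, geometry)[0] == "R"

    def test_below_face_is_nowhere(self, geometry):
        # default face region spans y in [0.065, 0.935]
        assert code_frame(0.5, 0.999, geometry)[0] == "N"

    def test_missing_and_offscreen_are_nowhere(self, geometry):
        assert code_frame(np.nan, np.nan, geometry)[0] == "N"
        assert code_frame(1.7, 0.5, geometry)[0] == "N"

    def test_boundary_inclusive(self, geometry):
        assert code_frame(geometry.face.x0, 0.5, geometry)[0] == "F"
        assert code_frame(geometry.face.x1, geometry.face.y1, geometry)[0] == "F"


def counts_row(nF, nL, nR, nN, **extra):
    row = {
        "participant": "p", "trial": 1, "stimulus_id": "s",
        "true_emotion": "happy", "nF": nF, "nL": nL, "nR": nR, "nN": nN,
        "window_frames": nF + nL + nR + nN,
    }
    row.update(extra)
    return row


class TestDistractionRatio:
    def test_hand_computed_values(self):
        df = distraction_ratio(pd.DataFrame([
            counts_row(10, 0, 0, 0),
            counts_row(3, 1, 1, 5),
            counts_row(0, 0, 0, 7),
        ]))
        assert df.loc[0, "d"] == 0 and df.loc[0, "d_flr"] == 0
        assert df.loc[1, "d"] == pytest.approx(0.2)
        assert df.loc[1, "d_flr"] == pytest.approx(0.4)
        assert df.loc[2, "d"] == 0
        assert not df.loc[2, "d_flr_defined"]

    def test_all_zero_counts_flagged_invalid(self):
        df = distraction_ratio(pd.DataFrame([counts_row(0, 0, 0, 0)]))
        assert not df.loc[0, "valid"]

    @settings(max_examples=200, deadline=None)
    @given(st.tuples(*[st.integers(0, 500)] * 4))
    def test_d_le_dflr_and_bounded(self, counts):
        nF, nL, nR, nN = counts
        df = distraction_ratio(pd.DataFrame([counts_row(nF, nL, nR, nN)]))
        row = df.iloc[0]
        if row["valid"]:
            assert 0 <= row["d"] <= 1
        if row["d_flr_defined"]:
            assert 0 <= row["d_flr"] <= 1
            assert row["d"] <= row["d_flr"] + 1e-12
        if row["valid"]:
            assert (row["d"] == 0) == (nL + nR == 0)


class TestAggregation:
    def test_mean_and_invalid_ignored(self):
        df = distraction_ratio(pd.DataFrame([
            counts_row(8, 2, 0, 0),   # d = 0.2
            counts_row(10, 0, 0, 0),  # d = 0
            counts_row(6, 0, 4, 0),   # d = 0.4
            counts_row(0, 0, 0, 0),   # invalid
        ]))
        d_p = aggregate_participant(df)
        assert d_p["p"] == pytest.approx(0.2)

    def test_participant_without_valid_records_warns(self):
        df = distraction_ratio(pd.DataFrame([
            counts_row(5, 5, 0, 0),
            counts_row(0, 0, 0, 0, participant="q"),
        ]))
        with pytest.warns(UserWarning, match="q"):
            d_p = aggregate_participant(df)
        assert "q" not in d_p.index

    def test_stimulus_order_invariance(self):
        rows = [counts_row(8, 2, 0, 0), counts_row(5, 0, 5, 0),
                counts_row(9, 0, 0, 1)]
        a = aggregate_participant(distraction_ratio(pd.DataFrame(rows)))
        b = aggregate_participant(distraction_ratio(pd.DataFrame(rows[::-1])))
        assert a["p"] == pytest.approx(b["p"])

    def test_per_emotion_mean_over_defined_only(self):
        df = distraction_ratio(pd.DataFrame([
            counts_row(9, 1, 0, 0),                  # d_flr = 0.1
            counts_row(9, 1, 0, 0),                  # d_flr = 0.1
            counts_row(0, 0, 0, 7),                  # undefined
            counts_row(4, 0, 4, 2, true_emotion="sad"),  # d_flr = 0.5
        ]))
        table = per_emotion_flr(df)
        happy = table[table["true_emotion"] == "happy"]["d_flr"].iloc[0]
        sad = table[table["true_emotion"] == "sad"]["d_flr"].iloc[0]
        assert happy == pytest.approx(0.1)
        assert sad == pytest.approx(0.5)
        assert "angry" not in set(table["true_emotion"])


class TestCodeSession:
    def test_hand_tally_fixture(self, geometry):
        """A 180-frame stimulus with 18 L frames gives nL=18 and d=0.1."""
        sched = make_schedule(trial_sizes=(1,), frame_rate=30, seed=0)
        x = np.full(sched.n_frames, geometry.face.cx)
        y = np.full(sched.n_frames, geometry.face.cy)
        x[:18] = geometry.left.cx
        gaze = pd.DataFrame({
            "frame": np.arange(sched.n_frames), "x": x, "y": y,
            "missing": False,
        })
        counts = code_session(gaze, sched, geometry)
        assert counts.loc[0, "nL"] == 18 and counts.loc[0, "nF"] == 162
        d = distraction_ratio(counts).loc[0, "d"]
        assert d == pytest.approx(0.1)

    def test_none_epoch_drops_everything(self, geometry, small_schedule, participant):
        gaze, _ = simulate_gaze(participant, small_schedule, geometry, seed=0)
        none_epochs = EpochAssignment(
            intervals=((0, small_schedule.n_frames, None),)
        )
        counts = code_session(gaze, small_schedule, geometry, epochs=none_epochs)
        assert (counts[["nF", "nL", "nR", "nN"]].to_numpy() == 0).all()

    def test_noiseless_session_matches_latent_tally(
        self, geometry, small_schedule, participant
    ):
        gaze, truth = simulate_gaze(
            participant, small_schedule, geometry, seed=4, noise_sd=0.0
        )
        counts = code_session(gaze, small_schedule, geometry)
        codes = truth["code"].to_numpy()
        for _, stim in small_schedule.iter_stimuli():
            window = codes[stim.onset_frame : stim.onset_frame + stim.duration_frames]
            row = counts[counts["stimulus_id"] == stim.stimulus_id].iloc[0]
            for c in "FLRN":
                assert row[f"n{c}"] == (window == c).sum()

    def test_frame_range_mismatch_rejected(self, geometry, small_schedule):
        gaze = pd.DataFrame({
            "frame": np.arange(10), "x": 0.5, "y": 0.5, "missing": False,
        })
        with pytest.raises(ValueError, match="frame range"):
            code_session(gaze, small_schedule, geometry)


class TestExcludeOutliers:
    base = pd.DataFrame([
        counts_row(30, 0, 0, 0, trial=1),
        counts_row(30, 0, 0, 0, trial=2),
    ])

    def test_all_above_threshold_untouched(self):
        out, report = exclude_outliers(self.base, min_fraction=0.5)
        assert out.equals(self.base) and report == []

    def test_low_fraction_trial_dropped(self):
        df = pd.DataFrame([
            counts_row(30, 0, 0, 0, trial=1),
            counts_row(6, 0, 0, 0, trial=2, window_frames=30),  # 0.2 trackable
        ])
        out, report = exclude_outliers(df, min_fraction=0.5)
        assert set(out["trial"]) == {1}
        assert report[0]["trial"] == 2

    def test_zero_threshold_never_drops(self):
        df = pd.DataFrame([counts_row(0, 0, 0, 0, trial=1)])
        out, report = exclude_outliers(df, min_fraction=0.0)
        assert len(out) == 1 and report == []


class TestGroupTTest:
    def test_identical_groups_p_half(self):
        res = group_ttest([0.1, 0.2, 0.3], [0.1, 0.2, 0.3])
        assert res["t"] == pytest.approx(0.0, abs=1e-12)
        assert res["p"] == pytest.approx(0.5)

    def test_separated_groups_significant(self):
        rng = np.random.default_rng(0)
        res = group_ttest(1 + rng.normal(0, 1e-3, 5), rng.normal(0, 1e-3, 5))
        assert res["p"] < 0.001

    def test_welch_formula_oracle(self):
        """Matches a hand-computed Welch t-test to near machine precision."""
        rng = np.random.default_rng(3)
        a, b = rng.normal(0.5, 0.2, 9), rng.normal(0.3, 0.1, 12)
        res = group_ttest(a, b)
        va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
        t = (a.mean() - b.mean()) / np.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
        p = stats.t.sf(t, df)
        assert res["t"] == pytest.approx(t, abs=1e-10)
        assert res["p"] == pytest.approx(p, abs=1e-10)

    def test_zero_variance_equal_means_flagged(self):
        res = group_ttest([0.2, 0.2], [0.2, 0.2])
        assert res["degenerate"] and res["p"] == 0.5
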