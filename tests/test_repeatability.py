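"""Epoching, composite responses, the MCC metric, and feature selection."""

import numpy as np
import pytest
from scipy import stats

from seegdecode import (
    EventTable,
    IAFMatrix,
    SelectionRule,
    composite_response,
    epoch_features,
    mcc,
    select_features,
)
from seegdecode.repeatability import EpochSet, MCCTable


def make_iaf(values, step=0.2):
    values = np.asarray(values, dtype=float)
    n_feat = values.shape[1]
    return IAFMatrix(
        values=values,
        window_start_times=np.arange(values.shape[0]) * step,
        pair_names=[f"P{j}" for j in range(n_feat)],
        band_names=["b"] * n_feat,
    )


def make_epochs(block, class_name="go"):
    """block: (trials, windows, features) array."""
    block = np.asarray(block, dtype=float)
    return EpochSet(
        trials={class_name: block},
        relative_times={class_name: np.arange(block.shape[1]) * 0.2},
        event_indices={class_name: list(range(block.shape[0]))},
        feature_names=[f"P{j}" for j in range(block.shape[2])],
    )


def mcc_oracle(block, mode="include_all"):
    """Brute-force per-feature MCC from the covariance/variance definition."""
    n_trials, n_win, n_feat = block.shape
    comp = block.mean(axis=0)
    out = np.empty(n_feat)
    for j in range(n_feat):
        rs = []
        for i in range(n_trials):
            ref = comp[:, j]
            if mode == "leave_one_out":
                ref = (n_trials * comp[:, j] - block[i, :, j]) / (n_trials - 1)
            x, y = block[i, :, j], ref
            sx = np.sqrt(np.mean((x - x.mean()) ** 2))
            sy = np.sqrt(np.mean((y - y.mean()) ** 2))
            if sx == 0 or sy == 0:
                continue
            rs.append(np.mean((x - x.mean()) * (y - y.mean())) / (sx * sy))
        out[j] = np.mean(rs) if rs else np.nan
    return out


class TestEpoching:
    def test_four_second_cue_yields_22_windows(self):
        iaf = make_iaf(np.random.default_rng(0).standard_normal((100, 2)))
        events = EventTable(np.array([10.0]), np.array([14.0]), ["go"])
        epochs = epoch_features(iaf, events)
        assert epochs.trials["go"].shape[1] == 22
        assert epochs.relative_times["go"][-1] == pytest.approx(4.2)

    def test_off_grid_onset_snaps_back_to_grid(self):
        rng = np.random.default_rng(1)
        iaf = make_iaf(rng.standard_normal((100, 1)))
        on_grid = epoch_features(
            iaf, EventTable(np.array([10.0]), np.array([14.0]), ["go"])
        )
        off_grid = epoch_features(
            iaf, EventTable(np.array([10.05]), np.array([14.05]), ["go"])
        )
        np.testing.assert_array_equal(
            on_grid.trials["go"], off_grid.trials["go"]
        )

    def test_trial_count_matches_events(self):
        iaf = make_iaf(np.random.default_rng(2).standard_normal((500, 1)))
        onsets = np.arange(10) * 10.0
        events = EventTable(onsets, onsets + 4.0, ["go"] * 10)
        assert epoch_features(iaf, events).n_trials("go") == 10

    def test_event_past_recording_end_dropped_with_warning(self, caplog):
        iaf = make_iaf(np.random.default_rng(3).standard_normal((60, 1)))
        events = EventTable(np.array([0.0, 8.0]), np.array([4.0, 12.0]), ["go", "go"])
        with caplog.at_level("WARNING"):
            epochs = epoch_features(iaf, events)
        assert epochs.n_trials("go") == 1

    def test_unequal_cue_durations_rejected_unless_cropped(self):
        iaf = make_iaf(np.random.default_rng(4).standard_normal((200, 1)))
        events = EventTable(np.array([0.0, 10.0]), np.array([4.0, 13.0]), ["go", "go"])
        with pytest.raises(ValueError, match="unequal cue durations"):
            epoch_features(iaf, events)
        cropped = epoch_features(iaf, events, crop_to_min=True)
        assert cropped.trials["go"].shape[1] == 17  # (3.0 + 0.4) / 0.2


class TestComposite:
    def test_single_trial_composite_is_that_trial(self, rng):
        block = rng.standard_normal((1, 22, 3))
        comp = composite_response(make_epochs(block))
        np.testing.assert_array_equal(comp.traces["go"], block[0])

    def test_opposite_trials_cancel(self, rng):
        x = rng.standard_normal((1, 22, 2))
        block = np.concatenate([x, -x])
        comp = composite_response(make_epochs(block))
        np.testing.assert_allclose(comp.traces["go"], 0.0, atol=1e-12)

    def test_matches_per_element_mean_oracle(self, rng):
        block = rng.standard_normal((5, 10, 3))
        comp = composite_response(make_epochs(block))
        oracle = np.array(
            [
                [np.mean(block[:, w, j]) for j in range(3)]
                for w in range(10)
            ]
        )
        np.testing.assert_allclose(comp.traces["go"], oracle, atol=1e-14)


class TestMCC:
    def test_identical_nonconstant_trials_score_one(self):
        trial = np.sin(np.linspace(0, 3, 22))[:, None]
        block = np.stack([trial] * 5)
        table = mcc(make_epochs(block))
        assert table.values["go"][0] == pytest.approx(1.0)

    def test_opposite_trials_make_feature_invalid(self, rng):
        x = rng.standard_normal((1, 22, 1))
        block = np.concatenate([x, -x])
        table = mcc(make_epochs(block))
        assert np.isnan(table.values["go"][0])
        assert table.n_valid_trials["go"][0] == 0

    @pytest.mark.parametrize("mode", ["include_all", "leave_one_out"])
    def test_matches_brute_force_pearson_loop(self, rng, mode):
        block = rng.standard_normal((8, 22, 3))
        table = mcc(make_epochs(block), mode=mode)
        np.testing.assert_allclose(
            table.values["go"], mcc_oracle(block, mode), rtol=1e-12, atol=1e-12
        )

    def test_invariant_to_trial_ordering(self, rng):
        block = rng.standard_normal((6, 15, 4))
        a = mcc(make_epochs(block)).values["go"]
        b = mcc(make_epochs(block[::-1].copy())).values["go"]
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_invariant_to_common_positive_affine_transform(self, rng):
        block = rng.standard_normal((6, 15, 4))
        a = mcc(make_epochs(block)).values["go"]
        b = mcc(make_epochs(3.5 * block - 7.0)).values["go"]
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_short_epochs_rejected(self, rng):
        with pytest.raises(ValueError, match="3 windows"):
            mcc(make_epochs(rng.standard_normal((4, 2, 1))))

    def test_include_all_bias_exceeds_leave_one_out_on_noise(self, rng):
        # include_all lets each trial correlate with a composite containing
        # itself, inflating MCC; leave-one-out removes that optimism.
        block = rng.standard_normal((10, 22, 300))
        inc = mcc(make_epochs(block), mode="include_all").values["go"]
        loo = mcc(make_epochs(block), mode="leave_one_out").values["go"]
        t = stats.ttest_rel(inc, loo, alternative="greater")
        assert t.pvalue < 0.01


class TestSelection:
    def make_table(self, values):
        names = [f"P{j}" for j in range(len(values))]
        return MCCTable(
            values={"go": np.asarray(values, dtype=float)},
            n_valid_trials={"go": np.full(len(values), 5)},
            feature_names=names,
        )

    def test_threshold_is_strict(self):
        sel = select_features(self.make_table([0.7, 0.6, 0.5]), ">0.6")
        assert sel.selected == ["P0"]

    def test_minus_one_threshold_selects_all_valid(self):
        sel = select_features(self.make_table([0.2, -0.5, 0.9]), ">-1.0")
        assert sel.selected == ["P0", "P1", "P2"]

    def test_range_rule_is_closed(self):
        sel = select_features(self.make_table([0.3, 0.4, 0.5, 0.6, 0.7]), "0.4:0.6")
        assert sel.selected == ["P1", "P2", "P3"]

    def test_invalid_features_never_selected(self):
        table = self.make_table([0.9, np.nan])
        table.n_valid_trials["go"][1] = 0
        assert select_features(table, ">-1.0").selected == ["P0"]

    def test_union_across_classes(self):
        table = MCCTable(
            values={"a": np.array([0.9, 0.1]), "b": np.array([0.1, 0.8])},
            n_valid_trials={"a": np.array([5, 5]), "b": np.array([5, 5])},
            feature_names=["P0", "P1"],
        )
        sel = select_features(table, ">0.6")
        assert sel.selected == ["P0", "P1"]
        assert sel.per_class == {"a": ["P0"], "b": ["P1"]}

    def test_raising_threshold_never_enlarges_selection(self, rng):
        table = self.make_table(rng.uniform(-1, 1, size=50))
        previous = None
        for t in np.linspace(-1, 1, 21):
            chosen = set(select_features(table, SelectionRule(threshold=t)).selected)
            if previous is not None:
                assert chosen <= previous
            previous = chosen

    def test_empty_selection_warns(self, caplog):
        with caplog.at_level("WARNING"):
            sel = select_features(self.make_table([0.1, 0.2]), ">0.99")
        assert len(sel) == 0
        assert any("no feature" in r.message for r in caplog.records)

    @pytest.mark.parametrize("text,expected", [
        (">0.6", SelectionRule(threshold=0.6)),
        ("0.4:0.6", SelectionRule(low=0.4, high=0.6)),
    ])
    def test_rule_parsing(self, text, expected):
        assert SelectionRule.parse(text) == expected

    def test_rule_parse_rejects_garbage(self):
        with pytest.raises(ValueError):
            SelectionRule.parse("between 0.4 and 0.6")

    def test_selection_round_trip_json(self, tmp_path, rng):
        sel = select_features(self.make_table([0.9, 0.1, 0.8]), ">0.6")
        sel.to_json(tmp_path / "sel.json")
        back = type(sel).from_json(tmp_path / "sel.json")
        assert back.selected == sel.selected
        assert back.rule == sel.rule
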