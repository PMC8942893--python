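"""Judgment errors, trial trimming, binding scores, participant screening."""

import io

import numpy as np
import pandas as pd
import pytest

from libetbind import tables
from libetbind.binding import (
    BLOCKS,
    SchemaError,
    TrimPolicy,
    binding_scores,
    compute_judgment_errors,
    read_trials,
    screen_participants,
    trim_cell,
    trim_trials,
    write_trials,
)


def make_trials(rows):
    base = {
        "participant_id": "P1",
        "condition": "2560",
        "block": "baseline_action",
        "trial_index": 0,
        "actual_event_ms": 2000.0,
        "reported_units": 0.0,
        "period_ms": 2560.0,
    }
    recs = []
    for i, r in enumerate(rows):
        rec = dict(base, trial_index=i)
        rec.update(r)
        recs.append(rec)
    return pd.DataFrame(recs)


class TestJudgmentErrors:
    def test_zero_error_when_report_matches_phase(self):
        df = make_trials([{"actual_event_ms": 2560.0 + 640.0, "reported_units": 15.0}])
        out = compute_judgment_errors(df)
        assert out["error_ms"].iloc[0] == pytest.approx(0.0)

    def test_hand_computed_error(self):
        # 50 units on a 2560 ms clock = 2133.33 ms phase; event at 2000 ms
        df = make_trials([{"actual_event_ms": 2000.0, "reported_units": 50.0}])
        out = compute_judgment_errors(df)
        assert out["error_ms"].iloc[0] == pytest.approx(2133.333333 - 2000.0, abs=1e-4)

    def test_deterministic_annotation(self):
        df = make_trials([{"reported_units": u} for u in [3, 17.5, 42]])
        a = compute_judgment_errors(df)
        b = compute_judgment_errors(df)
        pd.testing.assert_frame_equal(a, b)

    def test_out_of_range_report_names_row(self):
        df = make_trials([{"reported_units": 10.0}, {"reported_units": 60.0}])
        with pytest.raises(ValueError, match="row 2"):
            compute_judgment_errors(df)

    def test_missing_config_for_condition(self):
        from libetbind.clock import ClockConfig

        df = make_trials([{}])
        with pytest.raises(KeyError, match="2560"):
            compute_judgment_errors(df, configs={"other": ClockConfig(1280)})


class TestTrimming:
    def test_identical_errors_nothing_excluded(self):
        kept, frac = trim_cell([5.0] * 10)
        assert len(kept) == 10 and frac == 0.0

    def test_planted_outlier_excluded(self):
        errors = [0.0] * 9 + [100.0]  # mean 10, SD 31.62, bound 79.06
        kept, frac = trim_cell(errors)
        assert frac == pytest.approx(0.10)
        assert 100.0 not in kept and len(kept) == 9

    def test_huge_k_excludes_nothing(self):
        rng = np.random.default_rng(5)
        e = rng.normal(0, 50, 40)
        kept, frac = trim_cell(e, TrimPolicy(k=1e12))
        assert frac == 0.0 and len(kept) == 40

    def test_boundary_z_kept(self):
        # two points: each is exactly 1 SD·(1/sqrt(2))... use k large enough
        e = np.array([-1.0, 1.0])
        kept, frac = trim_cell(e, TrimPolicy(k=1.0))
        assert frac == 0.0  # |e - 0| = 1 < sd = sqrt(2)

    def test_singleton_cell_kept_with_warning(self):
        kept, frac = trim_cell([3.0])
        assert list(kept) == [3.0] and frac == 0.0

    def test_dataframe_trim_matches_cellwise(self):
        rng = np.random.default_rng(9)
        frames = []
        for pid in ("P1", "P2"):
            for block in BLOCKS:
                df = make_trials(
                    [{"reported_units": 0.0, "actual_event_ms": 2560.0}] * 20
                )
                df["participant_id"] = pid
                df["block"] = block
                frames.append(df)
        trials = compute_judgment_errors(pd.concat(frames, ignore_index=True))
        trials["error_ms"] = rng.normal(0, 50, len(trials))
        kept, report = trim_trials(trials)
        # compare against per-cell brute force
        n_kept = 0
        for _, cell in trials.groupby(["participant_id", "condition", "block"]):
            k, _ = trim_cell(cell["error_ms"].to_numpy())
            n_kept += len(k)
        assert len(kept) == n_kept
        assert report.n_total - report.n_excluded == n_kept
        assert 0 <= report.exclusion_fraction < 0.5

    def test_trim_keeps_majority_for_k_ge_1(self):
        rng = np.random.default_rng(31)
        for _ in range(20):
            e = rng.normal(0, 1, rng.integers(3, 30))
            kept, _ = trim_cell(e, TrimPolicy(k=1.0))
            assert len(kept) > len(e) - len(kept)


def _trials_from_block_means(means_by_cond, n_participants=4, n_trials=5, offsets=None):
    """Noiseless trials whose per-block errors equal the given means.

    ``offsets`` optionally shifts each participant's every block by a
    constant (a pure random intercept shared across blocks)."""
    offsets = offsets or [0.0] * n_participants
    rows = []
    for p in range(n_participants):
        for cond, mus in means_by_cond.items():
            for block, mu in mus.items():
                for t in range(n_trials):
                    actual = 3000.0 + 37.0 * t
                    err = mu + offsets[p]
                    rows.append(
                        {
                            "participant_id": f"P{p}",
                            "condition": cond,
                            "block": block,
                            "trial_index": t,
                            "actual_event_ms": actual,
                            "reported_units": ((actual + err) % 2560.0) / (2560.0 / 60),
                            "period_ms": 2560.0,
                        }
                    )
    return pd.DataFrame(rows)


class TestBindingScores:
    def test_shift_is_operant_minus_baseline_published_cells(self):
        t2 = tables.load_tables()["exp2"]["conditions"]
        means = {
            cond: {
                f"{blk}_{ev}": t2[cond][ev][blk]["mean"]
                for ev in ("action", "tone")
                for blk in ("baseline", "operant")
            }
            for cond in ("1280", "5120")
        }
        trials = compute_judgment_errors(_trials_from_block_means(means))
        table = binding_scores(trials)
        shifts = table.condition_shifts()
        assert shifts.loc["1280", "action"] == pytest.approx(21.89, abs=0.005)
        assert shifts.loc["5120", "tone"] == pytest.approx(-31.80, abs=0.005)

    def test_zero_shift_when_operant_equals_baseline(self):
        means = {"2560": {b: -15.0 for b in BLOCKS}}
        trials = compute_judgment_errors(_trials_from_block_means(means))
        shifts = binding_scores(trials).condition_shifts()
        assert shifts.loc["2560", "action"] == pytest.approx(0.0, abs=1e-9)
        assert shifts.loc["2560", "tone"] == pytest.approx(0.0, abs=1e-9)

    def test_invariant_to_trial_order(self):
        means = {"2560": {b: m for b, m in zip(BLOCKS, [-20, 5, -30, -90])}}
        trials = compute_judgment_errors(
            _trials_from_block_means(means, offsets=[0, 10, -5, 25])
        )
        shuffled = trials.sample(frac=1, random_state=1).reset_index(drop=True)
        a = binding_scores(trials).scores.sort_values("participant_id").reset_index(drop=True)
        b = binding_scores(shuffled).scores.sort_values("participant_id").reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)

    def test_mean_of_shifts_equals_difference_of_grand_means_balanced(self):
        means = {"2560": {b: m for b, m in zip(BLOCKS, [-20, 5, -30, -90])}}
        trials = compute_judgment_errors(
            _trials_from_block_means(means, offsets=[3, -7, 12, 0])
        )
        table = binding_scores(trials)
        grand = trials.groupby("block")["error_ms"].mean()
        assert table.condition_shifts().loc["2560", "action"] == pytest.approx(
            grand["operant_action"] - grand["baseline_action"]
        )

    def test_participant_missing_block_dropped_with_reason(self):
        means = {"2560": {b: 0.0 for b in BLOCKS}}
        trials = compute_judgment_errors(_trials_from_block_means(means))
        trials = trials[
            ~((trials.participant_id == "P0") & (trials.block == "operant_tone"))
        ]
        table = binding_scores(trials)
        assert ("P0", "2560", "missing block(s): operant_tone") in table.dropped
        assert "P0" not in set(table.scores["participant_id"])

    def test_summary_layout_mirrors_published_tables(self):
        means = {"2560": {b: m for b, m in zip(BLOCKS, [-20, 5, -30, -90])}}
        trials = compute_judgment_errors(_trials_from_block_means(means))
        summary = binding_scores(trials).summary
        assert set(summary.columns) >= {
            "condition",
            "event",
            "block",
            "raw_mean_ms",
            "raw_sd_ms",
            "shift_mean_ms",
            "shift_sd_ms",
        }
        assert len(summary) == 4  # 1 condition × 2 events × 2 blocks


class TestScreening:
    @staticmethod
    def _table(action, tone):
        scores = pd.DataFrame(
            {
                "participant_id": [f"P{i}" for i in range(len(action))],
                "condition": "2560",
                "action_binding_ms": action,
                "tone_binding_ms": tone,
            }
        )
        from libetbind.binding import BindingTable, _group_summary

        for b in BLOCKS:
            scores[f"mean_{b}"] = 0.0
        return BindingTable(scores=scores, summary=_group_summary(scores))

    def test_clean_symmetric_group_no_exclusions(self):
        rng = np.random.default_rng(17)
        table = self._table(rng.normal(30, 20, 30), rng.normal(-80, 30, 30))
        report = screen_participants(table)
        assert report.excluded == {}

    def test_planted_extreme_participant_flagged_and_excluded(self):
        rng = np.random.default_rng(17)
        tone = rng.normal(-80, 30, 30)
        tone[4] = -80 + 10 * 30  # 10 group-SDs off
        table = self._table(rng.normal(30, 20, 30), tone)
        report = screen_participants(table)
        assert "P4" in report.excluded
        assert any(m.startswith("tone") for m, _ in report.flagged["P4"])

    def test_excluded_subset_of_flagged(self):
        rng = np.random.default_rng(23)
        tone = rng.normal(-80, 30, 25)
        tone[0] = 200.0
        tone[1] = -95.0
        table = self._table(rng.normal(30, 20, 25), tone)
        report = screen_participants(table)
        assert set(report.excluded) <= set(report.flagged)

    def test_moments_are_bias_corrected(self):
        from scipy import stats

        rng = np.random.default_rng(2)
        a = rng.normal(0, 1, 12)
        table = self._table(a, rng.normal(-50, 10, 12))
        report = screen_participants(table)
        assert report.moments.loc["action:2560", "skewness"] == pytest.approx(
            stats.skew(a, bias=False)
        )
        assert report.moments.loc["action:2560", "kurtosis"] == pytest.approx(
            stats.kurtosis(a, fisher=True, bias=False)
        )

    def test_too_few_participants_rejected(self):
        table = self._table([1.0, 2.0, 3.0], [0.0, 0.0, 1.0])
        with pytest.raises(ValueError, match=">= 5"):
            screen_participants(table)


class TestCsvRoundTrip:
    def test_write_read_round_trip(self, tmp_path):
        means = {"2560": {b: 0.0 for b in BLOCKS}}
        df = _trials_from_block_means(means, n_participants=2, n_trials=3)
        path = tmp_path / "trials.csv"
        write_trials(df, path)
        back = read_trials(path)
        pd.testing.assert_frame_equal(
            back, df[back.columns], check_dtype=False, check_exact=False
        )

    def test_empty_file_is_schema_error(self):
        with pytest.raises((SchemaError, pd.errors.EmptyDataError)):
            read_trials(io.StringIO(""))

    def test_bad_block_reports_row(self, tmp_path):
        means = {"2560": {b: 0.0 for b in BLOCKS}}
        df = _trials_from_block_means(means, n_participants=1, n_trials=2)
        df.loc[3, "block"] = "operant"
        path = tmp_path / "bad.csv"
        df.to_csv(path, index=False)
        with pytest.raises(SchemaError, match="row 4"):
            read_trials(path)
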