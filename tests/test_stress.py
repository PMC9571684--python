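import numpy as np
import pandas as pd
import pytest

from wearcontext.stress import (
    ACTIVITY_CTX_COLS,
    SLEEP_CTX_COLS,
    STRESS3_ORDER,
    ExperimentConfig,
    assemble_events,
    assign_folds,
    collapse_stress,
    format_results_table,
    run_experiment,
    selfreport_activity_ctx,
    selfreport_sleep_ctx,
    train_variant,
    variant_columns,
    _metrics,
)
from wearcontext.synthetic import HourlyReport, NightReport


class TestCollapseStress:
    @pytest.mark.parametrize("level,expected", [
        (1, "no"), (2, "medium"), (3, "high"), (4, "high"), (5, "high")])
    def test_mapping(self, level, expected):
        assert collapse_stress(level) == expected

    @pytest.mark.parametrize("bad", [0, 6, -1])
    def test_out_of_range(self, bad):
        with pytest.raises(ValueError):
            collapse_stress(bad)


class TestActivityCtx:
    def test_sitting_and_biking_split_thirty_thirty(self):
        assert selfreport_activity_ctx({"sitting", "biking"}) == (30.0, 0.0, 30.0)

    def test_single_class_takes_the_hour(self):
        assert selfreport_activity_ctx({"walking"}) == (0.0, 60.0, 0.0)

    def test_three_way_split(self):
        assert selfreport_activity_ctx({"sitting", "walking", "biking"}) == \
            (20.0, 20.0, 20.0)

    def test_tokens_mapping_to_same_class_count_once(self):
        assert selfreport_activity_ctx({"sitting", "standing"}) == (60.0, 0.0, 0.0)

    def test_empty_set(self):
        assert selfreport_activity_ctx(set()) == (0.0, 0.0, 0.0)

    def test_unknown_token_ignored(self, caplog):
        with caplog.at_level("WARNING"):
            out = selfreport_activity_ctx({"sitting", "swimming"})
        assert out == (60.0, 0.0, 0.0)
        assert "swimming" in caplog.text


class TestSleepCtx:
    def test_across_midnight(self):
        rep = NightReport("S0", pd.Timestamp("2022-03-11"),
                          pd.Timestamp("2022-03-10 23:30"),
                          pd.Timestamp("2022-03-11 07:00"))
        assert selfreport_sleep_ctx(rep) == (23.5, 7.0, 7.5)

    def test_after_midnight_bedtime(self):
        rep = NightReport("S0", pd.Timestamp("2022-03-11"),
                          pd.Timestamp("2022-03-11 01:00"),
                          pd.Timestamp("2022-03-11 09:00"))
        assert selfreport_sleep_ctx(rep) == (1.0, 9.0, 8.0)


def _tiny_hour_features(subjects, dates, hours, n_physio=4, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for s in subjects:
        for d in dates:
            for h in hours:
                row = {"subject_id": s,
                       "hour_start": pd.Timestamp(d) + pd.Timedelta(hours=h),
                       "usable": True}
                row.update({f"p{i}": rng.normal() for i in range(n_physio)})
                rows.append(row)
    return pd.DataFrame(rows)


class TestAssembleEvents:
    DATES = ("2022-03-10", "2022-03-11")

    def _reports(self, subjects):
        reps = []
        for s in subjects:
            for d in self.DATES:
                for h in (9, 15):
                    reps.append(HourlyReport(
                        s, pd.Timestamp(d) + pd.Timedelta(hours=h),
                        1 + (h % 5), frozenset({"sitting"})))
        return reps

    def _nights(self, subjects, dates=None):
        return [NightReport(s, pd.Timestamp(d),
                            pd.Timestamp(d) - pd.Timedelta(hours=1),
                            pd.Timestamp(d) + pd.Timedelta(hours=7))
                for s in subjects for d in (dates or self.DATES)]

    def test_event_count_equals_complete_reports(self):
        subs = ["A", "B"]
        feats = _tiny_hour_features(subs, self.DATES, (9, 15))
        events, drops = assemble_events(feats, self._reports(subs),
                                        night_reports=self._nights(subs))
        assert len(events) == 8
        assert drops == {"no_physio": 0, "unusable_physio": 0,
                         "no_activity_ctx": 0, "no_sleep_ctx": 0}

    def test_missing_night_report_drops_event(self):
        subs = ["A"]
        feats = _tiny_hour_features(subs, self.DATES, (9, 15))
        events, drops = assemble_events(
            feats, self._reports(subs),
            night_reports=self._nights(subs, dates=self.DATES[:1]))
        assert len(events) == 2 and drops["no_sleep_ctx"] == 2

    def test_ml_without_overnight_data_drops_day(self):
        subs = ["A"]
        feats = _tiny_hour_features(subs, self.DATES, (9, 15))
        act = feats[["subject_id", "hour_start"]].copy()
        for c in ("sedentary", "walking", "cycling"):
            act[f"minutes_{c}"] = 20.0
        # sleep estimate exists only for the night before the second day
        slp = pd.DataFrame([{
            "subject_id": "A",
            "day_window_start": pd.Timestamp("2022-03-10 13:00"),
            "onset": pd.Timestamp("2022-03-10 23:00"),
            "offset": pd.Timestamp("2022-03-11 07:00"), "status": "ok"}])
        events, drops = assemble_events(feats, self._reports(subs),
                                        context_source="ml",
                                        activity_minutes=act,
                                        sleep_estimates=slp)
        assert len(events) == 2  # only the second day's events survive
        assert drops["no_sleep_ctx"] == 2
        assert (events["ctx_sleep_duration"] == 8.0).all()

    def test_circular_hour_encoding(self):
        subs = ["A"]
        feats = _tiny_hour_features(subs, self.DATES, (9, 15))
        events, _ = assemble_events(feats, self._reports(subs),
                                    night_reports=self._nights(subs),
                                    circular_hours=True)
        assert {"ctx_bed_sin", "ctx_bed_cos", "ctx_getup_sin",
                "ctx_getup_cos", "ctx_sleep_duration"} <= set(events.columns)
        assert "ctx_bed_hour" not in events.columns
        # sin/cos encode the same hour-of-day angle
        ang = np.arctan2(events["ctx_bed_sin"], events["ctx_bed_cos"])
        hours = (ang % (2 * np.pi)) * 24 / (2 * np.pi)
        assert np.allclose(hours, 23.0)
        assert len(variant_columns(events, "+sleep")) == 4 + 5

    def test_determinism(self):
        subs = ["A", "B"]
        feats = _tiny_hour_features(subs, self.DATES, (9, 15))
        args = (feats, self._reports(subs))
        e1, _ = assemble_events(*args, night_reports=self._nights(subs))
        e2, _ = assemble_events(*args, night_reports=self._nights(subs))
        pd.testing.assert_frame_equal(e1, e2)


def _toy_events(n_subjects=6, per_subject=30, n_physio=8, seed=3):
    """Synthetic numeric event table with a learnable structure."""
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_subjects):
        for k in range(per_subject):
            y = rng.choice(STRESS3_ORDER, p=[0.5, 0.3, 0.2])
            x = rng.normal(size=n_physio)
            x[0] += {"no": 0, "medium": 1.0, "high": 2.0}[y]
            row = {"subject_id": f"S{s}",
                   "hour_start": pd.Timestamp("2022-03-10") +
                   pd.Timedelta(hours=k),
                   "stress3": y}
            row.update({f"p{i}": x[i] for i in range(n_physio)})
            row.update({c: float(rng.integers(0, 60)) for c in ACTIVITY_CTX_COLS})
            row.update(dict(zip(SLEEP_CTX_COLS, (23.0, 7.0, 8.0))))
            rows.append(row)
    return pd.DataFrame(rows)


class TestFoldsAndVariants:
    def test_fold_discipline(self):
        events = _toy_events()
        folds = assign_folds(events, 3)
        per_subject = pd.Series(folds).groupby(events["subject_id"]).nunique()
        assert (per_subject == 1).all()
        assert set(folds) == {0, 1, 2}

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            assign_folds(_toy_events(n_subjects=2), 3)

    def test_variant_column_widths(self):
        events = _toy_events(n_physio=8)
        widths = {v: len(variant_columns(events, v))
                  for v in ("baseline", "+activity", "+sleep", "+activity+sleep")}
        assert widths == {"baseline": 8, "+activity": 11,
                         "+sleep": 11, "+activity+sleep": 14}

    def test_training_deterministic(self):
        events = _toy_events()
        folds = assign_folds(events, 3)
        cfg = ExperimentConfig(depth_grid=(3,), max_iterations=80,
                               early_stopping_rounds=20, seed=5)
        preds = []
        for _ in range(2):
            model, cols, _ = train_variant(events, "+activity",
                                           folds == 0, folds == 1, cfg)
            preds.append(model.predict(events.loc[folds == 2, cols]))
        np.testing.assert_array_equal(preds[0], preds[1])


class TestMetrics:
    def test_kappa_matches_hand_formula_on_confusion_matrix(self):
        # hand-built 3x3 confusion matrix expanded to label vectors
        cm = np.array([[20, 5, 2], [4, 15, 6], [1, 3, 10]])
        y_true, y_pred = [], []
        for i in range(3):
            for j in range(3):
                y_true += [i] * cm[i, j]
                y_pred += [j] * cm[i, j]
        y_true, y_pred = np.array(y_true), np.array(y_pred)
        n = cm.sum()
        p_o = np.trace(cm) / n
        p_e = sum(cm[i, :].sum() * cm[:, i].sum() for i in range(3)) / n ** 2
        expected = (p_o - p_e) / (1 - p_e)
        got = _metrics(y_true, y_pred, dummy_class=0)["kappa"]
        assert got == pytest.approx(100 * expected, rel=1e-9)

    def test_metrics_match_brute_force_on_random_sets(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            y = rng.integers(0, 3, 50)
            p = rng.integers(0, 3, 50)
            m = _metrics(y, p, dummy_class=int(np.bincount(y).argmax()))
            assert m["accuracy"] == pytest.approx(100 * np.mean(y == p))
            # weighted F1 by direct per-class computation
            wf1 = 0.0
            for c in range(3):
                tp = np.sum((y == c) & (p == c))
                fp = np.sum((y != c) & (p == c))
                fn = np.sum((y == c) & (p != c))
                prec = tp / (tp + fp) if tp + fp else 0.0
                rec = tp / (tp + fn) if tp + fn else 0.0
                f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
                wf1 += np.mean(y == c) * f1
            assert m["weighted_f1"] == pytest.approx(100 * wf1, rel=1e-9)

    def test_dummy_against_itself_scores_zero_delta(self):
        y = np.array([0] * 30 + [1] * 15 + [2] * 5)
        pred = np.zeros_like(y)
        m = _metrics(y, pred, dummy_class=0)
        assert m["vs_dummy"] == pytest.approx(0.0)

    def test_perfect_classifier(self):
        y = np.array([0] * 30 + [1] * 15 + [2] * 5)
        m = _metrics(y, y.copy(), dummy_class=0)
        assert m["accuracy"] == 100.0
        assert m["kappa"] == pytest.approx(100.0)
        assert m["vs_dummy"] > 0


class TestRunExperiment:
    def test_table_contract_and_determinism(self):
        events = _toy_events()
        cfg = ExperimentConfig(depth_grid=(3,), max_iterations=60,
                               early_stopping_rounds=15, seed=2)
        s1, d1 = run_experiment(events, cfg)
        s2, d2 = run_experiment(events, cfg)
        pd.testing.assert_frame_equal(s1, s2)
        pd.testing.assert_frame_equal(d1, d2)
        assert list(s1.index) == ["baseline", "+activity", "+sleep",
                                  "+activity+sleep"]
        assert (s1.filter(like="accuracy_mean") <= 100).all().all()
        assert (s1.filter(like="_sd") >= 0).all().all()
        rendered = format_results_table(s1)
        assert rendered.shape == (4, 4)
        assert "(" in rendered.iloc[0, 0]
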