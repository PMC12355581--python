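"""Event merging, sleep time, AHI/severity report, full pipeline."""

import pytest

from lrsahs import (
    DetectorConfig,
    EventType,
    Hypnogram,
    RespEvent,
    Severity,
    compute_report,
    merge_events,
    run_pipeline,
    severity_from_ahi,
    total_sleep_time,
)
from lrsahs.spo2_detector import DropEvent


def drop(t1, t2, t0=5.0, depth=0.04):
    return DropEvent(t1_s=t1, t2_s=t2, t0_s=t0, depth=depth)


class TestMergeEvents:
    def test_drop_shortly_after_apnea_is_attributed(self, cfg):
        apneas = [RespEvent("apnea", 100.0, 120.0)]
        merged = merge_events(apneas, [drop(140.0, 149.0)], cfg)  # 140 < 120 + 30
        assert merged == apneas

    def test_drop_beyond_lookback_becomes_hypopnea(self, cfg):
        apneas = [RespEvent("apnea", 100.0, 120.0)]
        merged = merge_events(apneas, [drop(160.0, 170.0)], cfg)  # 160 >= 150
        assert len(merged) == 2
        assert merged[1].type is EventType.HYPOPNEA

    def test_without_apneas_all_drops_become_hypopneas(self, cfg):
        drops = [drop(100.0, 110.0), drop(300.0, 320.0), drop(500.0, 540.0)]
        merged = merge_events([], drops, cfg)
        assert [e.type for e in merged] == [EventType.HYPOPNEA] * 3

    def test_drop_straddling_apnea_onset_is_attributed(self, cfg):
        # descent starts just before the apnea but reaches into it
        apneas = [RespEvent("apnea", 100.0, 130.0)]
        merged = merge_events(apneas, [drop(98.0, 115.0)], cfg)
        assert merged == apneas

    def test_lengthening_lookback_never_adds_hypopneas(self, cfg, short_night):
        from lrsahs import detect_apnea, detect_drops, local_range

        apneas = detect_apnea(local_range(short_night.flow, cfg), cfg)
        drops = detect_drops(short_night.spo2, cfg)
        counts = []
        for lb in (0.0, 15.0, 30.0, 60.0, 120.0):
            c = DetectorConfig(lookback_s=lb)
            merged = merge_events(apneas, drops, c)
            counts.append(sum(1 for e in merged if e.type is EventType.HYPOPNEA))
        assert counts == sorted(counts, reverse=True)

    def test_surviving_hypopneas_have_no_apnea_in_window(self, cfg, short_night):
        from lrsahs import run_pipeline

        res = run_pipeline(short_night.flow, short_night.spo2, short_night.hypnogram, cfg)
        apneas = [e for e in res.events if e.type is EventType.APNEA]
        for h in (e for e in res.events if e.type is EventType.HYPOPNEA):
            assert not any(
                a.start_s <= h.start_s < a.end_s + cfg.lookback_s for a in apneas
            )


class TestTotalSleepTime:
    def test_all_sleep(self):
        assert total_sleep_time(Hypnogram(("N2",) * 960)) == pytest.approx(8.0)

    def test_wake_epochs_excluded(self):
        h = Hypnogram(("W",) * 120 + ("N2",) * 840)
        assert total_sleep_time(h) == pytest.approx(7.0)

    def test_all_wake_gives_zero_and_undefined_ahi(self):
        h = Hypnogram(("W",) * 10)
        assert total_sleep_time(h) == 0.0
        with pytest.raises(ValueError, match="sleep time"):
            compute_report([], h)


class TestComputeReport:
    def test_no_events(self):
        rep = compute_report([], Hypnogram(("N2",) * 960))
        assert rep.ahi == 0.0
        assert rep.severity is Severity.NORMAL
        assert rep.duration_pct_total == 0.0

    def test_boundary_ahi_5_is_mild(self):
        events = [RespEvent("apnea", 100 * i, 100 * i + 20) for i in range(40)]
        rep = compute_report(events, Hypnogram(("N2",) * 960))
        assert rep.ahi == pytest.approx(5.0)
        assert rep.severity is Severity.MILD

    def test_counts_rates_and_duration_percentages(self):
        events = [RespEvent("apnea", 120 * i, 120 * i + 30) for i in range(30)]
        events += [RespEvent("hypopnea", 4000 + 120 * i, 4000 + 120 * i + 30) for i in range(10)]
        rep = compute_report(events, Hypnogram(("N2",) * 240))  # T = 2 h
        assert rep.n_apnea == 30 and rep.n_hypopnea == 10 and rep.n_sah == 40
        assert rep.ahi == pytest.approx(20.0)
        assert rep.severity is Severity.MODERATE
        assert rep.duration_pct_total == pytest.approx(100 * 1200 / 7200)

    @pytest.mark.parametrize(
        "ahi,expected",
        [
            (0.0, Severity.NORMAL),
            (4.9, Severity.NORMAL),
            (5.0, Severity.MILD),
            (14.9, Severity.MILD),
            (15.0, Severity.MODERATE),
            (29.9, Severity.MODERATE),
            (30.0, Severity.SEVERE),
            (57.4, Severity.SEVERE),
        ],
    )
    def test_severity_bands(self, ahi, expected):
        assert severity_from_ahi(ahi) is expected


class TestPipeline:
    def test_quiet_night_yields_zero_ahi(self):
        from lrsahs import SynthParams, generate_recording

        rec = generate_recording(
            SynthParams(seed=5, duration_h=0.5, n_apnea=0, n_hypopnea=0, n_flow_artifact=0)
        )
        res = run_pipeline(rec.flow, rec.spo2, rec.hypnogram)
        assert res.events == []
        assert res.report.ahi == 0.0
        assert res.report.severity is Severity.NORMAL

    def test_airflow_only_mode_nulls_hypopnea_fields(self, short_night):
        res = run_pipeline(short_night.flow, None, short_night.hypnogram)
        assert res.report.n_hypopnea is None
        assert res.report.hypopnea_rate_per_h is None
        assert res.report.n_apnea > 0

    def test_missing_hypnogram_flags_assumed_sleep_time(self, short_night):
        res = run_pipeline(short_night.flow, short_night.spo2, None)
        assert res.report.sleep_time_assumed
        assert res.report.total_sleep_time_h == pytest.approx(1.0, rel=1e-3)

    def test_conservation_of_event_counts(self, short_night):
        res = run_pipeline(short_night.flow, short_night.spo2, short_night.hypnogram)
        n_a = sum(1 for e in res.events if e.type is EventType.APNEA)
        n_h = sum(1 for e in res.events if e.type is EventType.HYPOPNEA)
        assert res.report.n_apnea == n_a
        assert res.report.n_hypopnea == n_h
        assert res.report.n_sah == n_a + n_h

    def test_report_json_roundtrip(self, short_night, tmp_path):
        import json

        res = run_pipeline(short_night.flow, short_night.spo2, short_night.hypnogram)
        res.report.to_json(tmp_path / "report.json")
        data = json.loads((tmp_path / "report.json").read_text())
        assert data["n_sah"] == res.report.n_sah
        assert data["severity"] == res.report.severity.value
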