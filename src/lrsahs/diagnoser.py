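"""Merging airflow and SpO2 detections into a diagnostic report.

A desaturation can be caused by either an apnea or a hypopnea.  Apneas are
found directly in the airflow, so each SpO2 drop is checked against the
apnea list with a 30-s lookback: if the drop onset lies within
``[apnea.start, apnea.end + lookback_s)`` for some apnea, the drop is that
apnea's desaturation and is discarded; otherwise it is classified as a
hypopnea.  The apnea-hypopnea index is then

    AHI = (nA + nH) / T,

with T the total sleep time in hours, computed from the hypnogram as the
time spent in N1 + N2 + N3 + R.  Severity bands: AHI < 5 normal, [5, 15)
mild, [15, 30) moderate, >= 30 severe.  The report also carries the
fraction of sleep time occupied by events (duration percentage), a summary
statistic of cumulative event burden.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .apnea_detector import detect_apnea, local_range
from .signal_model import (
    DetectorConfig,
    DiagnosticReport,
    EventType,
    Hypnogram,
    RespEvent,
    SampledSignal,
    Severity,
)
from .spo2_detector import DropEvent, detect_drops

__all__ = [
    "merge_events",
    "total_sleep_time",
    "compute_report",
    "run_pipeline",
    "severity_from_ahi",
    "PipelineResult",
]


def merge_events(
    apneas: Sequence[RespEvent],
    drops: Sequence[DropEvent],
    cfg: DetectorConfig | None = None,
) -> list[RespEvent]:
    """Combine apneas with SpO2 drops; surviving drops become hypopneas.

    Apneas pass through unchanged.  A drop is discarded when its descent
    (onset to nadir) intersects ``[a.start_s, a.end_s + lookback_s)`` for
    any apnea ``a`` -- the desaturation is then attributed to that apnea; it
    is discarded at most once even if it sits in two apneas' windows.  A
    surviving drop whose recovery tail reaches into a neighbouring event is
    clipped so the merged list stays disjoint.
    """
    cfg = cfg or DetectorConfig()
    out: list[RespEvent] = list(apneas)
    for d in drops:
        desc_end = getattr(d, "t2_s", d.end_s)  # nadir if known, else event end
        attributed = any(
            max(d.start_s, a.start_s) < min(desc_end, a.end_s + cfg.lookback_s)
            or a.start_s <= d.start_s < a.end_s + cfg.lookback_s
            for a in apneas
        )
        if not attributed:
            out.append(d.retyped(EventType.HYPOPNEA))
    out.sort(key=lambda e: (e.start_s, e.end_s))
    clipped: list[RespEvent] = []
    for cur, nxt in zip(out, out[1:] + [None]):
        if nxt is not None and cur.end_s > nxt.start_s:
            if cur.start_s >= nxt.start_s:
                continue  # fully swallowed by the next event
            cur = RespEvent(cur.type, cur.start_s, nxt.start_s)
        clipped.append(cur)
    return clipped


def total_sleep_time(h: Hypnogram) -> float:
    """Total sleep time in hours: time in stages N1, N2, N3 and R."""
    n_sleep = sum(1 for e in h.epochs if e != "W")
    return n_sleep * h.epoch_s / 3600.0


def severity_from_ahi(ahi: float) -> Severity:
    if ahi < 5:
        return Severity.NORMAL
    if ahi < 15:
        return Severity.MILD
    if ahi < 30:
        return Severity.MODERATE
    return Severity.SEVERE


def compute_report(
    events: Sequence[RespEvent],
    h: Hypnogram | None,
    *,
    recording_span_s: float | None = None,
    airflow_only: bool = False,
) -> DiagnosticReport:
    """Counts, AHI, severity and duration percentages from a merged event list.

    If no hypnogram is available, the full recording span is used as total
    sleep time and the report is flagged with ``sleep_time_assumed``.
    """
    if h is not None:
        tst_h = total_sleep_time(h)
        assumed = False
    elif recording_span_s is not None:
        tst_h = recording_span_s / 3600.0
        assumed = True
    else:
        raise ValueError("need a hypnogram or a recording span to compute sleep time")
    if tst_h <= 0:
        raise ValueError("total sleep time is zero: AHI undefined")
    tst_s = tst_h * 3600.0

    apneas = [e for e in events if e.type is EventType.APNEA]
    hypopneas = [e for e in events if e.type is EventType.HYPOPNEA]
    n_a, n_h = len(apneas), len(hypopneas)
    dur_a = sum(e.duration_s for e in apneas)
    dur_h = sum(e.duration_s for e in hypopneas)

    ahi = (n_a + (0 if airflow_only else n_h)) / tst_h
    return DiagnosticReport(
        n_apnea=n_a,
        n_hypopnea=None if airflow_only else n_h,
        total_sleep_time_h=tst_h,
        ahi=ahi,
        severity=severity_from_ahi(ahi),
        apnea_rate_per_h=n_a / tst_h,
        hypopnea_rate_per_h=None if airflow_only else n_h / tst_h,
        duration_pct_apnea=100.0 * dur_a / tst_s,
        duration_pct_hypopnea=None if airflow_only else 100.0 * dur_h / tst_s,
        duration_pct_total=100.0 * (dur_a + (0.0 if airflow_only else dur_h)) / tst_s,
        sleep_time_assumed=assumed,
    )


@dataclass(frozen=True)
class PipelineResult:
    """Merged events, the report, and per-stage counts for auditing."""

    events: list[RespEvent]
    report: DiagnosticReport
    stage_counts: dict = field(default_factory=dict)


def run_pipeline(
    flow: SampledSignal,
    spo2: SampledSignal | None,
    hypnogram: Hypnogram | None,
    cfg: DetectorConfig | None = None,
) -> PipelineResult:
    """Full automated run: LR -> apneas, SpO2 -> drops, merge, report.

    ``spo2=None`` runs airflow-only (apneas only; hypopnea fields null in
    the report).  ``hypnogram=None`` falls back to the recording span as
    sleep time, flagged in the report.
    """
    cfg = cfg or DetectorConfig()
    lr = local_range(flow, cfg)
    apneas = detect_apnea(lr, cfg)
    if spo2 is not None:
        drops = detect_drops(spo2, cfg)
        events = merge_events(apneas, drops, cfg)
    else:
        drops = []
        events = sorted(apneas, key=lambda e: e.start_s)
    report = compute_report(
        events,
        hypnogram,
        recording_span_s=flow.duration_s,
        airflow_only=spo2 is None,
    )
    counts = {
        "lr_points": len(lr),
        "apneas": len(apneas),
        "spo2_drops": len(drops),
        "hypopneas": sum(1 for e in events if e.type is EventType.HYPOPNEA),
        "merged_events": len(events),
    }
    return PipelineResult(events=events, report=report, stage_counts=counts)
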