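"""Detection of sudden SpO2 drops (oxygen desaturations).

A "sudden drop" runs from an onset t1 at the pre-drop plateau to a nadir t2
and is accepted when two rules hold simultaneously:

1. amplitude: ``Q(t1) - Q(t2) >= min_drop``   (default 3 sat. %, i.e. 0.03), and
2. slope:     ``(Q(t1) - Q(t2)) / (t2 - t1) > k0``   (default 0.001 fraction/s).

The event duration is ``(t2 - t1) + t0``, where ``t0`` is the dwell time of
the desaturation valley -- the time from the nadir until the signal first
rises ``valley_recovery`` (default 1 sat. %) above it.

Units: SpO2 is handled as a saturation *fraction* in [0, 1] and time in
seconds, so ``k0 = 0.001`` means 0.1 percentage points per second -- under
this reading a minimal 3% drop must complete within 30 s, the same horizon
used when attributing desaturations to airflow events.

The scan walks the series maximum-to-nadir: descent tracking tolerates
counter-rises up to ``valley_recovery`` (sensor noise), the onset is then
re-anchored to the last sample within ``onset_tol`` of the pre-nadir
maximum (so a long noisy plateau does not dilute the measured slope), and a
second dip that begins before the signal has recovered ``min_drop / 2``
above the previous nadir extends the previous event instead of opening a
new one (one physiological desaturation, not two).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .signal_model import DetectorConfig, EventType, RespEvent, SampledSignal

__all__ = ["DropEvent", "detect_drops"]


@dataclass(frozen=True)
class DropEvent(RespEvent):
    """A detected SpO2 sudden drop with its anatomy (onset, nadir, valley)."""

    t1_s: float
    t2_s: float
    t0_s: float
    depth: float

    def __init__(self, t1_s: float, t2_s: float, t0_s: float, depth: float):
        object.__setattr__(self, "t1_s", float(t1_s))
        object.__setattr__(self, "t2_s", float(t2_s))
        object.__setattr__(self, "t0_s", float(t0_s))
        object.__setattr__(self, "depth", float(depth))
        duration = (t2_s - t1_s) + t0_s
        RespEvent.__init__(self, EventType.SPO2_DROP, t1_s, t1_s + duration)
        if not self.t1_s < self.t2_s:
            raise ValueError("drop must have t1 < t2")
        if self.t0_s < 0 or self.depth <= 0:
            raise ValueError("drop must have t0 >= 0 and depth > 0")

    @property
    def slope(self) -> float:
        """Mean desaturation slope between onset and nadir, fraction/s."""
        return self.depth / (self.t2_s - self.t1_s)


def _median_filter(x: np.ndarray, width: int) -> np.ndarray:
    if width <= 1:
        return x
    pad = width // 2
    xp = np.pad(x, pad, mode="edge")
    sw = np.lib.stride_tricks.sliding_window_view(xp, width)[: x.size]
    return np.median(sw, axis=1)


def detect_drops(spo2: SampledSignal, cfg: DetectorConfig | None = None) -> list[DropEvent]:
    """Scan an SpO2 series for sudden-drop events satisfying both rules."""
    cfg = cfg or DetectorConfig()
    q = np.asarray(spo2.samples, dtype=float)
    if q.min() < 0.0 or q.max() > 1.0:
        raise ValueError("SpO2 samples must lie in [0, 1]")
    if cfg.spo2_median_filter_s > 0:
        q = _median_filter(q, int(round(cfg.spo2_median_filter_s * spo2.rate)) | 1)
    dt = 1.0 / spo2.rate
    n = q.size

    events: list[DropEvent] = []
    pending: dict | None = None  # candidate that may still be extended by a double dip
    i = 0
    while i < n - 1:
        # advance to the next descent start (q strictly decreases at i -> i+1)
        while i < n - 1 and q[i + 1] >= q[i]:
            i += 1
        if i >= n - 1:
            break
        onset_scan = i
        # descend to the nadir, tolerating counter-rises <= valley_recovery
        j = i + 1
        min_idx, min_val = j, q[j]
        recovered = False
        while j < n - 1:
            j += 1
            if q[j] < min_val:
                min_val, min_idx = q[j], j
            elif q[j] >= min_val + cfg.valley_recovery:
                recovered = True
                break
        cand = {"scan_start": onset_scan, "t2_idx": min_idx, "recovery_idx": j if recovered else n - 1,
                "recovered": recovered}
        if pending is not None:
            inter_max = q[pending["t2_idx"]: min_idx + 1].max()
            if inter_max < q[pending["t2_idx"]] + cfg.min_drop / 2.0:
                # double dip without recovery: extend the pending candidate
                pending = _extend(pending, cand, q)
            else:
                _finalize(pending, q, dt, spo2.t0, cfg, events)
                pending = cand
        else:
            pending = cand
        i = cand["recovery_idx"]
        if i <= onset_scan:  # safety against stalls at the array end
            break
    if pending is not None:
        _finalize(pending, q, dt, spo2.t0, cfg, events)
    return events


def _extend(pending: dict, cand: dict, q: np.ndarray) -> dict:
    """Merge a follow-on dip into the pending candidate (deepest nadir wins)."""
    lo, hi = pending["scan_start"], max(pending["t2_idx"], cand["t2_idx"])
    seg = q[lo: hi + 1]
    t2_idx = lo + int(np.argmin(seg))
    return {
        "scan_start": lo,
        "t2_idx": t2_idx,
        "recovery_idx": cand["recovery_idx"],
        "recovered": cand["recovered"],
    }


def _finalize(cand: dict, q: np.ndarray, dt: float, t_off: float, cfg: DetectorConfig,
              events: list[DropEvent]) -> None:
    """Re-anchor t1, measure the valley, apply both rules, emit if accepted."""
    lo, t2 = cand["scan_start"], cand["t2_idx"]
    if t2 <= lo:
        return
    seg = q[lo: t2 + 1]
    seg_max = seg.max()
    # t1: last pre-nadir sample still at plateau level (within onset_tol of the
    # maximum), then walked back up any monotone descent so that on noiseless
    # traces the onset is exactly the last plateau sample
    at_top = np.flatnonzero(seg[:-1] >= seg_max - cfg.onset_tol)
    if at_top.size == 0:
        return
    k = int(at_top[-1])
    while k > 0 and seg[k - 1] >= seg[k]:
        k -= 1
    t1 = lo + k
    depth = q[t1] - q[t2]
    fall_s = (t2 - t1) * dt
    if fall_s <= 0 or depth < cfg.min_drop or depth / fall_s <= cfg.k0:
        return
    # valley dwell: nadir until the first rise >= valley_recovery above it
    after = q[t2:]
    above = np.flatnonzero(after >= q[t2] + cfg.valley_recovery)
    t0_s = (int(above[0]) if above.size else (q.size - 1 - t2)) * dt
    events.append(DropEvent(t1_s=t_off + t1 * dt, t2_s=t_off + t2 * dt, t0_s=t0_s, depth=depth))
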