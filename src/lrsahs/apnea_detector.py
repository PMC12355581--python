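"""Apnea detection from airflow via local-range (peak-to-peak) analysis.

The local range of the airflow P(t) over a sliding window of length Δt,

    LR(t) = max(P(t .. t+Δt)) - min(P(t .. t+Δt)),

collapses during an apnea, so 1/LR peaks sharply when airflow ceases.  Two
thresholds on 1/LR segment and qualify events: a contiguous region with
1/LR > Ta is one *candidate* event (dense super-Ta peaks belong to a single
apnea), and the candidate is confirmed as an apnea only if it contains at
least one point with 1/LR > Tc.  The event duration is the super-Ta dwell
time plus the window length (the window delays detection by up to Δt, and
Δt equals the 10-s clinical minimum apnea duration):

    ΔT_apnea = ΔT(1/LR > Ta) + Δt.

Candidates whose extended intervals overlap are joined before confirmation,
which keeps detected events disjoint.

The default thresholds ``(Ta, Tc) = (10, 25)`` apply to 1/LR in inverse
device units; :func:`optimize_thresholds` re-derives them on annotated
recordings by minimizing the sum of the overcheck (false-positive) and miss
(false-negative) rates over a grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .signal_model import DetectorConfig, EventType, RespEvent, SampledSignal

__all__ = ["LrSeries", "GridSearchResult", "local_range", "detect_apnea", "optimize_thresholds"]

DEFAULT_TA_GRID = (5.0, 10.0, 15.0, 20.0)
DEFAULT_TC_GRID = (15.0, 20.0, 25.0, 30.0, 35.0)


@dataclass(frozen=True)
class LrSeries:
    """Local-range values on a uniform grid of window start times."""

    values: np.ndarray
    step_s: float
    window_s: float
    start_s: float = 0.0

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", arr)
        if arr.ndim != 1 or arr.size == 0:
            raise ValueError("LR series must be non-empty and 1-D")
        if not np.all(np.isfinite(arr)) or arr.min() < 0:
            raise ValueError("LR values must be finite and >= 0")

    def __len__(self) -> int:
        return int(self.values.size)

    def times(self) -> np.ndarray:
        return self.start_s + np.arange(len(self)) * self.step_s


@dataclass(frozen=True)
class GridSearchResult:
    """Outcome of the (Ta, Tc) grid search."""

    best_ta: float
    best_tc: float
    table: pd.DataFrame  # columns: ta, tc, overcheck_rate, miss_rate, sum_rate


def _round_int(x: float, what: str) -> int:
    n = int(round(x))
    if abs(x - n) > 1e-9 * max(1.0, abs(x)) or n < 1:
        raise ValueError(f"{what} must correspond to a whole positive number of samples, got {x}")
    return n


def local_range(flow: SampledSignal, cfg: DetectorConfig | None = None) -> LrSeries:
    """Sliding peak-to-peak amplitude of the airflow, every ``lr_step_s`` seconds.

    Bit-identical to the naive per-window ``max - min`` loop: when the window
    is a whole multiple of the step, window extrema are assembled exactly
    from per-step block extrema; otherwise a strided view is reduced
    directly.
    """
    cfg = cfg or DetectorConfig()
    x = flow.samples
    win = _round_int(cfg.window_s * flow.rate, "window_s * rate")
    step = _round_int(cfg.lr_step_s * flow.rate, "lr_step_s * rate")
    if len(x) < win:
        raise ValueError(
            f"signal too short for one window: {len(x)} samples < {win} (= {cfg.window_s} s)"
        )
    m = (len(x) - win) // step + 1
    if win % step == 0:
        k = win // step
        nb = m - 1 + k
        blocks = x[: nb * step].reshape(nb, step)
        bmax = blocks.max(axis=1)
        bmin = blocks.min(axis=1)
        wmax = np.lib.stride_tricks.sliding_window_view(bmax, k).max(axis=1)
        wmin = np.lib.stride_tricks.sliding_window_view(bmin, k).min(axis=1)
        lr = wmax - wmin
    else:
        sw = np.lib.stride_tricks.sliding_window_view(x, win)[:: step]
        lr = sw.max(axis=1) - sw.min(axis=1)
    return LrSeries(values=lr, step_s=cfg.lr_step_s, window_s=cfg.window_s, start_s=flow.t0)


def _true_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True, as (first index, last index) inclusive."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1)
    if mask[0]:
        starts = np.r_[0, starts]
    if mask[-1]:
        ends = np.r_[ends, mask.size - 1]
    return list(zip(starts.tolist(), ends.tolist()))


def detect_apnea(lr: LrSeries, cfg: DetectorConfig | None = None) -> list[RespEvent]:
    """Apply the dual-threshold rule to 1/LR and return apnea events.

    Returns disjoint, time-ordered events, each of duration >= ``window_s``.
    """
    cfg = cfg or DetectorConfig()
    inv = 1.0 / np.maximum(lr.values, cfg.lr_floor)
    runs = _true_runs(inv > cfg.ta)
    if not runs:
        return []
    # candidate = run of super-Ta points, extended by the window length;
    # overlapping extensions are dense peaks of one event -> join them
    candidates: list[list[tuple[int, int]]] = []
    for run in runs:
        if candidates and _ext_start(lr, run, cfg) < _ext_end(lr, candidates[-1][-1], cfg):
            candidates[-1].append(run)
        else:
            candidates.append([run])
    events: list[RespEvent] = []
    for group in candidates:
        confirmed = any(np.any(inv[i0 : i1 + 1] > cfg.tc) for i0, i1 in group)
        if not confirmed:
            continue
        start = _ext_start(lr, group[0], cfg)
        end = _ext_end(lr, group[-1], cfg)
        events.append(RespEvent(EventType.APNEA, start, end))
    return events


def _ext_start(lr: LrSeries, run: tuple[int, int], cfg: DetectorConfig) -> float:
    return lr.start_s + run[0] * lr.step_s


def _ext_end(lr: LrSeries, run: tuple[int, int], cfg: DetectorConfig) -> float:
    i0, i1 = run
    dwell = (i1 - i0 + 1) * lr.step_s  # super-Ta dwell time of this run
    return lr.start_s + i0 * lr.step_s + dwell + cfg.window_s


def optimize_thresholds(
    recordings: list[tuple[SampledSignal | LrSeries, list[RespEvent]]],
    ta_grid=DEFAULT_TA_GRID,
    tc_grid=DEFAULT_TC_GRID,
    cfg: DetectorConfig | None = None,
) -> GridSearchResult:
    """Grid search for the (Ta, Tc) pair minimizing overcheck + miss rate.

    Each recording is an (airflow or precomputed LR series, reference apnea
    events) pair.  Rates are pooled over all recordings with the manually
    marked total as denominator for both error types.  Pairs violating
    ``Ta < Tc`` are skipped; ties are broken toward smaller Ta, then Tc.
    """
    from .evaluator import match_events  # local import to avoid a cycle

    cfg = cfg or DetectorConfig()
    if not recordings:
        raise ValueError("no recordings supplied")
    n_ref = sum(len(refs) for _, refs in recordings)
    if n_ref == 0:
        raise ValueError("reference event sets are all empty: error rates undefined")
    lrs = [
        (sig if isinstance(sig, LrSeries) else local_range(sig, cfg), refs)
        for sig, refs in recordings
    ]
    rows = []
    for ta in sorted(ta_grid):
        for tc in sorted(tc_grid):
            if not ta < tc:
                continue
            pair_cfg = DetectorConfig(
                window_s=cfg.window_s, lr_step_s=cfg.lr_step_s, ta=float(ta), tc=float(tc),
                min_drop=cfg.min_drop, k0=cfg.k0, lookback_s=cfg.lookback_s,
                valley_recovery=cfg.valley_recovery, lr_floor=cfg.lr_floor,
                onset_tol=cfg.onset_tol, spo2_median_filter_s=cfg.spo2_median_filter_s,
            )
            fp = fn = 0
            for lr, refs in lrs:
                detected = detect_apnea(lr, pair_cfg)
                m = match_events(detected, refs)
                fp += m.fp
                fn += m.fn
            rows.append(
                {
                    "ta": float(ta),
                    "tc": float(tc),
                    "overcheck_rate": fp / n_ref,
                    "miss_rate": fn / n_ref,
                    "sum_rate": (fp + fn) / n_ref,
                }
            )
    if not rows:
        raise ValueError("grid contains no valid (Ta < Tc) pair")
    table = pd.DataFrame(rows)
    best = min(rows, key=lambda r: (r["sum_rate"], r["ta"], r["tc"]))
    return GridSearchResult(best_ta=best["ta"], best_tc=best["tc"], table=table)
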