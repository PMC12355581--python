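"""Event-by-event and cohort-level scoring of the automated detection.

Scoring vocabulary follows sleep-event practice: an *overcheck* is a false
positive (a non-event reported as an event) and a *miss* is a false
negative.  Detected and reference events are matched one-to-one by greatest
temporal overlap; both the miss rate and the overcheck rate are expressed
relative to the manually marked total, while PPV uses the detected total.
Apnea/hypopnea labels are ignored by default, since both contribute equally
to the AHI; a by-type mode is available for per-type comparisons.

Cohort agreement on per-patient summary variables (AHI, apnea/h,
hypopnea/h, duration %) is quantified with the root mean squared error

    RMSE = sqrt( sum_i (X_i^auto - X_i^manual)^2 / N ).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .diagnoser import compute_report
from .signal_model import EventType, Hypnogram, RespEvent, check_sorted_disjoint

__all__ = ["MatchResult", "CohortStats", "match_events", "rmse", "score_cohort"]


@dataclass(frozen=True)
class MatchResult:
    """Confusion counts and rates of event-by-event scoring."""

    n_ref: int
    tp: int
    fn: int
    fp: int

    def __post_init__(self) -> None:
        if self.tp + self.fn != self.n_ref:
            raise ValueError("tp + fn must equal the number of reference events")
        if min(self.n_ref, self.tp, self.fn, self.fp) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n_det(self) -> int:
        return self.tp + self.fp

    @property
    def sensitivity(self) -> float:
        return self.tp / self.n_ref if self.n_ref else float("nan")

    @property
    def ppv(self) -> float:
        return self.tp / self.n_det if self.n_det else float("nan")

    @property
    def miss_rate(self) -> float:
        return self.fn / self.n_ref if self.n_ref else float("nan")

    @property
    def overcheck_rate(self) -> float:
        return self.fp / self.n_ref if self.n_ref else float("nan")

    def __add__(self, other: "MatchResult") -> "MatchResult":
        return MatchResult(
            n_ref=self.n_ref + other.n_ref,
            tp=self.tp + other.tp,
            fn=self.fn + other.fn,
            fp=self.fp + other.fp,
        )


@dataclass(frozen=True)
class CohortStats:
    """Per-patient automated vs manual values of one summary variable."""

    variable: str
    automated: tuple[float, ...]
    manual: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.automated) != len(self.manual) or len(self.automated) == 0:
            raise ValueError("need equal-length, non-empty paired columns")

    @property
    def rmse(self) -> float:
        return rmse(self.automated, self.manual)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"automated": self.automated, "manual": self.manual})


def rmse(automated: Sequence[float], manual: Sequence[float]) -> float:
    """Root mean squared error between paired per-patient values."""
    if len(automated) != len(manual) or len(automated) == 0:
        raise ValueError("need equal-length, non-empty paired sequences")
    sq = [(a - m) ** 2 for a, m in zip(automated, manual)]
    return math.sqrt(sum(sq) / len(sq))


def match_events(
    detected: Sequence[RespEvent],
    reference: Sequence[RespEvent],
    *,
    by_type: bool = False,
    min_overlap_frac: float = 0.0,
) -> MatchResult:
    """Greedy one-to-one matching of detected to reference events by overlap.

    Pairs are considered in order of decreasing overlap (ties: earlier
    reference, then earlier detection); each event participates in at most
    one match.  ``min_overlap_frac`` optionally requires the overlap to
    cover at least that fraction of the shorter event.  With ``by_type``
    the labels must also agree.
    """
    detected = sorted(detected, key=lambda e: (e.start_s, e.end_s))
    reference = sorted(reference, key=lambda e: (e.start_s, e.end_s))
    check_sorted_disjoint(detected, "detected events")
    check_sorted_disjoint(reference, "reference events")

    pairs: list[tuple[float, float, float, int, int]] = []
    ri = 0
    for di, d in enumerate(detected):
        # references are sorted and disjoint: scan a sliding lower bound
        while ri < len(reference) and reference[ri].end_s <= d.start_s:
            ri += 1
        rj = ri
        while rj < len(reference) and reference[rj].start_s < d.end_s:
            r = reference[rj]
            ov = d.overlap_s(r)
            shorter = min(d.duration_s, r.duration_s)
            if ov > 0 and ov >= min_overlap_frac * shorter:
                if not by_type or d.type == r.type:
                    pairs.append((-ov, r.start_s, d.start_s, rj, di))
            rj += 1
    pairs.sort()
    used_d: set[int] = set()
    used_r: set[int] = set()
    tp = 0
    for _, _, _, rj, di in pairs:
        if di in used_d or rj in used_r:
            continue
        used_d.add(di)
        used_r.add(rj)
        tp += 1
    return MatchResult(
        n_ref=len(reference), tp=tp, fn=len(reference) - tp, fp=len(detected) - tp
    )


def score_cohort(
    pairs: Sequence[tuple[Sequence[RespEvent], Sequence[RespEvent], Hypnogram]],
    *,
    by_type: bool = False,
) -> tuple[MatchResult, dict[str, CohortStats]]:
    """Pool event-by-event counts over patients and compare summary variables.

    Each element is (detected events, reference events, hypnogram).  Returns
    the pooled :class:`MatchResult` and per-variable :class:`CohortStats`
    (``ahi``, ``apnea_per_h``, ``hypopnea_per_h``, ``duration_pct_total``),
    with both columns computed by the same report arithmetic.
    """
    if not pairs:
        raise ValueError("empty cohort")
    pooled = MatchResult(n_ref=0, tp=0, fn=0, fp=0)
    cols: dict[str, tuple[list[float], list[float]]] = {
        "ahi": ([], []),
        "apnea_per_h": ([], []),
        "hypopnea_per_h": ([], []),
        "duration_pct_total": ([], []),
    }
    for detected, reference, hyp in pairs:
        pooled = pooled + match_events(detected, reference, by_type=by_type)
        rep_a = compute_report(detected, hyp)
        rep_m = compute_report(reference, hyp)
        for key, (auto_col, man_col) in cols.items():
            auto_col.append(_report_var(rep_a, key))
            man_col.append(_report_var(rep_m, key))
    stats = {
        key: CohortStats(variable=key, automated=tuple(a), manual=tuple(m))
        for key, (a, m) in cols.items()
    }
    return pooled, stats


def _report_var(rep, key: str) -> float:
    return {
        "ahi": rep.ahi,
        "apnea_per_h": rep.apnea_rate_per_h,
        "hypopnea_per_h": rep.hypopnea_rate_per_h or 0.0,
        "duration_pct_total": rep.duration_pct_total,
    }[key]
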