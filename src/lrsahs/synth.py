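"""Seeded generator of synthetic overnight recordings with ground truth.

Emulates the statistical structure the detector assumes, not respiratory
physiology in detail:

* airflow -- a quasi-periodic oscillation (sinusoid with per-breath period
  and amplitude jitter) whose peak-to-peak amplitude collapses to
  ``apnea_residual_frac`` during apneas (near-complete cessation) and to
  ``hypopnea_residual_frac`` during hypopneas (>50% reduction), plus white
  sensor noise;
* SpO2 -- a high baseline with a trapezoidal desaturation (linear fall,
  flat valley, slower linear recovery) following every event after a short
  patient-like delay, every synthetic drop satisfying the >=3% depth and
  slope rules by construction;
* hypnogram -- 30-s epochs with wake concentrated at sleep onset, offset
  and a few mid-night arousals; events are placed only in sleep;
* flow artifacts -- occasional shallow-breathing spells (moderate amplitude
  reduction with *no* desaturation, excluded from the ground truth).  Real
  airflow contains such non-scored amplitude dips; they are what makes a
  too-permissive confirmation threshold overcheck, so the threshold grid
  search has a genuine optimum.

Amplitude calibration: normal breathing peak-to-peak is 0.2 device units
(1/LR ~ 5, below Ta = 10) and the within-apnea residual is 0.02 units
(1/LR ~ 50 before noise, well above Tc = 25), so the shipped default
thresholds are exercised meaningfully.

All randomness flows from one seed through ``numpy.random.default_rng``;
identical parameters give bit-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .signal_model import (
    EventType,
    Hypnogram,
    RespEvent,
    SampledSignal,
    write_events,
    write_hypnogram,
    write_signal,
)

__all__ = ["SynthParams", "SynthRecording", "generate_recording", "generate_cohort"]

FLOW_RATE_HZ = 200.0
SPO2_RATE_HZ = 10.0
EPOCH_S = 30.0


@dataclass(frozen=True)
class SynthParams:
    """Conditions of one synthetic night.  Units in field names."""

    duration_h: float = 8.0
    seed: int = 0
    breath_freq_hz: float = 0.25
    breath_jitter: float = 0.2        # fractional per-breath period jitter
    amp_jitter: float = 0.15          # fractional per-breath amplitude jitter
    normal_pp_amplitude: float = 0.2  # peak-to-peak, device units
    apnea_residual_frac: float = 0.1
    hypopnea_residual_frac: float = 0.4
    n_apnea: int = 20
    n_hypopnea: int = 10
    event_dur_range_s: tuple[float, float] = (12.0, 60.0)
    spo2_baseline: float = 0.97
    desat_depth_range: tuple[float, float] = (0.03, 0.08)
    desat_delay_range_s: tuple[float, float] = (5.0, 25.0)
    desat_fall_range_s: tuple[float, float] = (10.0, 20.0)
    desat_valley_range_s: tuple[float, float] = (5.0, 20.0)
    desat_recovery_range_s: tuple[float, float] = (20.0, 40.0)
    noise_sd: float = 0.01            # fraction of normal_pp_amplitude
    spo2_noise_sd: float = 0.001      # saturation fraction
    frac_W_epochs: float = 0.1
    n_flow_artifact: int = 15
    artifact_residual_range: tuple[float, float] = (0.18, 0.25)
    artifact_dur_range_s: tuple[float, float] = (12.0, 25.0)
    min_gap_s: float = 75.0

    def __post_init__(self) -> None:
        if not (0 < self.apnea_residual_frac < self.hypopnea_residual_frac < 1):
            raise ValueError("need 0 < apnea residual < hypopnea residual < 1")
        if self.desat_depth_range[0] < 0.03:
            raise ValueError("synthetic desaturations must be >= 3% deep")
        if self.desat_delay_range_s[1] > 30.0:
            raise ValueError("desaturation delay must stay within the 30-s lookback")
        if self.min_gap_s < 60.0:
            raise ValueError("events must be separated by at least 60 s")
        if self.duration_h <= 0 or self.n_apnea < 0 or self.n_hypopnea < 0:
            raise ValueError("invalid duration or event counts")


@dataclass(frozen=True)
class SynthRecording:
    """One generated night: signals, hypnogram, truth, non-event artifacts."""

    flow: SampledSignal
    spo2: SampledSignal
    hypnogram: Hypnogram
    truth: list[RespEvent]
    artifacts: list[tuple[float, float, float]] = field(default_factory=list)
    # artifacts: (start_s, end_s, residual_frac) shallow spells, not ground truth


class GenerationError(RuntimeError):
    """Raised when the requested events cannot be placed in the night."""


def _make_hypnogram(n_ep: int, frac_w: float, rng: np.random.Generator) -> Hypnogram:
    n_w = int(round(frac_w * n_ep))
    labels = np.array(
        rng.choice(["N1", "N2", "N3", "R"], size=n_ep, p=[0.1, 0.5, 0.2, 0.2])
    )
    # wake: sleep-onset block, final-awakening block, a few brief arousals
    n_start = min(n_ep, int(round(0.4 * n_w)))
    n_end = min(n_ep - n_start, int(round(0.2 * n_w)))
    labels[:n_start] = "W"
    if n_end:
        labels[n_ep - n_end:] = "W"
    n_left = n_w - n_start - n_end
    while n_left > 0:
        block = min(n_left, int(rng.integers(1, 4)))
        pos = int(rng.integers(n_start, max(n_start + 1, n_ep - n_end - block)))
        labels[pos: pos + block] = "W"
        n_left -= block
    return Hypnogram(epochs=tuple(labels.tolist()), epoch_s=EPOCH_S)


def _place_intervals(
    durations: list[float],
    sleep_spans: list[tuple[float, float]],
    gap_s: float,
    rng: np.random.Generator,
) -> list[tuple[float, float]]:
    """Randomly place non-overlapping intervals inside sleep, >= gap_s apart."""
    placed: list[tuple[float, float]] = []
    for dur in durations:
        ok_spans = [(a, b) for a, b in sleep_spans if b - a >= dur]
        if not ok_spans:
            raise GenerationError(f"no sleep span can host a {dur:.0f}-s event")
        for _ in range(5000):
            a, b = ok_spans[int(rng.integers(len(ok_spans)))]
            s = float(rng.uniform(a, b - dur))
            e = s + dur
            if all(e + gap_s <= ps or s >= pe + gap_s for ps, pe in placed):
                placed.append((s, e))
                break
        else:
            raise GenerationError(
                f"could not place {len(durations)} events of up to "
                f"{max(durations):.0f} s with {gap_s:.0f}-s gaps; reduce counts"
            )
    return placed


def _breathing(n: int, rate: float, p: SynthParams, rng: np.random.Generator) -> np.ndarray:
    duration = n / rate
    mean_period = 1.0 / p.breath_freq_hz
    n_breaths = int(np.ceil(duration / (mean_period * (1 - p.breath_jitter)))) + 2
    periods = mean_period * (1.0 + rng.uniform(-p.breath_jitter, p.breath_jitter, n_breaths))
    amps = (p.normal_pp_amplitude / 2.0) * (
        1.0 + rng.uniform(-p.amp_jitter, p.amp_jitter, n_breaths)
    )
    starts = np.concatenate([[0.0], np.cumsum(periods)[:-1]])
    t = np.arange(n) / rate
    idx = np.searchsorted(starts, t, side="right") - 1
    phase = 2.0 * np.pi * (t - starts[idx]) / periods[idx]
    return amps[idx] * np.sin(phase)


def generate_recording(p: SynthParams) -> SynthRecording:
    """Generate one night (airflow @200 Hz, SpO2 @10 Hz, hypnogram, truth)."""
    rng = np.random.default_rng(p.seed)
    duration_s = p.duration_h * 3600.0
    n_ep = int(round(duration_s / EPOCH_S))

    hyp = _make_hypnogram(n_ep, p.frac_W_epochs, rng)
    spans = hyp.sleep_spans()
    if not spans and (p.n_apnea + p.n_hypopnea + p.n_flow_artifact) > 0:
        raise GenerationError("hypnogram contains no sleep to place events in")

    # sample durations, place everything jointly, then assign kinds
    kinds = (
        [EventType.APNEA] * p.n_apnea
        + [EventType.HYPOPNEA] * p.n_hypopnea
        + [None] * p.n_flow_artifact
    )
    order = rng.permutation(len(kinds))
    durations = []
    for k in order:
        lo, hi = p.event_dur_range_s if kinds[k] is not None else p.artifact_dur_range_s
        durations.append(float(rng.uniform(lo, hi)))
    intervals = _place_intervals(durations, spans, p.min_gap_s, rng)

    truth: list[RespEvent] = []
    artifacts: list[tuple[float, float, float]] = []
    residuals: list[tuple[float, float, float]] = []  # (start, end, residual frac)
    for k, (s, e) in zip(order, intervals):
        kind = kinds[k]
        if kind is EventType.APNEA:
            truth.append(RespEvent(kind, s, e))
            residuals.append((s, e, p.apnea_residual_frac))
        elif kind is EventType.HYPOPNEA:
            truth.append(RespEvent(kind, s, e))
            residuals.append((s, e, p.hypopnea_residual_frac))
        else:
            r = float(rng.uniform(*p.artifact_residual_range))
            artifacts.append((s, e, r))
            residuals.append((s, e, r))
    truth.sort(key=lambda ev: ev.start_s)
    artifacts.sort()

    # airflow: jittered oscillation x event envelope + sensor noise
    n_flow = int(round(duration_s * FLOW_RATE_HZ))
    flow = _breathing(n_flow, FLOW_RATE_HZ, p, rng)
    env = np.ones(n_flow)
    for s, e, r in residuals:
        env[int(round(s * FLOW_RATE_HZ)): int(round(e * FLOW_RATE_HZ))] = r
    flow = flow * env + rng.normal(0.0, p.noise_sd * p.normal_pp_amplitude, n_flow)

    # SpO2: baseline minus trapezoid desaturations (one per true event)
    n_q = int(round(duration_s * SPO2_RATE_HZ))
    qt = np.arange(n_q) / SPO2_RATE_HZ
    depression = np.zeros(n_q)
    for ev in truth:
        delay = float(rng.uniform(*p.desat_delay_range_s))
        delay = min(delay, 0.8 * ev.duration_s)
        onset = ev.start_s + delay
        fall = float(rng.uniform(*p.desat_fall_range_s))
        valley = float(rng.uniform(*p.desat_valley_range_s))
        recovery = float(rng.uniform(*p.desat_recovery_range_s))
        depth = float(rng.uniform(*p.desat_depth_range))
        xp = [onset, onset + fall, onset + fall + valley, onset + fall + valley + recovery]
        depression = np.maximum(depression, np.interp(qt, xp, [0.0, depth, depth, 0.0]))
    spo2 = p.spo2_baseline - depression + rng.normal(0.0, p.spo2_noise_sd, n_q)
    spo2 = np.clip(spo2, 0.0, 1.0)

    return SynthRecording(
        flow=SampledSignal(flow, FLOW_RATE_HZ, kind="airflow"),
        spo2=SampledSignal(spo2, SPO2_RATE_HZ, kind="spo2"),
        hypnogram=hyp,
        truth=truth,
        artifacts=artifacts,
    )


def generate_cohort(
    n_patients: int,
    base: SynthParams | None = None,
    seed: int = 0,
    outdir: str | Path | None = None,
) -> list[tuple[SynthParams, SynthRecording]]:
    """Generate a cohort of nights with patient-to-patient variability.

    Per-patient seeds are derived from ``seed`` via ``numpy``'s
    ``SeedSequence`` spawning, and event counts / breathing amplitude are
    jittered around the base parameters.  If ``outdir`` is given, each
    patient's signals, hypnogram and truth are written as plain text files
    together with a ``manifest.json``.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    base = base or SynthParams()
    children = np.random.SeedSequence(seed).spawn(n_patients)
    out: list[tuple[SynthParams, SynthRecording]] = []
    manifest = []
    for i, child in enumerate(children):
        pr = np.random.default_rng(child)
        jit_a = max(1, base.n_apnea // 4)
        jit_h = max(1, base.n_hypopnea // 4)
        params = replace(
            base,
            seed=int(child.generate_state(1)[0] % (2**31)),
            n_apnea=max(0, base.n_apnea + int(pr.integers(-jit_a, jit_a + 1))),
            n_hypopnea=max(0, base.n_hypopnea + int(pr.integers(-jit_h, jit_h + 1))),
            normal_pp_amplitude=base.normal_pp_amplitude * float(pr.uniform(0.9, 1.1)),
        )
        rec = generate_recording(params)
        out.append((params, rec))
        if outdir is not None:
            pdir = Path(outdir) / f"patient_{i:03d}"
            pdir.mkdir(parents=True, exist_ok=True)
            write_signal(rec.flow, pdir / "flow.csv")
            write_signal(rec.spo2, pdir / "spo2.csv")
            write_hypnogram(rec.hypnogram, pdir / "hypnogram.txt")
            write_events(rec.truth, pdir / "truth.csv")
            manifest.append(
                {
                    "patient": i,
                    "flow": str(pdir / "flow.csv"),
                    "spo2": str(pdir / "spo2.csv"),
                    "hypnogram": str(pdir / "hypnogram.txt"),
                    "truth": str(pdir / "truth.csv"),
                    "n_apnea": params.n_apnea,
                    "n_hypopnea": params.n_hypopnea,
                }
            )
    if outdir is not None:
        (Path(outdir) / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
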