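"""Venous air embolism detection from the segmented impedance signal.

Two detection modalities, mirroring the two physical presentations of
intravenous air:

* **Blips** — rapid, brief impedance excursions (a large bolus transiting
  the chest): intervals where the raw trace exceeds a rolling-median
  baseline by about one respiratory amplitude, lasting at most a few
  seconds.  An excursion only counts as a blip if its peak also tops the
  neighbouring breath peaks — a sustained level or tidal-volume change
  raises the following breaths too, a bolus does not.

* **Trends** — gradual air entrainment raises the whole signal, so both
  the end-expiratory and the end-inspiratory impedance (EEI, EII) rise
  together across consecutive breaths.  A rise in EII alone is the
  signature of a tidal-volume change; a rise in EEI alone of an unusual
  PEEP-up/TV-down combination.  Paired rises are therefore classified
  ``vae_or_peep`` (the ambiguity with a PEEP increase is surfaced, not
  resolved) and accumulated while consecutive.

When no valid ventilation is present the breath-relative machinery is
blind, and a third path compares the running median of the signal against
a slowly adapting reference baseline: a sustained absolute rise drives the
score directly and bypasses the SQI alarm gate (a silent, unventilated
patient with climbing impedance is exactly the case that must alarm).

The three evidence classes are combined by taking the maximum of their
component scores (each scaled to [0, 100]) rather than their sum, so one
physical event is never double counted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

import numpy as np

from .acquisition import ImpedanceTrace
from .config import AppConfig, DetectionConfig
from .respiratory import CycleSet, analyze_respiration
from .sqi import SQIReport, compute_sqi

__all__ = [
    "BlipEvent",
    "CycleDelta",
    "VAEAssessment",
    "detect_blips",
    "compare_cycles",
    "detect_absolute_rise",
    "vae_score",
    "StreamAnalyzer",
    "run_stream",
    "analyze_trace",
]

#: Shortest excursion counted as a blip (rejects single-sample noise spikes).
_MIN_BLIP_S = 0.05

#: Advisory attached when the paired-rise trend drives the score.
_PAIRED_RISE_ADVISORY = (
    "paired EEI/EII rise: suggests air entrainment or a PEEP increase"
)


@dataclass(frozen=True)
class BlipEvent:
    """A brief impedance excursion above the local baseline."""

    t_onset: float
    t_offset: float
    amplitude: float   #: ohms above the rolling-median baseline
    duration: float    #: seconds

    def as_dict(self) -> dict:
        return {
            "t_onset": self.t_onset,
            "t_offset": self.t_offset,
            "amplitude": self.amplitude,
            "duration": self.duration,
        }


@dataclass(frozen=True)
class CycleDelta:
    """Change in the robust breath summaries between consecutive cycles."""

    d_eei: float
    d_eii: float
    classification: str  #: vae_or_peep | tv_change | peep_tv_edge | stable
    t_prev: float        #: peak time of the earlier cycle
    t_curr: float        #: peak time of the later cycle (used for stream dedup)


@dataclass(frozen=True)
class VAEAssessment:
    """Windowed VAE verdict: score in [0, 100], evidence, alarm state."""

    t_window: float
    score: float
    trend_component: float
    blip_component: float
    absolute_component: float
    alarm: bool
    suppressed: bool          #: score crossed the threshold but SQI vetoed the alarm
    sqi: SQIReport
    events: tuple[BlipEvent, ...]
    deltas: tuple[CycleDelta, ...]
    rate_bpm: float
    cycles_valid: bool
    trend_count: int
    advisory: str = ""

    def as_dict(self) -> dict:
        return {
            "t_window": self.t_window,
            "score": self.score,
            "components": {
                "trend": self.trend_component,
                "blip": self.blip_component,
                "absolute": self.absolute_component,
            },
            "alarm": self.alarm,
            "suppressed": self.suppressed,
            "sqi": {"value": self.sqi.value, **self.sqi.components()},
            "events": [b.as_dict() for b in self.events],
            "rate_bpm": self.rate_bpm,
            "cycles_valid": self.cycles_valid,
            "advisory": self.advisory,
        }


def _rolling_median(z: np.ndarray, rate_hz: float, window_s: float) -> np.ndarray:
    """Rolling median baseline, computed on a decimated grid for speed."""
    stride = max(1, int(round(rate_hz / 20.0)))
    zd = z[::stride]
    w = max(3, int(round(window_s * rate_hz / stride)))
    w = min(w, zd.size)
    if w % 2 == 0:
        w -= 1
    half = w // 2
    padded = np.concatenate((np.full(half, zd[0]), zd, np.full(half, zd[-1])))
    windows = np.lib.stride_tricks.sliding_window_view(padded, w)
    med = np.median(windows, axis=1)
    idx_d = np.arange(zd.size) * stride
    return np.interp(np.arange(z.size), idx_d, med)


def detect_blips(
    trace: ImpedanceTrace,
    cycles: CycleSet,
    cfg: DetectionConfig | None = None,
) -> list[BlipEvent]:
    """Brief excursions above a rolling-median baseline.

    Works on the raw (unsmoothed) window so sharp onsets are preserved.
    The candidate threshold is ``blip_k`` times the median per-breath
    excursion (or an absolute floor when no valid ventilation is present);
    candidates longer than ``max_blip_s`` are not blips — sustained rises
    belong to the trend or absolute paths.  While ventilated, a candidate
    must additionally top the nearest uninvolved breath peak by
    ``blip_peak_margin`` respiratory amplitudes, which rejects the
    transient the baseline makes when a level or tidal-volume step lands.
    Candidate onsets/offsets are refined to the residual's local minima so
    the reported onset tracks the physical rise, not the threshold
    crossing.
    """
    cfg = cfg or DetectionConfig()
    n = len(trace)
    if n < 3:
        return []
    rate = trace.rate_hz
    period = cycles.median_period_s
    win = 2.5 * cfg.max_blip_s
    if np.isfinite(period):
        win = max(win, 1.5 * period)
    baseline = _rolling_median(trace.z, rate, win)
    residual = trace.z - baseline

    amp = cycles.median_amplitude
    ventilated = cycles.valid and np.isfinite(amp) and amp > 0
    thr = cfg.blip_k * amp if ventilated else cfg.blip_floor_ohm

    above = np.concatenate(([False], residual >= thr, [False]))
    d = np.diff(above.astype(np.int8))
    run_starts = np.flatnonzero(d == 1)
    run_ends = np.flatnonzero(d == -1)  # exclusive

    min_len = max(2, int(round(_MIN_BLIP_S * rate)))
    max_len = int(round(cfg.max_blip_s * rate))
    max_walk = int(0.5 * rate)
    # Onset refinement follows the steep excursion edge back from the
    # threshold crossing; the floor keeps it from crawling down the much
    # gentler respiratory rise.
    slope_floor = 0.1 * thr
    blips: list[BlipEvent] = []
    for i0, i1 in zip(run_starts, run_ends):
        if i0 == 0 or i1 >= n:
            continue  # touches the window edge: evidence incomplete, defer
        length = i1 - i0
        if length < min_len or length > max_len:
            continue
        if ventilated:
            ref = _reference_cycle_max(cycles, trace.t[i1 - 1])
            if ref is None:
                continue  # no uninvolved breath follows yet: defer to a later window
            peak_z = float(np.max(trace.z[i0:i1]))
            if peak_z < ref + cfg.blip_peak_margin * amp:
                continue
        j = int(i0)
        while j > 0 and residual[j] - residual[j - 1] > slope_floor and (i0 - j) < max_walk:
            j -= 1
        k = int(i1) - 1
        while k < n - 1 and residual[k] - residual[k + 1] > slope_floor and (k - i1) < max_walk:
            k += 1
        # amplitude against the signal level just before onset: the rolling
        # median sits mid-breath, which would fold the carrier phase into
        # the reported bolus size
        j0 = max(0, j - int(round(0.2 * rate)))
        pre_level = float(np.median(trace.z[j0:j])) if j0 < j else float(trace.z[j])
        blips.append(
            BlipEvent(
                t_onset=float(trace.t[j]),
                t_offset=float(trace.t[k]),
                amplitude=float(np.max(trace.z[i0:i1]) - pre_level),
                duration=float(trace.t[k] - trace.t[j]),
            )
        )
    return blips


def _reference_cycle_max(cycles: CycleSet, t1: float) -> float | None:
    """Peak impedance of the first breath starting after t1.

    Only a *following* breath discriminates: after a sustained level or
    tidal-volume step the next breath peaks as high as the excursion did,
    whereas after a transient bolus it does not.  The preceding breath
    cannot tell the two apart, so a candidate with no following breath in
    the window is deferred (overlapping windows revisit it).
    """
    for c in cycles.cycles:
        if c.t_start >= t1:
            return c.z_max
    return None


def compare_cycles(cycles: CycleSet, tau: float = 0.1) -> list[CycleDelta]:
    """EEI/EII changes between consecutive breaths, classified.

    Paired rises above ``tau`` suggest air entrainment (or a PEEP change);
    an isolated EII change is a tidal-volume signature; an isolated EEI
    rise the uncommon PEEP-up/TV-down edge; anything else is stable.
    """
    out: list[CycleDelta] = []
    cs = cycles.cycles
    for prev, curr in zip(cs[:-1], cs[1:]):
        d_eei = curr.eei - prev.eei
        d_eii = curr.eii - prev.eii
        if d_eei > tau and d_eii > tau:
            cls = "vae_or_peep"
        elif d_eei > tau:
            cls = "peep_tv_edge"
        elif abs(d_eii) > tau:
            cls = "tv_change"
        else:
            cls = "stable"
        out.append(CycleDelta(d_eei, d_eii, cls, prev.t_peak, curr.t_peak))
    return out


def detect_absolute_rise(
    trace: ImpedanceTrace,
    cycles: CycleSet,
    cfg: DetectionConfig | None = None,
    reference: float | None = None,
) -> tuple[float, float]:
    """Absolute-rise component for unventilated signal, plus updated reference.

    Compares a trailing-median profile of the window against a slowly
    adapting reference baseline.  Scaled so a sustained rise equal to
    ``abs_rise_ohm`` reaches the alarm threshold (a rise of twice that
    saturates at 100).  Returns 0 while a valid respiratory signal is
    present — sustained rises are then the trend path's business.  The
    trailing-median span ``abs_confirm_s`` is the confirmation time: a
    transient shorter than half of it cannot move the median and is left
    to the blip path.
    """
    cfg = cfg or DetectionConfig()
    n = len(trace)
    if n < 3:
        return 0.0, reference if reference is not None else float("nan")
    window_median = float(np.median(trace.z))
    if reference is None:
        m = max(3, int(round(cfg.abs_ref_s * trace.rate_hz)))
        reference = float(np.median(trace.z[:m]))
    new_ref = reference + cfg.abs_ref_alpha * (window_median - reference)
    if cycles.valid:
        return 0.0, new_ref
    profile = _rolling_median(trace.z, trace.rate_hz, cfg.abs_confirm_s)
    skip = min(n - 1, int(round(cfg.abs_confirm_s * trace.rate_hz)))
    rise = float(np.max(profile[skip:] - reference)) if skip < n else 0.0
    scale = cfg.alarm_threshold / cfg.abs_rise_ohm
    component = float(np.clip(max(0.0, rise) * scale, 0.0, 100.0))
    return component, new_ref


def _update_trend_count(
    count: int, deltas: Iterable[CycleDelta], cfg: DetectionConfig
) -> int:
    """Consecutive paired-rise counter with dual-threshold hysteresis.

    A run starts only on a full ``vae_or_peep`` classification (both
    summaries up by more than tau) but, once running, continues while both
    keep rising by at least ``trend_continue_frac * tau`` — a gradual
    entrainment whose per-breath rise straddles the threshold should not
    reset the evidence on one marginal breath.  Anything else resets.
    """
    lo = cfg.trend_continue_frac * cfg.trend_tau_ohm
    for d in deltas:
        if d.classification == "vae_or_peep":
            count += 1
        elif count >= 1 and d.d_eei > lo and d.d_eii > lo:
            count += 1
        else:
            count = 0
    return count


def _trend_component(count: int, cfg: DetectionConfig) -> float:
    return 100.0 * min(1.0, count / cfg.trend_saturation_cycles)


def _blip_component(
    blips: Iterable[BlipEvent], resp_amplitude: float, cfg: DetectionConfig
) -> float:
    blips = tuple(blips)
    if not blips:
        return 0.0
    amp_ref = (
        resp_amplitude
        if np.isfinite(resp_amplitude) and resp_amplitude > 0
        else cfg.blip_floor_ohm
    )
    biggest = max(b.amplitude for b in blips)
    return 100.0 * min(1.0, biggest / (cfg.blip_saturation_frac * amp_ref))


def vae_score(
    deltas: Iterable[CycleDelta],
    blips: Iterable[BlipEvent],
    absolute: float,
    sqi: SQIReport,
    cfg: DetectionConfig | None = None,
    sqi_floor: float = 0.3,
    resp_amplitude: float = float("nan"),
    initial_trend_count: int = 0,
    t_window: float = 0.0,
    rate_bpm: float = float("nan"),
    cycles_valid: bool = False,
) -> VAEAssessment:
    """Combine trend, blip and absolute evidence into a scored assessment.

    * trend: consecutive ``vae_or_peep`` deltas (continuing any run carried
      in via ``initial_trend_count``), saturating after
      ``trend_saturation_cycles``;
    * blip: largest blip amplitude relative to the respiratory amplitude
      (or the configured floor when unventilated);
    * absolute: passed through from :func:`detect_absolute_rise`.

    ``score = max(components)``; the alarm requires the score to reach the
    threshold with adequate signal quality, except that the absolute path
    fires regardless of SQI (it exists precisely for windows without a
    trustworthy respiratory signal).  A vetoed alarm is reported with the
    ``suppressed`` flag so the score is never silently hidden.
    """
    cfg = cfg or DetectionConfig()
    deltas = tuple(deltas)
    blips = tuple(blips)

    count = _update_trend_count(initial_trend_count, deltas, cfg)
    trend = _trend_component(count, cfg)
    blip_comp = _blip_component(blips, resp_amplitude, cfg)
    absolute = float(np.clip(absolute, 0.0, 100.0))
    score = float(np.clip(max(trend, blip_comp, absolute), 0.0, 100.0))

    over = score >= cfg.alarm_threshold
    absolute_fired = absolute >= cfg.alarm_threshold
    alarm = (over and sqi.value >= sqi_floor) or absolute_fired
    return VAEAssessment(
        t_window=t_window,
        score=score,
        trend_component=trend,
        blip_component=blip_comp,
        absolute_component=absolute,
        alarm=alarm,
        suppressed=over and not alarm,
        sqi=sqi,
        events=blips,
        deltas=deltas,
        rate_bpm=rate_bpm,
        cycles_valid=cycles_valid,
        trend_count=count,
        advisory=_PAIRED_RISE_ADVISORY if trend >= cfg.alarm_threshold else "",
    )


class StreamAnalyzer:
    """Sliding-window analysis with cross-window alarm and trend state.

    Windows of ``window_s`` advance by ``hop_s``; each complete window runs
    smooth → peaks → validate → segment → SQI → deltas → blips → absolute →
    score.  Because windows are slices of the accumulated sample stream,
    feeding the same recording in chunks of any size yields exactly the
    assessments of a batch run — chunk boundaries are invisible.

    Cross-window state:

    * the consecutive paired-rise count (deltas deduplicated by breath peak
      time, since adjacent windows overlap),
    * the slowly adapting absolute-rise reference baseline,
    * the alarm latch, cleared only after ``hysteresis_windows`` quiet
      windows.
    """

    def __init__(self, config: AppConfig | None = None):
        self.config = config or AppConfig()
        self.config.validate()
        self._t: list[np.ndarray] = []
        self._z: list[np.ndarray] = []
        self._rate: float | None = None
        self._k = 0
        self._trend_count = 0
        self._last_delta_t = -np.inf
        self._abs_ref: float | None = None
        self._alarm_on = False
        self._quiet = 0
        self._finished = False
        self._last_end = -np.inf

    # -- buffering ---------------------------------------------------------

    def _append(self, chunk: ImpedanceTrace):
        if len(chunk) == 0:
            return
        if self._rate is None:
            self._rate = chunk.rate_hz
        elif abs(chunk.rate_hz - self._rate) > 1e-9 * self._rate:
            raise ValueError("chunk sample rate changed mid-stream")
        if self._t and chunk.t[0] <= self._t[-1][-1]:
            raise ValueError("chunks must be contiguous and time-ordered")
        self._t.append(np.asarray(chunk.t, dtype=float))
        self._z.append(np.asarray(chunk.z, dtype=float))

    def _buffer(self) -> ImpedanceTrace:
        return ImpedanceTrace(
            np.concatenate(self._t), np.concatenate(self._z), self._rate
        )

    # -- windowing ---------------------------------------------------------

    def push(self, chunk: ImpedanceTrace) -> list[VAEAssessment]:
        """Feed a chunk; returns assessments for every window it completed."""
        if self._finished:
            raise RuntimeError("stream already finished")
        self._append(chunk)
        if self._rate is None:
            return []
        det = self.config.detection
        dt = 1.0 / self._rate
        t_last = self._t[-1][-1]
        out = []
        while True:
            end = self._k * det.hop_s + det.window_s
            if t_last < end - dt - 1e-9:
                break
            out.append(self._assess(self._k * det.hop_s, end))
            self._k += 1
        return out

    def finish(self) -> list[VAEAssessment]:
        """Flush: assess the final partial window if it is long enough."""
        if self._finished or self._rate is None:
            self._finished = True
            return []
        self._finished = True
        det = self.config.detection
        t0 = self._k * det.hop_s
        t_end = self._t[-1][-1] + 1.0 / self._rate
        if t_end - t0 >= det.min_window_s and t_end > self._last_end + 1e-9:
            return [self._assess(t0, t_end)]
        return []

    # -- per-window pipeline ------------------------------------------------

    def _assess(self, t0: float, t1: float) -> VAEAssessment:
        det = self.config.detection
        self._last_end = t1
        raw = self._buffer().slice(t0, t1)
        smoothed, cycles = analyze_respiration(
            raw, self.config.smoothing, self.config.peaks, self.config.rate
        )
        sqi = compute_sqi(raw, cycles, self.config.sqi)
        deltas = compare_cycles(cycles, det.trend_tau_ohm) if cycles.valid else []
        # overlapping windows re-see most breaths: only deltas whose later
        # breath is new advance the consecutive-rise count
        new = [d for d in deltas if d.t_curr > self._last_delta_t + 1.0]
        if new:
            self._trend_count = _update_trend_count(self._trend_count, new, det)
            self._last_delta_t = new[-1].t_curr
        blips = detect_blips(raw, cycles, det)
        absolute, self._abs_ref = detect_absolute_rise(raw, cycles, det, self._abs_ref)

        trend = _trend_component(self._trend_count, det)
        blip_comp = _blip_component(blips, cycles.median_amplitude, det)
        absolute = float(np.clip(absolute, 0.0, 100.0))
        score = float(np.clip(max(trend, blip_comp, absolute), 0.0, 100.0))

        over = score >= det.alarm_threshold
        absolute_fired = absolute >= det.alarm_threshold
        eligible = (over and sqi.value >= self.config.sqi.floor) or absolute_fired
        if eligible:
            self._alarm_on = True
            self._quiet = 0
        elif self._alarm_on:
            self._quiet += 1
            if self._quiet >= det.hysteresis_windows:
                self._alarm_on = False
                self._quiet = 0
        return VAEAssessment(
            t_window=t1,
            score=score,
            trend_component=trend,
            blip_component=blip_comp,
            absolute_component=absolute,
            alarm=self._alarm_on,
            suppressed=over and not eligible,
            sqi=sqi,
            events=tuple(blips),
            deltas=tuple(deltas),
            rate_bpm=cycles.rate_bpm,
            cycles_valid=cycles.valid,
            trend_count=self._trend_count,
            advisory=_PAIRED_RISE_ADVISORY if trend >= det.alarm_threshold else "",
        )


def run_stream(
    chunks: Iterable[ImpedanceTrace],
    config: AppConfig | None = None,
) -> Iterator[VAEAssessment]:
    """Analyze a chunk stream; yields assessments as windows complete."""
    analyzer = StreamAnalyzer(config)
    for chunk in chunks:
        yield from analyzer.push(chunk)
    yield from analyzer.finish()


def analyze_trace(
    trace: ImpedanceTrace,
    config: AppConfig | None = None,
) -> list[VAEAssessment]:
    """Batch analysis: identical to streaming the trace in one chunk."""
    analyzer = StreamAnalyzer(config)
    out = analyzer.push(trace)
    out.extend(analyzer.finish())
    return out
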