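"""Respiratory-cycle tracking in chest impedance.

Lung air volume dominates the time-varying part of trans-thoracic
impedance, so each mechanical breath appears as a 5–10 ohm oscillation on
top of a large static baseline.  This module recovers that structure:

1. a trailing running average suppresses sample noise,
2. continuous-wavelet ridge detection finds end-inspiratory peaks,
3. inter-peak intervals are checked against the plausible surgical
   ventilation band (6–30 breaths/minute) and a regularity gate,
4. the trace is cut into breaths at the troughs between validated peaks
   and each breath is summarised robustly.

Per breath we keep the minimum, maximum and the 25th/75th percentile of
the samples.  The quartiles serve as noise-robust estimates of the
end-expiratory and end-inspiratory impedance (EEI := p25, EII := p75):
inspiration inflates the lungs and raises impedance, so the upper quartile
tracks the inspiratory plateau and the lower quartile the expiratory one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy.signal import find_peaks

from .acquisition import ImpedanceTrace, InvalidConfigurationError
from .config import PeaksConfig, RateConfig, SmoothingConfig

__all__ = [
    "RespiratoryCycle",
    "CycleSet",
    "smooth",
    "detect_peaks",
    "validate_rate",
    "segment_cycles",
    "analyze_respiration",
]


@dataclass(frozen=True)
class RespiratoryCycle:
    """One segmented breath (trough to trough, containing one peak).

    ``z_p25`` and ``z_p75`` are the robust end-expiratory / end-inspiratory
    impedance estimates (EEI / EII) for the breath.
    """

    t_start: float
    t_end: float
    t_peak: float
    z_min: float
    z_max: float
    z_p25: float
    z_p75: float
    n_samples: int

    @property
    def duration_s(self) -> float:
        return self.t_end - self.t_start

    @property
    def eei(self) -> float:
        """End-expiratory impedance estimate (lower quartile)."""
        return self.z_p25

    @property
    def eii(self) -> float:
        """End-inspiratory impedance estimate (upper quartile)."""
        return self.z_p75

    @property
    def amplitude(self) -> float:
        """Peak-to-trough excursion of the breath, ohms."""
        return self.z_max - self.z_min


@dataclass(frozen=True)
class CycleSet:
    """Segmented breaths plus the rate-validation verdict for a window."""

    cycles: tuple[RespiratoryCycle, ...]
    rate_bpm: float          #: breaths/minute from the median inter-peak interval (nan if invalid)
    valid: bool              #: True iff a plausible, regular respiratory signal was found
    peak_times: tuple[float, ...] = field(default=())

    def __len__(self) -> int:
        return len(self.cycles)

    @property
    def median_amplitude(self) -> float:
        """Median per-breath peak-to-trough excursion, ohms (nan if no cycles)."""
        if not self.cycles:
            return float("nan")
        return float(np.median([c.amplitude for c in self.cycles]))

    @property
    def median_period_s(self) -> float:
        if len(self.peak_times) < 2:
            return float("nan")
        return float(np.median(np.diff(self.peak_times)))


INVALID_CYCLESET = CycleSet(cycles=(), rate_bpm=float("nan"), valid=False)


def smooth(trace: ImpedanceTrace, cfg: SmoothingConfig | None = None) -> ImpedanceTrace:
    """Trailing running average: out(t) = mean of samples in (t − window, t].

    Causal by construction (a "time-delayed" average): the reported value at
    each time uses only samples already seen.  During the first ``window_s``
    seconds fewer samples are available and the mean is taken over what
    exists; that span is recorded as ``meta["warmup_s"]``.
    """
    cfg = cfg or SmoothingConfig()
    cfg.validate()
    n = len(trace)
    if n == 0:
        raise InvalidConfigurationError("cannot smooth an empty trace")
    w = max(1, int(round(cfg.window_s * trace.rate_hz)))
    if w >= n:
        raise InvalidConfigurationError(
            f"smoothing window {cfg.window_s} s is not shorter than the trace"
        )
    csum = np.concatenate(([0.0], np.cumsum(trace.z)))
    idx = np.arange(n)
    lo = np.maximum(0, idx - w + 1)
    out = (csum[idx + 1] - csum[lo]) / (idx + 1 - lo)
    meta = dict(trace.meta)
    meta["warmup_s"] = cfg.window_s
    meta["smoothing_window_s"] = cfg.window_s
    t = trace.t if cfg.delay_s == 0 else trace.t + cfg.delay_s
    return ImpedanceTrace(t, out, trace.rate_hz, meta)


def _cwt_ridge(z: np.ndarray, rate_hz: float, cfg: PeaksConfig) -> tuple[np.ndarray, np.ndarray]:
    """CWT coefficients at the dominant respiratory scale, with reflection padding.

    Returns (ridge row over the original samples, scale period in seconds).
    """
    dt = 1.0 / rate_hz
    # scan beyond the validation band so an out-of-band rhythm is seen at
    # its true period and rejected, rather than aliased onto a subharmonic
    # that happens to fall inside the band
    periods = np.geomspace(cfg.min_period_s / 1.5, cfg.max_period_s * 1.3, cfg.n_scales)
    fc = pywt.central_frequency("mexh")
    scales = fc * periods / dt
    pad = int(round(cfg.max_period_s * rate_hz))
    pad = min(pad, len(z) - 1)
    padded = np.concatenate((z[pad:0:-1], z, z[-2:-2 - pad:-1])) if pad else z
    coef, _ = pywt.cwt(padded, scales, "mexh", sampling_period=dt, method="fft")
    if pad:
        coef = coef[:, pad:pad + len(z)]
    # median (not total) energy across time: a sustained rhythm keeps its
    # scale's coefficients high throughout, a lone transient does not
    energy = np.median(coef**2, axis=1)
    k = int(np.argmax(energy))
    return coef[k], periods[k]


def detect_peaks(smoothed: ImpedanceTrace, cfg: PeaksConfig | None = None) -> np.ndarray:
    """End-inspiratory peak times via continuous-wavelet ridge detection.

    The trace is correlated with a Mexican-hat wavelet over scales spanning
    the 2–10 s breath-period band; local maxima of the dominant-scale
    coefficients mark breaths.  Ridge peaks far below the typical ridge
    height are discarded (they are noise excursions, not breaths), each
    surviving peak is refined to the local maximum of the trace itself, and
    peaks closer than the minimum period are merged keeping the higher one
    (ties broken toward the earlier peak).
    """
    cfg = cfg or PeaksConfig()
    cfg.validate()
    n = len(smoothed)
    rate = smoothed.rate_hz
    if n < 2 or n < int(cfg.max_period_s * rate):
        return np.array([])
    z = smoothed.z - float(np.mean(smoothed.z))
    if np.ptp(z) == 0:
        return np.array([])
    # clip against a robust envelope so one large transient (an air bolus)
    # cannot drag the dominant wavelet scale away from the breathing rhythm;
    # the respiratory oscillation itself sits well inside 2.5 IQRs
    med = float(np.median(z))
    iqr = float(np.percentile(z, 75) - np.percentile(z, 25))
    if iqr > 0:
        z = np.clip(z, med - 2.5 * iqr, med + 2.5 * iqr)
    row, period = _cwt_ridge(z, rate, cfg)
    # merge distance adapts to the dominant period (half a period) but
    # never exceeds the configured minimum breath length
    min_dist = max(1, int(round(min(cfg.min_period_s, 0.5 * period) * rate)))
    idx, props = find_peaks(row, distance=min_dist, height=0.0)
    if idx.size == 0:
        return np.array([])
    heights = props["peak_heights"]
    # median reference: robust both to one huge outlier (a bolus excursion
    # must not mask the ordinary breaths) and to a few tiny ridge wiggles
    ref = np.median(heights)
    keep = heights >= cfg.height_frac * ref
    idx = idx[keep]
    # refine to the local maximum of the signal itself
    half = max(1, int(round(0.25 * period * rate)))
    refined = []
    for i in idx:
        lo, hi = max(0, i - half), min(n, i + half + 1)
        refined.append(lo + int(np.argmax(smoothed.z[lo:hi])))
    refined = sorted(set(refined))
    # merge peaks closer than the minimum period, keeping the higher
    merged: list[int] = []
    for i in refined:
        if merged and (i - merged[-1]) < min_dist:
            if smoothed.z[i] > smoothed.z[merged[-1]]:
                merged[-1] = i
        else:
            merged.append(i)
    return smoothed.t[np.array(merged, dtype=int)]


def validate_rate(
    peaks: np.ndarray, cfg: RateConfig | None = None
) -> tuple[bool, float]:
    """Check peak spacing against the plausible ventilation band.

    Valid iff at least 3 peaks were found, the median inter-peak interval
    lies within the band (6–30 bpm ⇒ 2–10 s), and the intervals are regular
    (median absolute deviation at most ``regularity_mad_frac`` of the
    median).  Returns ``(valid, rate_bpm)``; the rate is NaN when invalid.
    """
    cfg = cfg or RateConfig()
    cfg.validate()
    peaks = np.asarray(peaks, dtype=float)
    if peaks.size < 3:
        return False, float("nan")
    intervals = np.diff(peaks)
    med = float(np.median(intervals))
    if med <= 0:
        return False, float("nan")
    rate_bpm = 60.0 / med
    tol = cfg.band_tol_frac
    if not (cfg.min_bpm * (1 - tol) <= rate_bpm <= cfg.max_bpm * (1 + tol)):
        return False, float("nan")
    mad = float(np.median(np.abs(intervals - med)))
    if mad > cfg.regularity_mad_frac * med:
        return False, float("nan")
    return True, rate_bpm


def segment_cycles(
    smoothed: ImpedanceTrace,
    peaks: np.ndarray,
    rate_cfg: RateConfig | None = None,
) -> CycleSet:
    """Cut the trace into breaths at the expiratory rests between peaks.

    Each cycle contains exactly one end-inspiratory peak, so its upper
    quartile estimates EII and its lower quartile EEI.  The boundary
    between two breaths is placed at the time midpoint between their
    peaks: for a symmetric waveform this is the trough, and when
    expiration ends in a flat rest (typical of mechanical ventilation) it
    falls inside that rest while remaining deterministic — the literal
    sample minimum wanders anywhere within the rest under noise, which
    would jitter every per-cycle percentile.  Cycles with implausible
    durations (outside the 2–10 s breath band) are discarded.  Percentiles
    use linear interpolation between order statistics.
    """
    rate_cfg = rate_cfg or RateConfig()
    valid, rate_bpm = validate_rate(peaks, rate_cfg)
    peaks = np.asarray(peaks, dtype=float)
    if peaks.size < 2:
        return CycleSet((), rate_bpm, valid, tuple(peaks))
    t, z = smoothed.t, smoothed.z
    peak_idx = np.searchsorted(t, peaks)
    peak_idx = np.clip(peak_idx, 0, len(t) - 1)
    troughs = []
    for a, b in zip(peak_idx[:-1], peak_idx[1:]):
        if b - a < 2:
            continue
        troughs.append((a + b) // 2)
    # duration gate with slack so breaths at the band edges, jittered by
    # noise, are not discarded
    min_d = 0.7 * 60.0 / rate_cfg.max_bpm
    max_d = 1.3 * 60.0 / rate_cfg.min_bpm
    cycles = []
    for i0, i1 in zip(troughs[:-1], troughs[1:]):
        seg = z[i0:i1 + 1]
        dur = t[i1] - t[i0]
        if not (min_d <= dur <= max_d) or seg.size < 3:
            continue
        inner = peaks[(peaks > t[i0]) & (peaks <= t[i1])]
        t_pk = float(inner[np.argmax(np.interp(inner, t, z))]) if inner.size else float(
            t[i0 + int(np.argmax(seg))]
        )
        cycles.append(
            RespiratoryCycle(
                t_start=float(t[i0]),
                t_end=float(t[i1]),
                t_peak=t_pk,
                z_min=float(np.min(seg)),
                z_max=float(np.max(seg)),
                z_p25=float(np.percentile(seg, 25)),
                z_p75=float(np.percentile(seg, 75)),
                n_samples=int(seg.size),
            )
        )
    valid = valid and len(cycles) >= 1
    return CycleSet(tuple(cycles), rate_bpm, valid, tuple(peaks))


def analyze_respiration(
    trace: ImpedanceTrace,
    smoothing: SmoothingConfig | None = None,
    peaks_cfg: PeaksConfig | None = None,
    rate_cfg: RateConfig | None = None,
) -> tuple[ImpedanceTrace, CycleSet]:
    """Convenience pipeline: smooth → detect peaks → validate → segment.

    Adds an amplitude-significance gate on top of the rate validation: a
    "respiratory" waveform whose per-breath excursion is below an absolute
    floor, or not well clear of the raw-trace noise floor, is band-passed
    noise, not ventilation, and the cycle set is marked invalid.
    """
    rate_cfg = rate_cfg or RateConfig()
    sm = smooth(trace, smoothing)
    pk = detect_peaks(sm, peaks_cfg)
    cycles = segment_cycles(sm, pk, rate_cfg)
    if cycles.valid:
        from .sqi import noise_sigma  # local import avoids a module cycle

        amp = cycles.median_amplitude
        floor = max(rate_cfg.min_amplitude_ohm,
                    rate_cfg.min_amplitude_snr * noise_sigma(trace))
        if not np.isfinite(amp) or amp < floor:
            cycles = CycleSet(cycles.cycles, cycles.rate_bpm, False, cycles.peak_times)
    return sm, cycles
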