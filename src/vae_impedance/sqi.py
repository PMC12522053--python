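"""Signal quality index (SQI) gating the VAE alarm.

A heuristic [0, 1] summary of whether the impedance signal is trustworthy,
in the spirit of the quality indices used by automated pulse oximetry and
EEG monitors.  Five named components are combined as a weighted mean:

``presence``     a plausible, regular respiratory waveform was found;
``regularity``   inter-peak interval consistency;
``amplitude``    respiratory excursion relative to the sample noise floor;
``robustness``   agreement of the quartile summaries with the per-cycle
                 extrema (quartiles far inside the min–max range indicate
                 spiky, artifact-laden cycles);
``consistency``  stability of the per-cycle EEI/EII summaries across the
                 analysis window.

Waveform presence and summary consistency carry the largest weights — they
are the strongest indicators that the breath segmentation the detector
relies on is real.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .acquisition import ImpedanceTrace
from .config import SQIConfig
from .respiratory import CycleSet

__all__ = ["SQIReport", "compute_sqi", "noise_sigma"]

#: Quartile-vs-extrema gap fraction of an ideal sampled sinusoid:
#: ((p25 - min) + (max - p75)) / (max - min) = 2 * (0.5 - cos(pi/4)/2).
_IDEAL_GAP_FRACTION = 1.0 - np.sqrt(2.0) / 2.0

#: Excess gap fraction (beyond the sinusoidal ideal) that zeroes robustness.
_GAP_SCALE = 0.5

#: Normalised EEI/EII dispersion that zeroes consistency.
_DISPERSION_SCALE = 0.5


@dataclass(frozen=True)
class SQIReport:
    value: float
    c_presence: float
    c_regularity: float
    c_amplitude: float
    c_robustness: float
    c_consistency: float

    def components(self) -> dict:
        return {
            "presence": self.c_presence,
            "regularity": self.c_regularity,
            "amplitude": self.c_amplitude,
            "robustness": self.c_robustness,
            "consistency": self.c_consistency,
        }


def noise_sigma(trace: ImpedanceTrace) -> float:
    """Noise floor estimate from the unsmoothed trace, ohms.

    Median absolute successive difference scaled to a Gaussian sigma
    (successive differences of white noise have sigma*sqrt(2); the median
    of a half-normal is 0.6745 sigma).  Robust to the slow respiratory
    component, which contributes little sample-to-sample change at 100 Hz.
    """
    if len(trace) < 3:
        return 0.0
    mad = float(np.median(np.abs(np.diff(trace.z))))
    return mad / (0.6745 * np.sqrt(2.0))


def _clip01(x: float) -> float:
    return float(min(1.0, max(0.0, x)))


def compute_sqi(
    trace: ImpedanceTrace,
    cycles: CycleSet,
    cfg: SQIConfig | None = None,
) -> SQIReport:
    """Compute the SQI for one analysis window.

    ``trace`` should be the raw (unsmoothed) window — the noise floor is
    estimated from it — while ``cycles`` comes from the smoothed pipeline.
    Degenerate cycles (zero excursion) score 0 on amplitude and robustness.
    """
    cfg = cfg or SQIConfig()
    cfg.validate()

    presence = 1.0 if cycles.valid else 0.0

    peaks = np.asarray(cycles.peak_times, dtype=float)
    if peaks.size >= 3:
        intervals = np.diff(peaks)
        med = float(np.median(intervals))
        mad = float(np.median(np.abs(intervals - med)))
        regularity = _clip01(1.0 - mad / (0.25 * med)) if med > 0 else 0.0
    else:
        regularity = 0.0

    sigma = noise_sigma(trace)
    amp = cycles.median_amplitude
    # without a credible respiratory waveform the per-breath summaries
    # describe pseudo-cycles cut from noise; the components derived from
    # them carry no quality information and gate to zero
    if not cycles.valid or not cycles.cycles or not np.isfinite(amp) or amp <= 0:
        amplitude = 0.0
        robustness = 0.0
        consistency = 0.0
    else:
        snr = amp / sigma if sigma > 0 else np.inf
        amplitude = _clip01(snr / cfg.snr_saturation)

        gaps = []
        for c in cycles.cycles:
            rng = c.z_max - c.z_min
            if rng <= 0:
                gaps.append(1.0)
                continue
            gaps.append(((c.z_p25 - c.z_min) + (c.z_max - c.z_p75)) / rng)
        excess = max(0.0, float(np.mean(gaps)) - _IDEAL_GAP_FRACTION)
        robustness = _clip01(1.0 - excess / _GAP_SCALE)

        eei = np.array([c.eei for c in cycles.cycles])
        eii = np.array([c.eii for c in cycles.cycles])
        if eei.size >= 2:
            disp = (float(np.std(eei)) + float(np.std(eii))) / (2.0 * amp)
            consistency = _clip01(1.0 - disp / _DISPERSION_SCALE)
        else:
            consistency = 0.0

    w = cfg.weights
    value = (
        w.presence * presence
        + w.regularity * regularity
        + w.amplitude * amplitude
        + w.robustness * robustness
        + w.consistency * consistency
    )
    return SQIReport(
        value=_clip01(value),
        c_presence=presence,
        c_regularity=regularity,
        c_amplitude=amplitude,
        c_robustness=robustness,
        c_consistency=consistency,
    )
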