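"""Application configuration: nested defaults, YAML loading, validation.

Every tunable threshold of the pipeline lives here so that a single YAML
file documents a deployment.  Unknown keys are rejected rather than
ignored — a typo in an alarm threshold must not silently fall back to a
default.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, is_dataclass, replace
from typing import Any

import yaml

__all__ = [
    "ConfigError",
    "SmoothingConfig",
    "PeaksConfig",
    "RateConfig",
    "DetectionConfig",
    "SQIConfig",
    "SimulateConfig",
    "AppConfig",
    "load_config",
]


class ConfigError(ValueError):
    """Invalid or unknown configuration content."""


@dataclass(frozen=True)
class SmoothingConfig:
    """Trailing (causal) running average applied before peak detection."""

    window_s: float = 0.5   #: averaging window, seconds
    delay_s: float = 0.0    #: additional reporting delay, seconds

    def validate(self):
        if self.window_s <= 0:
            raise ConfigError("smoothing.window_s must be positive")
        if self.delay_s < 0:
            raise ConfigError("smoothing.delay_s must be >= 0")


@dataclass(frozen=True)
class PeaksConfig:
    """Wavelet peak detection over the plausible breath-period band."""

    min_period_s: float = 2.0    #: shortest plausible breath (30 bpm)
    max_period_s: float = 10.0   #: longest plausible breath (6 bpm)
    n_scales: int = 16           #: log-spaced wavelet scales across the band
    height_frac: float = 0.4     #: drop ridge peaks below this fraction of the
                                 #: median ridge peak height

    def validate(self):
        if not 0 < self.min_period_s < self.max_period_s:
            raise ConfigError("peaks: need 0 < min_period_s < max_period_s")
        if self.n_scales < 2:
            raise ConfigError("peaks.n_scales must be >= 2")
        if not 0 <= self.height_frac < 1:
            raise ConfigError("peaks.height_frac must be in [0, 1)")


@dataclass(frozen=True)
class RateConfig:
    """Respiratory-rate plausibility band and regularity gate."""

    min_bpm: float = 6.0
    max_bpm: float = 30.0
    regularity_mad_frac: float = 0.25  #: MAD(intervals) <= frac * median
    band_tol_frac: float = 0.05        #: slack on the band edges, so a rate truly
                                       #: at 6 or 30 bpm does not flap in and out
                                       #: of validity under estimator jitter
    min_amplitude_ohm: float = 0.5     #: smallest credible respiratory excursion
    min_amplitude_snr: float = 3.0     #: excursion must exceed this multiple of the noise floor

    def validate(self):
        if not 0 < self.min_bpm < self.max_bpm:
            raise ConfigError("rate: need 0 < min_bpm < max_bpm")
        if self.regularity_mad_frac <= 0:
            raise ConfigError("rate.regularity_mad_frac must be positive")
        if self.min_amplitude_ohm < 0 or self.min_amplitude_snr < 0:
            raise ConfigError("rate: amplitude gates must be >= 0")


@dataclass(frozen=True)
class DetectionConfig:
    """Blip, trend and absolute-rise detection plus alarm policy."""

    trend_tau_ohm: float = 0.1        #: per-cycle EEI/EII change threshold
    trend_continue_frac: float = 0.5  #: hysteresis: once a paired-rise run has started,
                                      #: it continues at this fraction of the threshold
    trend_saturation_cycles: int = 6  #: consecutive paired rises saturating the trend score
    max_blip_s: float = 3.0           #: longest excursion still counted a blip
    blip_k: float = 1.0               #: candidate threshold, fraction of resp amplitude
    blip_peak_margin: float = 0.5     #: excursion peak must top the neighbouring
                                      #: breath peak by this fraction of resp amplitude
    blip_floor_ohm: float = 1.0       #: amplitude floor when no valid ventilation
    blip_saturation_frac: float = 2.0 #: blip amplitude (in resp amplitudes) scoring 100
    abs_rise_ohm: float = 1.0         #: sustained unventilated rise reaching the alarm threshold
    abs_confirm_s: float = 1.5        #: trailing median span confirming a sustained rise
    abs_ref_s: float = 5.0            #: initial span used to seed the reference baseline
    abs_ref_alpha: float = 0.2        #: per-window adaptation rate of the reference
    alarm_threshold: float = 50.0     #: score at or above which the alarm is raised
    hysteresis_windows: int = 2       #: quiet windows required to clear an alarm
    window_s: float = 30.0            #: sliding analysis window length
    hop_s: float = 5.0                #: window advance per assessment
    min_window_s: float = 10.0        #: shortest window worth assessing

    def validate(self):
        for name in ("trend_tau_ohm", "max_blip_s", "blip_k", "blip_floor_ohm",
                     "abs_rise_ohm", "abs_confirm_s", "abs_ref_s", "alarm_threshold",
                     "window_s", "hop_s", "min_window_s", "blip_saturation_frac"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"detection.{name} must be positive")
        if self.trend_saturation_cycles < 1 or self.hysteresis_windows < 1:
            raise ConfigError("detection: saturation and hysteresis must be >= 1")
        if not 0 < self.abs_ref_alpha <= 1:
            raise ConfigError("detection.abs_ref_alpha must be in (0, 1]")
        if not 0 < self.trend_continue_frac <= 1:
            raise ConfigError("detection.trend_continue_frac must be in (0, 1]")
        if self.hop_s > self.window_s:
            raise ConfigError("detection.hop_s must not exceed window_s")
        if self.min_window_s > self.window_s:
            raise ConfigError("detection.min_window_s must not exceed window_s")


@dataclass(frozen=True)
class SQIWeights:
    presence: float = 0.35
    regularity: float = 0.20
    amplitude: float = 0.20
    robustness: float = 0.10
    consistency: float = 0.15

    def validate(self):
        vals = [self.presence, self.regularity, self.amplitude,
                self.robustness, self.consistency]
        if any(v < 0 for v in vals):
            raise ConfigError("sqi.weights must be non-negative")
        if abs(sum(vals) - 1.0) > 1e-9:
            raise ConfigError("sqi.weights must sum to 1")


@dataclass(frozen=True)
class SQIConfig:
    """Signal quality index weights and alarm-suppression floor."""

    weights: SQIWeights = field(default_factory=SQIWeights)
    floor: float = 0.3           #: alarms suppressed (flagged) below this value
    snr_saturation: float = 20.0 #: respiratory amplitude / noise sigma scoring 1

    def validate(self):
        self.weights.validate()
        if not 0 <= self.floor <= 1:
            raise ConfigError("sqi.floor must be in [0, 1]")
        if self.snr_saturation <= 0:
            raise ConfigError("sqi.snr_saturation must be positive")


@dataclass(frozen=True)
class SimulateConfig:
    """Defaults for the synthetic trace generator (CLI convenience)."""

    duration_s: float = 120.0
    rate_hz: float = 100.0
    baseline_ohm: float = 250.0
    resp_rate_bpm: float = 12.0
    resp_amplitude_ohm: float = 7.0
    resp_shape: str = "skewed"
    noise_sigma_ohm: float = 0.2
    seed: int = 0

    def validate(self):
        if self.duration_s <= 0 or self.rate_hz <= 0:
            raise ConfigError("simulate: duration_s and rate_hz must be positive")
        if self.resp_amplitude_ohm < 0 or self.noise_sigma_ohm < 0:
            raise ConfigError("simulate: amplitudes must be >= 0")
        if not 0 <= self.resp_rate_bpm <= 60:
            raise ConfigError("simulate.resp_rate_bpm must be in [0, 60]")
        if self.resp_shape not in ("sinusoid", "skewed"):
            raise ConfigError("simulate.resp_shape must be 'sinusoid' or 'skewed'")


@dataclass(frozen=True)
class AppConfig:
    smoothing: SmoothingConfig = field(default_factory=SmoothingConfig)
    peaks: PeaksConfig = field(default_factory=PeaksConfig)
    rate: RateConfig = field(default_factory=RateConfig)
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    sqi: SQIConfig = field(default_factory=SQIConfig)
    simulate: SimulateConfig = field(default_factory=SimulateConfig)

    def validate(self):
        for f in fields(self):
            getattr(self, f.name).validate()


def _merge(obj: Any, data: dict, path: str) -> Any:
    if not isinstance(data, dict):
        raise ConfigError(f"{path or 'config'}: expected a mapping, got {type(data).__name__}")
    known = {f.name: f for f in fields(obj)}
    updates = {}
    for key, value in data.items():
        if key not in known:
            raise ConfigError(f"unknown config key '{path + key}'")
        current = getattr(obj, key)
        if is_dataclass(current):
            updates[key] = _merge(current, value, f"{path}{key}.")
        else:
            if isinstance(value, bool) or not isinstance(value, (int, float, str)):
                if value is not None:
                    raise ConfigError(f"config key '{path + key}': unsupported value {value!r}")
            updates[key] = value
    return replace(obj, **updates)


def config_from_dict(data: dict | None) -> AppConfig:
    """Build an :class:`AppConfig` from a (possibly partial) nested mapping."""
    cfg = AppConfig()
    if data:
        cfg = _merge(cfg, data, "")
    cfg.validate()
    return cfg


def load_config(path: str | None) -> AppConfig:
    """Load a YAML config file; ``None`` returns the defaults."""
    if path is None:
        cfg = AppConfig()
        cfg.validate()
        return cfg
    with open(path, "r", encoding="utf-8") as fh:
        try:
            data = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ConfigError(f"invalid YAML in {path}: {exc}") from exc
    return config_from_dict(data or {})
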