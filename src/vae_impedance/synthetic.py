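"""Synthetic chest-impedance traces with ground-truth event logs.

The generator emulates the signal model the detector assumes: a large
static baseline (hundreds of ohms across needle leads), a respiratory
carrier of 5–10 ohms peak-to-peak at surgical ventilation rates, and the
disturbances of interest layered on top —

* ``blip``            — brief smoothed-rectangular rise (air bolus),
* ``ramp``            — slow linear rise that then persists (gradual air
                        entrainment; also what a PEEP increase can look like),
* ``baseline_step`` / ``peep_step`` — additive level shifts moving EEI and
                        EII together,
* ``tv_step``         — multiplies the carrier amplitude only (tidal-volume
                        change; moves EII but not EEI),
* ``cautery_burst``   — interval-gated high-amplitude noise,
* ``irregular_ventilation`` — per-breath period and amplitude jitter
                        (hand ventilation),
* ``apnea_interval``  — carrier suppressed.

``generate`` is a pure function of its configuration (including the seed)
and returns, besides the trace, the noise-free additive/multiplicative
decomposition so tests can verify the confounder contract directly, plus a
ground-truth log with exact event timing.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np

from .acquisition import ImpedanceTrace, write_trace
from .config import ConfigError

__all__ = ["SimEvent", "SimulationConfig", "SimResult", "generate", "make_fixture_suite"]

_EVENT_KINDS = (
    "blip",
    "ramp",
    "baseline_step",
    "tv_step",
    "peep_step",
    "cautery_burst",
    "irregular_ventilation",
    "apnea_interval",
)

#: Events that persist after onset (duration is the transition time).
_PERSISTENT = ("ramp", "baseline_step", "tv_step", "peep_step")

#: Raised-cosine edge length of a blip, seconds.  Air boluses arrive
#: abruptly; the short edge keeps the onset sharp at 100 Hz.
_BLIP_EDGE_S = 0.02


@dataclass(frozen=True)
class SimEvent:
    """One injected disturbance.

    ``magnitude`` is in ohms except for ``tv_step`` where it is the
    multiplicative factor applied to the carrier amplitude, and
    ``cautery_burst`` where it is the burst noise sigma in ohms.
    For persistent kinds (ramp and the steps) ``duration_s`` is the
    transition time and the new level holds until the end of the trace;
    for the interval kinds it is the interval length.
    """

    kind: str
    t_start: float
    duration_s: float
    magnitude: float
    #: per-kind extras: blip ``edge_s``; irregular_ventilation
    #: ``period_jitter`` / ``amplitude_jitter`` (fractional, default 0.3)
    params: dict = field(default_factory=dict)

    def validate(self, duration_s: float):
        if self.kind not in _EVENT_KINDS:
            raise ConfigError(f"unknown event kind '{self.kind}'")
        if not 0 <= self.t_start <= duration_s:
            raise ConfigError(f"event {self.kind} starts outside the trace")
        if self.duration_s < 0 or self.t_start + self.duration_s > duration_s + 1e-9:
            raise ConfigError(f"event {self.kind} extends outside the trace")
        if self.kind == "blip" and not 0 < self.duration_s <= 5.0:
            raise ConfigError("blip duration must be in (0, 5] s")
        if self.kind == "tv_step" and self.magnitude <= 0:
            raise ConfigError("tv_step magnitude is a positive amplitude factor")

    @property
    def t_end(self) -> float:
        return self.t_start + self.duration_s


@dataclass(frozen=True)
class SimulationConfig:
    duration_s: float = 120.0
    rate_hz: float = 100.0
    baseline_ohm: float = 250.0
    resp_rate_bpm: float = 12.0        #: 0 = apnea (no ventilation)
    resp_amplitude_ohm: float = 7.0    #: peak-to-peak respiratory excursion
    resp_shape: str = "skewed"         #: "skewed" (faster inspiration, expiratory pause) or "sinusoid"
    noise_sigma_ohm: float = 0.0
    seed: int = 0
    events: tuple[SimEvent, ...] = ()

    def validate(self):
        if self.duration_s <= 0 or self.rate_hz <= 0:
            raise ConfigError("duration_s and rate_hz must be positive")
        if self.resp_amplitude_ohm < 0 or self.noise_sigma_ohm < 0:
            raise ConfigError("amplitudes must be >= 0")
        if not 0 <= self.resp_rate_bpm <= 60:
            raise ConfigError("resp_rate_bpm must be in [0, 60]")
        if self.resp_shape not in ("sinusoid", "skewed"):
            raise ConfigError("resp_shape must be 'sinusoid' or 'skewed'")
        for ev in self.events:
            ev.validate(self.duration_s)
        self._check_overlaps()

    def _check_overlaps(self):
        # Apnea (no ventilation) contradicts events that modulate ventilation.
        apneas = [e for e in self.events if e.kind == "apnea_interval"]
        vents = [e for e in self.events if e.kind in ("tv_step", "irregular_ventilation")]
        for a in apneas:
            for v in vents:
                v_end = self.duration_s if v.kind in _PERSISTENT else v.t_end
                if a.t_start < v_end and v.t_start < a.t_end:
                    raise ConfigError(
                        f"contradictory overlap: apnea_interval with {v.kind}"
                    )


@dataclass(frozen=True)
class SimResult:
    """Generated trace, ground-truth event log and noise-free decomposition."""

    trace: ImpedanceTrace
    truth: tuple[dict, ...]
    #: arrays over the same samples: "baseline" (constant), "carrier"
    #: (respiratory term incl. tv/irregular/apnea modulation), "additive"
    #: (blips, ramps, steps), "noise" (Gaussian + cautery)
    parts: dict


def _shape_sinusoid(phase: np.ndarray) -> np.ndarray:
    return 0.5 - 0.5 * np.cos(2 * np.pi * phase)


def _shape_skewed(phase: np.ndarray) -> np.ndarray:
    """Ventilator-like breath: inspiration over 40% of the cycle, passive
    expiration over 30%, expiratory pause at functional residual capacity
    for the remaining 30%.  The pause anchors the lower quartile of each
    cycle at the end-expiratory level independent of tidal volume."""
    out = np.zeros_like(phase)
    rise = phase < 0.4
    fall = (phase >= 0.4) & (phase < 0.7)
    out[rise] = 0.5 - 0.5 * np.cos(np.pi * phase[rise] / 0.4)
    out[fall] = 0.5 + 0.5 * np.cos(np.pi * (phase[fall] - 0.4) / 0.3)
    return out


def _smoothstep(t: np.ndarray, t0: float, width: float) -> np.ndarray:
    """0→1 raised-cosine transition starting at t0 (instant if width == 0)."""
    if width <= 0:
        return (t >= t0).astype(float)
    x = np.clip((t - t0) / width, 0.0, 1.0)
    return 0.5 - 0.5 * np.cos(np.pi * x)


def generate(config: SimulationConfig) -> SimResult:
    """Synthesize a trace; pure function of the configuration and seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = int(round(config.duration_s * config.rate_hz))
    dt = 1.0 / config.rate_hz
    t = np.arange(n) * dt

    # --- respiratory carrier, breath by breath ---------------------------
    carrier = np.zeros(n)
    if config.resp_rate_bpm > 0 and config.resp_amplitude_ohm > 0:
        base_period = 60.0 / config.resp_rate_bpm
        irregular = [e for e in config.events if e.kind == "irregular_ventilation"]
        starts = [0.0]
        periods: list[float] = []
        amps: list[float] = []
        while starts[-1] < config.duration_s:
            s = starts[-1]
            period, amp = base_period, 1.0
            for ev in irregular:
                if ev.t_start <= s < ev.t_end:
                    pj = ev.params.get("period_jitter", 0.3)
                    aj = ev.params.get("amplitude_jitter", 0.3)
                    period = base_period * (1.0 + pj * rng.uniform(-1, 1))
                    amp = max(0.1, 1.0 + aj * rng.uniform(-1, 1))
            periods.append(period)
            amps.append(amp)
            starts.append(s + period)
        starts_arr = np.array(starts[:-1])
        breath = np.clip(np.searchsorted(starts_arr, t, side="right") - 1, 0, len(periods) - 1)
        phase = (t - starts_arr[breath]) / np.array(periods)[breath]
        shape = _shape_skewed(phase) if config.resp_shape == "skewed" else _shape_sinusoid(phase)
        carrier = config.resp_amplitude_ohm * np.array(amps)[breath] * shape
        for ev in config.events:
            if ev.kind == "tv_step":
                factor = 1.0 + (ev.magnitude - 1.0) * _smoothstep(t, ev.t_start, ev.duration_s)
                carrier = carrier * factor
            elif ev.kind == "apnea_interval":
                carrier[(t >= ev.t_start) & (t < ev.t_end)] = 0.0

    # --- additive disturbances -------------------------------------------
    additive = np.zeros(n)
    for ev in config.events:
        if ev.kind == "blip":
            edge = ev.params.get("edge_s", _BLIP_EDGE_S)
            up = _smoothstep(t, ev.t_start, edge)
            down = _smoothstep(t, ev.t_end - edge, edge)
            additive += ev.magnitude * np.clip(up - down, 0.0, 1.0)
        elif ev.kind == "ramp":
            additive += ev.magnitude * _smoothstep(t, ev.t_start, 0) * np.clip(
                (t - ev.t_start) / max(ev.duration_s, dt), 0.0, 1.0
            )
        elif ev.kind in ("baseline_step", "peep_step"):
            additive += ev.magnitude * _smoothstep(t, ev.t_start, ev.duration_s)

    # --- noise ------------------------------------------------------------
    noise = rng.normal(0.0, config.noise_sigma_ohm, n) if config.noise_sigma_ohm > 0 else np.zeros(n)
    for ev in config.events:
        if ev.kind == "cautery_burst":
            mask = (t >= ev.t_start) & (t < ev.t_end)
            noise[mask] += rng.normal(0.0, ev.magnitude, int(mask.sum()))

    z = config.baseline_ohm + carrier + additive + noise
    meta = {
        "source": "synthetic",
        "note": f"seed={config.seed} resp_rate_bpm={config.resp_rate_bpm}",
    }
    trace = ImpedanceTrace(t, z, config.rate_hz, meta)
    truth = tuple(
        {
            "kind": ev.kind,
            "t_start": ev.t_start,
            "t_end": ev.t_end,
            "duration_s": ev.duration_s,
            "magnitude": ev.magnitude,
            "persistent": ev.kind in _PERSISTENT,
        }
        for ev in config.events
    )
    parts = {
        "baseline": np.full(n, config.baseline_ohm),
        "carrier": carrier,
        "additive": additive,
        "noise": noise,
    }
    return SimResult(trace=trace, truth=truth, parts=parts)


# ---------------------------------------------------------------------------
# Named fixture suite


def _suite_configs(seed: int) -> dict[str, SimulationConfig]:
    """Named scenario set exercising every pathway the detector has."""
    def s(k):  # derived per-scenario seed, kept well below 2**31
        return (seed * 1009 + k) % (2**31 - 1)

    configs: dict[str, SimulationConfig] = {}
    for i, bpm in enumerate((6, 12, 20, 30)):
        configs[f"clean_{bpm:02d}bpm"] = SimulationConfig(
            duration_s=90.0, resp_rate_bpm=bpm, noise_sigma_ohm=0.2, seed=s(i)
        )
    configs["gradual_vae"] = SimulationConfig(
        duration_s=120.0, noise_sigma_ohm=0.2, seed=s(10),
        events=(SimEvent("ramp", t_start=45.0, duration_s=30.0, magnitude=1.0),),
    )
    configs["bolus_blip"] = SimulationConfig(
        duration_s=90.0, noise_sigma_ohm=0.2, seed=s(11),
        events=(SimEvent("blip", t_start=42.0, duration_s=1.0, magnitude=14.0),),
    )
    configs["tv_confounder"] = SimulationConfig(
        duration_s=90.0, resp_amplitude_ohm=5.0, noise_sigma_ohm=0.2, seed=s(12),
        events=(SimEvent("tv_step", t_start=45.0, duration_s=0.0, magnitude=1.8),),
    )
    configs["peep_confounder"] = SimulationConfig(
        duration_s=90.0, noise_sigma_ohm=0.2, seed=s(13),
        events=(SimEvent("peep_step", t_start=45.0, duration_s=0.0, magnitude=2.0),),
    )
    configs["apnea_step"] = SimulationConfig(
        duration_s=90.0, resp_rate_bpm=0.0, noise_sigma_ohm=0.1, seed=s(14),
        events=(
            SimEvent("baseline_step", t_start=30.0, duration_s=0.0, magnitude=2.0),
            SimEvent("baseline_step", t_start=60.0, duration_s=0.0, magnitude=2.0),
        ),
    )
    configs["cautery"] = SimulationConfig(
        duration_s=90.0, noise_sigma_ohm=0.2, seed=s(15),
        events=(
            SimEvent("cautery_burst", t_start=30.0, duration_s=4.0, magnitude=4.0),
            SimEvent("cautery_burst", t_start=60.0, duration_s=4.0, magnitude=4.0),
        ),
    )
    configs["irregular_ventilation"] = SimulationConfig(
        duration_s=90.0, noise_sigma_ohm=0.2, seed=s(16),
        events=(SimEvent("irregular_ventilation", t_start=0.0, duration_s=90.0,
                         magnitude=0.0),),
    )
    return configs


def make_fixture_suite(out_dir, seed: int = 0) -> dict[str, str]:
    """Write the named scenario traces plus ground-truth JSON files.

    Returns a mapping of scenario name to trace path.  Regenerating with the
    same seed produces byte-identical files.
    """
    os.makedirs(out_dir, exist_ok=True)
    paths = {}
    for name, cfg in _suite_configs(seed).items():
        result = generate(cfg)
        trace_path = os.path.join(out_dir, f"{name}.csv")
        write_trace(result.trace, trace_path)
        truth_path = os.path.join(out_dir, f"{name}.truth.json")
        with open(truth_path, "w", encoding="utf-8") as fh:
            json.dump(
                {"config": _config_dict(cfg), "events": list(result.truth)},
                fh, indent=2, sort_keys=True,
            )
            fh.write("\n")
        paths[name] = trace_path
    return paths


def _config_dict(cfg: SimulationConfig) -> dict:
    d = asdict(cfg)
    d["events"] = [asdict(e) for e in cfg.events]
    return d
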