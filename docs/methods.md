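# Methods

## Signal model

Trans-thoracic electrical impedance, measured with a high-frequency AC
carrier (20–100 kHz) across chest leads, is dominated in its time-varying
part by lung air volume: each mechanical breath raises impedance by
roughly 5–10 Ω on top of a large static baseline (hundreds of ohms with
needle leads). Air entrained into the venous circulation also raises
impedance — transiently when a large bolus transits the chest, gradually
when air accumulates — with clinically significant volumes expected to
produce rises on the order of 0.01–1 Ω. The package analyses a uniformly
sampled impedance trace (default 100 Hz, emulating an instrument that
averages 32 raw readings every 10 ms) and scores the likelihood and
severity of venous air embolism (VAE) per sliding analysis window.

The front-end conversion assumes a series voltage divider: a known
reference resistor R and the chest load driven by a constant AC source,
giving Z = (V₁ − V₂)·R / V₂ from the two scope lead voltages. The 50 kHz
carrier itself is abstracted away; inputs are RMS voltages or impedance
samples.

## Respiratory tracking

1. **Smoothing.** A trailing (causal) running average, default window
   0.5 s. Short enough not to blunt sub-second bolus transients — which
   are detected on the *unsmoothed* trace — while suppressing sample
   noise ahead of peak detection. The first window-length of output is
   marked warm-up.

2. **Peak detection.** Continuous wavelet transform (Mexican hat,
   PyWavelets, FFT path) over 16 log-spaced scales. The validation band
   is 2–10 s breath periods (30 down to 6 breaths/min), but the scan
   deliberately extends beyond it (÷1.5 below, ×1.3 above) so an
   out-of-band rhythm is seen at its true period and rejected rather than
   aliased onto an in-band subharmonic. The dominant scale is chosen by
   *median* coefficient energy over time — a sustained rhythm keeps its
   scale energised throughout, a lone transient does not — and the signal
   is clipped to ±2.5 IQR around its median before the transform so a
   single large bolus cannot drag the scale choice. Ridge maxima below
   0.4× the median ridge-peak height are dropped; surviving peaks are
   refined to the local maximum of the smoothed trace and merged when
   closer than min(2 s, half the dominant period), keeping the higher
   (earlier on ties).

3. **Validation.** A window holds a valid respiratory signal iff: at
   least 3 peaks; the median inter-peak interval maps to 6–30 breaths/min
   (with 5% slack at the band edges, so a ventilation truly at 6 or
   30 bpm does not flap in and out of validity under estimator jitter);
   the intervals are regular (MAD ≤ 25% of the median); and the median
   per-breath excursion exceeds max(0.5 Ω, 3× the raw noise floor). The
   amplitude gate matters: band-passed white noise produces regular
   wavelet-ridge peaks that pass the interval tests but has pseudo-breath
   excursions far below any credible tidal swing.

4. **Segmentation and summaries.** Breath boundaries are placed at the
   time midpoint between consecutive peaks. For a symmetric waveform this
   is the trough; for the ventilator-like waveform with an expiratory
   rest it falls inside the rest while remaining deterministic — the
   literal sample argmin wanders anywhere within a flat rest under noise,
   which would jitter every per-cycle percentile by a substantial
   fraction of an ohm and swamp the clinical trend scale. Each breath is
   summarised by min, max and the 25th/75th percentiles (linear
   interpolation between order statistics). The quartiles are the robust
   end-expiratory and end-inspiratory impedance estimates (EEI := p25,
   EII := p75): inspiration raises impedance, so the upper quartile
   tracks the inspiratory plateau. Breaths with durations outside
   0.7×2 s – 1.3×10 s are discarded.

## Detection

**Trend path (gradual entrainment).** Consecutive breaths are compared on
(ΔEEI, ΔEII) with threshold τ = 0.1 Ω (inside the 0.01–1 Ω clinical
scale; configurable). Both rising above τ ⇒ `vae_or_peep` — gradual air
entrainment and a PEEP increase are indistinguishable on this signal, so
the ambiguity is surfaced in the classification and an advisory string,
not resolved. An isolated EII change ⇒ `tv_change` (tidal-volume
signature); an isolated EEI rise ⇒ `peep_tv_edge` (the uncommon
PEEP-up/TV-down combination); anything else ⇒ `stable`. A consecutive
run of paired rises is counted across windows (deltas deduplicated by
breath peak time, since adjacent windows overlap) with dual-threshold
hysteresis: a run starts at full τ but continues at τ/2, so a gradual
rise whose per-breath increment straddles τ is not reset by one marginal
breath. The trend score is 100·min(1, count/6): three consecutive paired
rises reach the alarm threshold of 50, saturation at six keeps severity
interpretable.

**Blip path (bolus transit).** On the raw window, excursions above a
rolling-median baseline (window ≥ max(7.5 s, 1.5 breaths), so a ≤3 s
excursion can never capture the median) by at least 1.0× the median
breath excursion are candidates; when no valid ventilation exists, an
absolute floor of 1 Ω is used instead. Candidates longer than 3 s are
not blips (they belong to the trend/absolute paths); shorter than 50 ms
are noise spikes. While ventilated, a candidate must additionally top the
peak of the first *following* uninvolved breath by 0.5 breath
amplitudes: after a tidal-volume or level step the next breath peaks as
high as the step transient did, after a bolus it does not. A candidate
with no following breath in its window is deferred — overlapping windows
(hop 5 s) revisit it — which means a bolus in the final breaths of a
recording can be missed (known limitation). Onset and offset are refined
by following the steep excursion edge back from the threshold crossing
(slope floor 0.1× threshold per sample keeps the walk off the gentler
respiratory rise), and amplitude is measured against the signal level
just before onset. The blip score is 100·min(1, amplitude / (2×
breath amplitude)).

**Absolute path (no ventilation).** When the window has no valid
respiratory signal, a trailing-median profile (1.5 s confirmation span —
a transient shorter than half of it cannot move the median and is left to
the blip path) is compared against a slowly adapting reference baseline
(seeded from the first 5 s, EMA α = 0.2 per window). The component is
scaled so a sustained rise of 1 Ω reaches the alarm threshold. This path
exists for the unventilated case — circulatory air with no breathing
signal — and therefore *bypasses* the SQI alarm gate.

**Score and alarm.** score = max(trend, blip, absolute), clamped to
[0, 100] — the modalities are alternative evidence classes for the same
physical event, so max avoids double counting. Alarm when score ≥ 50
with SQI ≥ 0.3, or when the absolute path itself reaches 50; a vetoed
alarm is reported with a `suppressed` flag rather than hidden. A raised
alarm latches until two consecutive quiet windows.

**Windowing.** 30 s sliding windows advancing 5 s. The short hop bounds
alarm-latency granularity: with the trend alarm at three consecutive
paired rises (~20 s of breaths at 12 bpm), a 5 s hop keeps worst-case
latency within six breaths of onset. Windows shorter than 10 s are
withheld (warm-up); a final partial window is assessed if ≥ 10 s.
Because windows are slices of the accumulated sample stream, chunked
streaming and batch analysis are identical by construction.

## Signal quality index

Weighted mean of five [0, 1] components: presence (0.35) — a valid
respiratory waveform was found; regularity (0.20) — 1 − MAD/0.25·median
of inter-peak intervals; amplitude (0.20) — median breath excursion over
the noise floor, saturating at SNR 20; robustness (0.10) — how far the
mean per-breath quartile-vs-extrema gap fraction exceeds the sampled-
sinusoid ideal (1 − √2/2 ≈ 0.293), scaled over 0.5; consistency (0.15)
— 1 − the EEI/EII standard deviations across the window normalised by
twice the breath amplitude, scaled over 0.5. The noise floor is the
median absolute successive difference of the unsmoothed trace scaled to a
Gaussian σ (robust; the slow respiratory component contributes little
sample-to-sample change at 100 Hz). When no valid waveform is present
the cycle-derived components (amplitude, robustness, consistency) gate to
zero — they would otherwise describe pseudo-breaths cut from noise.
Weights follow the ranking of waveform presence and signal consistency as
the dominant quality contributors; all are configurable.

## Synthetic data

The generator is the package's test bench and encodes the study
conditions: baseline 250 Ω; respiratory carrier default 7 Ω peak-to-peak
(range 5–10) at 12 breaths/min (range 6–30); white Gaussian sample noise,
default σ 0.2 Ω for detection studies. The default breath shape is
ventilator-like: raised-cosine inspiration over 40% of the cycle, passive
expiration over 30%, and an expiratory rest at functional residual
capacity for 30% — the rest anchors each breath's lower quartile at the
end-expiratory level independent of tidal volume, which is precisely what
makes a tidal-volume change an EII-only event. A pure sinusoid shape is
retained for analytic tests.

Events: `blip` (smoothed rectangle, 20 ms raised-cosine edges — boluses
arrive abruptly; default test magnitude 2× the respiratory amplitude,
between the 0.01–1 Ω clinical scale and the respiratory scale, standing
in for the large 60 mL test boluses whose ohmic deflection is not
otherwise pinned down), `ramp` (linear rise, then holds), `baseline_step`
/ `peep_step` (additive level shifts moving EEI and EII together),
`tv_step` (multiplies the carrier amplitude only), `cautery_burst`
(interval-gated noise, test σ 4 Ω ≈ 20× the ambient), `irregular_
ventilation` (±30% per-breath period and amplitude jitter — hand
ventilation), `apnea_interval` (carrier suppressed). Contradictory
overlaps (apnea with ventilation-modulating events) are rejected. The
generator returns the noise-free additive/multiplicative decomposition
alongside the trace, so the confounder contracts are testable directly,
and a ground-truth log with exact event timing; it is a pure function of
its configuration including the seed.

What the generator does **not** emulate: cardiogenic impedance
oscillations, electrode/skin impedance drift, movement artifact with
structure (it only has white and gated-white noise), and real ventilator
waveform variety. Passing tests demonstrate the algorithm's behaviour
under its stated signal model, not clinical performance.

## Numerical and design choices

* Percentiles: numpy linear interpolation, pinned by a brute-force
  sort-and-interpolate oracle in the tests.
* Rolling medians are computed on a 20 Hz-decimated grid and interpolated
  back (the baselines they feed vary on multi-second scales).
* Trace files are plain CSV with `# key=value` headers; floats are
  written with `repr` so read(write(x)) is exact. Reports round floats to
  6 significant digits and sort keys, so identical runs are
  byte-identical.
* All randomness is seed-controlled; analyses of fixed inputs are fully
  deterministic.
* Desk-scale problem sizes: detection studies use 90–120 s traces; the
  batch suites in `tests/` and `scripts/acceptance.py` use 50–100 seeded
  runs per property.

## Known limitations

* PEEP changes alarm as VAE (by design: the signal cannot distinguish
  them; the classification and advisory say so).
* A bolus in the last breaths of a recording may be missed (the
  following-breath discriminator has nothing to compare against).
* Rates just outside the 6–30 bpm band (e.g. 36–45 bpm) can alias onto
  an in-band subharmonic if their fundamental also has in-band energy;
  the widened scan band handles the common cases (tested at 3, 40 and
  60 bpm) but is not a guarantee.
* Irregular hand ventilation degrades the SQI rather than being
  analysed; alarms are then suppressed-and-flagged, not raised.
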