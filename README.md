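# geciquant

Simulation and quantification toolkit for genetically encoded calcium
indicators (GECIs), built around the characterisation workflow of red
indicators such as FRCaMPi and its soma-targeted (ribo-tagged) variant.

Densely labelled calcium imaging suffers from neuropil contamination: the
mesh of neurites around each cell body adds a shared signal to every somatic
ROI, inflating pairwise correlations between neurons — most severely in
wide-field (one-photon) imaging, where out-of-focus light dominates.
Soma-targeted sensors restrict expression to cell bodies and suppress the
problem at the source; the conventional algorithmic remedy subtracts an
annulus neuropil estimate, `F_corrected = F_soma − 0.7·F_neuropil`. This
package implements, end to end and with a fully synthetic test bed:

- **Equilibrium biophysics** — Hill transduction
  `F = F_apo + (F_sat − F_apo)·[Ca]ⁿ/([Ca]ⁿ + K_dⁿ)`, titration fitting
  (K_d, Hill n, dynamic range), pH titrations (pKa), photobleaching fits,
  and EGTA/Ca-EGTA free-calcium buffer arithmetic.
- **Transient synthesis** — Poisson and stimulus-train spike sources
  (1–160 pulses at 83 Hz), an exponential-kernel calcium surrogate,
  equilibrium/kinetic fluorescence transduction, photon noise.
- **Scene synthesis** — somas plus random-walk neurites with exponential
  expression decay `exp(−d/λ)` (λ ≈ 5–6× shorter for soma-targeted
  sensors), wide-field vs two-photon rendering with ground-truth masks.
- **Trace metrics** — baselines (pre-window mean, sliding percentiles,
  splines), ΔF/F₀, peak SNR, half-rise/half-decay from single-exponential
  fits, full decay time, responsiveness classifiers (rank-sum and z > 2.5
  within 3 s), OSI, isolated-spike selection, event-triggered averages.
- **Spatial metrics** — ROI trace extraction, annulus neuropil and 0.7
  subtraction, neurite decay fitting (e⁻¹ length constant), soma/neuropil
  ratio, IOU-based ROI matching (threshold 0.5), labeling density, a minimal
  threshold segmenter.
- **Population analysis** — distance-binned pairwise Pearson correlations
  (0–200/200–400/400–800 µm), responsive fractions, per-FOV summaries, and
  the matched soma-targeted vs non-targeted contamination experiment.

## Worked example

```python
import numpy as np
import geciquant as gq

# fit a 16-point Ca2+ titration (1% measurement noise) with the Hill model
ca = np.array([2.1, 7.9, 16.3, 35.4, 79.2, 135.5, 208.4, 312.6, 468.9,
               731.5, 1254.6, 2817.6, 5856.0, 11858.0, 21923.7, 81276.0])
rng = np.random.default_rng(0)
f = gq.hill_fluorescence(ca, gq.FRCAMPI) * (1 + 0.01 * rng.standard_normal(ca.size))
fit, params = gq.fit_hill_titration(gq.TitrationCurve(x=ca, y=f))
print(f"Kd = {fit.params['kd']:.1f} nM, n = {fit.params['hill_n']:.2f}, "
      f"dynamic range = {fit.params['dynamic_range']:.1f} (r2 = {fit.r2:.4f})")

# simulate a 10-pulse 83 Hz stimulus train and quantify the transient
sched = gq.StimulusSchedule(trains=((1.0, 10, 83.0),), duration=8.0)
caT = gq.calcium_from_spikes(gq.schedule_to_spikes(sched), frame_rate=20.0)
trace = gq.add_photon_noise(
    gq.fluorescence_from_calcium(caT, gq.FRCAMPI), 500.0, seed=1)
f0 = gq.estimate_baseline(
    trace, gq.BaselineSpec(method="pre_window_mean", window=1.0, window_unit="s"),
    event_onset=20)
d = gq.dff(trace, f0)
m = gq.half_times(gq.DffTrace(values=d.values[15:], f0=f0, frame_rate=20.0))
print(f"peak dF/F0 = {gq.peak_dff(d):.2f}, "
      f"SNR = {gq.peak_snr(trace, slice(0, 20)):.1f}, "
      f"t_half_decay = {m.t_half_decay:.2f} s")
```

Output:

```
Kd = 80.8 nM, n = 3.28, dynamic range = 15.5 (r2 = 0.9997)
peak dF/F0 = 3.35, SNR = 234.3, t_half_decay = 2.72 s
```

The fitted constants recover the generating FRCaMPi parameters (K_d 81 nM,
n 3.1, dynamic range 16.3) to within the injected 1 % noise. The 10-pulse
train drives the indicator close to saturation, which is why the apparent
half-decay (2.7 s) is slower than the calcium kernel's 1 s time constant —
the saturating Hill transfer flattens the top of the transient.

A command line mirrors the library:

```bash
geci fit-titration --input curve.csv --kind calcium --out fit.json
geci simulate-movie --config examples/pipeline_demo.yml --out movie.tif --truth truth/
geci contamination-experiment --seed 1 --out contamination.json
```

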