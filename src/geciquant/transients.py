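"""Synthetic fluorescence transients: spikes -> calcium -> indicator -> noise.

The generator chain produces the per-neuron truth signals used throughout the
package: spike trains (Poisson surrogates of spontaneous activity, or
field-stimulation schedules of 1–160 pulse trains at 83 Hz), a linear
exponential-kernel calcium surrogate, equilibrium or kinetic Hill transduction
into indicator fluorescence, and Poisson photon noise with Gaussian read noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from geciquant.biophysics import IndicatorParams, hill_fluorescence, _hill_occupancy

__all__ = [
    "SpikeTrain",
    "StimulusSchedule",
    "Trace",
    "CalciumTrace",
    "DEFAULT_PULSE_COUNTS",
    "DEFAULT_PULSE_RATE_HZ",
    "default_stimulus_schedule",
    "generate_poisson_spike_train",
    "schedule_to_spikes",
    "calcium_from_spikes",
    "fluorescence_from_calcium",
    "add_photon_noise",
]

#: Field-stimulation protocol: trains of increasing pulse count at 83 Hz.
DEFAULT_PULSE_COUNTS = (1, 2, 3, 5, 10, 20, 40, 80, 160)
DEFAULT_PULSE_RATE_HZ = 83.0


@dataclass(frozen=True)
class SpikeTrain:
    """Sorted event times (s) within ``[0, duration)``."""

    times: np.ndarray
    duration: float

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", t)
        if t.size and (t[0] < 0 or t[-1] >= self.duration):
            raise ValueError("spike times must lie in [0, duration)")
        if np.any(np.diff(t) <= 0):
            raise ValueError("spike times must be strictly increasing")

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class StimulusSchedule:
    """Stimulus trains: (onset s, pulse_count, pulse_rate Hz) triples."""

    trains: tuple[tuple[float, int, float], ...]
    duration: float

    def __post_init__(self) -> None:
        for onset, count, rate in self.trains:
            if count < 1:
                raise ValueError("pulse_count must be >= 1")
            if rate <= 0:
                raise ValueError("pulse_rate must be > 0")
            if onset < 0:
                raise ValueError("onset must be >= 0")


def default_stimulus_schedule(
    inter_train_gap: float = 10.0,
    pulse_counts: tuple[int, ...] = DEFAULT_PULSE_COUNTS,
    pulse_rate: float = DEFAULT_PULSE_RATE_HZ,
    onset: float = 2.0,
) -> StimulusSchedule:
    """The standard culture protocol: trains of 1–160 pulses at 83 Hz."""
    trains = []
    t = onset
    for k in pulse_counts:
        trains.append((t, k, pulse_rate))
        t += (k - 1) / pulse_rate + inter_train_gap
    return StimulusSchedule(trains=tuple(trains), duration=t + inter_train_gap)


@dataclass(frozen=True)
class Trace:
    """A sampled fluorescence time series (a.u.) at a fixed frame rate."""

    values: np.ndarray
    frame_rate: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be > 0")
        if not np.all(np.isfinite(v)):
            raise ValueError("trace values must be finite")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.values.size) / self.frame_rate

    def __len__(self) -> int:
        return int(self.values.size)


@dataclass(frozen=True)
class CalciumTrace:
    """Free intracellular [Ca2+] (nM) per frame.

    Resting calcium in neurons sits around 30–100 nM; each action potential
    adds ``a_per_ap`` nM that relaxes back with time constant ``tau_ca``.
    """

    values: np.ndarray
    frame_rate: float
    ca_rest: float = 50.0
    a_per_ap: float = 150.0
    tau_ca: float = 1.0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be > 0")
        if np.any(v < 0):
            raise ValueError("[Ca2+] must be >= 0")


def generate_poisson_spike_train(
    rate: float,
    duration: float,
    refractory: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> SpikeTrain:
    """Homogeneous Poisson spike train thinned to a minimum inter-event gap.

    Events are drawn as a Poisson process of the given rate over ``duration``
    then thinned left-to-right so that consecutive kept events are at least
    ``refractory`` seconds apart. Reproducible for a fixed seed.
    """
    if rate < 0 or refractory < 0:
        raise ValueError("rate and refractory must be >= 0")
    if refractory > 0 and rate * refractory >= 1.0:
        raise ValueError(
            f"infeasible rate: rate*refractory = {rate * refractory:.3f} >= 1"
        )
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if rate == 0 or duration <= 0:
        return SpikeTrain(times=np.empty(0), duration=max(duration, 0.0))
    n = rng.poisson(rate * duration)
    times = np.sort(rng.uniform(0.0, duration, size=n))
    if refractory > 0 and times.size:
        kept = [times[0]]
        for t in times[1:]:
            if t - kept[-1] >= refractory:
                kept.append(t)
        times = np.asarray(kept)
    # strict monotonicity guard against duplicate uniform draws
    dup = np.flatnonzero(np.diff(times) <= 0)
    if dup.size:
        times = np.delete(times, dup + 1)
    return SpikeTrain(times=times, duration=duration)


def schedule_to_spikes(schedule: StimulusSchedule) -> SpikeTrain:
    """Expand a stimulus schedule: k pulses at rate r give k events 1/r apart."""
    windows = []
    times = []
    for onset, count, rate in schedule.trains:
        end = onset + (count - 1) / rate
        windows.append((onset, end))
        times.append(onset + np.arange(count) / rate)
    windows.sort()
    for (s0, e0), (s1, _) in zip(windows, windows[1:]):
        if s1 <= e0:
            raise ValueError(
                f"stimulus trains overlap: train starting at {s1:g}s begins "
                f"before the previous train ends at {e0:g}s"
            )
    all_times = np.sort(np.concatenate(times)) if times else np.empty(0)
    duration = max(schedule.duration, float(all_times[-1]) + 1e-9 if all_times.size else 0.0)
    return SpikeTrain(times=all_times, duration=duration)


def calcium_from_spikes(
    spikes: SpikeTrain,
    ca_rest: float = 50.0,
    a_per_ap: float = 150.0,
    tau_ca: float = 1.0,
    frame_rate: float = 20.0,
    duration: float | None = None,
) -> CalciumTrace:
    """Linear exponential-kernel calcium surrogate.

    ``ca(t) = ca_rest + sum_i a_per_ap * exp(-(t - t_i)/tau_ca)`` for frames at
    or after each spike. Superposition is linear: coincident spikes add.
    """
    if tau_ca <= 0:
        raise ValueError("tau_ca must be > 0")
    dur = duration if duration is not None else spikes.duration
    n_frames = int(np.ceil(dur * frame_rate))
    t = np.arange(n_frames) / frame_rate
    ca = np.full(n_frames, float(ca_rest))
    # recursive update: between frames the summed kernel decays by a fixed factor
    decay = np.exp(-1.0 / (frame_rate * tau_ca))
    acc = 0.0
    spike_iter = iter(spikes.times)
    next_spike = next(spike_iter, None)
    for k in range(n_frames):
        if k:
            acc *= decay
        while next_spike is not None and next_spike <= t[k]:
            # kernel evaluated at the frame, honouring sub-frame spike timing
            acc += a_per_ap * np.exp(-(t[k] - next_spike) / tau_ca)
            next_spike = next(spike_iter, None)
        ca[k] += acc
    return CalciumTrace(
        values=ca, frame_rate=frame_rate, ca_rest=ca_rest,
        a_per_ap=a_per_ap, tau_ca=tau_ca,
    )


def fluorescence_from_calcium(
    ca: CalciumTrace,
    params: IndicatorParams,
    mode: str = "equilibrium",
    k_on: float | None = None,
    k_off: float | None = None,
    steps_per_frame: int = 20,
) -> Trace:
    """Map a calcium trace to indicator fluorescence.

    ``equilibrium`` applies the Hill transduction pointwise (valid when binding
    is fast relative to the frame interval). ``kinetic`` integrates the bound
    fraction ``b`` of the sensor through::

        db/dt = k_on_eff(ca) * (1 - b) - k_off * b

    where the on-drive ``k_on_eff(ca) = k_off * (ca/kd)^n`` inherits the Hill
    cooperativity so the fast-binding limit recovers the equilibrium map; the
    bound fraction is then mapped affinely onto ``[f_apo, f_sat]``. ``k_off``
    (1/s) sets the kinetic speed; ``k_on`` may override the implied on-rate
    scale (then ``kd_eff = (k_off/k_on)^(1/n)`` replaces ``params.kd``). The
    integrator uses the exact exponential update of the linear ODE per substep
    (unconditionally stable, bound fraction stays in [0, 1]).
    """
    if mode == "equilibrium":
        return Trace(values=hill_fluorescence(ca.values, params), frame_rate=ca.frame_rate)
    if mode != "kinetic":
        raise ValueError(f"unknown mode {mode!r}")
    if k_off is None or k_off <= 0:
        raise ValueError("kinetic mode requires k_off > 0 (1/s)")
    if steps_per_frame < 1:
        raise ValueError("steps_per_frame must be >= 1")
    kd = params.kd
    if k_on is not None:
        if k_on <= 0:
            raise ValueError("k_on must be > 0")
        kd = (k_off / k_on) ** (1.0 / params.hill_n)

    dt = 1.0 / (ca.frame_rate * steps_per_frame)
    values = np.asarray(ca.values, dtype=float)
    n_frames = values.size
    out = np.empty(n_frames)
    occ0 = _hill_occupancy(np.asarray([values[0]]), kd, params.hill_n)[0]
    b = occ0  # start at equilibrium with the first frame
    out[0] = b
    for k in range(1, n_frames):
        # linear interpolation of [Ca] across substeps within the frame
        for s in range(steps_per_frame):
            frac = (s + 0.5) / steps_per_frame
            ca_sub = values[k - 1] + frac * (values[k] - values[k - 1])
            kon_eff = k_off * (ca_sub / kd) ** params.hill_n if ca_sub > 0 else 0.0
            ktot = kon_eff + k_off
            b_inf = kon_eff / ktot
            b = b_inf + (b - b_inf) * np.exp(-ktot * dt)
        out[k] = b
    f = params.f_apo + (params.f_sat - params.f_apo) * out
    return Trace(values=f, frame_rate=ca.frame_rate)


def add_photon_noise(
    trace: Trace,
    photons_per_unit: float,
    read_noise_sd: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> Trace:
    """Shot noise plus Gaussian read noise.

    Each frame is drawn ``Poisson(photons_per_unit * F) / photons_per_unit``
    then perturbed by ``N(0, read_noise_sd)``. The transform is unbiased and
    reproducible for a fixed seed.
    """
    if photons_per_unit <= 0:
        raise ValueError("photons_per_unit must be > 0")
    v = np.asarray(trace.values, dtype=float)
    if np.any(v < 0):
        raise ValueError("photon noise requires non-negative fluorescence")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    noisy = rng.poisson(photons_per_unit * v).astype(float) / photons_per_unit
    if read_noise_sd > 0:
        noisy = noisy + rng.normal(0.0, read_noise_sd, size=noisy.shape)
    return Trace(values=noisy, frame_rate=trace.frame_rate, t0=trace.t0)
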