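"""Equilibrium biophysics of a calcium indicator.

Hill-model transduction of free [Ca2+] into fluorescence, least-squares fitting
of Ca2+ titrations, pH titrations and photobleaching decays, and the reciprocal
EGTA/Ca-EGTA dilution arithmetic used to build free-calcium calibration series.

The Hill model for a sensor with apo brightness ``F_apo`` and saturated
brightness ``F_sat`` is::

    F([Ca]) = F_apo + (F_sat - F_apo) * [Ca]^n / ([Ca]^n + Kd^n)

with dissociation constant ``Kd`` (nM, the half-saturation concentration) and
Hill coefficient ``n`` (cooperativity).  The dynamic range is ``F_sat/F_apo``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "IndicatorParams",
    "TitrationCurve",
    "BufferMixSpec",
    "FitResult",
    "NonIdentifiableError",
    "FRCAMPI",
    "hill_fluorescence",
    "fit_hill_titration",
    "free_calcium_series",
    "fit_ph_titration",
    "fit_photobleach",
]


class NonIdentifiableError(ValueError):
    """Raised when a titration curve carries no usable modulation to fit."""


@dataclass(frozen=True)
class IndicatorParams:
    """Biophysical constants of one indicator state pair.

    Parameters
    ----------
    name : str
        Indicator name, e.g. ``"FRCaMPi"``.
    kd : float
        Ca2+ dissociation constant, nM.
    hill_n : float
        Hill coefficient (dimensionless cooperativity).
    f_apo : float
        Ca2+-free brightness, arbitrary units, > 0.
    f_sat : float
        Ca2+-saturated brightness, arbitrary units, >= ``f_apo``.
    pka_apo, pka_sat : float, optional
        pH midpoints of the Ca-free / Ca-saturated states.
    bleach_tau : float, optional
        Mono-exponential photobleaching time constant, s.
    """

    name: str
    kd: float
    hill_n: float
    f_apo: float
    f_sat: float
    pka_apo: float | None = None
    pka_sat: float | None = None
    bleach_tau: float | None = None

    def __post_init__(self) -> None:
        if self.kd <= 0:
            raise ValueError(f"kd must be > 0, got {self.kd}")
        if self.hill_n <= 0:
            raise ValueError(f"hill_n must be > 0, got {self.hill_n}")
        if not self.f_apo > 0:
            raise ValueError(f"f_apo must be > 0, got {self.f_apo}")
        if self.f_sat < self.f_apo:
            raise ValueError("f_sat must be >= f_apo")

    @property
    def dynamic_range(self) -> float:
        """F_sat / F_apo, dimensionless."""
        return self.f_sat / self.f_apo


#: FRCaMPi constants: Kd = 81 nM, Hill n = 3.1, dynamic range 16.3-fold
#: (f_apo normalised to 1), pKa of the Ca-saturated state 6.48.
FRCAMPI = IndicatorParams(
    name="FRCaMPi", kd=81.0, hill_n=3.1, f_apo=1.0, f_sat=16.3, pka_sat=6.48
)


@dataclass(frozen=True)
class TitrationCurve:
    """A titration series: free-ligand axis plus measured fluorescence."""

    x: np.ndarray
    y: np.ndarray
    x_kind: Literal["calcium", "ph"] = "calcium"

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        if x.ndim != 1 or y.ndim != 1 or x.size != y.size:
            raise ValueError("x and y must be 1-D and the same length")
        if x.size < 3:
            raise ValueError("need at least 3 titration points")
        if np.any(np.diff(x) <= 0):
            raise ValueError("x must be strictly increasing")
        if np.any(y < 0):
            raise ValueError("fluorescence values must be >= 0")
        if self.x_kind not in ("calcium", "ph"):
            raise ValueError(f"unknown x_kind {self.x_kind!r}")


@dataclass(frozen=True)
class BufferMixSpec:
    """Reciprocal-dilution series of chelator vs Ca-chelator stock buffers.

    ``kd_chelator_eff`` is the effective Ca-chelator dissociation constant in
    nM under the assay's ionic conditions; it must be supplied by the user.
    ``correction`` is the calibration correction factor applied to the free
    calcium values (1.084 by default, the factor used to align the series to
    the GCaMP6s reference Kd).
    """

    ca_total: np.ndarray
    kd_chelator_eff: float
    chelator_total: float = 10.0
    correction: float = 1.084

    def __post_init__(self) -> None:
        ca = np.atleast_1d(np.asarray(self.ca_total, dtype=float))
        object.__setattr__(self, "ca_total", ca)
        if self.kd_chelator_eff <= 0:
            raise ValueError("kd_chelator_eff must be > 0")
        if self.correction <= 0:
            raise ValueError("correction must be > 0")
        if np.any(ca < 0):
            raise ValueError("ca_total must be >= 0")
        if np.any(ca >= self.chelator_total):
            raise ZeroDivisionError(
                "ca_total must be < chelator_total (saturated buffer has no "
                "free chelator to buffer against)"
            )


@dataclass
class FitResult:
    """Outcome of a nonlinear least-squares fit.

    ``params`` maps parameter names to point estimates; ``r2`` is the
    coefficient of determination of the fit; when ``converged`` is False the
    parameters are flagged unusable and should not be consumed downstream.
    """

    params: dict[str, float] = field(default_factory=dict)
    r2: float = float("nan")
    converged: bool = False


def _r_squared(y: np.ndarray, y_fit: np.ndarray) -> float:
    ss_res = float(np.sum((y - y_fit) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    if ss_tot == 0.0:
        return 1.0 if ss_res == 0.0 else float("-inf")
    return 1.0 - ss_res / ss_tot


def hill_fluorescence(
    ca_free: float | np.ndarray, params: IndicatorParams
) -> float | np.ndarray:
    """Equilibrium fluorescence of the indicator at free [Ca2+] (nM).

    Monotonically non-decreasing in ``ca_free``; returns ``f_apo`` at zero
    calcium and approaches ``f_sat`` at saturation, with half-maximal response
    at ``ca_free = kd``.
    """
    ca = np.asarray(ca_free, dtype=float)
    if np.any(ca < 0):
        raise ValueError("ca_free must be >= 0 (nM)")
    occ = _hill_occupancy(ca, params.kd, params.hill_n)
    out = params.f_apo + (params.f_sat - params.f_apo) * occ
    return float(out) if np.isscalar(ca_free) else out


def _hill_occupancy(ca: np.ndarray, kd: float, n: float) -> np.ndarray:
    # ca^n/(ca^n + kd^n) computed as 1/(1 + (kd/ca)^n) to avoid overflow at
    # large ca; ca = 0 handled explicitly.
    ca = np.asarray(ca, dtype=float)
    out = np.zeros_like(ca)
    nz = ca > 0
    with np.errstate(over="ignore"):
        out[nz] = 1.0 / (1.0 + (kd / ca[nz]) ** n)
    return out


def _check_modulation(y: np.ndarray, what: str) -> None:
    lo, hi = float(np.min(y)), float(np.max(y))
    if lo <= 0 or hi / lo < 1.05:
        raise NonIdentifiableError(
            f"{what} is flat (max/min = {hi / lo if lo > 0 else float('inf'):.3f}"
            " < 1.05); parameters are not identifiable"
        )


def fit_hill_titration(
    curve: TitrationCurve,
    init: Mapping[str, float] | None = None,
    name: str = "fit",
) -> tuple[FitResult, IndicatorParams | None]:
    """Fit the Hill equation to a Ca2+ titration curve.

    Returns the :class:`FitResult` (params ``kd``, ``hill_n``, ``f_apo``,
    ``f_sat``, ``dynamic_range``, plus ``r2``) and the fitted
    :class:`IndicatorParams` (``None`` when the fit did not converge).

    Initialisation is data-driven: ``kd0`` at the half-range crossing of the
    curve (linear interpolation), ``n0 = 2``, ``f_apo0 = min(y)``,
    ``f_sat0 = max(y)``; bounds keep kd in (0, 1e6] nM, n in (0, 10] and both
    brightness values positive.
    """
    if curve.x_kind != "calcium":
        raise ValueError("fit_hill_titration expects a calcium titration")
    x, y = curve.x, curve.y
    if x.size < 5:
        raise ValueError("need >= 5 concentrations to fit a Hill curve")
    _check_modulation(y, "titration curve")

    half = 0.5 * (np.min(y) + np.max(y))
    kd0 = float(np.interp(half, y, x)) if np.all(np.diff(y) >= 0) else float(
        x[np.argmin(np.abs(y - half))]
    )
    kd0 = min(max(kd0, 1e-6), 1e6)
    p0 = {
        "kd": kd0,
        "hill_n": 2.0,
        "f_apo": float(np.min(y)),
        "f_sat": float(np.max(y)),
    }
    if init:
        p0.update(init)

    def model(ca, kd, n, f_apo, f_sat):
        return f_apo + (f_sat - f_apo) * _hill_occupancy(ca, kd, n)

    result = FitResult()
    try:
        popt, _ = curve_fit(
            model,
            x,
            y,
            p0=[p0["kd"], p0["hill_n"], max(p0["f_apo"], 1e-12), p0["f_sat"]],
            bounds=([1e-9, 1e-9, 1e-12, 1e-12], [1e6, 10.0, np.inf, np.inf]),
            maxfev=20000,
        )
    except RuntimeError:
        return result, None
    kd, n, f_apo, f_sat = (float(v) for v in popt)
    result.params = {
        "kd": kd,
        "hill_n": n,
        "f_apo": f_apo,
        "f_sat": f_sat,
        "dynamic_range": f_sat / f_apo,
    }
    result.r2 = _r_squared(y, model(x, *popt))
    result.converged = True
    fitted = IndicatorParams(
        name=name, kd=kd, hill_n=n, f_apo=f_apo, f_sat=max(f_sat, f_apo)
    )
    return result, fitted


def free_calcium_series(spec: BufferMixSpec) -> np.ndarray:
    """Free [Ca2+] (nM) of a reciprocal chelator / Ca-chelator dilution series.

    For total-calcium fraction ``f = ca_total/chelator_total`` the free
    calcium is ``correction * kd_chelator_eff * f / (1 - f)`` — strictly
    increasing in ``ca_total`` and linear in both the effective chelator Kd
    and the correction factor.
    """
    f = spec.ca_total / spec.chelator_total
    return spec.correction * spec.kd_chelator_eff * f / (1.0 - f)


def fit_ph_titration(curve: TitrationCurve, name: str = "fit") -> FitResult:
    """Fit a pH titration with a Hill-type sigmoid in [H+].

    The model in pH units is::

        F(pH) = f_lo + (f_hi - f_lo) / (1 + 10**(n * (pka - pH)))

    which is the Hill form in proton concentration; ``pka`` is the pH of
    half-maximal fluorescence between the fitted asymptotes.
    """
    if curve.x_kind != "ph":
        raise ValueError("fit_ph_titration expects a pH titration")
    x, y = curve.x, curve.y
    _check_modulation(y, "pH titration")

    def model(ph, pka, n, f_lo, f_hi):
        return f_lo + (f_hi - f_lo) / (1.0 + 10.0 ** (n * (pka - ph)))

    half = 0.5 * (np.min(y) + np.max(y))
    pka0 = float(x[np.argmin(np.abs(y - half))])
    result = FitResult()
    try:
        popt, _ = curve_fit(
            model,
            x,
            y,
            p0=[pka0, 1.0, float(np.min(y)), float(np.max(y))],
            bounds=([0.0, 0.05, 0.0, 0.0], [14.0, 10.0, np.inf, np.inf]),
            maxfev=20000,
        )
    except RuntimeError:
        return result
    result.params = {
        "pka": float(popt[0]),
        "hill_n": float(popt[1]),
        "f_lo": float(popt[2]),
        "f_hi": float(popt[3]),
    }
    result.r2 = _r_squared(y, model(x, *popt))
    result.converged = True
    return result


def fit_photobleach(
    trace,
    model: Literal["mono", "bi"] = "mono",
    frame_rate: float = 1.0,
) -> FitResult:
    """Fit a photobleaching decay.

    ``trace`` is either a :class:`~geciquant.transients.Trace` (its frame rate
    is used) or a plain value sequence sampled at ``frame_rate`` Hz. ``mono``
    fits ``A*exp(-t/tau) + C`` and reports ``bleach_tau`` (s), its half-life
    ``tau*ln 2`` and ``r2``; ``bi`` fits a two-component decay and reports both
    time constants. A non-decaying trace returns ``converged=False``.
    """
    if hasattr(trace, "values") and hasattr(trace, "frame_rate"):
        y = np.asarray(trace.values, dtype=float)
        t = np.arange(y.size) / trace.frame_rate
    else:
        y = np.asarray(trace, dtype=float)
        t = np.arange(y.size) / frame_rate
    if t.size != y.size or t.size < 10:
        raise ValueError("need matched times/values with >= 10 frames")
    if np.any(y <= 0):
        raise ValueError("photobleach trace values must be > 0")

    result = FitResult()
    # crude decay check: first fifth vs last fifth
    k = max(t.size // 5, 1)
    if np.mean(y[:k]) <= np.mean(y[-k:]) * (1.0 + 1e-9):
        return result  # non-decaying: converged=False

    t0 = t - t[0]
    span = float(np.max(y) - np.min(y))
    tau0 = max((t0[-1] - t0[0]) / 3.0, 1e-9)
    try:
        if model == "mono":
            def f(tt, a, tau, c):
                return a * np.exp(-tt / tau) + c

            popt, _ = curve_fit(
                f, t0, y,
                p0=[span, tau0, float(np.min(y))],
                bounds=([0, 1e-12, 0], [np.inf, np.inf, np.inf]),
                maxfev=20000,
            )
            result.params = {
                "amplitude": float(popt[0]),
                "bleach_tau": float(popt[1]),
                "offset": float(popt[2]),
                "half_life": float(popt[1]) * float(np.log(2.0)),
            }
            result.r2 = _r_squared(y, f(t0, *popt))
        elif model == "bi":
            def f2(tt, a1, tau1, a2, tau2, c):
                return a1 * np.exp(-tt / tau1) + a2 * np.exp(-tt / tau2) + c

            popt, _ = curve_fit(
                f2, t0, y,
                p0=[span / 2, tau0 / 3, span / 2, tau0 * 3, float(np.min(y))],
                bounds=([0, 1e-12, 0, 1e-12, 0], [np.inf] * 5),
                maxfev=40000,
            )
            result.params = {
                "amplitude_fast": float(popt[0]),
                "tau_fast": float(popt[1]),
                "amplitude_slow": float(popt[2]),
                "tau_slow": float(popt[3]),
                "offset": float(popt[4]),
            }
            result.r2 = _r_squared(y, f2(t0, *popt))
        else:
            raise ValueError(f"unknown photobleach model {model!r}")
    except RuntimeError:
        return result
    result.converged = True
    return result
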