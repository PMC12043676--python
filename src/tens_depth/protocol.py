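"""Stimulus waveform, threshold titration and strength-duration analysis.

The stimulus is a charge-balanced biphasic rectangular pulse of unit
amplitude.  Titration finds the scaling factor T such that the axon fires
exactly one propagating action potential; the threshold current is then
I_T = T times the baseline current at which the extracellular drive was
computed.  Thresholds across pulse widths form the strength-duration
curve, fitted with the Weiss or Lapicque two-parameter forms to extract
rheobase and chronaxie.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .axon import AxonModel, ExtracellularDrive, detect_ap, integrate

__all__ = [
    "PulseSpec",
    "TitrationResult",
    "SDCurve",
    "SDFit",
    "ProtocolError",
    "InexcitableError",
    "make_pulse",
    "titrate",
    "sd_curve",
    "fit_sd",
    "DEFAULT_PULSE_WIDTHS_US",
]

DEFAULT_PULSE_WIDTHS_US = (30.0, 88.0, 146.0, 262.0, 495.0)


class ProtocolError(ValueError):
    pass


class InexcitableError(RuntimeError):
    """No spike within the titration bracketing cap."""


@dataclass(frozen=True)
class PulseSpec:
    """Charge-balanced biphasic rectangular pulse, unit peak amplitude."""

    pw_us: float
    interphase_ms: float = 0.1
    polarity: str = "cathodic_first"  # or "anodic_first"

    def __post_init__(self) -> None:
        if self.pw_us <= 0:
            raise ProtocolError("pulse width must be > 0")
        if self.interphase_ms < 0:
            raise ProtocolError("interphase interval must be >= 0")
        if self.polarity not in ("cathodic_first", "anodic_first"):
            raise ProtocolError(f"unknown polarity {self.polarity!r}")

    @property
    def pw_ms(self) -> float:
        return self.pw_us * 1e-3

    @property
    def second_phase_start_ms(self) -> float:
        return self.pw_ms + self.interphase_ms

    @property
    def total_width_ms(self) -> float:
        return 2 * self.pw_ms + self.interphase_ms

    def value_at(self, t) -> np.ndarray | float:
        """Normalized waveform a(t); t in ms.  Integral of a(t) is zero."""
        t = np.asarray(t, dtype=float)
        first = (t > 0) & (t <= self.pw_ms)
        second = (t > self.second_phase_start_ms) & (t <= self.total_width_ms)
        a = np.where(first, -1.0, 0.0) + np.where(second, 1.0, 0.0)
        if self.polarity == "anodic_first":
            a = -a
        return a if a.shape else float(a)


def make_pulse(
    pw_us: float, interphase_ms: float = 0.1, polarity: str = "cathodic_first"
) -> PulseSpec:
    return PulseSpec(pw_us=pw_us, interphase_ms=interphase_ms, polarity=polarity)


@dataclass
class TitrationResult:
    """Threshold scaling factor and the current it implies."""

    factor: float  # T, unitless
    baseline_mA: float  # I
    tol: float
    pw_us: float
    history: list = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    @property
    def threshold_mA(self) -> float:
        """I_T = T * I, exact by construction."""
        return self.factor * self.baseline_mA


def _fires(
    axon: AxonModel,
    drive: ExtracellularDrive,
    pulse: PulseSpec,
    amplitude: float,
    duration: float,
    dt: float,
) -> bool:
    trace = integrate(axon, drive, pulse, amplitude, duration=duration, dt=dt)
    fired, _ = detect_ap(trace)
    return fired


def titrate(
    axon: AxonModel,
    drive: ExtracellularDrive,
    pulse: PulseSpec,
    baseline_mA: float,
    tol: float = 0.01,
    start: float = 0.1,
    cap: float = 2.0**15,
    duration: float = 3.5,
    dt: float = 0.0025,
) -> TitrationResult:
    """Bracket (geometric doubling) then bisect the excitation threshold.

    ``drive`` must hold the extracellular profile produced by
    ``baseline_mA`` of electrode current; the result reports the unitless
    factor T and the threshold current T * baseline_mA.
    """
    if baseline_mA <= 0:
        raise ProtocolError("baseline current must be > 0")
    history: list[tuple[float, bool]] = []

    def fires(T: float) -> bool:
        hit = _fires(axon, drive, pulse, T, duration, dt)
        history.append((T, hit))
        return hit

    T = start
    if fires(T):
        # walk down to find a non-firing lower bracket
        while T > 1e-6:
            T /= 2.0
            if not fires(T):
                break
        else:
            raise ProtocolError(
                "axon fires at vanishing amplitude: degenerate extracellular drive"
            )
        lo, hi = T, T * 2.0
    else:
        while not fires(T * 2.0):
            T *= 2.0
            if T >= cap:
                raise InexcitableError(
                    f"no action potential up to factor {cap}: "
                    "axon inexcitable under this montage"
                )
        lo, hi = T, T * 2.0

    while (hi - lo) / hi > tol:
        mid = np.sqrt(lo * hi)
        if fires(mid):
            hi = mid
        else:
            lo = mid
    return TitrationResult(
        factor=hi,
        baseline_mA=baseline_mA,
        tol=tol,
        pw_us=pulse.pw_us,
        history=history,
        meta={"bracket": (lo, hi)},
    )


@dataclass
class SDCurve:
    """(pulse width, threshold current) pairs for one montage and fiber."""

    pw_us: np.ndarray
    threshold_mA: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pw_us = np.asarray(self.pw_us, dtype=float)
        self.threshold_mA = np.asarray(self.threshold_mA, dtype=float)
        if self.pw_us.shape != self.threshold_mA.shape or self.pw_us.ndim != 1:
            raise ProtocolError("pulse widths and thresholds must be 1-D and aligned")
        if len(self.pw_us) < 2:
            raise ProtocolError("a strength-duration curve needs >= 2 pulse widths")
        order = np.argsort(self.pw_us)
        self.pw_us = self.pw_us[order]
        self.threshold_mA = self.threshold_mA[order]
        if np.any(self.threshold_mA <= 0):
            raise ProtocolError("thresholds must be strictly positive")

    def __len__(self) -> int:
        return len(self.pw_us)


def sd_curve(
    axon: AxonModel,
    drive: ExtracellularDrive,
    pw_list_us,
    baseline_mA: float,
    interphase_ms: float = 0.1,
    polarity: str = "cathodic_first",
    tol: float = 0.01,
    duration: float = 3.5,
    dt: float = 0.0025,
) -> tuple[SDCurve, list[TitrationResult]]:
    """One titration per pulse width on a shared extracellular drive."""
    pw_list = list(pw_list_us)
    if len(pw_list) < 2:
        raise ProtocolError("a strength-duration curve needs >= 2 pulse widths")
    results = []
    for pw in pw_list:
        pulse = make_pulse(pw, interphase_ms=interphase_ms, polarity=polarity)
        try:
            results.append(
                titrate(axon, drive, pulse, baseline_mA, tol=tol, duration=duration, dt=dt)
            )
        except (InexcitableError, ProtocolError) as exc:
            raise type(exc)(f"titration failed at pulse width {pw} us: {exc}") from exc
    curve = SDCurve(
        pw_us=np.array(pw_list),
        threshold_mA=np.array([r.threshold_mA for r in results]),
        meta={"baseline_mA": baseline_mA, "tol": tol, "polarity": polarity},
    )
    return curve, results


def weiss_model(pw_us, rheobase, chronaxie_us):
    """Weiss: I(PW) = I_rh * (1 + c / PW); I(c) = 2 * I_rh."""
    return rheobase * (1.0 + chronaxie_us / pw_us)


def lapicque_model(pw_us, rheobase, chronaxie_us):
    """Lapicque: I(PW) = I_rh / (1 - 2^(-PW/c)); chronaxie = tau * ln 2."""
    return rheobase / (1.0 - 2.0 ** (-np.asarray(pw_us, dtype=float) / chronaxie_us))


_SD_MODELS = {"weiss": weiss_model, "lapicque": lapicque_model}


@dataclass
class SDFit:
    form: str
    rheobase_mA: float
    chronaxie_us: float
    residuals: np.ndarray
    covariance: np.ndarray | None = None
    exact: bool = False  # two-point fit: exactly determined, no residual dof

    def predict(self, pw_us):
        return _SD_MODELS[self.form](pw_us, self.rheobase_mA, self.chronaxie_us)


def fit_sd(curve: SDCurve, form: str = "weiss") -> SDFit:
    """Nonlinear least-squares fit of rheobase and chronaxie."""
    if form not in _SD_MODELS:
        raise ProtocolError(f"unknown strength-duration form {form!r}")
    model = _SD_MODELS[form]
    exact = len(curve) == 2
    p0 = (float(curve.threshold_mA.min()), float(np.median(curve.pw_us)))
    try:
        popt, pcov = curve_fit(
            model,
            curve.pw_us,
            curve.threshold_mA,
            p0=p0,
            bounds=([1e-12, 1e-6], [np.inf, np.inf]),
            maxfev=20_000,
        )
    except RuntimeError as exc:
        raise ProtocolError(f"strength-duration fit did not converge: {exc}") from exc
    resid = curve.threshold_mA - model(curve.pw_us, *popt)
    if not np.all(np.isfinite(popt)) or popt[0] <= 0 or popt[1] <= 0:
        raise ProtocolError(f"non-physical fit parameters {popt}")
    return SDFit(
        form=form,
        rheobase_mA=float(popt[0]),
        chronaxie_us=float(popt[1]),
        residuals=resid,
        covariance=pcov,
        exact=exact,
    )
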