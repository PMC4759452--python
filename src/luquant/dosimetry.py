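"""Time-activity curves, mono-exponential fits, and electron self-dose.

Organ activity after a therapy infusion is modelled as a single clearing
compartment, y(t) = A0 * exp(-lambda * t), combining physical decay and
biological clearance.  From the fitted decay constant follow

* the effective half-life  T_eff = ln 2 / lambda,
* the cumulated activity   A~ = integral_0^inf y dt = A0 / lambda,
* the electron self-dose   D = A~ * E_mean / m,

with E_mean the mean electron energy emitted per decay (Lu-177 default from
ICRP-style tabulations) and m the organ mass.  Photon cross-dose is not
included; for Lu-177 electrons carry ~96 % of the absorbed dose.

The fit is an unweighted least-squares fit of the exponential in linear
space, initialized from the log-linear closed form; with exactly two points
it returns the exact interpolant.  Non-decaying data (lambda <= 0) is flagged
non-physical rather than raising, so screening large TAC batches does not
abort; the derived quantities raise when asked for a non-physical fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .config import LU177_MEAN_ELECTRON_KEV

__all__ = ["TimeActivityCurve", "MonoExpFit", "MonoExponentialModel",
           "fit_monoexponential", "effective_half_life", "cumulated_activity",
           "absorbed_dose", "DoseEstimate", "compare_compensations"]

_KEV_TO_J = 1.602176634e-16
_MBQ_H_TO_DECAYS = 1e6 * 3600.0


@dataclass
class TimeActivityCurve:
    """Organ activity (MBq) at post-infusion sampling times (h)."""

    times_h: np.ndarray
    activities_MBq: np.ndarray
    source: str = ""

    def __post_init__(self):
        self.times_h = np.asarray(self.times_h, dtype=float)
        self.activities_MBq = np.asarray(self.activities_MBq, dtype=float)
        if self.times_h.shape != self.activities_MBq.shape:
            raise ValueError("times and activities must have equal length")
        if len(self.times_h) < 2:
            raise ValueError("need at least two time points")
        if np.any(np.diff(self.times_h) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.activities_MBq <= 0):
            raise ValueError("activities must be positive for fitting")


@dataclass(frozen=True)
class MonoExpFit:
    """Fitted y(t) = A0 exp(-lambda t)."""

    A0_MBq: float
    lambda_per_h: float
    residual_norm: float = 0.0
    physical: bool = True

    def predict(self, t_h):
        return self.A0_MBq * np.exp(-self.lambda_per_h * np.asarray(t_h, dtype=float))


def fit_monoexponential(tac: TimeActivityCurve) -> MonoExpFit:
    """Least-squares mono-exponential fit of a time-activity curve."""
    t, y = tac.times_h, tac.activities_MBq
    # log-linear closed form: exact for 2 points, initializer otherwise
    slope, intercept = np.polyfit(t, np.log(y), 1)
    A0, lam = float(np.exp(intercept)), float(-slope)

    if len(t) > 2 and lam > 0:
        try:
            popt, _ = curve_fit(
                lambda tt, a, l: a * np.exp(-l * tt), t, y,
                p0=[A0, lam], maxfev=10000,
            )
            A0, lam = float(popt[0]), float(popt[1])
        except RuntimeError:
            pass  # keep the log-linear solution

    resid = float(np.linalg.norm(y - A0 * np.exp(-lam * t)))
    return MonoExpFit(A0_MBq=A0, lambda_per_h=lam, residual_norm=resid,
                      physical=lam > 0 and A0 > 0)


def effective_half_life(fit: MonoExpFit) -> float:
    """T_eff = ln 2 / lambda (hours)."""
    if not fit.physical or fit.lambda_per_h <= 0:
        raise ValueError("non-physical fit (lambda <= 0): no effective half-life")
    return float(np.log(2.0) / fit.lambda_per_h)


def cumulated_activity(fit: MonoExpFit) -> float:
    """A~ = A0 / lambda (MBq h), the analytic integral of the fit over [0, inf)."""
    if not fit.physical or fit.lambda_per_h <= 0:
        raise ValueError("non-physical fit (lambda <= 0): integral diverges")
    return float(fit.A0_MBq / fit.lambda_per_h)


def absorbed_dose(cumulated_MBq_h: float, mass_g: float,
                  mean_electron_keV: float = LU177_MEAN_ELECTRON_KEV) -> float:
    """Electron self-dose in Gy.

    Unit chain: MBq h -> decays (x 3.6e9), x mean electron energy per decay
    (keV -> J), / mass (g -> kg) = J/kg = Gy.
    """
    if mass_g <= 0:
        raise ValueError("organ mass must be positive")
    if cumulated_MBq_h < 0 or mean_electron_keV <= 0:
        raise ValueError("cumulated activity and energy must be non-negative/positive")
    energy_J = cumulated_MBq_h * _MBQ_H_TO_DECAYS * mean_electron_keV * _KEV_TO_J
    return energy_J / (mass_g / 1000.0)


@dataclass(frozen=True)
class DoseEstimate:
    T_eff_h: float
    cumulated_MBq_h: float
    D_Gy: float
    mass_g: float
    mean_electron_keV: float = LU177_MEAN_ELECTRON_KEV

    def __post_init__(self):
        if min(self.T_eff_h, self.cumulated_MBq_h, self.D_Gy, self.mass_g) <= 0:
            raise ValueError("dose estimate fields must be positive")
        expected = absorbed_dose(self.cumulated_MBq_h, self.mass_g, self.mean_electron_keV)
        if abs(self.D_Gy - expected) > 1e-9 * max(expected, 1e-30):
            raise ValueError("D_Gy inconsistent with cumulated activity and mass")


def compare_compensations(doses: dict) -> dict:
    """Percent dose differences of AR/ARS relative to the A baseline."""
    if "A" not in doses:
        raise ValueError("missing the A (attenuation-only) baseline dose")
    base = doses["A"].D_Gy if isinstance(doses["A"], DoseEstimate) else float(doses["A"])
    out = {}
    for key, d in doses.items():
        if key == "A":
            continue
        val = d.D_Gy if isinstance(d, DoseEstimate) else float(d)
        out[key] = 100.0 * (val - base) / base
    return out


# ---------------------------------------------------------------------------
# model / results presentation
# ---------------------------------------------------------------------------

class MonoExponentialModel:
    """Mono-exponential clearance model for a time-activity curve.

    Examples
    --------
    >>> model = MonoExponentialModel([24, 48, 168], [95.3, 81.0, 40.1])
    >>> res = model.fit()
    >>> round(res.T_eff_h, 1)
    115.6
    """

    def __init__(self, times_h, activities_MBq, source: str = ""):
        self.tac = TimeActivityCurve(times_h, activities_MBq, source)

    @classmethod
    def from_dataframe(cls, df, time_col="time_h", activity_col="activity_MBq",
                       source: str = ""):
        return cls(df[time_col].to_numpy(), df[activity_col].to_numpy(), source)

    def fit(self) -> "MonoExpResults":
        return MonoExpResults(model=self, fit_=fit_monoexponential(self.tac))


@dataclass
class MonoExpResults:
    model: MonoExponentialModel
    fit_: MonoExpFit

    @property
    def A0_MBq(self) -> float:
        return self.fit_.A0_MBq

    @property
    def lambda_per_h(self) -> float:
        return self.fit_.lambda_per_h

    @property
    def T_eff_h(self) -> float:
        return effective_half_life(self.fit_)

    @property
    def cumulated_MBq_h(self) -> float:
        return cumulated_activity(self.fit_)

    def dose(self, mass_g: float,
             mean_electron_keV: float = LU177_MEAN_ELECTRON_KEV) -> DoseEstimate:
        cum = self.cumulated_MBq_h
        return DoseEstimate(
            T_eff_h=self.T_eff_h,
            cumulated_MBq_h=cum,
            D_Gy=absorbed_dose(cum, mass_g, mean_electron_keV),
            mass_g=mass_g,
            mean_electron_keV=mean_electron_keV,
        )

    def summary(self) -> str:
        f = self.fit_
        lines = [
            "Mono-exponential TAC fit",
            "------------------------",
            f"source        : {self.model.tac.source or '-'}",
            f"A0 (MBq)      : {f.A0_MBq:.4g}",
            f"lambda (1/h)  : {f.lambda_per_h:.6g}",
            f"residual norm : {f.residual_norm:.4g}",
            f"physical      : {f.physical}",
        ]
        if f.physical:
            lines += [
                f"T_eff (h)     : {self.T_eff_h:.4g}",
                f"A~ (MBq h)    : {self.cumulated_MBq_h:.4g}",
            ]
        return "\n".join(lines)
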