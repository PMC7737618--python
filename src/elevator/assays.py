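"""Functional-assay numerics: dequench percentage, Michaelis–Menten and
four-parameter-logistic melting fits.

The proton-transport readout is an ACMA fluorescence trace: a pump builds a
proton gradient (quench), substrate addition dissipates it (dequench), and
ammonium chloride collapses what remains.  The dequench percentage condenses
one trace to a number from the fluorescence at the 3, 4 and 5 minute marks.
Dose–response series of dequench values against substrate concentration are
fitted to v = V_max·S/(K_M + S); melting curves are fitted to a 4-parameter
logistic with the apparent T_m at the inflection, and ΔT_m is the shift of a
condition against its control.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import FitError, InsufficientDataError, ValidationError


@dataclass
class DequenchTrace:
    """Fluorescence trace with the assay event times (minutes).

    Defaults follow the assay protocol: gradient formation from t≈0,
    substrate addition at 3 min, the post-substrate read at 4 min and
    gradient collapse at 5 min.
    """

    time_min: np.ndarray
    fi: np.ndarray
    t_gradient: float = 0.0
    t_substrate: float = 3.0
    t_post: float = 4.0
    t_collapse: float = 5.0

    def __post_init__(self) -> None:
        self.time_min = np.asarray(self.time_min, dtype=float)
        self.fi = np.asarray(self.fi, dtype=float)
        if self.time_min.shape != self.fi.shape or self.time_min.ndim != 1:
            raise ValidationError("time and FI must be equal-length 1-D arrays")
        if np.any(np.diff(self.time_min) <= 0):
            raise ValidationError("timestamps must be strictly increasing")
        if np.any(self.fi <= 0):
            raise ValidationError("fluorescence intensities must be positive")

    def fi_at(self, t: float, tolerance: float = 0.1) -> float:
        i = int(np.argmin(np.abs(self.time_min - t)))
        if abs(self.time_min[i] - t) > tolerance:
            raise ValidationError(
                f"no sample within {tolerance} min of t = {t} min"
            )
        return float(self.fi[i])


def load_trace(path: str | Path, **event_times) -> DequenchTrace:
    """Read a ``time,FI`` CSV trace."""
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    if "time" not in cols or "fi" not in cols:
        raise ValidationError(f"trace CSV needs columns time,FI; got {list(df.columns)}")
    return DequenchTrace(
        time_min=df[cols["time"]].to_numpy(),
        fi=df[cols["fi"]].to_numpy(),
        **event_times,
    )


def dequench_percent(trace: DequenchTrace, formula: str = "span-normalized") -> float:
    """Percentage of dequenching from the 3/4/5-minute fluorescence reads.

    ``span-normalized`` (default): (FI₄ − FI₃)/(FI₅ − FI₃)·100, the fraction
    of the collapsible gradient dissipated by substrate.  ``as-printed``:
    (FI₄ − FI₃)/(FI₅/FI₃)·100, the literal form some protocols state; it is
    dimensionally odd but retained for literal reproduction.
    """
    fi3 = trace.fi_at(trace.t_substrate)
    fi4 = trace.fi_at(trace.t_post)
    fi5 = trace.fi_at(trace.t_collapse)
    if formula == "as-printed":
        denom = fi5 / fi3
        if denom == 0:
            raise FitError("degenerate trace: FI5/FI3 is zero")
        return (fi4 - fi3) / denom * 100.0
    if formula == "span-normalized":
        denom = fi5 - fi3
        if denom == 0:
            raise FitError("degenerate trace: FI5 equals FI3 (no collapsible gradient)")
        return (fi4 - fi3) / denom * 100.0
    raise ValidationError(f"unknown dequench formula {formula!r}")


# ---------------------------------------------------------------------------
# Michaelis–Menten
# ---------------------------------------------------------------------------


def michaelis_menten(s: np.ndarray, vmax: float, km: float) -> np.ndarray:
    return vmax * s / (km + s)


@dataclass
class KineticsFit:
    """Michaelis–Menten fit: K_M (mM), V_max, standard errors, residuals."""

    km: float
    vmax: float
    km_se: float
    vmax_se: float
    concentrations: np.ndarray
    responses: np.ndarray  # n_conc x n_rep
    residuals: np.ndarray = field(repr=False, default=None)

    def predicted(self, s: np.ndarray | None = None) -> np.ndarray:
        s = self.concentrations if s is None else np.asarray(s, dtype=float)
        return michaelis_menten(s, self.vmax, self.km)

    def to_dict(self) -> dict:
        return {
            "K_M_mM": self.km,
            "V_max": self.vmax,
            "K_M_se": self.km_se,
            "V_max_se": self.vmax_se,
        }


def mm_fit(concentrations, responses) -> KineticsFit:
    """Nonlinear least-squares fit of v = V_max·S/(K_M + S).

    ``responses`` is an (n_conc x n_rep) replicate matrix (a 1-D vector is
    treated as a single replicate).  Initialization: V_max⁰ = max response,
    K_M⁰ = concentration nearest half-max; Levenberg–Marquardt; standard
    errors from the Jacobian.  Invariant to concentration ordering and
    replicate permutation.
    """
    s = np.asarray(concentrations, dtype=float)
    y = np.asarray(responses, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    if y.shape[0] != s.shape[0]:
        raise ValidationError(
            f"responses ({y.shape[0]} rows) must align with concentrations ({s.shape[0]})"
        )
    if len(np.unique(s)) < 4:
        raise InsufficientDataError("need >= 4 distinct concentrations")
    if np.any(y < 0):
        raise ValidationError("responses must be nonnegative")
    if np.allclose(y, y.ravel()[0]):
        raise FitError("degenerate data: all responses equal")
    s_flat = np.repeat(s, y.shape[1])
    y_flat = y.ravel()
    vmax0 = float(y_flat.max())
    km0 = float(s[np.argmin(np.abs(y.mean(axis=1) - vmax0 / 2.0))])
    try:
        popt, pcov = curve_fit(
            michaelis_menten,
            s_flat,
            y_flat,
            p0=(vmax0, max(km0, 1e-6)),
            method="lm",
            maxfev=2000,
        )
    except RuntimeError as exc:
        raise FitError(f"Michaelis–Menten fit did not converge: {exc}") from exc
    vmax, km = float(popt[0]), float(popt[1])
    if km <= 0:
        raise FitError(f"fit produced nonpositive K_M = {km:.3g} mM")
    se = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else np.full(2, np.nan)
    resid = y_flat - michaelis_menten(s_flat, *popt)
    return KineticsFit(
        km=km,
        vmax=vmax,
        km_se=float(se[1]),
        vmax_se=float(se[0]),
        concentrations=s,
        responses=y,
        residuals=resid,
    )


def load_kinetics_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a ``conc_mM,rep1,rep2,...`` dose–response CSV."""
    df = pd.read_csv(path)
    if "conc_mM" not in df.columns:
        raise ValidationError(f"kinetics CSV needs a conc_mM column; got {list(df.columns)}")
    reps = [c for c in df.columns if c != "conc_mM"]
    if not reps:
        raise ValidationError("kinetics CSV needs at least one replicate column")
    return df["conc_mM"].to_numpy(dtype=float), df[reps].to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# 4-parameter logistic melting fits
# ---------------------------------------------------------------------------


def logistic4(t: np.ndarray, a: float, d: float, tm: float, b: float) -> np.ndarray:
    """4PL on linear temperature: y = d + (a − d)/(1 + (T/T_m)^b).

    ``a`` is the low-temperature plateau, ``d`` the high-temperature
    plateau and T_m the inflection (the EC50 analogue on temperature).
    """
    return d + (a - d) / (1.0 + (t / tm) ** b)


@dataclass
class MeltFit:
    """Apparent melting temperature from a 4PL fit."""

    tm: float
    slope: float
    plateau_low: float  # lower signal plateau
    plateau_high: float  # upper signal plateau
    tm_se: float
    temperatures: np.ndarray
    signal: np.ndarray

    def predicted(self, t: np.ndarray | None = None) -> np.ndarray:
        t = self.temperatures if t is None else np.asarray(t, dtype=float)
        # a = signal at low T; for a melting (decreasing) curve that is the
        # high plateau
        return logistic4(t, self._a, self._d, self.tm, self.slope)

    _a: float = 0.0
    _d: float = 0.0

    def to_dict(self) -> dict:
        return {
            "T_m_C": self.tm,
            "slope": self.slope,
            "plateau_low": self.plateau_low,
            "plateau_high": self.plateau_high,
            "T_m_se": self.tm_se,
        }


def logistic4_fit(temperatures, signal) -> MeltFit:
    """Fit a melting curve to the 4-parameter logistic.

    Needs ≥ 5 temperatures spanning the transition.  Initialization:
    plateaus from the curve ends, T_m from the half-signal crossing, slope
    sign from the overall trend.  Raises :class:`FitError` on flat or
    non-sigmoidal data.
    """
    t = np.asarray(temperatures, dtype=float)
    y = np.asarray(signal, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise ValidationError("temperatures and signal must be equal-length 1-D arrays")
    if len(t) < 5:
        raise InsufficientDataError("need >= 5 temperatures spanning the transition")
    if np.any(t <= 0):
        raise ValidationError("temperatures must be positive (°C scale)")
    order = np.argsort(t)
    t, y = t[order], y[order]
    span = float(y.max() - y.min())
    if span == 0 or span < 1e-12 * max(abs(y).max(), 1.0):
        raise FitError("degenerate melt data: signal is flat")
    a0 = float(np.mean(y[:2]))  # low-T end
    d0 = float(np.mean(y[-2:]))  # high-T end
    half = 0.5 * (a0 + d0)
    tm0 = float(t[np.argmin(np.abs(y - half))])
    b0 = 15.0 if a0 > d0 else -15.0
    try:
        popt, pcov = curve_fit(
            logistic4,
            t,
            y,
            p0=(a0, d0, tm0, b0),
            method="lm",
            maxfev=5000,
        )
    except RuntimeError as exc:
        raise FitError(f"4PL fit did not converge: {exc}") from exc
    a, d, tm, b = (float(v) for v in popt)
    if not (t.min() <= tm <= t.max()):
        raise FitError(
            f"fitted T_m = {tm:.1f} °C lies outside the measured range "
            f"[{t.min():.1f}, {t.max():.1f}]"
        )
    resid_fit = float(np.sum((y - logistic4(t, *popt)) ** 2))
    resid_init = float(np.sum((y - logistic4(t, a0, d0, tm0, b0)) ** 2))
    if resid_fit > resid_init + 1e-9 * max(resid_init, 1.0):
        raise FitError("4PL optimizer failed to improve on its initialization")
    se = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else np.full(4, np.nan)
    lo, hi = (d, a) if a > d else (a, d)
    fit = MeltFit(
        tm=tm,
        slope=b,
        plateau_low=lo,
        plateau_high=hi,
        tm_se=float(se[2]),
        temperatures=t,
        signal=y,
    )
    fit._a, fit._d = a, d
    return fit


def delta_tm(fit: MeltFit, control: MeltFit) -> float:
    """ΔT_m = T_m(condition) − T_m(control), in °C."""
    return fit.tm - control.tm


def load_melt_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a ``temp_C,signal`` melting-curve CSV."""
    df = pd.read_csv(path)
    needed = {"temp_C", "signal"}
    if not needed <= set(df.columns):
        raise ValidationError(f"melt CSV needs columns {sorted(needed)}; got {list(df.columns)}")
    return df["temp_C"].to_numpy(dtype=float), df["signal"].to_numpy(dtype=float)
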