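"""ATPase kinetics (Michaelis-Menten) and nanoDSF melt-curve analysis.

The transporter's ATP hydrolysis stimulated by acyl-CoA substrate follows
simple saturation kinetics, v = Vmax * s / (Km + s). Fitting is nonlinear
least squares initialised from the Hanes-Woolf linearisation
(s/v = s/Vmax + Km/Vmax), which is robust on sparse concentration grids;
standard errors come from the Jacobian-based covariance at the optimum.

Thermal stability is read from nanoDSF ratio curves: Tm is the temperature
at the extremum of the smoothed first derivative of F350/F330 over an
ascending temperature ramp.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .errors import (
    DegenerateDataError,
    FitError,
    NormalizationError,
    NoTransitionError,
    ValidationError,
)


@dataclass
class KineticsDataset:
    """Substrate concentrations (uM) and rates (mol Pi min^-1 mol^-1 protein)."""

    substrate_conc: np.ndarray
    rate: np.ndarray
    replicate_id: str | None = None

    def __post_init__(self):
        self.substrate_conc = np.asarray(self.substrate_conc, dtype=float)
        self.rate = np.asarray(self.rate, dtype=float)
        if self.substrate_conc.shape != self.rate.shape:
            raise ValidationError("substrate_conc and rate must have equal length")
        if np.any(self.substrate_conc < 0):
            raise ValidationError("substrate concentrations must be >= 0")
        if not np.all(np.isfinite(self.rate)):
            raise ValidationError("rates must be finite")


@dataclass
class MMFit:
    vmax: float
    km: float
    rss: float
    se_vmax: float
    se_km: float
    converged: bool = True
    n_obs: int = 0

    def as_dict(self) -> dict:
        return {
            "vmax": self.vmax,
            "km": self.km,
            "rss": self.rss,
            "se_vmax": self.se_vmax,
            "se_km": self.se_km,
            "converged": self.converged,
            "n_obs": self.n_obs,
        }


def mm_rate(s, vmax: float, km: float):
    """Michaelis-Menten rate v = vmax * s / (km + s).

    Accepts scalar or array s; 0 <= v < vmax with v(km) = vmax/2 exactly.
    """
    if vmax <= 0 or km <= 0:
        raise ValidationError(f"vmax and km must be > 0 (got {vmax}, {km})")
    s_arr = np.asarray(s, dtype=float)
    if np.any(s_arr < 0):
        raise ValidationError("substrate concentration must be >= 0")
    v = vmax * s_arr / (km + s_arr)
    return float(v) if np.isscalar(s) or s_arr.ndim == 0 else v


def _hanes_woolf_init(s: np.ndarray, v: np.ndarray) -> tuple[float, float]:
    """Linearised initial guess: s/v = s/vmax + km/vmax."""
    mask = (s > 0) & (v > 0)
    if mask.sum() >= 2:
        slope, intercept = np.polyfit(s[mask], s[mask] / v[mask], 1)
        if slope > 0 and intercept > 0:
            return 1.0 / slope, intercept / slope
    vmax0 = float(v.max()) * 1.2 if v.max() > 0 else 1.0
    km0 = float(np.median(s[s > 0])) if np.any(s > 0) else 1.0
    return vmax0, km0


def fit_michaelis_menten(data: KineticsDataset) -> MMFit:
    """Hanes-Woolf-initialised nonlinear least-squares fit of (Vmax, Km)."""
    s, v = data.substrate_conc, data.rate
    if len(np.unique(s)) < 3:
        raise ValidationError("need >= 3 distinct substrate concentrations")
    if not np.any(s > 0):
        raise ValidationError("need at least one positive substrate concentration")
    if np.allclose(v, 0):
        raise DegenerateDataError("all rates are zero; kinetics are unfittable")

    vmax0, km0 = _hanes_woolf_init(s, v)

    def model(x, vmax, km):
        return vmax * x / (km + x)

    try:
        popt, pcov = curve_fit(
            model, s, v, p0=[vmax0, km0],
            bounds=([1e-12, 1e-12], [np.inf, np.inf]), maxfev=10000,
        )
    except RuntimeError as exc:
        raise FitError(
            f"Michaelis-Menten fit did not converge: {exc}",
            diagnostics={"init_vmax": vmax0, "init_km": km0, "n_obs": len(s)},
        ) from exc
    vmax, km = map(float, popt)
    resid = v - model(s, vmax, km)
    rss = float(resid @ resid)
    with np.errstate(invalid="ignore"):
        se = np.sqrt(np.diag(pcov))
    return MMFit(
        vmax=vmax, km=km, rss=rss,
        se_vmax=float(se[0]), se_km=float(se[1]),
        converged=True, n_obs=len(s),
    )


# ---------------------------------------------------------------------------
# thermal melts


@dataclass
class MeltCurve:
    """nanoDSF channels over an ascending temperature ramp (degC)."""

    temperature: np.ndarray
    f350: np.ndarray
    f330: np.ndarray

    def __post_init__(self):
        self.temperature = np.asarray(self.temperature, dtype=float)
        self.f350 = np.asarray(self.f350, dtype=float)
        self.f330 = np.asarray(self.f330, dtype=float)
        if not (self.temperature.shape == self.f350.shape == self.f330.shape):
            raise ValidationError("temperature/f350/f330 must have equal length")
        if np.any(np.diff(self.temperature) <= 0):
            raise ValidationError("temperature must be strictly increasing")
        if np.any(self.f330 <= 0):
            raise ValidationError("f330 must be positive")

    @property
    def ratio(self) -> np.ndarray:
        return self.f350 / self.f330


@dataclass
class TmResult:
    tm: float
    derivative_sign: int  # +1 ratio rises through the transition, -1 falls
    peak_value: float


def melt_tm(curve: MeltCurve, smoothing_window: int = 7,
            min_peak_factor: float = 3.0) -> TmResult:
    """Tm from the extremum of the smoothed first derivative of F350/F330.

    The finite-difference derivative of the ratio is smoothed by a centred
    moving average (default window 7 points); Tm is the temperature at the
    extremum of largest magnitude. A curve whose derivative never stands
    out from its own background (max excursion < ``min_peak_factor`` x the
    median absolute excursion) has no transition and raises.
    """
    if smoothing_window < 1 or smoothing_window % 2 == 0:
        raise ValidationError("smoothing_window must be a positive odd integer")
    t = curve.temperature
    if len(t) < 11:
        raise ValidationError("need >= 11 temperature points")

    def moving_average(y: np.ndarray) -> np.ndarray:
        if smoothing_window == 1:
            return y
        pad = smoothing_window // 2
        padded = np.concatenate([np.full(pad, y[0]), y, np.full(pad, y[-1])])
        return np.convolve(padded, np.ones(smoothing_window) / smoothing_window,
                           mode="valid")

    # smooth the ratio before differentiating, then smooth the derivative:
    # the finite difference amplifies channel noise otherwise
    ratio = moving_average(curve.ratio)
    dt = moving_average(np.gradient(ratio, t))

    centred = dt - np.median(dt)
    mag = np.abs(centred)
    # the two edge-padded smoothing passes plus the gradient stencil bias up
    # to a full window at each end; exclude that from the peak search
    guard = max(smoothing_window, 1)
    interior = slice(guard, len(mag) - guard)
    peak_idx = guard + int(np.argmax(mag[interior]))
    background = float(np.median(mag))
    if mag[peak_idx] <= 1e-12 or (
        background > 0 and mag[peak_idx] < min_peak_factor * background
    ):
        raise NoTransitionError(
            "no unfolding transition: derivative extremum does not rise above background"
        )

    # sub-grid refinement: quadratic vertex over the contiguous region where
    # the signed derivative stays above half its peak (FWHM parabola)
    sign = int(np.sign(centred[peak_idx])) or 1
    y = sign * centred
    half_max = y[peak_idx] / 2.0
    lo = peak_idx
    while lo > 0 and y[lo - 1] >= half_max:
        lo -= 1
    hi = peak_idx
    while hi < len(y) - 1 and y[hi + 1] >= half_max:
        hi += 1
    tm = float(t[peak_idx])
    if hi - lo + 1 >= 3:
        a, b, _ = np.polyfit(t[lo:hi + 1], y[lo:hi + 1], 2)
        if a < 0:
            vertex = -b / (2 * a)
            if t[lo] <= vertex <= t[hi]:
                tm = float(vertex)
    return TmResult(
        tm=tm,
        derivative_sign=sign,
        peak_value=float(dt[peak_idx]),
    )


def normalize_to_wt(values: dict[str, float], wt_label: str = "WT") -> dict[str, float]:
    """Express each construct's measurement as a fraction of wild type."""
    if wt_label not in values:
        raise NormalizationError(f"wild-type label {wt_label!r} missing from panel")
    wt = values[wt_label]
    if wt == 0 or not np.isfinite(wt):
        raise NormalizationError(f"wild-type value {wt} cannot normalize the panel")
    return {k: v / wt for k, v in values.items()}
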