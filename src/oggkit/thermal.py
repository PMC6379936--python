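"""Two-state thermal denaturation analysis of CD melting curves.

The 222 nm molar-ellipticity channel tracks α-helical content; heating an
initially folded protein relaxes the strongly negative native signal toward
a shallower denatured baseline. The observed ellipticity is modelled as a
population-weighted mix of two linear baselines,

    θ(T) = f_folded(T) · θ_N(T) + (1 − f_folded(T)) · θ_D(T),

with the folded fraction given by a ΔCp = 0 van't Hoff equilibrium:

    K(T)     = exp[ −(ΔH_vH / R) (1/T − 1/Tm) ]   (T in Kelvin)
    f_folded = 1 / (1 + K)

Tm is the midpoint (K = 1, half the population unfolded) and ΔH_vH sets
the sharpness of the transition. A smoothed-derivative Tm (temperature of
the steepest ellipticity change) serves as an independent cross-check on
the parametric fit.
"""

from __future__ import annotations

from typing import Optional, Sequence, Union

import numpy as np
from scipy import optimize
from scipy.signal import savgol_filter

from .models import (
    ConfigurationError,
    DomainError,
    MeltCurve,
    MeltFit,
    NoTransitionError,
)

__all__ = [
    "R_GAS",
    "CELSIUS_OFFSET",
    "fraction_folded",
    "two_state_theta",
    "smooth_melt",
    "tm_by_derivative",
    "fit_melt",
    "fraction_denatured",
    "average_melts",
    "MeltAverage",
]

R_GAS = 8.314          # J mol^-1 K^-1
CELSIUS_OFFSET = 273.15

MIN_MELT_POINTS = 20


def fraction_folded(
    T: Union[float, np.ndarray], tm: float, dh_vh: float
) -> Union[float, np.ndarray]:
    """Folded fraction at temperature ``T`` (°C) for a two-state unfolding.

    ``tm`` is the midpoint in °C and ``dh_vh`` the van't Hoff enthalpy in
    kJ·mol⁻¹ (must be positive for a cooperative transition).
    """
    if not (dh_vh > 0):
        raise DomainError("dh_vh must be > 0")
    t_abs = np.asarray(T, dtype=float) + CELSIUS_OFFSET
    tm_abs = tm + CELSIUS_OFFSET
    k_eq = np.exp(-(dh_vh * 1e3 / R_GAS) * (1.0 / t_abs - 1.0 / tm_abs))
    f = 1.0 / (1.0 + k_eq)
    if np.isscalar(T) or np.ndim(T) == 0:
        return float(f)
    return f


def two_state_theta(
    T: np.ndarray,
    tm: float,
    dh_vh: float,
    native_baseline: tuple,
    denatured_baseline: tuple,
) -> np.ndarray:
    """Model ellipticity: folded/unfolded mix of two linear baselines."""
    f = fraction_folded(T, tm, dh_vh)
    theta_n = native_baseline[0] + native_baseline[1] * T
    theta_d = denatured_baseline[0] + denatured_baseline[1] * T
    return f * theta_n + (1.0 - f) * theta_d


def smooth_melt(curve: MeltCurve, window: int = 11, order: int = 3) -> MeltCurve:
    """Savitzky–Golay smoothing of the ellipticity trace.

    ``window`` must be odd, larger than ``order`` and smaller than the
    number of points; endpoints are handled by polynomial extension
    (``mode='interp'``). Idempotent to within the noise floor on data that
    are already smooth.
    """
    if window % 2 == 0 or window <= order or window >= curve.n_points:
        raise ConfigurationError(
            f"invalid smoothing window/order ({window}, {order}) "
            f"for {curve.n_points} points"
        )
    theta = savgol_filter(curve.theta222, window, order, mode="interp")
    return MeltCurve(
        variant=curve.variant,
        replicate=curve.replicate,
        temperature=curve.temperature.copy(),
        theta222=theta,
    )


def _derivative(curve: MeltCurve) -> np.ndarray:
    return np.gradient(curve.theta222, curve.temperature)


def tm_by_derivative(
    curve: MeltCurve,
    *,
    window: int = 11,
    order: int = 3,
    smooth: bool = True,
) -> float:
    """Tm as the temperature of maximum |dθ/dT|.

    The discrete maximum is refined by local quadratic interpolation over
    its three-point neighbourhood. A maximum at the edge of the scanned
    range, or a derivative with no clear peak (a featureless sloped line),
    raises :class:`NoTransitionError`.
    """
    work = smooth_melt(curve, window, order) if smooth else curve
    d = np.abs(_derivative(work))
    # the Savitzky-Golay endpoint extension can fabricate steep derivatives
    # in the first/last half-window; search the interior only
    hw = window // 2 if smooth else 1
    interior = d[hw : d.size - hw]
    i = hw + int(np.argmax(interior))
    if i <= hw or i >= d.size - 1 - hw:
        raise NoTransitionError(
            "derivative maximum at the edge of the temperature range"
        )
    med = float(np.median(d))
    if med > 0 and d[i] < 1.5 * med:
        raise NoTransitionError("no clear unfolding transition in the scan")
    # quadratic through the three points around the maximum
    t3 = work.temperature[i - 1 : i + 2]
    d3 = d[i - 1 : i + 2]
    a, b, _ = np.polyfit(t3, d3, 2)
    if a == 0:
        return float(t3[1])
    t_peak = -b / (2.0 * a)
    lo, hi = float(t3[0]), float(t3[2])
    return float(min(max(t_peak, lo), hi))


def _edge_baseline(T: np.ndarray, theta: np.ndarray, frac: float, side: str) -> tuple:
    n = max(int(round(frac * T.size)), 5)
    sl = slice(0, n) if side == "low" else slice(T.size - n, T.size)
    slope, intercept = np.polyfit(T[sl], theta[sl], 1)
    return float(intercept), float(slope)


def fit_melt(
    curve: MeltCurve,
    *,
    dh_init: float = 200.0,
    baseline_fraction: float = 0.15,
    smoothing_window: int = 11,
    smoothing_order: int = 3,
) -> MeltFit:
    """Six-parameter two-state fit of a melting curve.

    Free parameters: Tm, ΔH_vH and the (intercept, slope) pairs of the
    native and denatured baselines. The parametric fit runs on the raw
    (unsmoothed) ellipticities; smoothing enters only through the
    derivative-method Tm that is fitted's cross-check and initial guess.

    Raises :class:`NoTransitionError` when the scan shows no interior
    transition, and :class:`~oggkit.models.InsufficientDataError`-like
    ``DomainError`` when fewer than 20 points are supplied.
    """
    if curve.n_points < MIN_MELT_POINTS:
        raise DomainError(
            f"melt fit needs >= {MIN_MELT_POINTS} points, got {curve.n_points}"
        )
    T, theta = curve.temperature, curve.theta222
    tm0 = tm_by_derivative(
        curve, window=smoothing_window, order=smoothing_order, smooth=True
    )
    nat0 = _edge_baseline(T, theta, baseline_fraction, "low")
    den0 = _edge_baseline(T, theta, baseline_fraction, "high")
    x0 = np.array([tm0, dh_init, nat0[0], nat0[1], den0[0], den0[1]])

    def resid(x: np.ndarray) -> np.ndarray:
        return (
            two_state_theta(T, x[0], x[1], (x[2], x[3]), (x[4], x[5])) - theta
        )

    span = float(T.max() - T.min())
    lower = np.array([T.min() + 0.01 * span, 10.0, -np.inf, -np.inf, -np.inf, -np.inf])
    upper = np.array([T.max() - 0.01 * span, 5000.0, np.inf, np.inf, np.inf, np.inf])
    x0 = np.clip(x0, lower, upper)
    res = optimize.least_squares(
        resid, x0, bounds=(lower, upper), method="trf",
        xtol=1e-14, ftol=1e-14, gtol=1e-14,
    )
    rss = float(res.fun @ res.fun)
    dof = max(curve.n_points - 6, 1)
    jtj = res.jac.T @ res.jac
    try:
        cov = np.linalg.inv(jtj) * rss / dof
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(jtj) * rss / dof
    se_tm = float(np.sqrt(max(cov[0, 0], 0.0)))
    tm, dh = float(res.x[0]), float(res.x[1])
    msg = ""
    if abs(tm - tm0) > 2.0:
        msg = (
            f"two-state Tm ({tm:.2f} °C) and derivative Tm ({tm0:.2f} °C) "
            "disagree by > 2 °C; sloping baselines bias the derivative method"
        )
    return MeltFit(
        tm=tm,
        dh_vh=dh,
        native_baseline=(float(res.x[2]), float(res.x[3])),
        denatured_baseline=(float(res.x[4]), float(res.x[5])),
        method="two_state_fit",
        se_tm=se_tm,
        rss=rss,
        n_points=curve.n_points,
        variant=curve.variant,
        tm_derivative=tm0,
        message=msg,
    )


def fraction_denatured(
    curve: MeltCurve, fit: MeltFit, *, flag_beyond: float = 0.05
) -> tuple[np.ndarray, bool]:
    """Baseline-corrected fraction denatured along the scan.

    Returns ``(fraction, flagged)`` where ``flagged`` is True when the
    normalized signal strays beyond ``[-flag_beyond, 1 + flag_beyond]``
    (more than noise-level excursions outside the physical range).
    """
    T = curve.temperature
    theta_n = fit.native_baseline[0] + fit.native_baseline[1] * T
    theta_d = fit.denatured_baseline[0] + fit.denatured_baseline[1] * T
    denom = theta_d - theta_n
    if np.any(np.abs(denom) < 1e-12):
        raise DomainError("degenerate baselines: zero native-denatured contrast")
    frac = (curve.theta222 - theta_n) / denom
    flagged = bool(np.any(frac < -flag_beyond) or np.any(frac > 1 + flag_beyond))
    return frac, flagged


class MeltAverage:
    """Replicate-averaged melt: per-replicate Tm values and the mean
    normalized denaturation curve on the common temperature grid."""

    def __init__(
        self,
        variant: str,
        tm_values: list,
        tm_mean: float,
        tm_sd: Optional[float],
        temperature: np.ndarray,
        mean_fraction_denatured: np.ndarray,
        fits: list,
    ) -> None:
        self.variant = variant
        self.tm_values = tm_values
        self.tm_mean = tm_mean
        self.tm_sd = tm_sd
        self.temperature = temperature
        self.mean_fraction_denatured = mean_fraction_denatured
        self.fits = fits

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        sd = "n/a" if self.tm_sd is None else f"{self.tm_sd:.2f}"
        return (
            f"MeltAverage({self.variant!r}, Tm = {self.tm_mean:.2f} ± {sd} °C, "
            f"n = {len(self.tm_values)})"
        )


def average_melts(
    replicates: Sequence[MeltCurve], *, temp_tol: float = 1e-6, **fit_kwargs
) -> MeltAverage:
    """Fit each replicate melt and summarise Tm across replicates.

    Replicate grids must agree within ``temp_tol`` °C. With a single
    replicate the mean is returned and the SD reported absent (None);
    otherwise the sample SD (n−1) over per-replicate Tm values is given,
    alongside the mean baseline-normalized fraction-denatured curve.
    """
    if not replicates:
        raise ValueError("no melt curves supplied")
    ref = replicates[0].temperature
    for c in replicates[1:]:
        if c.temperature.size != ref.size or np.any(
            np.abs(c.temperature - ref) > temp_tol
        ):
            raise DomainError("replicate temperature grids do not align")
    fits = [fit_melt(c, **fit_kwargs) for c in replicates]
    fracs = np.array(
        [fraction_denatured(c, f)[0] for c, f in zip(replicates, fits)]
    )
    tm_values = [f.tm for f in fits]
    tm_mean = float(np.mean(tm_values))
    tm_sd = float(np.std(tm_values, ddof=1)) if len(tm_values) > 1 else None
    return MeltAverage(
        variant=replicates[0].variant,
        tm_values=tm_values,
        tm_mean=tm_mean,
        tm_sd=tm_sd,
        temperature=ref.copy(),
        mean_fraction_denatured=fracs.mean(axis=0),
        fits=fits,
    )
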