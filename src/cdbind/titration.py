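"""Fluorescence-titration binding analysis for a 1:1 host-guest complex.

The double-reciprocal (Benesi-Hildebrand) linearization

    1/dF = 1/dF_C + 1/(K_C * dF_C * [CD]_0)

is fitted by ordinary least squares of 1/dF against 1/[CD]_0 over the
nonzero host concentrations; the association constant is
``intercept/slope``.  A direct nonlinear fit of the isotherm is provided
as a cross-check, together with a linearity-based stoichiometry verdict.
The excess-host approximation ([CD]_free = [CD]_0) is built in; the
nonlinear fitter can optionally solve the exact 1:1 mass balance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "TitrationSeries",
    "BindingFit",
    "TitrationError",
    "fit_benesi_hildebrand",
    "fit_isotherm_nonlinear",
    "stoichiometry_check",
]


class TitrationError(RuntimeError):
    """Raised for degenerate or assumption-violating titration data."""


@dataclass(frozen=True)
class TitrationSeries:
    """Host concentrations (M, increasing, first entry 0) and intensities.

    The zero-concentration intensity is the reference F0 from which all
    dF values are measured.
    """

    cd_conc: np.ndarray
    intensity: np.ndarray
    guest_conc: float = 25e-6

    def __post_init__(self) -> None:
        c = np.asarray(self.cd_conc, dtype=float)
        f = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "cd_conc", c)
        object.__setattr__(self, "intensity", f)
        if c.size != f.size:
            raise ValueError("cd_conc and intensity must have equal lengths")
        if c.size < 2:
            raise ValueError("need the zero point plus at least one titration point")
        if c[0] != 0.0:
            raise ValueError("first concentration must be 0 (reference intensity)")
        if np.any(np.diff(c) <= 0):
            raise ValueError("concentrations must be strictly increasing")
        if np.any(c < 0):
            raise ValueError("concentrations must be non-negative")
        if not np.all(np.isfinite(f)):
            raise ValueError("intensities must be finite")

    @property
    def delta_f(self) -> np.ndarray:
        """dF = F(c) - F(0) over the nonzero concentrations."""
        return self.intensity[1:] - self.intensity[0]

    @property
    def nonzero_conc(self) -> np.ndarray:
        return self.cd_conc[1:]


@dataclass(frozen=True)
class BindingFit:
    kc: float  # 1/M
    dF_c: float
    r_squared: float
    stderr_kc: float = float("nan")
    method: str = "benesi_hildebrand"

    def __post_init__(self) -> None:
        if self.kc <= 0:
            raise TitrationError("fitted association constant is non-positive")


def _reciprocal_regression(series: TitrationSeries):
    df = series.delta_f
    if np.any(df <= 0):
        raise TitrationError(
            "non-positive dF at a nonzero concentration: the fluorescence "
            "enhancement assumption of the double-reciprocal fit is violated"
        )
    x = 1.0 / series.nonzero_conc
    y = 1.0 / df
    if x.size < 4:
        raise TitrationError("need at least 4 nonzero-concentration points")
    (slope, intercept), cov = np.polyfit(x, y, 1, cov=True)
    pred = slope * x + intercept
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return float(slope), float(intercept), cov, r2


def fit_benesi_hildebrand(series: TitrationSeries) -> BindingFit:
    """Double-reciprocal estimate: ``K_C = intercept/slope``.

    ``dF_C = 1/intercept``.  The standard error of K_C comes from
    first-order propagation of the regression coefficient covariance.
    """
    slope, intercept, cov, r2 = _reciprocal_regression(series)
    if slope == 0:
        raise TitrationError("zero slope: association constant diverges")
    if abs(intercept) < 1e-12 * abs(slope):
        raise TitrationError(
            "near-zero intercept: the data are saturating and K_C is unstable"
        )
    kc = intercept / slope
    # K = b/m: grad = (dK/dm, dK/db) = (-b/m^2, 1/m)
    grad = np.array([-intercept / slope**2, 1.0 / slope])
    var_kc = float(grad @ cov @ grad)
    return BindingFit(
        kc=kc,
        dF_c=1.0 / intercept,
        r_squared=min(max(r2, 0.0), 1.0),
        stderr_kc=float(np.sqrt(max(var_kc, 0.0))),
        method="benesi_hildebrand",
    )


def _isotherm_excess(c: np.ndarray, dfc: float, kc: float) -> np.ndarray:
    return dfc * kc * c / (1.0 + kc * c)


def _isotherm_exact(c: np.ndarray, dfc: float, kc: float, guest: float) -> np.ndarray:
    # exact 1:1 mass balance: complex concentration from the quadratic
    s = c + guest + 1.0 / kc
    complexed = 0.5 * (s - np.sqrt(s**2 - 4.0 * c * guest))
    return dfc * complexed / guest


def fit_isotherm_nonlinear(
    series: TitrationSeries,
    mass_balance: Literal["excess_host", "exact"] = "excess_host",
) -> BindingFit:
    """Direct nonlinear least squares of ``dF(c) = dF_C K_C c / (1 + K_C c)``.

    With ``mass_balance='exact'`` the exact 1:1 quadratic is solved
    instead of the excess-host approximation (validation only).  On
    noise-free data the estimate agrees with the double-reciprocal one.
    """
    c = series.nonzero_conc
    df = series.delta_f
    if np.any(df <= 0):
        raise TitrationError("non-positive dF at a nonzero concentration")
    try:
        bh = fit_benesi_hildebrand(series)
        p0 = [bh.dF_c, bh.kc]
    except TitrationError:
        p0 = [float(df.max()) * 1.5, 1.0 / float(np.median(c))]

    if mass_balance == "excess_host":
        model = _isotherm_excess
    elif mass_balance == "exact":
        def model(cc, dfc, kc):
            return _isotherm_exact(cc, dfc, kc, series.guest_conc)
    else:
        raise ValueError(f"unknown mass_balance {mass_balance!r}")

    popt, pcov = curve_fit(model, c, df, p0=p0, maxfev=20000)
    dfc, kc = (float(v) for v in popt)
    # saturation diagnostic: all points in the flat regime leave K_C free
    if kc * c.min() > 20.0:
        raise TitrationError(
            "all points are saturated (K_C*c >> 1 everywhere): K_C is unidentifiable"
        )
    pred = model(c, *popt)
    ss_res = float(np.sum((df - pred) ** 2))
    ss_tot = float(np.sum((df - df.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return BindingFit(
        kc=kc,
        dF_c=dfc,
        r_squared=min(max(r2, 0.0), 1.0),
        stderr_kc=float(np.sqrt(max(pcov[1, 1], 0.0))),
        method=f"nonlinear_{mass_balance}",
    )


def stoichiometry_check(
    series: TitrationSeries, r2_threshold: float = 0.99
) -> tuple[float, str]:
    """Linearity of the double-reciprocal plot as a 1:1 consistency check.

    Returns ``(r_squared, verdict)``.  A straight double-reciprocal plot
    is *consistent with* (never proof of) 1:1 stoichiometry.
    """
    if np.ptp(series.intensity) == 0:
        return float("nan"), "no binding signal"
    try:
        _, _, _, r2 = _reciprocal_regression(series)
    except TitrationError as err:
        return float("nan"), f"not assessable: {err}"
    verdict = (
        "consistent with 1:1" if r2 >= r2_threshold else "inconsistent with 1:1"
    )
    return r2, verdict
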