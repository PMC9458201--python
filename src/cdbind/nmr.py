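"""NMR-side estimators.

Inversion-recovery T1 fitting (three-parameter mono-exponential
``B + F*exp(-x*G)`` with ``T1 = 1/G``), the tabulated percentage-change
metric for T1 pairs, Stejskal-Tanner log-linear diffusion fitting for
pulsed-field-gradient attenuation data, and chemical-shift-perturbation
bookkeeping for free-vs-complex peak tables.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .constants import GAMMA_1H, GAUSS_PER_CM_TO_T_PER_M

__all__ = [
    "DecaySeries",
    "RelaxationFit",
    "DiffusionFit",
    "ShiftTable",
    "ShiftEntry",
    "FitError",
    "fit_inversion_recovery",
    "t1_percentage_change",
    "fit_diffusion",
    "shift_differences",
    "rank_perturbations",
    "round_half_up",
]


class FitError(RuntimeError):
    """Raised when a series cannot be fitted meaningfully."""


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Decimal round-half-up (printed-table convention, unlike banker's).

    The value is first quantized six digits below the target so that
    binary-float artifacts (1.005 - 1.0 = 0.004999...) do not flip a
    half-way case the wrong way.
    """
    d = decimal.Decimal(repr(float(x)))
    d = d.quantize(decimal.Decimal(1).scaleb(-(ndigits + 6)), rounding=decimal.ROUND_HALF_EVEN)
    d = d.quantize(decimal.Decimal(1).scaleb(-ndigits), rounding=decimal.ROUND_HALF_UP)
    return float(d)


@dataclass(frozen=True)
class DecaySeries:
    """A generic (x, signal) series for relaxation or diffusion fitting.

    ``x`` is the delay in seconds for ``kind='inversion_recovery'`` and
    the gradient strength in gauss/cm for ``kind='gradient_decay'``; the
    gradient kind must carry its acquisition constants (gamma in
    rad s^-1 T^-1, little_delta and big_delta in s).
    """

    x: np.ndarray
    signal: np.ndarray
    kind: Literal["inversion_recovery", "gradient_decay"]
    gamma: float = GAMMA_1H
    little_delta: float | None = None
    big_delta: float | None = None

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        s = np.asarray(self.signal, dtype=float)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "signal", s)
        if x.size != s.size:
            raise ValueError("x and signal must have equal lengths")
        if np.any(x < 0):
            raise ValueError("x values must be non-negative")
        if not np.all(np.isfinite(s)):
            raise ValueError("signal must be finite")

    def n_distinct(self) -> int:
        return int(np.unique(self.x).size)


@dataclass(frozen=True)
class RelaxationFit:
    """Result of a three-parameter inversion-recovery fit."""

    B: float
    F: float
    G: float
    residual_rms: float

    def __post_init__(self) -> None:
        if self.G <= 0:
            raise ValueError("relaxation rate G must be positive")

    @property
    def T1(self) -> float:
        return 1.0 / self.G


@dataclass(frozen=True)
class DiffusionFit:
    """Result of a Stejskal-Tanner log-linear fit."""

    D: float  # m^2/s
    I0: float
    r_squared: float


def _model(x: np.ndarray, b: float, f: float, g: float) -> np.ndarray:
    return b + f * np.exp(-x * g)


def fit_inversion_recovery(
    series: DecaySeries,
    max_restarts: int = 5,
    seed: int = 0,
) -> RelaxationFit:
    """Nonlinear least-squares fit of ``B + F*exp(-x*G)``; ``T1 = 1/G``.

    Initialization: ``B0`` is the signal at the longest delay, ``F0`` the
    offset of the shortest-delay signal from ``B0``, and ``G0`` comes
    from a log-linear regression of ``|signal - B0|``.  On convergence
    failure the fit is restarted with jittered ``G0`` (seeded, at most
    ``max_restarts`` times).
    """
    if series.kind != "inversion_recovery":
        raise ValueError("series kind must be 'inversion_recovery'")
    if series.n_distinct() < 3:
        raise FitError("need at least 3 distinct delays to fit 3 parameters")
    x, y = series.x, series.signal
    if np.ptp(y) <= 1e-12 * max(1.0, float(np.abs(y).max())):
        raise FitError("flat signal: amplitude F is zero and G is unidentifiable")

    order = np.argsort(x)
    x, y = x[order], y[order]
    b0 = float(y[-1])
    f0 = float(y[0] - b0)
    resid = np.abs(y - b0)
    usable = resid > 1e-3 * max(abs(f0), np.ptp(y))
    if usable.sum() >= 2:
        slope = np.polyfit(x[usable], np.log(resid[usable]), 1)[0]
        g0 = -slope if slope < 0 else 1.0 / max(x[x > 0].mean(), 1e-12)
    else:
        g0 = 1.0 / max(x[x > 0].mean(), 1e-12)

    rng = np.random.default_rng(seed)
    last_err: Exception | None = None
    for attempt in range(max_restarts + 1):
        g_init = g0 if attempt == 0 else g0 * float(rng.lognormal(0.0, 0.5))
        try:
            popt, _ = curve_fit(_model, x, y, p0=[b0, f0, g_init], maxfev=10000)
            b, f, g = (float(v) for v in popt)
            if g <= 0:
                raise FitError("fitted relaxation rate is non-positive")
            rms = float(np.sqrt(np.mean((_model(x, b, f, g) - y) ** 2)))
            return RelaxationFit(B=b, F=f, G=g, residual_rms=rms)
        except (RuntimeError, FitError) as err:  # curve_fit raises RuntimeError
            last_err = err
    raise FitError(f"inversion-recovery fit did not converge after restarts: {last_err}")


def t1_percentage_change(t1_free: float, t1_complex: float) -> int:
    """Tabulated percentage-change metric for a T1 pair.

    Returns ``|t1_free - t1_complex| * 100`` rounded half-up to an
    integer, i.e. the absolute difference in seconds scaled by 100 - the
    convention that reproduces every scalar printed row.  For the
    conventional relative change use :func:`t1_relative_change`.
    """
    return int(round_half_up(abs(t1_free - t1_complex) * 100.0))


def t1_relative_change(t1_free: float, t1_complex: float) -> float:
    """Conventional relative change in percent, ``|dT1|/T1_free * 100``."""
    if t1_free == 0:
        raise ValueError("t1_free must be nonzero")
    return abs(t1_free - t1_complex) / abs(t1_free) * 100.0


def stejskal_tanner_abscissa(series: DecaySeries) -> np.ndarray:
    """``gamma^2 g^2 delta^2 (Delta - delta/3)`` in SI units (s/m^2)."""
    if series.little_delta is None or series.big_delta is None:
        raise ValueError("gradient series must carry little_delta and big_delta")
    g_si = series.x * GAUSS_PER_CM_TO_T_PER_M
    return (
        series.gamma**2
        * g_si**2
        * series.little_delta**2
        * (series.big_delta - series.little_delta / 3.0)
    )


def fit_diffusion(series: DecaySeries) -> DiffusionFit:
    """Diffusion coefficient from a gradient-attenuation series.

    Ordinary least squares of ``ln(I)`` against the Stejskal-Tanner
    abscissa; the slope is ``-D`` and ``exp(intercept)`` recovers the
    zero-gradient intensity.
    """
    if series.kind != "gradient_decay":
        raise ValueError("series kind must be 'gradient_decay'")
    if np.any(series.signal <= 0):
        raise FitError("non-positive intensities cannot be log-fitted")
    x = stejskal_tanner_abscissa(series)
    if np.unique(x).size < 3:
        raise FitError("need at least 3 distinct abscissa points")
    y = np.log(series.signal)
    slope, intercept = np.polyfit(x, y, 1)
    pred = slope * x + intercept
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return DiffusionFit(D=float(-slope), I0=float(np.exp(intercept)), r_squared=r2)


# ---------------------------------------------------------------------------
# chemical-shift perturbation


@dataclass(frozen=True)
class ShiftEntry:
    """One peak: a scalar shift in ppm, or a (high, low) ppm interval for
    ranged multiplets."""

    label: str
    value: float | None = None
    interval: tuple | None = None

    def __post_init__(self) -> None:
        if (self.value is None) == (self.interval is None):
            raise ValueError("exactly one of value or interval must be given")

    @property
    def is_scalar(self) -> bool:
        return self.value is not None


@dataclass(frozen=True)
class ShiftTable:
    """An ordered list of peaks.  Duplicate labels are permitted (printed
    tables reuse labels for distinct peaks); matching between tables is by
    label occurrence order."""

    entries: Sequence[ShiftEntry]

    def __post_init__(self) -> None:
        object.__setattr__(self, "entries", tuple(self.entries))


@dataclass(frozen=True)
class ShiftDifference:
    label: str
    delta: float | None  # |free - complex| in ppm, rounded to 2 decimals
    interval_delta: tuple | None = None  # per-endpoint differences for ranged rows
    missing_in: str | None = None  # "free"/"complex" when unmatched

    @property
    def is_scalar(self) -> bool:
        return self.delta is not None


def _occurrence_keys(entries: Sequence[ShiftEntry]) -> list[tuple]:
    seen: dict = {}
    keys = []
    for e in entries:
        k = seen.get(e.label, 0)
        seen[e.label] = k + 1
        keys.append((e.label, k))
    return keys


def shift_differences(free: ShiftTable, complexed: ShiftTable) -> list[ShiftDifference]:
    """Per-peak ``|delta_free - delta_complex|`` rounded to 2 decimals.

    Peaks are matched by label (k-th occurrence to k-th occurrence).
    Ranged (interval) rows yield per-endpoint interval differences and are
    flagged non-scalar; unmatched labels are reported as missing, never
    as zero.
    """
    free_map = dict(zip(_occurrence_keys(free.entries), free.entries))
    cx_map = dict(zip(_occurrence_keys(complexed.entries), complexed.entries))
    out: list[ShiftDifference] = []
    for key, fe in free_map.items():
        ce = cx_map.get(key)
        if ce is None:
            out.append(ShiftDifference(label=fe.label, delta=None, missing_in="complex"))
            continue
        if fe.is_scalar and ce.is_scalar:
            out.append(
                ShiftDifference(label=fe.label, delta=round_half_up(abs(fe.value - ce.value), 2))
            )
        else:
            fi = fe.interval if fe.interval is not None else (fe.value, fe.value)
            ci = ce.interval if ce.interval is not None else (ce.value, ce.value)
            iv = tuple(round_half_up(abs(a - b), 2) for a, b in zip(fi, ci))
            out.append(ShiftDifference(label=fe.label, delta=None, interval_delta=iv))
    for key, ce in cx_map.items():
        if key not in free_map:
            out.append(ShiftDifference(label=ce.label, delta=None, missing_in="free"))
    return out


def rank_perturbations(differences: Sequence[ShiftDifference]) -> list[str]:
    """Scalar-row labels ordered by descending perturbation, ties
    broken lexicographically."""
    scalars = [d for d in differences if d.is_scalar]
    return [d.label for d in sorted(scalars, key=lambda d: (-d.delta, d.label))]
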