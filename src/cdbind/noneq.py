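"""Bidirectional non-equilibrium work analysis.

Free-energy estimation from forward/reverse work samples via the
maximum-likelihood (Bennett/Crooks) estimator, one-sided exponential
averaging as a diagnostic, bootstrap uncertainties, and an overlap
coefficient between the two work distributions.

Sign convention: reverse works are stored as the work performed along the
reverse transition, so ``-W_rev`` is the reverse-side estimate of the
forward free-energy difference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np
from scipy.special import expit, logsumexp

from .constants import beta as _beta

__all__ = [
    "WorkSet",
    "FreeEnergyEstimate",
    "EstimationError",
    "cft_ml_estimate",
    "jarzynski_estimate",
    "bootstrap_uncertainty",
    "work_overlap",
]


class EstimationError(RuntimeError):
    """Raised when an estimator cannot produce a meaningful result."""


@dataclass(frozen=True)
class WorkSet:
    """Labelled forward/reverse non-equilibrium work samples.

    Parameters
    ----------
    forward_works, reverse_works:
        Work values in kcal/mol.  Reverse works follow the
        reverse-direction convention (see module docstring).
    temperature:
        Kelvin.
    label:
        Free-text leg identifier (e.g. ``"solvation"``).
    """

    forward_works: np.ndarray
    reverse_works: np.ndarray
    temperature: float = 298.0
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "forward_works", np.asarray(self.forward_works, dtype=float))
        object.__setattr__(self, "reverse_works", np.asarray(self.reverse_works, dtype=float))
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        for name in ("forward_works", "reverse_works"):
            arr = getattr(self, name)
            if arr.ndim != 1:
                raise ValueError(f"{name} must be one-dimensional")
            if arr.size and not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite values")

    @property
    def n_forward(self) -> int:
        return int(self.forward_works.size)

    @property
    def n_reverse(self) -> int:
        return int(self.reverse_works.size)

    def swapped(self) -> "WorkSet":
        """The work set for the opposite process direction."""
        return WorkSet(
            forward_works=self.reverse_works.copy(),
            reverse_works=self.forward_works.copy(),
            temperature=self.temperature,
            label=self.label,
        )


@dataclass(frozen=True)
class FreeEnergyEstimate:
    """A free-energy value with its uncertainty and provenance."""

    value: float
    uncertainty: float = 0.0
    method: str = "cft_ml"
    n_bootstrap: int = 0
    overlap: float = float("nan")
    label: str = ""

    def __post_init__(self) -> None:
        if self.uncertainty < 0:
            raise ValueError("uncertainty must be non-negative")
        if np.isfinite(self.overlap) and not (0.0 <= self.overlap <= 1.0 + 1e-12):
            raise ValueError("overlap must lie in [0, 1]")


def _ml_residual(dg: float, w_f: np.ndarray, r: np.ndarray, beta: float, log_ratio: float) -> float:
    # Fermi-function form of the two-sided self-consistency equation;
    # expit avoids overflow at the bracket extremes.
    fwd = expit(-(beta * (w_f - dg) + log_ratio))
    rev = expit(-(beta * (dg - r) - log_ratio))
    return float(np.sum(fwd) - np.sum(rev))


def cft_ml_estimate(
    works: WorkSet,
    *,
    xtol: float = 1e-10,
    bracket_width_kt: float = 50.0,
    n_bootstrap: int = 0,
    seed: int | None = None,
    n_bins: int | None = None,
) -> FreeEnergyEstimate:
    """Maximum-likelihood free-energy estimate from bidirectional works.

    Solves the two-sided self-consistency equation

    .. math::

        \\sum_i \\left[1 + \\tfrac{n_F}{n_R} e^{\\beta(W_i^F - \\Delta G)}\\right]^{-1}
        = \\sum_j \\left[1 + \\tfrac{n_R}{n_F} e^{\\beta(\\Delta G + W_j^R)}\\right]^{-1}

    by bisection on a bracket spanning the pooled work range.  The residual
    is strictly monotone in ``dG`` so the root is unique.

    When ``n_bootstrap >= 2`` the returned estimate also carries a
    bootstrap standard error and the Bhattacharyya overlap coefficient.
    """
    if works.n_forward < 1 or works.n_reverse < 1:
        raise EstimationError("need at least one work value on each side")
    b = _beta(works.temperature)
    kt = 1.0 / b
    w_f = works.forward_works
    r = -works.reverse_works  # reverse-side estimates on the forward scale
    log_ratio = np.log(works.n_forward / works.n_reverse)

    pool = np.concatenate([w_f, r])
    lo = float(pool.min()) - bracket_width_kt * kt
    hi = float(pool.max()) + bracket_width_kt * kt

    f_lo = _ml_residual(lo, w_f, r, b, log_ratio)
    f_hi = _ml_residual(hi, w_f, r, b, log_ratio)
    widenings = 0
    while f_lo * f_hi > 0 and widenings < 10:
        span = hi - lo
        lo -= span
        hi += span
        f_lo = _ml_residual(lo, w_f, r, b, log_ratio)
        f_hi = _ml_residual(hi, w_f, r, b, log_ratio)
        widenings += 1
    if f_lo * f_hi > 0:
        raise EstimationError(
            "self-consistency residual has no sign change: forward and "
            f"reverse samples do not overlap (residuals {f_lo:.3g}, {f_hi:.3g} "
            f"on [{lo:.3g}, {hi:.3g}])"
        )

    while hi - lo > xtol:
        mid = 0.5 * (lo + hi)
        f_mid = _ml_residual(mid, w_f, r, b, log_ratio)
        if f_lo * f_mid <= 0:
            hi = mid
        else:
            lo, f_lo = mid, f_mid
    value = 0.5 * (lo + hi)

    uncertainty = 0.0
    if n_bootstrap:
        uncertainty = bootstrap_uncertainty(
            works, lambda ws: cft_ml_estimate(ws).value, n_boot=n_bootstrap, seed=seed
        )
    return FreeEnergyEstimate(
        value=value,
        uncertainty=uncertainty,
        method="cft_ml",
        n_bootstrap=n_bootstrap,
        overlap=work_overlap(works, n_bins=n_bins),
        label=works.label,
    )


def jarzynski_estimate(
    works: Sequence[float] | np.ndarray,
    temperature: float,
    direction: Literal["forward", "reverse"] = "forward",
) -> FreeEnergyEstimate:
    """One-sided exponential-average estimate (diagnostic only).

    ``dG = -kT ln <exp(-beta W)>`` for the forward direction; the reverse
    direction estimates ``-dG`` and the sign is flipped accordingly.  The
    estimator is biased at finite sample size and is provided only as a
    cross-check on the two-sided result.
    """
    w = np.asarray(works, dtype=float)
    if w.size < 1:
        raise EstimationError("need at least one work value")
    if direction not in ("forward", "reverse"):
        raise ValueError(f"unknown direction {direction!r}")
    b = _beta(temperature)
    kt = 1.0 / b
    dg = -kt * (logsumexp(-b * w) - np.log(w.size))
    if direction == "reverse":
        dg = -dg
    return FreeEnergyEstimate(value=float(dg), method=f"jarzynski_{direction[:3]}")


def bootstrap_uncertainty(
    works: WorkSet,
    estimator: Callable[[WorkSet], float],
    n_boot: int = 1000,
    seed: int | None = None,
) -> float:
    """Bootstrap standard error of ``estimator`` over resampled work sets.

    Forward and reverse lists are resampled independently with
    replacement (the two directions are independent experiments).
    """
    if n_boot < 2:
        raise ValueError("n_boot must be at least 2")
    rng = np.random.default_rng(seed)
    values = np.empty(n_boot)
    for i in range(n_boot):
        fwd = rng.choice(works.forward_works, size=works.n_forward, replace=True)
        rev = rng.choice(works.reverse_works, size=works.n_reverse, replace=True)
        values[i] = estimator(
            WorkSet(fwd, rev, temperature=works.temperature, label=works.label)
        )
    return float(np.std(values, ddof=1))


def work_overlap(works: WorkSet, n_bins: int | None = None) -> float:
    """Bhattacharyya coefficient between forward and mirrored-reverse works.

    Both samples are histogrammed on shared bin edges (Freedman-Diaconis
    on the pooled sample unless ``n_bins`` is given) and the coefficient
    ``sum(sqrt(p_i * q_i))`` is returned: 1 for identical samples,
    approaching 0 for disjoint supports.
    """
    w_f = works.forward_works
    r = -works.reverse_works
    pool = np.concatenate([w_f, r])
    if pool.size == 0:
        raise EstimationError("empty work set")
    if np.ptp(pool) == 0:
        return 1.0
    if n_bins is not None:
        edges = np.histogram_bin_edges(pool, bins=int(n_bins))
    else:
        edges = np.histogram_bin_edges(pool, bins="fd")
        if edges.size - 1 < 10:  # FD collapses on tiny/degenerate samples
            edges = np.histogram_bin_edges(pool, bins=10)
    p, _ = np.histogram(w_f, bins=edges)
    q, _ = np.histogram(r, bins=edges)
    p = p / max(w_f.size, 1)
    q = q / max(r.size, 1)
    return float(np.sum(np.sqrt(p * q)))
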