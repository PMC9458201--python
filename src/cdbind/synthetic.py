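"""Synthetic input generators with known ground truth.

Every stage of the analysis pipeline can be exercised without a
simulation engine or spectrometer: work distributions satisfying the
Crooks relation for a chosen free-energy difference, 1:1 binding
isotherms with a stated association constant, mono-exponential
inversion-recovery and Gaussian gradient-attenuation curves, clustered
toy conformer ensembles, and harmonic restraint coordinate traces.

All generators draw i.i.d. samples from the target laws (no dynamics)
and take one explicit seed each; identical seeds and parameters give
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .constants import (
    DEFAULT_BIG_DELTA,
    DEFAULT_LITTLE_DELTA,
    GAMMA_1H,
    GAUSS_PER_CM_TO_T_PER_M,
    KB,
    beta as _beta,
)
from .ensemble import ConformerEnsemble
from .nmr import DecaySeries
from .noneq import WorkSet
from .restraints import DOF_NAMES, BoreschRestraint, RestraintTrace
from .titration import TitrationSeries

__all__ = [
    "GroundTruth",
    "gen_crooks_work",
    "gen_titration",
    "gen_inversion_recovery",
    "gen_gradient_decay",
    "gen_toy_ensemble",
    "gen_restraint_timeseries",
]


@dataclass(frozen=True)
class GroundTruth:
    """Generator-side truth for one synthetic dataset."""

    dg_true: float = -5.09  # kcal/mol
    sigma_w: float = 1.0  # kcal/mol
    kc_true: float = 520.0  # 1/M
    t1_true: float = 1.36  # s
    d_true: float = 1.9e-10  # m^2/s
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_w < 0:
            raise ValueError("sigma_w must be non-negative")
        for name in ("kc_true", "t1_true", "d_true"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def gen_crooks_work(
    dg_true: float,
    sigma_w: float,
    n_fwd: int,
    n_rev: int,
    temperature: float = 298.0,
    seed: int = 0,
    label: str = "synthetic",
) -> WorkSet:
    """Crooks-consistent Gaussian forward/reverse work samples.

    Forward works are N(dg_true + beta*sigma_w^2/2, sigma_w^2); reverse
    works (reverse-direction convention) are
    N(-dg_true + beta*sigma_w^2/2, sigma_w^2).  This pair satisfies
    ``P_F(W)/P_R(-W) = exp(beta (W - dg_true))`` exactly in distribution.
    """
    if n_fwd < 1 or n_rev < 1:
        raise ValueError("need at least one transition per direction")
    if sigma_w < 0:
        raise ValueError("sigma_w must be non-negative")
    b = _beta(temperature)
    dissipation = 0.5 * b * sigma_w**2
    rng = np.random.default_rng(seed)
    fwd = rng.normal(dg_true + dissipation, sigma_w, size=n_fwd)
    rev = rng.normal(-dg_true + dissipation, sigma_w, size=n_rev)
    return WorkSet(fwd, rev, temperature=temperature, label=label)


def gen_titration(
    kc_true: float,
    dF_c: float,
    conc_list: Sequence[float],
    noise_sd: float = 0.0,
    seed: int = 0,
    f0: float = 100.0,
    guest_conc: float = 25e-6,
) -> TitrationSeries:
    """1:1 binding isotherm under the excess-host approximation.

    ``dF(c) = dF_c * kc_true * c / (1 + kc_true * c)`` plus Gaussian
    noise; the leading zero concentration carries the (noisy) reference
    intensity ``f0``.
    """
    c = np.asarray(conc_list, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentrations must be non-negative")
    if c[0] != 0:
        raise ValueError("the first concentration must be 0 (reference point)")
    if kc_true <= 0:
        raise ValueError("kc_true must be positive")
    rng = np.random.default_rng(seed)
    df = dF_c * kc_true * c / (1.0 + kc_true * c)
    intensity = f0 + df + rng.normal(0.0, noise_sd, size=c.size) if noise_sd > 0 else f0 + df
    return TitrationSeries(cd_conc=c, intensity=intensity, guest_conc=guest_conc)


def gen_inversion_recovery(
    t1_true: float,
    m0: float,
    delays: Sequence[float],
    noise_sd: float = 0.0,
    seed: int = 0,
) -> DecaySeries:
    """Inversion-recovery curve ``B + F*exp(-tau*G)`` with ``B = m0``,
    ``F = -2*m0``, ``G = 1/t1_true``, plus Gaussian noise."""
    if t1_true <= 0:
        raise ValueError("t1_true must be positive")
    tau = np.asarray(delays, dtype=float)
    rng = np.random.default_rng(seed)
    signal = m0 - 2.0 * m0 * np.exp(-tau / t1_true)
    if noise_sd > 0:
        signal = signal + rng.normal(0.0, noise_sd, size=tau.size)
    return DecaySeries(x=tau, signal=signal, kind="inversion_recovery")


def gen_gradient_decay(
    d_true: float,
    i0: float,
    gradients: Sequence[float] | None = None,
    gamma: float = GAMMA_1H,
    little_delta: float = DEFAULT_LITTLE_DELTA,
    big_delta: float = DEFAULT_BIG_DELTA,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> DecaySeries:
    """Stejskal-Tanner attenuation over a gradient ramp (gauss/cm).

    ``I(g) = i0 * exp(-d_true * gamma^2 g^2 delta^2 (Delta - delta/3))``
    with g converted to T/m.  Default ramp: 32 gradients from 0 to 60
    gauss/cm.
    """
    if d_true < 0:
        raise ValueError("d_true must be non-negative")
    g = (
        np.linspace(0.0, 60.0, 32)
        if gradients is None
        else np.asarray(gradients, dtype=float)
    )
    g_si = g * GAUSS_PER_CM_TO_T_PER_M
    attenuation = d_true * gamma**2 * g_si**2 * little_delta**2 * (big_delta - little_delta / 3.0)
    signal = i0 * np.exp(-attenuation)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        signal = signal + rng.normal(0.0, noise_sd, size=g.size)
    return DecaySeries(
        x=g,
        signal=signal,
        kind="gradient_decay",
        gamma=gamma,
        little_delta=little_delta,
        big_delta=big_delta,
    )


def gen_toy_ensemble(
    n_clusters: int,
    frames_per_cluster: int,
    spread: float,
    n_atoms: int,
    seed: int = 0,
    template_scale: float = 5.0,
) -> ConformerEnsemble:
    """Clustered toy conformer ensemble with ground-truth labels.

    Each cluster has a random template structure (coordinates of scale
    ``template_scale``); frames are random rigid-body transforms of their
    template plus isotropic Gaussian jitter of scale ``spread``.  With
    ``spread`` much smaller than the template scale, intra-cluster RMSDs
    sit near ``spread*sqrt(3)`` while inter-cluster RMSDs stay at the
    template scale.
    """
    if n_clusters < 1 or frames_per_cluster < 1 or n_atoms < 1:
        raise ValueError("counts must be positive")
    if spread < 0:
        raise ValueError("spread must be non-negative")
    rng = np.random.default_rng(seed)
    templates = rng.normal(0.0, template_scale, size=(n_clusters, n_atoms, 3))
    frames = []
    labels = []
    for k in range(n_clusters):
        for _ in range(frames_per_cluster):
            coords = templates[k] + rng.normal(0.0, spread, size=(n_atoms, 3)) if spread > 0 else templates[k].copy()
            coords = coords @ _random_rotation(rng).T + rng.normal(0.0, 10.0, size=3)
            frames.append(coords)
            labels.append(k)
    return ConformerEnsemble(coords=np.array(frames), labels=np.array(labels))


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation via QR of a Gaussian matrix."""
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q = q @ np.diag(np.sign(np.diag(r)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def gen_restraint_timeseries(
    restraint: BoreschRestraint,
    n_frames: int,
    temperature: float = 298.0,
    seed: int = 0,
    candidate_id: str = "",
) -> RestraintTrace:
    """Independent harmonic-Boltzmann samples of the six restrained dofs.

    Each dof is drawn from a Gaussian of std ``sqrt(kT/K)`` about its
    equilibrium value (angular dofs sampled in radians, stored in
    degrees; dihedrals wrapped to (-180, 180]).
    """
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    kt = KB * _check_positive_temperature(temperature)
    rng = np.random.default_rng(seed)
    eq = restraint.equilibria
    ks = restraint.force_constants
    values: dict[str, np.ndarray] = {}
    for dof in DOF_NAMES:
        sd = np.sqrt(kt / ks[dof])
        if dof == "r":
            values[dof] = rng.normal(eq[dof], sd, size=n_frames)
        else:
            sampled = rng.normal(np.radians(eq[dof]), sd, size=n_frames)
            deg = np.degrees(sampled)
            if dof.startswith("phi"):
                deg = (deg + 180.0) % 360.0 - 180.0
            values[dof] = deg
    return RestraintTrace(values=values, candidate_id=candidate_id)


def _check_positive_temperature(temperature: float) -> float:
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return temperature
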