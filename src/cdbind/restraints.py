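"""Orientational restraints, the double-decoupling cycle, and replica averaging.

Implements the closed-form standard-state free energy of imposing six
harmonic restraints (one distance, two angles, three dihedrals) between
three host and three guest anchor atoms, a dispersion-based selection of
the best restraint candidate from coordinate traces, the four-leg
thermodynamic-cycle assembly, and the averaging of independent replica
estimates with root-sum-square error propagation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import circmean, circstd

from .constants import KB, STANDARD_VOLUME
from .noneq import FreeEnergyEstimate

__all__ = [
    "BoreschRestraint",
    "RestraintTrace",
    "CycleLegs",
    "ReplicaSet",
    "DOF_NAMES",
    "boresch_analytical",
    "select_restraints",
    "derive_force_constants",
    "assemble_cycle",
    "aggregate_replicas",
]

#: Degree-of-freedom order used by every trace and restraint container.
DOF_NAMES = ("r", "thetaA", "thetaB", "phiA", "phiB", "phiC")
_ANGLE_DOFS = ("thetaA", "thetaB")
_DIHEDRAL_DOFS = ("phiA", "phiB", "phiC")


@dataclass(frozen=True)
class BoreschRestraint:
    """Six-degree-of-freedom orientational restraint.

    Distances in Angstrom, angles in degrees; force constants in
    kcal/(mol A^2) for the distance and kcal/(mol rad^2) for angular
    degrees of freedom.
    """

    r0: float
    thetaA0: float
    thetaB0: float
    phiA0: float
    phiB0: float
    phiC0: float
    k_r: float
    k_thetaA: float
    k_thetaB: float
    k_phiA: float
    k_phiB: float
    k_phiC: float
    anchor_atoms: tuple = ()  # (guest1, guest2, guest3, host1, host2, host3)

    def __post_init__(self) -> None:
        if self.r0 <= 0:
            raise ValueError("r0 must be positive")
        for theta in (self.thetaA0, self.thetaB0):
            if not 0.0 < theta < 180.0:
                raise ValueError("theta equilibrium angles must lie strictly in (0, 180) degrees")
        for name in ("k_r", "k_thetaA", "k_thetaB", "k_phiA", "k_phiB", "k_phiC"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def equilibria(self) -> dict:
        return {
            "r": self.r0,
            "thetaA": self.thetaA0,
            "thetaB": self.thetaB0,
            "phiA": self.phiA0,
            "phiB": self.phiB0,
            "phiC": self.phiC0,
        }

    @property
    def force_constants(self) -> dict:
        return {
            "r": self.k_r,
            "thetaA": self.k_thetaA,
            "thetaB": self.k_thetaB,
            "phiA": self.k_phiA,
            "phiB": self.k_phiB,
            "phiC": self.k_phiC,
        }


@dataclass(frozen=True)
class RestraintTrace:
    """Per-frame values of the six restrained degrees of freedom.

    ``values`` maps each name in :data:`DOF_NAMES` to an equal-length
    array (A for ``r``, degrees for all angles/dihedrals).
    """

    values: Mapping[str, np.ndarray]
    candidate_id: str = ""

    def __post_init__(self) -> None:
        converted = {k: np.asarray(v, dtype=float) for k, v in self.values.items()}
        object.__setattr__(self, "values", converted)
        missing = set(DOF_NAMES) - set(converted)
        if missing:
            raise ValueError(f"trace is missing degrees of freedom: {sorted(missing)}")
        lengths = {v.size for v in converted.values()}
        if len(lengths) != 1:
            raise ValueError("all degrees of freedom must have the same number of frames")
        if self.n_frames < 2:
            raise ValueError("need at least 2 frames for dispersion statistics")

    @property
    def n_frames(self) -> int:
        return int(next(iter(self.values.values())).size)


@dataclass(frozen=True)
class CycleLegs:
    """The four free-energy legs of the double-decoupling cycle (kcal/mol)."""

    dG_solv_elec_vdw: float
    dG_solv_restr: float
    dG_prot_elec_vdw: float
    dG_prot_restr: float
    u_solv_elec_vdw: float = 0.0
    u_solv_restr: float = 0.0
    u_prot_elec_vdw: float = 0.0
    u_prot_restr: float = 0.0

    def __post_init__(self) -> None:
        for name in ("u_solv_elec_vdw", "u_solv_restr", "u_prot_elec_vdw", "u_prot_restr"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class ReplicaSet:
    """Per-replica binding free-energy estimates for one system."""

    estimates: Sequence[tuple]  # (value, uncertainty) pairs, kcal/mol
    system_label: str = ""

    def __post_init__(self) -> None:
        if len(self.estimates) < 1:
            raise ValueError("need at least one replica")
        for value, uncertainty in self.estimates:
            if uncertainty < 0:
                raise ValueError("replica uncertainties must be non-negative")


def boresch_analytical(
    restraint: BoreschRestraint,
    temperature: float = 298.0,
    standard_volume: float = STANDARD_VOLUME,
) -> float:
    """Standard-state free energy of imposing the six harmonic restraints.

    Returns

    .. math::

        kT \\ln \\frac{8\\pi^2 V^\\circ \\sqrt{k_r k_{\\theta A} k_{\\theta B}
        k_{\\phi A} k_{\\phi B} k_{\\phi C}}}
        {r_0^2 \\sin\\theta_{A0} \\sin\\theta_{B0} (2\\pi k T)^3}

    which is positive for stiff restraints: restraining a non-interacting
    guest at standard-state concentration costs free energy.  Substituted
    as ``dG_solv_restr`` in :func:`assemble_cycle`, the release of the
    restraints in the bound leg enters with opposite sign through
    ``dG_prot_restr``.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    kt = KB * temperature
    sin_a = math.sin(math.radians(restraint.thetaA0))
    sin_b = math.sin(math.radians(restraint.thetaB0))
    if sin_a < 1e-9 or sin_b < 1e-9:
        raise ValueError(
            "theta equilibrium angle at 0 or 180 degrees: the restraint "
            "Jacobian sin(theta) vanishes and the closed form diverges"
        )
    k_prod = (
        restraint.k_r
        * restraint.k_thetaA
        * restraint.k_thetaB
        * restraint.k_phiA
        * restraint.k_phiB
        * restraint.k_phiC
    )
    numerator = 8.0 * math.pi**2 * standard_volume * math.sqrt(k_prod)
    denominator = restraint.r0**2 * sin_a * sin_b * (2.0 * math.pi * kt) ** 3
    return kt * math.log(numerator / denominator)


def _dof_std(trace: RestraintTrace, dof: str) -> float:
    """Per-dof standard deviation: A for r, radians for angles/dihedrals.

    Dihedrals use circular statistics so traces straddling +/-180 degrees
    are not inflated by the wrap.
    """
    x = trace.values[dof]
    if dof == "r":
        return float(np.std(x, ddof=1))
    if dof in _DIHEDRAL_DOFS:
        return float(np.radians(circstd(x, high=180.0, low=-180.0)))
    return float(np.std(np.radians(x), ddof=1))


def _dof_mean(trace: RestraintTrace, dof: str) -> float:
    x = trace.values[dof]
    if dof in _DIHEDRAL_DOFS:
        return float(circmean(x, high=180.0, low=-180.0))
    return float(np.mean(x))


def _wrapped_delta(x: np.ndarray, center: float) -> np.ndarray:
    """Signed angular difference in degrees, wrapped to (-180, 180]."""
    return (x - center + 180.0) % 360.0 - 180.0


def select_restraints(
    candidates: Sequence[RestraintTrace],
    normalize: bool = False,
) -> tuple[str, int]:
    """Pick the stiffest restraint candidate and its reference frame.

    Each candidate is scored by the sum of its six per-dof standard
    deviations (distance in A, angles in radians); the candidate with the
    lowest score wins.  With ``normalize=True`` each dof's std is divided
    by the across-candidate mean of that dof's std before summing, which
    equalizes the weight of dofs with very different natural scales.

    The reference frame is the one minimizing the Euclidean norm of the
    z-scored six-vector deviation from the candidate's mean.

    Returns ``(candidate_id, frame_index)``.
    """
    if len(candidates) == 0:
        raise ValueError("empty candidate list")

    stds = np.array([[_dof_std(t, dof) for dof in DOF_NAMES] for t in candidates])
    if normalize:
        scale = stds.mean(axis=0)
        scale[scale == 0] = 1.0
        scores = (stds / scale).sum(axis=1)
    else:
        scores = stds.sum(axis=1)
    best = int(np.argmin(scores))
    chosen = candidates[best]

    # z-scored distance of each frame to the per-dof means
    z2 = np.zeros(chosen.n_frames)
    for j, dof in enumerate(DOF_NAMES):
        x = chosen.values[dof]
        mu = _dof_mean(chosen, dof)
        if dof == "r":
            delta = x - mu
        elif dof in _DIHEDRAL_DOFS:
            delta = np.radians(_wrapped_delta(x, mu))
        else:
            delta = np.radians(x - mu)
        sd = stds[best, j]
        if sd > 0:
            z2 += (delta / sd) ** 2
    frame = int(np.argmin(z2))
    cid = chosen.candidate_id or str(best)
    return cid, frame


def derive_force_constants(
    trace: RestraintTrace,
    temperature: float = 298.0,
    anchor_atoms: tuple = (),
) -> BoreschRestraint:
    """Equipartition inversion of a restraint trace: ``K = kT / var``.

    Equilibrium values are the trace means (circular means for the
    dihedrals); variances are in A^2 for the distance and rad^2 for all
    angular degrees of freedom.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    kt = KB * temperature
    means = {dof: _dof_mean(trace, dof) for dof in DOF_NAMES}
    ks = {}
    for dof in DOF_NAMES:
        sd = _dof_std(trace, dof)
        if sd == 0:
            raise ValueError(
                f"degree of freedom {dof!r} has zero variance: "
                "the implied force constant is infinite"
            )
        ks[dof] = kt / sd**2
    return BoreschRestraint(
        r0=means["r"],
        thetaA0=means["thetaA"],
        thetaB0=means["thetaB"],
        phiA0=means["phiA"],
        phiB0=means["phiB"],
        phiC0=means["phiC"],
        k_r=ks["r"],
        k_thetaA=ks["thetaA"],
        k_thetaB=ks["thetaB"],
        k_phiA=ks["phiA"],
        k_phiB=ks["phiB"],
        k_phiC=ks["phiC"],
        anchor_atoms=anchor_atoms,
    )


def assemble_cycle(legs: CycleLegs) -> FreeEnergyEstimate:
    """Absolute binding free energy from the four cycle legs.

    ``dG_bind = dG_solv^{elec+vdw} + dG_solv^{restr} - dG_prot^{elec+vdw}
    - dG_prot^{restr}``; the uncertainty is the root-sum-square of the
    four leg uncertainties.
    """
    value = (
        legs.dG_solv_elec_vdw
        + legs.dG_solv_restr
        - legs.dG_prot_elec_vdw
        - legs.dG_prot_restr
    )
    uncertainty = math.sqrt(
        legs.u_solv_elec_vdw**2
        + legs.u_solv_restr**2
        + legs.u_prot_elec_vdw**2
        + legs.u_prot_restr**2
    )
    return FreeEnergyEstimate(value=value, uncertainty=uncertainty, method="cycle")


def aggregate_replicas(replicas: ReplicaSet) -> FreeEnergyEstimate:
    """Mean of replica values with root-sum-square error propagation."""
    values = np.array([v for v, _ in replicas.estimates], dtype=float)
    errors = np.array([u for _, u in replicas.estimates], dtype=float)
    return FreeEnergyEstimate(
        value=float(values.mean()),
        uncertainty=float(np.sqrt(np.sum(errors**2))),
        method="replica_mean",
        label=replicas.system_label,
    )
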