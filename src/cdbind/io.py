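"""Plain-text readers and writers.

All on-disk formats are TSV/CSV/JSON with ``# key=value`` comment
headers so that generated files carry their own ground truth and sign
conventions.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .nmr import DecaySeries
from .noneq import WorkSet
from .restraints import DOF_NAMES, BoreschRestraint, CycleLegs, ReplicaSet, RestraintTrace
from .titration import TitrationSeries

__all__ = [
    "write_table",
    "read_table",
    "write_workset",
    "read_workset",
    "read_dhdl_works",
    "write_titration",
    "read_titration",
    "write_decay",
    "read_decay",
    "write_restraint",
    "read_restraint",
    "write_restraint_trace",
    "read_restraint_trace",
    "read_cycle_legs",
    "read_replicas",
]

_REVERSE_NOTE = (
    "reverse works are the work along the reverse transition; "
    "-W_rev estimates dG from the reverse side"
)


def write_table(path: str | Path, frame: pd.DataFrame, meta: dict[str, Any] | None = None, sep: str = "\t") -> None:
    """Write a data frame as (T|C)SV with ``# key=value`` header lines."""
    path = Path(path)
    with path.open("w") as fh:
        for key, value in (meta or {}).items():
            fh.write(f"# {key}={value}\n")
        frame.to_csv(fh, sep=sep, index=False)


def read_table(path: str | Path, sep: str = "\t") -> tuple[pd.DataFrame, dict[str, str]]:
    """Read a table written by :func:`write_table`; returns (frame, meta)."""
    path = Path(path)
    meta: dict[str, str] = {}
    with path.open() as fh:
        lines = fh.readlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            stripped = line.lstrip("#").strip()
            if "=" in stripped:
                key, _, value = stripped.partition("=")
                meta[key.strip()] = value.strip()
            body_start = i + 1
        else:
            break
    from io import StringIO

    frame = pd.read_csv(
        StringIO("".join(lines[body_start:])), sep=sep, float_precision="round_trip"
    )
    return frame, meta


def write_workset(path: str | Path, works: WorkSet, meta: dict[str, Any] | None = None) -> None:
    frame = pd.DataFrame(
        {
            "direction": ["forward"] * works.n_forward + ["reverse"] * works.n_reverse,
            "work_kcal_per_mol": np.concatenate([works.forward_works, works.reverse_works]),
        }
    )
    full_meta = {
        "temperature_K": works.temperature,
        "label": works.label,
        "sign_convention": _REVERSE_NOTE,
    }
    full_meta.update(meta or {})
    write_table(path, frame, full_meta)


def read_workset(path: str | Path) -> tuple[WorkSet, dict[str, str]]:
    frame, meta = read_table(path)
    if not {"direction", "work_kcal_per_mol"} <= set(frame.columns):
        raise ValueError("work file needs columns: direction, work_kcal_per_mol")
    fwd = frame.loc[frame["direction"] == "forward", "work_kcal_per_mol"].to_numpy()
    rev = frame.loc[frame["direction"] == "reverse", "work_kcal_per_mol"].to_numpy()
    temperature = float(meta.get("temperature_K", 298.0))
    return WorkSet(fwd, rev, temperature=temperature, label=meta.get("label", "")), meta


def read_dhdl_works(path: str | Path) -> tuple[WorkSet, dict[str, str]]:
    """Integrate per-snapshot dH/dlambda traces to work values.

    Expects columns ``direction, transition, lam, dhdl``; each
    (direction, transition) group is sorted by lambda and integrated by
    the trapezoid rule.
    """
    frame, meta = read_table(path)
    required = {"direction", "transition", "lam", "dhdl"}
    if not required <= set(frame.columns):
        raise ValueError(f"dhdl file needs columns: {sorted(required)}")
    works: dict[str, list[float]] = {"forward": [], "reverse": []}
    for (direction, _), group in frame.groupby(["direction", "transition"], sort=True):
        if direction not in works:
            raise ValueError(f"unknown direction {direction!r}")
        g = group.sort_values("lam")
        works[direction].append(float(np.trapezoid(g["dhdl"].to_numpy(), g["lam"].to_numpy())))
    temperature = float(meta.get("temperature_K", 298.0))
    return (
        WorkSet(works["forward"], works["reverse"], temperature=temperature, label=meta.get("label", "")),
        meta,
    )


def write_titration(path: str | Path, series: TitrationSeries, meta: dict[str, Any] | None = None) -> None:
    frame = pd.DataFrame(
        {"concentration_mM": series.cd_conc * 1e3, "intensity": series.intensity}
    )
    full_meta = {"guest_conc_M": series.guest_conc}
    full_meta.update(meta or {})
    write_table(path, frame, full_meta, sep=",")


def read_titration(path: str | Path) -> tuple[TitrationSeries, dict[str, str]]:
    frame, meta = read_table(path, sep=",")
    if not {"concentration_mM", "intensity"} <= set(frame.columns):
        raise ValueError("titration file needs columns: concentration_mM, intensity")
    series = TitrationSeries(
        cd_conc=frame["concentration_mM"].to_numpy() * 1e-3,
        intensity=frame["intensity"].to_numpy(),
        guest_conc=float(meta.get("guest_conc_M", 25e-6)),
    )
    return series, meta


def write_decay(path: str | Path, series: DecaySeries, meta: dict[str, Any] | None = None) -> None:
    x_name = "delay_s" if series.kind == "inversion_recovery" else "gradient_G_per_cm"
    frame = pd.DataFrame({x_name: series.x, "signal": series.signal})
    full_meta: dict[str, Any] = {"kind": series.kind}
    if series.kind == "gradient_decay":
        full_meta.update(
            gamma_rad_per_s_T=series.gamma,
            little_delta_s=series.little_delta,
            big_delta_s=series.big_delta,
        )
    full_meta.update(meta or {})
    write_table(path, frame, full_meta, sep=",")


def read_decay(path: str | Path) -> tuple[DecaySeries, dict[str, str]]:
    frame, meta = read_table(path, sep=",")
    kind = meta.get("kind")
    if kind == "inversion_recovery":
        series = DecaySeries(x=frame["delay_s"].to_numpy(), signal=frame["signal"].to_numpy(), kind=kind)
    elif kind == "gradient_decay":
        series = DecaySeries(
            x=frame["gradient_G_per_cm"].to_numpy(),
            signal=frame["signal"].to_numpy(),
            kind=kind,
            gamma=float(meta["gamma_rad_per_s_T"]),
            little_delta=float(meta["little_delta_s"]),
            big_delta=float(meta["big_delta_s"]),
        )
    else:
        raise ValueError(f"unknown or missing series kind in header: {kind!r}")
    return series, meta


def write_restraint(path: str | Path, restraint: BoreschRestraint, temperature: float = 298.0, standard_volume: float = 1660.539) -> None:
    """Flat key=value text block for a six-dof restraint definition."""
    lines = [
        f"anchor_atoms={','.join(map(str, restraint.anchor_atoms))}",
        f"r0_A={restraint.r0!r}",
        f"thetaA0_deg={restraint.thetaA0!r}",
        f"thetaB0_deg={restraint.thetaB0!r}",
        f"phiA0_deg={restraint.phiA0!r}",
        f"phiB0_deg={restraint.phiB0!r}",
        f"phiC0_deg={restraint.phiC0!r}",
        f"k_r_kcal_per_mol_A2={restraint.k_r!r}",
        f"k_thetaA_kcal_per_mol_rad2={restraint.k_thetaA!r}",
        f"k_thetaB_kcal_per_mol_rad2={restraint.k_thetaB!r}",
        f"k_phiA_kcal_per_mol_rad2={restraint.k_phiA!r}",
        f"k_phiB_kcal_per_mol_rad2={restraint.k_phiB!r}",
        f"k_phiC_kcal_per_mol_rad2={restraint.k_phiC!r}",
        f"temperature_K={temperature!r}",
        f"standard_volume_A3={standard_volume!r}",
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_restraint(path: str | Path) -> tuple[BoreschRestraint, float, float]:
    """Read a restraint block; returns (restraint, temperature, V0)."""
    kv: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, value = line.partition("=")
        kv[key.strip()] = value.strip()
    anchors = tuple(a for a in kv.get("anchor_atoms", "").split(",") if a)
    restraint = BoreschRestraint(
        r0=float(kv["r0_A"]),
        thetaA0=float(kv["thetaA0_deg"]),
        thetaB0=float(kv["thetaB0_deg"]),
        phiA0=float(kv["phiA0_deg"]),
        phiB0=float(kv["phiB0_deg"]),
        phiC0=float(kv["phiC0_deg"]),
        k_r=float(kv["k_r_kcal_per_mol_A2"]),
        k_thetaA=float(kv["k_thetaA_kcal_per_mol_rad2"]),
        k_thetaB=float(kv["k_thetaB_kcal_per_mol_rad2"]),
        k_phiA=float(kv["k_phiA_kcal_per_mol_rad2"]),
        k_phiB=float(kv["k_phiB_kcal_per_mol_rad2"]),
        k_phiC=float(kv["k_phiC_kcal_per_mol_rad2"]),
        anchor_atoms=anchors,
    )
    return restraint, float(kv.get("temperature_K", 298.0)), float(kv.get("standard_volume_A3", 1660.539))


def write_restraint_trace(path: str | Path, trace: RestraintTrace, meta: dict[str, Any] | None = None) -> None:
    frame = pd.DataFrame({dof: trace.values[dof] for dof in DOF_NAMES})
    frame.insert(0, "frame", np.arange(trace.n_frames))
    full_meta = {"candidate_id": trace.candidate_id}
    full_meta.update(meta or {})
    write_table(path, frame, full_meta)


def read_restraint_trace(path: str | Path) -> tuple[RestraintTrace, dict[str, str]]:
    frame, meta = read_table(path)
    values = {dof: frame[dof].to_numpy() for dof in DOF_NAMES}
    return RestraintTrace(values=values, candidate_id=meta.get("candidate_id", "")), meta


def read_cycle_legs(path: str | Path) -> CycleLegs:
    """Cycle legs from a JSON object with the CycleLegs field names."""
    payload = json.loads(Path(path).read_text())
    return CycleLegs(**payload)


def read_replicas(path: str | Path) -> list[ReplicaSet]:
    """Per-replica estimates from a TSV with columns
    ``system, value_kcal_per_mol, uncertainty_kcal_per_mol``."""
    frame, _ = read_table(path)
    required = {"system", "value_kcal_per_mol", "uncertainty_kcal_per_mol"}
    if not required <= set(frame.columns):
        raise ValueError(f"replica file needs columns: {sorted(required)}")
    out = []
    for system, group in frame.groupby("system", sort=False):
        estimates = list(
            zip(group["value_kcal_per_mol"].astype(float), group["uncertainty_kcal_per_mol"].astype(float))
        )
        out.append(ReplicaSet(estimates=estimates, system_label=str(system)))
    return out
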