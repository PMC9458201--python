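"""Bundled reference tables.

Small plain-text tables shipped with the package: per-replica binding
free energies, T1 relaxation pairs, and free/complex chemical-shift
tables for the two host systems.  Ranged (multiplet) entries are stored
as ``high-low`` interval strings and surface as intervals, not scalars.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .nmr import ShiftEntry, ShiftTable
from .restraints import ReplicaSet

__all__ = [
    "load_replica_estimates",
    "load_t1_table",
    "load_shift_tables",
    "parse_scalar_or_interval",
]

_T1_FILES = {"2HP-b-CD": "t1_2hp.tsv", "2,6Me-b-CD": "t1_26me.tsv"}


def _read(name: str) -> pd.DataFrame:
    ref = resources.files("cdbind.data").joinpath(name)
    with ref.open() as fh:
        return pd.read_csv(fh, sep="\t", comment="#", dtype=str)


def parse_scalar_or_interval(text: str) -> float | tuple:
    """Parse ``'1.36'`` to a float or ``'1.36-1.4'`` to a (high, low) tuple."""
    text = str(text).strip().rstrip("s").strip()
    if "-" in text[1:]:  # allow a leading minus sign on scalars
        hi, lo = text.split("-", 1)
        return (float(hi), float(lo))
    return float(text)


def load_replica_estimates() -> dict[str, ReplicaSet]:
    """Per-system replica sets of (value, uncertainty) pairs in kcal/mol."""
    frame = _read("replica_free_energies.tsv")
    out: dict[str, ReplicaSet] = {}
    for system, group in frame.groupby("system", sort=False):
        estimates = list(
            zip(
                group["value_kcal_per_mol"].astype(float),
                group["uncertainty_kcal_per_mol"].astype(float),
            )
        )
        out[str(system)] = ReplicaSet(estimates=estimates, system_label=str(system))
    return out


def load_t1_table(system: str) -> pd.DataFrame:
    """T1 pairs for one host system; values are floats or interval tuples."""
    if system not in _T1_FILES:
        raise KeyError(f"unknown system {system!r}; choose from {sorted(_T1_FILES)}")
    frame = _read(_T1_FILES[system])
    frame["t1_free"] = frame["t1_free"].map(parse_scalar_or_interval)
    frame["t1_complex"] = frame["t1_complex"].map(parse_scalar_or_interval)
    return frame


def load_shift_tables() -> tuple[ShiftTable, ShiftTable]:
    """Free and complexed chemical-shift tables for the methylated host."""
    frame = _read("shifts_26me.tsv")

    def to_entries(column: str) -> list[ShiftEntry]:
        entries = []
        for _, row in frame.iterrows():
            parsed = parse_scalar_or_interval(row[column])
            if isinstance(parsed, tuple):
                entries.append(ShiftEntry(label=row["label"], interval=parsed))
            else:
                entries.append(ShiftEntry(label=row["label"], value=parsed))
        return entries

    return ShiftTable(to_entries("delta_free")), ShiftTable(to_entries("delta_complex"))
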