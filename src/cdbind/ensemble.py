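"""Conformational clustering and end-point energy bookkeeping.

Pairwise least-squares-superposition RMSD, greedy neighbor-count
(gromos/Daura-style) clustering under an RMSD cutoff, representative
selection, and the per-structure binding-energy decomposition
``dG_bind = G_complex - G_host - G_guest`` summarized over cluster
representatives.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ConformerEnsemble",
    "Cluster",
    "MMGBSAResult",
    "ENERGY_COMPONENTS",
    "pairwise_rmsd",
    "superposed_rmsd",
    "gromos_cluster",
    "top_representatives",
    "mmgbsa_binding",
]

#: Column order of component tables.
ENERGY_COMPONENTS = ("vdW", "Coulomb", "SolvGB", "Lipo", "Hbond", "Covalent")


@dataclass(frozen=True)
class ConformerEnsemble:
    """A stack of frames with a constant atom count.

    ``coords`` has shape ``(n_frames, n_atoms, 3)`` in Angstrom;
    ``labels`` optionally carries per-frame ground-truth cluster ids.
    """

    coords: np.ndarray
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.coords, dtype=float)
        object.__setattr__(self, "coords", arr)
        if arr.ndim != 3 or arr.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if arr.shape[0] < 1 or arr.shape[1] < 1:
            raise ValueError("need at least one frame and one atom")
        if not np.all(np.isfinite(arr)):
            raise ValueError("coordinates must be finite")
        if self.labels is not None:
            lab = np.asarray(self.labels)
            if lab.shape[0] != arr.shape[0]:
                raise ValueError("labels must have one entry per frame")
            object.__setattr__(self, "labels", lab)

    @property
    def n_frames(self) -> int:
        return int(self.coords.shape[0])

    @property
    def n_atoms(self) -> int:
        return int(self.coords.shape[1])


@dataclass(frozen=True)
class Cluster:
    """One cluster: its center frame and all member frames (center included)."""

    center: int
    members: tuple

    @property
    def size(self) -> int:
        return len(self.members)


def superposed_rmsd(p: np.ndarray, q: np.ndarray) -> float:
    """Minimal RMSD between two frames after optimal rigid superposition.

    Both frames are centered and the optimal proper rotation is found via
    the Kabsch SVD solution (reflections excluded).
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("frames must have identical shapes")
    pc = p - p.mean(axis=0)
    qc = q - q.mean(axis=0)
    h = pc.T @ qc
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    diff = pc @ rot.T - qc
    return float(np.sqrt((diff**2).sum() / p.shape[0]))


def pairwise_rmsd(
    ensemble: ConformerEnsemble,
    atom_selection: Sequence[int] | None = None,
) -> np.ndarray:
    """Symmetric matrix of superposition RMSDs between all frame pairs.

    ``atom_selection`` restricts the fit and the RMSD to the given atom
    indices (e.g. heavy atoms); default is all atoms.
    """
    coords = ensemble.coords
    if atom_selection is not None:
        coords = coords[:, np.asarray(atom_selection, dtype=int), :]
    n = coords.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = superposed_rmsd(coords[i], coords[j])
    return out


def gromos_cluster(rmsd_matrix: np.ndarray, cutoff: float) -> list[Cluster]:
    """Greedy neighbor-count clustering under an RMSD cutoff.

    Repeatedly: count, for every unassigned frame, its unassigned
    neighbors within ``cutoff``; the frame with the most neighbors (ties
    broken by lower index) becomes a center and forms a cluster with its
    neighbors; all are removed.  Clusters are returned ordered by
    decreasing size (size ties by lower center index).
    """
    m = np.asarray(rmsd_matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("rmsd matrix must be square")
    if not np.allclose(m, m.T, atol=1e-8):
        raise ValueError("rmsd matrix must be symmetric")
    if np.any(m < 0):
        raise ValueError("rmsd matrix must be non-negative")

    n = m.shape[0]
    adjacency = m <= cutoff
    np.fill_diagonal(adjacency, False)
    unassigned = np.ones(n, dtype=bool)
    clusters: list[Cluster] = []
    while unassigned.any():
        counts = (adjacency & unassigned[None, :]).sum(axis=1)
        counts[~unassigned] = -1
        center = int(np.argmax(counts))  # argmax takes the first maximum: lower index wins
        members = np.flatnonzero(adjacency[center] & unassigned)
        group = (center, *[int(i) for i in members if i != center])
        clusters.append(Cluster(center=center, members=tuple(sorted(group))))
        unassigned[list(group)] = False
    clusters.sort(key=lambda c: (-c.size, c.center))
    return clusters


def top_representatives(clusters: Sequence[Cluster], k: int) -> list[int]:
    """Center frames of the ``k`` most populated clusters.

    If fewer than ``k`` clusters exist, all centers are returned (no
    padding).  Size ties are broken by lower center index.
    """
    ordered = sorted(clusters, key=lambda c: (-c.size, c.center))
    return [c.center for c in ordered[:k]]


@dataclass(frozen=True)
class MMGBSAResult:
    """Per-structure binding decomposition and its mean/std summary."""

    per_structure: pd.DataFrame  # component deltas + 'total', one row per structure
    mean: pd.Series
    std: pd.Series  # sample (n-1) standard deviation; 0.0 for a single structure


def _check_components(table: pd.DataFrame, name: str) -> pd.DataFrame:
    missing = [c for c in ENERGY_COMPONENTS if c not in table.columns]
    if missing:
        raise ValueError(f"{name} table is missing components: {missing}")
    sub = table.loc[:, list(ENERGY_COMPONENTS)].astype(float)
    if not np.all(np.isfinite(sub.to_numpy())):
        raise ValueError(f"{name} table contains non-finite values")
    return sub


def mmgbsa_binding(
    complex_table: pd.DataFrame,
    host_table: pd.DataFrame,
    guest_table: pd.DataFrame,
) -> MMGBSAResult:
    """Binding energy decomposition over matched structure rows.

    For each structure, every component delta is
    ``complex - host - guest`` and the total is the sum of the component
    deltas (the decomposition closes by construction).  The summary is
    the mean and sample standard deviation over structures.
    """
    cx = _check_components(complex_table, "complex")
    host = _check_components(host_table, "host")
    guest = _check_components(guest_table, "guest")
    if not (len(cx) == len(host) == len(guest)):
        raise ValueError("complex, host and guest tables must have the same number of rows")
    delta = cx.reset_index(drop=True) - host.reset_index(drop=True) - guest.reset_index(drop=True)
    delta["total"] = delta.sum(axis=1)
    mean = delta.mean()
    std = delta.std(ddof=1) if len(delta) > 1 else delta.iloc[0] * 0.0
    return MMGBSAResult(per_structure=delta, mean=mean, std=std)
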