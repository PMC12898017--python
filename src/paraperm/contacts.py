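"""Per-residue ion contacts and channel occupancy.

An ion is "in contact" with a residue in a frame when its center lies
within a cutoff (default 4 Å) of any heavy atom of that residue,
minimum-image distances, closed (≤) comparison. Residue occupancy is
the mean number of contacting ions per frame — the convention behind
"average number of ions bound to a residue". Channel occupancy counts
ions inside a cylindrical pore region anchored at the selectivity-filter
center.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import SelectionError
from .traj import (
    Selection,
    Trajectory,
    WATER_RESNAMES,
    minimum_image_distances,
    select,
)


@dataclass(frozen=True)
class ContactConfig:
    """Contact distance cutoff (Å) and whether hydrogens are excluded."""

    cutoff_A: float = 4.0
    heavy_atoms_only: bool = True

    def __post_init__(self) -> None:
        if self.cutoff_A <= 0:
            raise ValueError("cutoff must be > 0")


@dataclass
class PoreRegion:
    """Cylinder about the pore axis: |axial offset| ≤ half_length and
    radial distance ≤ radius (closed boundaries)."""

    center: np.ndarray
    axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    half_length_A: float = 20.0
    radius_A: float = 8.0

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        self.axis = np.asarray(self.axis, dtype=float)
        n = np.linalg.norm(self.axis)
        if n == 0:
            raise ValueError("axis must be non-zero")
        self.axis = self.axis / n
        if self.half_length_A <= 0 or self.radius_A <= 0:
            raise ValueError("half_length and radius must be > 0")

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask of points inside the cylinder."""
        d = np.atleast_2d(points) - self.center
        axial = d @ self.axis
        radial = np.linalg.norm(d - np.outer(axial, self.axis), axis=1)
        return (np.abs(axial) <= self.half_length_A) & (radial <= self.radius_A)


@dataclass
class ResidueOccupancy:
    chain_id: str
    residue_id: int
    residue_name: str
    mean_ions: float
    sd: float
    contact_fraction: float


def _default_residue_selection() -> Selection:
    return select(
        predicate=lambda a: a.species is None
        and a.residue_name not in WATER_RESNAMES,
        label="protein",
    )


def residue_ion_occupancy(
    traj: Trajectory,
    ion_sel: Selection,
    cfg: ContactConfig = ContactConfig(),
    residue_sel: Selection | None = None,
) -> list[ResidueOccupancy]:
    """Mean ion contacts and contact fraction per residue.

    Per frame, an ion contacts a residue when the minimum-image distance
    from the ion center to the residue's nearest (heavy) atom is ≤ the
    cutoff; an ion may count toward multiple residues simultaneously.
    ``mean_ions`` averages the per-frame contact count, ``contact_fraction``
    is the fraction of frames with at least one contacting ion. Sorted by
    mean_ions descending.
    """
    ion_idx = ion_sel.resolve(traj.topology)
    if ion_idx.size == 0:
        raise SelectionError("ion selection matched no atoms")
    res_sel = residue_sel if residue_sel is not None else _default_residue_selection()
    res_idx = res_sel.resolve_or_raise(traj.topology)
    if cfg.heavy_atoms_only:
        res_idx = np.array(
            [i for i in res_idx if traj.topology.atoms[i].element.upper() != "H"],
            dtype=np.intp,
        )
        if res_idx.size == 0:
            raise SelectionError("residue selection has no heavy atoms")

    keys = [
        (
            traj.topology.atoms[i].chain_id,
            traj.topology.atoms[i].residue_id,
            traj.topology.atoms[i].residue_name,
        )
        for i in res_idx
    ]
    unique_keys = sorted(set(keys))
    key_pos = {k: j for j, k in enumerate(unique_keys)}
    col = np.array([key_pos[k] for k in keys])

    n_frames = traj.n_frames
    counts = np.zeros((n_frames, len(unique_keys)))
    for fi, frame in enumerate(traj.frames):
        dists = minimum_image_distances(
            frame.coords[ion_idx], frame.coords[res_idx], frame.box_lengths
        )
        within = dists <= cfg.cutoff_A  # (n_ions, n_res_atoms)
        for j in range(len(unique_keys)):
            cols = col == j
            counts[fi, j] = np.sum(np.any(within[:, cols], axis=1))
    mean = counts.mean(axis=0)
    sd = counts.std(axis=0, ddof=0)
    frac = (counts >= 1).mean(axis=0)
    out = [
        ResidueOccupancy(k[0], k[1], k[2], float(mean[j]), float(sd[j]), float(frac[j]))
        for j, k in enumerate(unique_keys)
    ]
    out.sort(key=lambda r: r.mean_ions, reverse=True)
    return out


def occupancy_table(rows: list[ResidueOccupancy]) -> pd.DataFrame:
    """Per-residue table mirroring the bound-ion summary layout."""
    return pd.DataFrame(
        [
            {
                "chain": r.chain_id,
                "resid": r.residue_id,
                "resname": r.residue_name,
                "mean_ions": r.mean_ions,
                "sd": r.sd,
                "contact_fraction": r.contact_fraction,
            }
            for r in rows
        ]
    )


def channel_occupancy(
    traj: Trajectory,
    region: PoreRegion,
    cation_sel: Selection,
    anion_sel: Selection,
) -> tuple[float, float, pd.DataFrame]:
    """Mean cation and anion counts inside the pore region.

    Returns (mean cations, mean anions, per-frame series with columns
    time_ns, n_cations, n_anions). Boundary placements count as inside
    (closed cylinder).
    """
    cat_idx = cation_sel.resolve(traj.topology)
    an_idx = anion_sel.resolve(traj.topology)
    rows = []
    for frame in traj.frames:
        n_cat = int(np.sum(region.contains(frame.coords[cat_idx]))) if cat_idx.size else 0
        n_an = int(np.sum(region.contains(frame.coords[an_idx]))) if an_idx.size else 0
        rows.append({"time_ns": frame.time_ns, "n_cations": n_cat, "n_anions": n_an})
    series = pd.DataFrame(rows)
    return (
        float(series["n_cations"].mean()),
        float(series["n_anions"].mean()),
        series,
    )


def selectivity_filter_center(traj: Trajectory, filter_sel: Selection) -> np.ndarray:
    """Time-averaged centroid of the selectivity-filter atoms — the anchor
    point for pore regions and radius-profile axes."""
    idx = filter_sel.resolve_or_raise(traj.topology)
    X = traj.coords_array()[:, idx, :]
    return X.mean(axis=(0, 1))
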