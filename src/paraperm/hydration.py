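"""Hydration-shell coordination analysis.

Counts first-shell oxygens around each permeating ion per frame —
water oxygens and protein oxygens separately — with species-specific
cutoffs (3.5 Å for the small cations Li⁺/Na⁺, 4.0 Å for larger ones),
closed (≤) comparison, minimum-image distances. On top of the raw
series it provides axial hydration profiles, dehydration-event
detection (losing ≥ 2 first-shell waters relative to the bulk baseline)
and the per-residue frequency of assisting protein oxygens.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, SelectionError
from .species import SPECIES_TABLE
from .traj import Selection, Trajectory, minimum_image_distances, select


def default_cutoffs() -> dict[str, float]:
    return {name: spec.hydration_cutoff_A for name, spec in SPECIES_TABLE.items()}


def water_oxygen_selection() -> Selection:
    return select(
        elements={"O"},
        predicate=lambda a: a.residue_name
        in {"HOH", "TIP3", "WAT", "SOL", "SPC", "TIP4"},
        label="water oxygens",
    )


def protein_oxygen_selection() -> Selection:
    return select(
        elements={"O"},
        predicate=lambda a: a.species is None
        and a.residue_name not in {"HOH", "TIP3", "WAT", "SOL", "SPC", "TIP4"},
        label="protein oxygens",
    )


@dataclass
class HydrationConfig:
    """Species cutoffs plus the water / protein oxygen selections.

    Protein-oxygen coordination uses the same species cutoff as water by
    default; ``protein_cutoff_by_species`` overrides it.
    """

    cutoff_by_species: dict[str, float] = field(default_factory=default_cutoffs)
    water_oxygen_sel: Selection = field(default_factory=water_oxygen_selection)
    protein_oxygen_sel: Selection = field(default_factory=protein_oxygen_selection)
    protein_cutoff_by_species: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if any(c <= 0 for c in self.cutoff_by_species.values()):
            raise ValueError("cutoffs must be > 0")

    def cutoff_for(self, species: str) -> float:
        try:
            return self.cutoff_by_species[species]
        except KeyError:
            raise ConfigurationError(f"no hydration cutoff for species {species!r}")

    def protein_cutoff_for(self, species: str) -> float:
        if self.protein_cutoff_by_species is not None:
            return self.protein_cutoff_by_species.get(
                species, self.cutoff_for(species)
            )
        return self.cutoff_for(species)


@dataclass
class CoordinationSeries:
    """Per-ion time series of first-shell composition.

    ``table`` columns: ion_id, species, frame, time_ns, n_water,
    n_protein_O, s_A (axial coordinate of the ion).
    """

    table: pd.DataFrame

    def for_ion(self, ion_id: int) -> pd.DataFrame:
        return self.table[self.table["ion_id"] == ion_id].reset_index(drop=True)

    @property
    def ion_ids(self) -> list[int]:
        return sorted(self.table["ion_id"].unique())


def _resolved_disjoint(
    traj: Trajectory, cfg: HydrationConfig
) -> tuple[np.ndarray, np.ndarray]:
    w = cfg.water_oxygen_sel.resolve(traj.topology)
    p = cfg.protein_oxygen_sel.resolve(traj.topology)
    if np.intersect1d(w, p).size:
        raise ConfigurationError("water and protein oxygen selections overlap")
    return w, p


def coordination_counts(
    traj: Trajectory,
    ion_sel: Selection,
    cfg: HydrationConfig | None = None,
    axis_origin: np.ndarray | None = None,
    axis_direction: np.ndarray | None = None,
) -> CoordinationSeries:
    """First-shell water and protein-oxygen counts per ion per frame.

    The axial coordinate ``s_A`` is the projection of the ion position
    onto the pore axis (default: z through the origin).
    """
    cfg = cfg or HydrationConfig()
    ion_idx = ion_sel.resolve(traj.topology)
    if ion_idx.size == 0:
        raise SelectionError("ion selection matched no atoms")
    w_idx, p_idx = _resolved_disjoint(traj, cfg)
    origin = np.zeros(3) if axis_origin is None else np.asarray(axis_origin, float)
    direction = (
        np.array([0.0, 0.0, 1.0])
        if axis_direction is None
        else np.asarray(axis_direction, float)
    )
    direction = direction / np.linalg.norm(direction)

    ion_species = []
    cut_w = []
    cut_p = []
    for i in ion_idx:
        sp = traj.topology.atoms[i].species
        if sp is None:
            raise ConfigurationError(f"selected atom {i} is not an ion")
        ion_species.append(sp)
        cut_w.append(cfg.cutoff_for(sp))
        cut_p.append(cfg.protein_cutoff_for(sp))
    cut_w = np.asarray(cut_w)[:, None]
    cut_p = np.asarray(cut_p)[:, None]

    rows = []
    for fi, frame in enumerate(traj.frames):
        ions = frame.coords[ion_idx]
        s = (ions - origin) @ direction
        if w_idx.size:
            dw = minimum_image_distances(ions, frame.coords[w_idx], frame.box_lengths)
            n_w = np.sum(dw <= cut_w, axis=1)
        else:
            n_w = np.zeros(ion_idx.size, dtype=int)
        if p_idx.size:
            dp = minimum_image_distances(ions, frame.coords[p_idx], frame.box_lengths)
            n_p = np.sum(dp <= cut_p, axis=1)
        else:
            n_p = np.zeros(ion_idx.size, dtype=int)
        for k, pos in enumerate(ion_idx):
            rows.append(
                {
                    "ion_id": traj.topology.atoms[pos].atom_id,
                    "species": ion_species[k],
                    "frame": fi,
                    "time_ns": frame.time_ns,
                    "n_water": int(n_w[k]),
                    "n_protein_O": int(n_p[k]),
                    "s_A": float(s[k]),
                }
            )
    return CoordinationSeries(pd.DataFrame(rows))


def hydration_profile(
    series_list: CoordinationSeries | Sequence[CoordinationSeries],
    bin_width_A: float = 1.0,
    s_range: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Axial hydration profile: per-bin mean ± SD of (n_water, n_protein_O).

    Multiple channels' series may be pooled. Bins with no samples are
    omitted (missing, not zero). Columns: s_center_A, n, mean_n_water,
    sd_n_water, mean_n_protein_O, sd_n_protein_O.
    """
    if isinstance(series_list, CoordinationSeries):
        series_list = [series_list]
    table = pd.concat([s.table for s in series_list], ignore_index=True)
    if table.empty:
        return pd.DataFrame(
            columns=[
                "s_center_A", "n", "mean_n_water", "sd_n_water",
                "mean_n_protein_O", "sd_n_protein_O",
            ]
        )
    if s_range is None:
        s_range = (float(table["s_A"].min()), float(table["s_A"].max()) + 1e-9)
    lo, hi = s_range
    edges = np.arange(lo, hi + bin_width_A, bin_width_A)
    idx = np.digitize(table["s_A"].to_numpy(), edges) - 1
    table = table.assign(_bin=idx)
    table = table[(idx >= 0) & (idx < len(edges) - 1)]
    out = []
    for b, grp in table.groupby("_bin"):
        out.append(
            {
                "s_center_A": edges[b] + bin_width_A / 2.0,
                "n": len(grp),
                "mean_n_water": grp["n_water"].mean(),
                "sd_n_water": grp["n_water"].std(ddof=0),
                "mean_n_protein_O": grp["n_protein_O"].mean(),
                "sd_n_protein_O": grp["n_protein_O"].std(ddof=0),
            }
        )
    return pd.DataFrame(out).sort_values("s_center_A").reset_index(drop=True)


@dataclass
class DehydrationEvent:
    """Maximal interval (inclusive frames) of first-shell water loss."""

    start_frame: int
    end_frame: int
    min_n_water: int


def dehydration_events(
    n_water: Sequence[int],
    drop_threshold: int = 2,
    smoothing_window: int = 1,
) -> list[DehydrationEvent]:
    """Detect intervals where an ion loses ≥ ``drop_threshold`` first-shell
    waters relative to its baseline (median of the smoothed series).

    ``smoothing_window`` applies a centered moving average before
    thresholding (1 = no smoothing, the default).
    """
    n = np.asarray(n_water, dtype=float)
    if smoothing_window > 1:
        if n.size <= smoothing_window:
            raise ValueError("series must be longer than the smoothing window")
        smoothed = (
            pd.Series(n).rolling(smoothing_window, center=True, min_periods=1).mean()
        ).to_numpy()
    else:
        smoothed = n
    baseline = float(np.median(smoothed))
    low = smoothed <= baseline - drop_threshold
    events: list[DehydrationEvent] = []
    start = None
    for i, flag in enumerate(low):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            events.append(
                DehydrationEvent(start, i - 1, int(np.min(n[start:i])))
            )
            start = None
    if start is not None:
        events.append(DehydrationEvent(start, len(low) - 1, int(np.min(n[start:]))))
    return events


def dehydration_participation(
    series: CoordinationSeries,
    traj: Trajectory,
    cfg: HydrationConfig | None = None,
) -> dict[tuple[str, int, str], float]:
    """Frequency with which each residue's oxygens assist ion coordination.

    Over all (ion, frame) samples where the ion has ≥ 1 coordinating
    protein oxygen, a sample is attributed to every residue that
    contributes one; frequency = attributed samples / coordinating
    samples. Frequencies need not sum to 1 (several residues may assist
    the same ion simultaneously).
    """
    cfg = cfg or HydrationConfig()
    coordinating = series.table[series.table["n_protein_O"] >= 1]
    total = len(coordinating)
    if total == 0:
        return {}
    p_idx = cfg.protein_oxygen_sel.resolve_or_raise(traj.topology)
    res_keys = [
        (
            traj.topology.atoms[i].chain_id,
            traj.topology.atoms[i].residue_id,
            traj.topology.atoms[i].residue_name,
        )
        for i in p_idx
    ]
    id_to_pos = {traj.topology.atoms[i].atom_id: i for i in range(len(traj.topology))}
    counts: dict[tuple[str, int, str], int] = {}
    for row in coordinating.itertuples():
        frame = traj.frames[row.frame]
        ion_pos = id_to_pos[row.ion_id]
        cutoff = cfg.protein_cutoff_for(row.species)
        d = minimum_image_distances(
            frame.coords[ion_pos][None, :], frame.coords[p_idx], frame.box_lengths
        )[0]
        hit_res = {res_keys[j] for j in np.nonzero(d <= cutoff)[0]}
        for key in hit_res:
            counts[key] = counts.get(key, 0) + 1
    return {k: v / total for k, v in counts.items()}
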