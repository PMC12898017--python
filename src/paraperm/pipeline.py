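"""Workflow orchestration and report assembly.

Three workflows mirror how the analyses are used in practice:

* ``ephys`` — read reversal-potential (and optionally TER) CSV tables,
  recover β and γ by GHK inversion, report permeability profiles;
* ``trajectory`` — read a topology plus one or more constant-voltage
  trajectory runs, compute currents from displacement charge, the I–V
  relationship and conductance, then per-residue contacts, channel
  occupancy, pore-radius and hydration analyses where the required
  atoms exist;
* ``synthetic`` — generate a Brownian ground-truth bundle for testing.

Every output file embeds the resolved configuration (JSON in a ``#``
comment header for CSV, a ``config`` key for JSON); reruns with the same
config and seed are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
import time
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import ghk, hydration, synth, transport
from .contacts import (
    ContactConfig,
    PoreRegion,
    channel_occupancy,
    occupancy_table,
    residue_ion_occupancy,
    selectivity_filter_center,
)
from .errors import ConfigurationError
from .ghk import EphysParams
from .radius import AxisSpec, VdwTable, averaged_profile
from .species import SPECIES_TABLE, charges
from .traj import (
    Selection,
    Trajectory,
    backbone_selection,
    ion_selection,
    read_frames,
    read_topology,
    rmsd_timeseries,
    select,
    unwrap_coordinates,
    write_native,
    write_topology,
)

logger = logging.getLogger("paraperm")
logging.basicConfig(stream=sys.stderr, format="%(name)s: %(message)s")
logger.setLevel(logging.INFO)

CSV_FLOAT_FORMAT = "%.10g"


@dataclass
class TrajectoryRun:
    frames: str
    voltage_mV: float
    replica: str = "1"


@dataclass
class RunConfig:
    """Resolved configuration for any workflow; echoed into every output."""

    workflow: str = "trajectory"
    seed: int = 0
    outdir: str = "paraperm-out"
    # ephys
    potentials_csv: str | None = None
    ter_csv: str | None = None
    alpha: float = 1.9
    rtf_mV: float = 26.6
    potential_sign: int = 1
    # trajectory
    topology: str | None = None
    runs: list[TrajectoryRun] = field(default_factory=list)
    field_axis: str = "x"
    n_parallel_pores: int = 1
    fit_window_fraction: float = 0.8
    bfactor_as_vdw: bool = False
    contact_cutoff_A: float = 4.0
    filter_resids: list[int] = field(default_factory=list)
    region_half_length_A: float = 20.0
    region_radius_A: float = 8.0
    radius_span: tuple[float, float] = (-15.0, 15.0)
    radius_station_spacing_A: float = 0.25
    radius_axis: str = "z"
    radius_stride: int = 1
    hydration_bin_width_A: float = 1.0
    compute_contacts: bool | None = None
    compute_occupancy: bool | None = None
    compute_radius: bool | None = None
    compute_hydration: bool | None = None
    compute_rmsd: bool | None = None
    # synthetic
    brownian: dict = field(default_factory=dict)

    def ephys_params(self) -> EphysParams:
        return EphysParams(self.alpha, self.rtf_mV, self.potential_sign)

    def as_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, sort_keys=True, default=str)


def load_config(path: str | Path) -> RunConfig:
    """Read a RunConfig from TOML; unknown keys are an error."""
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    runs = [TrajectoryRun(**r) for r in raw.pop("runs", [])]
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    if "radius_span" in raw:
        raw["radius_span"] = tuple(raw["radius_span"])
    return RunConfig(runs=runs, **raw)


def _write_csv(path: Path, df: pd.DataFrame, config: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(f"# paraperm config: {config.as_json()}\n")
        fh.write(f"# seed: {config.seed}\n")
        df.to_csv(fh, index=False, float_format=CSV_FLOAT_FORMAT)


def _write_json(path: Path, payload: dict, config: RunConfig) -> None:
    payload = dict(payload)
    payload["config"] = json.loads(config.as_json())
    payload["seed"] = config.seed
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# ephys workflow
# ---------------------------------------------------------------------------


def run_ephys(config: RunConfig) -> dict:
    """GHK analysis of measured reversal potentials (and optional TER)."""
    t0 = time.perf_counter()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if config.potentials_csv is None:
        raise ConfigurationError("ephys workflow needs potentials_csv")
    table = pd.read_csv(config.potentials_csv, comment="#", keep_default_na=False)
    if table.empty:
        raise ConfigurationError(f"{config.potentials_csv}: empty potentials table")
    p = config.ephys_params()
    ratios, audit = ghk.analyze_potentials(table, p)
    pm_pcl = ghk.relative_to_chloride(ratios)
    summary = pd.DataFrame(
        [
            {
                "species": sp,
                "gamma_PM_PNa": ratios.gamma.get(sp, np.nan),
                "PM_PCl": pm_pcl.get(sp, np.nan),
            }
            for sp in sorted(set(ratios.gamma) | {"NA"})
        ]
    )
    summary.loc[summary["species"] == "NA", "gamma_PM_PNa"] = 1.0
    summary.loc[summary["species"] == "NA", "PM_PCl"] = 1.0 / ratios.beta
    _write_csv(outdir / "permeability_ratios.csv", summary, config)
    _write_csv(outdir / "potential_audit.csv", audit, config)
    result = {"beta_PCl_PNa": ratios.beta, "gamma": ratios.gamma}
    if config.ter_csv is not None:
        ter = ghk.summarize_ter(
            pd.read_csv(config.ter_csv, comment="#", keep_default_na=False)
        )
        _write_csv(outdir / "ter.csv", ter, config)
        result["mean_ter_ohm_cm2"] = float(ter["ter_ohm_cm2"].mean())
    _write_json(outdir / "ephys_summary.json", result, config)
    logger.info("ephys workflow done in %.2f s", time.perf_counter() - t0)
    return result


# ---------------------------------------------------------------------------
# trajectory workflow
# ---------------------------------------------------------------------------


def _load_runs(config: RunConfig) -> list[tuple[TrajectoryRun, Trajectory]]:
    if config.topology is None or not config.runs:
        raise ConfigurationError("trajectory workflow needs topology and runs")
    top, _ = read_topology(config.topology, bfactor_as_vdw=config.bfactor_as_vdw)
    ion_idx = ion_selection().resolve(top)
    for i in ion_idx:
        sp = top.atoms[i].species
        if sp not in SPECIES_TABLE:
            raise ConfigurationError(f"ion species {sp!r} has no table entry")
    return [(run, read_frames(run.frames, top)) for run in config.runs]


def run_trajectory(config: RunConfig) -> dict:
    """Full trajectory analysis: I–V/conductance plus structural stages."""
    t0 = time.perf_counter()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    loaded = _load_runs(config)
    result: dict = {}

    # --- currents and conductance -----------------------------------------
    ions = ion_selection()
    points: list[transport.IVPoint] = []
    for run, traj in loaded:
        unwrapped = unwrap_coordinates(traj, axes=(config.field_axis,))
        series = transport.displacement_charge(
            unwrapped, ions, charges(), axis=config.field_axis
        )
        t = series.time_ns
        window = (t[0] + (1 - config.fit_window_fraction) * (t[-1] - t[0]), t[-1])
        current = transport.current_from_displacement(series, window)
        points.append(
            transport.IVPoint(run.voltage_mV, current, replica=run.replica)
        )
        logger.info("run %s: V=%g mV -> I=%.4g pA", run.frames, run.voltage_mV, current)
    _write_csv(outdir / "iv.csv", transport.iv_table(points), config)
    g = transport.conductance(points, "per_voltage_mean")
    top0 = loaded[0][1]
    box = top0.frames[0].box_lengths
    ax = {"x": 0, "y": 1, "z": 2}[config.field_axis]
    geom = transport.BoxGeometry(
        length_along_field_A=float(box[ax]),
        cross_section_A2=float(np.prod(np.delete(box, ax))),
        n_parallel_pores=config.n_parallel_pores,
    )
    g_pore = transport.per_pore(g, geom)
    result["conductance_total_pS"] = g.g_pS
    result["conductance_total_sd_pS"] = g.sd_pS
    result["conductance_per_pore_pS"] = g_pore.g_pS
    result["bulk_conductivity_S_per_m"] = transport.bulk_conductivity(g, geom)
    result["iv_r2_origin"] = transport.iv_r2_through_origin(points)

    # --- structural stages on the first run -------------------------------
    first = loaded[0][1]
    topology = first.topology
    has_protein = any(
        a.species is None and a.residue_name not in {"HOH", "TIP3", "WAT", "SOL"}
        for a in topology.atoms
    )
    has_water = any(
        a.residue_name in {"HOH", "TIP3", "WAT", "SOL"} for a in topology.atoms
    )

    def enabled(flag: bool | None, default: bool) -> bool:
        return default if flag is None else flag

    if config.filter_resids:
        filter_sel: Selection | None = select(
            resids=config.filter_resids,
            predicate=lambda a: a.species is None,
            label="selectivity filter",
        )
        center = selectivity_filter_center(first, filter_sel)
    else:
        filter_sel = None
        center = np.asarray(box, dtype=float) / 2.0

    if enabled(config.compute_contacts, has_protein):
        occ = residue_ion_occupancy(
            first, ions, ContactConfig(cutoff_A=config.contact_cutoff_A)
        )
        _write_csv(outdir / "residue_occupancy.csv", occupancy_table(occ), config)
        result["n_contact_residues"] = len(occ)

    if enabled(config.compute_occupancy, True):
        axis_vec = np.zeros(3)
        axis_vec[{"x": 0, "y": 1, "z": 2}[config.radius_axis]] = 1.0
        region = PoreRegion(
            center=center,
            axis=axis_vec,
            half_length_A=config.region_half_length_A,
            radius_A=config.region_radius_A,
        )
        mean_cat, mean_an, series = channel_occupancy(
            first,
            region,
            ion_selection(sp for sp, s in SPECIES_TABLE.items() if s.charge_e > 0),
            ion_selection(sp for sp, s in SPECIES_TABLE.items() if s.charge_e < 0),
        )
        _write_csv(outdir / "channel_occupancy.csv", series, config)
        result["mean_cations_in_channel"] = mean_cat
        result["mean_anions_in_channel"] = mean_an
        result["pore_region"] = {
            "center": [float(c) for c in center],
            "half_length_A": config.region_half_length_A,
            "radius_A": config.region_radius_A,
        }

    if enabled(config.compute_radius, has_protein):
        axis_vec = np.zeros(3)
        axis_vec[{"x": 0, "y": 1, "z": 2}[config.radius_axis]] = 1.0
        axis_spec = AxisSpec(
            origin=center,
            direction=axis_vec,
            span=config.radius_span,
            station_spacing_A=config.radius_station_spacing_A,
        )
        profile = averaged_profile(
            first, [axis_spec], VdwTable(), stride=config.radius_stride
        )
        _write_csv(outdir / "pore_radius_profile.csv", profile.to_frame(), config)
        _write_json(outdir / "pore_radius_summary.json", profile.summary(), config)
        result["mean_pore_radius_A"] = profile.mean_radius_A
        result["min_pore_radius_A"] = profile.min_radius_A

    if enabled(config.compute_hydration, has_water):
        coord = hydration.coordination_counts(
            first, ions, axis_origin=center,
            axis_direction=np.eye(3)[{"x": 0, "y": 1, "z": 2}[config.radius_axis]],
        )
        _write_csv(outdir / "coordination.csv", coord.table, config)
        prof = hydration.hydration_profile(coord, config.hydration_bin_width_A)
        _write_csv(outdir / "hydration_profile.csv", prof, config)
        n_events = sum(
            len(
                hydration.dehydration_events(
                    coord.for_ion(i)["n_water"].to_numpy()
                )
            )
            for i in coord.ion_ids
        )
        result["n_dehydration_events"] = n_events

    if enabled(config.compute_rmsd, has_protein):
        rmsd = rmsd_timeseries(first, backbone_selection())
        df = pd.DataFrame({"time_ns": first.times_ns, "rmsd_A": rmsd})
        _write_csv(outdir / "backbone_rmsd.csv", df, config)
        result["mean_backbone_rmsd_A"] = float(np.mean(rmsd))

    _write_json(outdir / "trajectory_summary.json", result, config)
    logger.info("trajectory workflow done in %.2f s", time.perf_counter() - t0)
    return result


# ---------------------------------------------------------------------------
# synthetic workflow
# ---------------------------------------------------------------------------


def _brownian_spec_from_config(config: RunConfig) -> synth.BrownianSimSpec:
    b = dict(config.brownian)
    ions = []
    for entry in b.pop("ions", [["NA", 8], ["CL", 8]]):
        name, count = entry
        ions.append((SPECIES_TABLE[str(name)], int(count)))
    if "box_lengths" in b:
        b["box_lengths"] = tuple(b["box_lengths"])
    return synth.BrownianSimSpec(ions=ions, seed=config.seed, **b)


def run_synthetic(config: RunConfig) -> dict:
    """Generate a Brownian ground-truth bundle: topology (PDB), frames
    (native JSONL) and a manifest carrying the exact expected conductance."""
    t0 = time.perf_counter()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spec = _brownian_spec_from_config(config)
    traj = synth.simulate_brownian_ions(spec)
    write_topology(outdir / "ions.pdb", traj.topology, traj.frames[0])
    write_native(outdir / "ions.jsonl", traj)
    manifest = {
        "workflow": "synthetic",
        "n_atoms": traj.topology.n_atoms,
        "n_frames": traj.n_frames,
        "analytic_conductance_pS": synth.analytic_conductance(spec),
        "voltage_mV": spec.voltage_mV,
        "temperature_K": spec.temperature_K,
        "field_axis": spec.field_axis,
        "box_lengths_A": list(spec.box_lengths),
        "ions": [[ion.species, count] for ion, count in spec.ions],
        "dt_ns": spec.dt_ns,
        "n_steps": spec.n_steps,
        "sample_every": spec.sample_every,
    }
    _write_json(outdir / "manifest.json", manifest, config)
    logger.info("synthetic workflow done in %.2f s", time.perf_counter() - t0)
    return manifest


WORKFLOWS = {
    "ephys": run_ephys,
    "trajectory": run_trajectory,
    "synthetic": run_synthetic,
}


def run(config: RunConfig) -> dict:
    try:
        fn = WORKFLOWS[config.workflow]
    except KeyError:
        raise ConfigurationError(f"unknown workflow {config.workflow!r}")
    return fn(config)
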