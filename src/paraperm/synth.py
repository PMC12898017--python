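"""Synthetic-data generators with known ground truth.

Every analysis stage gets a generator whose truth is known in closed
form:

* **Brownian ion trajectories** — overdamped Langevin dynamics of
  non-interacting ions drifting in a constant electric field, with the
  exact conductance available analytically (Nernst–Einstein):

      G = Σ_species  N · (q e)² · D / (k_B T L²)

* **pseudo-atom pores** — rings of atoms with a prescribed radius
  profile (cylinder or hourglass), so the maximal-inscribed-sphere
  profile is known by construction;
* **hydration fixtures** — an ion with water/protein oxygens placed at
  exact distances;
* **noisy electrophysiology tables** — GHK forward potentials plus
  Gaussian noise at stated true β and γ.

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .constants import DEFAULT_TEMPERATURE_K, beta_e_per_mV, kT_joule, ELEMENTARY_CHARGE_C
from .errors import PlacementError, StabilityError
from .ghk import BIIONIC_CONDITION, DILUTION_CONDITION, EphysParams, biionic_forward, dilution_forward
from .species import IonSpec, SPECIES_TABLE
from .traj import Atom, Frame, Topology, Trajectory, axis_index


# ---------------------------------------------------------------------------
# Brownian ion dynamics under constant field
# ---------------------------------------------------------------------------


@dataclass
class BrownianSimSpec:
    """Overdamped-Langevin simulation of ions under a constant axial field.

    Per step and axis: Δx = (D·q·E/k_BT)·dt·ê_field + √(2·D·dt)·η with
    η ~ N(0,1) and E = voltage/box length along the field axis. The
    field axis is wrapped periodically; ``radial_confinement_radius_A``
    optionally adds reflecting walls about the field axis. Frames are
    stored every ``sample_every`` steps (dynamics still integrate at dt).
    """

    ions: Sequence[tuple[IonSpec, int]]
    box_lengths: tuple[float, float, float] = (80.0, 80.0, 80.0)
    field_axis: str = "x"
    voltage_mV: float = 0.0
    temperature_K: float = DEFAULT_TEMPERATURE_K
    dt_ns: float = 5e-4
    n_steps: int = 10_000
    seed: int = 0
    radial_confinement_radius_A: float | None = None
    sample_every: int = 1

    def __post_init__(self) -> None:
        if self.dt_ns <= 0 or self.n_steps <= 0 or self.sample_every <= 0:
            raise ValueError("dt_ns, n_steps and sample_every must be positive")
        if any(c < 0 for _, c in self.ions):
            raise ValueError("ion counts must be >= 0")

    @property
    def axis(self) -> int:
        return axis_index(self.field_axis)

    def max_drift_per_step(self) -> float:
        L = self.box_lengths[self.axis]
        b = beta_e_per_mV(self.temperature_K)
        return max(
            (
                abs(spec.diffusion_A2_per_ns * spec.charge_e * self.voltage_mV)
                * b / L * self.dt_ns
                for spec, c in self.ions
                if c > 0
            ),
            default=0.0,
        )


def analytic_conductance(spec: BrownianSimSpec) -> float:
    """Exact conductance (pS) of the homogeneous drift system:
    G = Σ N·(qe)²·D/(k_B·T·L²), with L the box length along the field axis."""
    L_m = spec.box_lengths[spec.axis] * 1e-10
    kT = kT_joule(spec.temperature_K)
    g_S = 0.0
    for ion, count in spec.ions:
        q_C = ion.charge_e * ELEMENTARY_CHARGE_C
        D_m2s = ion.diffusion_A2_per_ns * 1e-11
        g_S += count * q_C**2 * D_m2s / (kT * L_m**2)
    return g_S * 1e12


def _ion_topology(spec: BrownianSimSpec) -> tuple[Topology, np.ndarray, np.ndarray]:
    atoms: list[Atom] = []
    D = []
    q = []
    aid = 1
    for ion, count in spec.ions:
        for k in range(count):
            atoms.append(
                Atom(
                    atom_id=aid,
                    name=ion.species[:4],
                    element=ion.species[:1],
                    residue_name=ion.species[:4],
                    residue_id=aid,
                    chain_id="I",
                    species=ion.species,
                )
            )
            D.append(ion.diffusion_A2_per_ns)
            q.append(ion.charge_e)
            aid += 1
    return Topology(atoms), np.asarray(D), np.asarray(q)


def simulate_brownian_ions(spec: BrownianSimSpec) -> Trajectory:
    """Run the Brownian simulation; deterministic given the seed.

    Returns a trajectory whose field-axis coordinate is wrapped into
    [0, L); transverse axes are unwrapped (or reflected at the optional
    radial confinement wall). Raises :class:`StabilityError` when the
    deterministic drift per step exceeds a tenth of the box.
    """
    L = np.asarray(spec.box_lengths, dtype=float)
    ax = spec.axis
    if spec.max_drift_per_step() > L[ax] / 10.0:
        raise StabilityError(
            f"drift per step {spec.max_drift_per_step():.3g} Å exceeds box/10; "
            "reduce dt_ns"
        )
    top, D, q = _ion_topology(spec)
    n = len(D)
    rng = np.random.default_rng(spec.seed)
    x = rng.uniform(0.0, L, size=(n, 3))
    confine = spec.radial_confinement_radius_A
    if confine is not None:
        trans = [a for a in range(3) if a != ax]
        center = L[trans] / 2.0
        r = rng.uniform(0.0, confine * 0.7, size=n)
        theta = rng.uniform(0.0, 2 * np.pi, size=n)
        x[:, trans[0]] = center[0] + r * np.cos(theta)
        x[:, trans[1]] = center[1] + r * np.sin(theta)

    drift = np.zeros((n, 3))
    b = beta_e_per_mV(spec.temperature_K)
    E = spec.voltage_mV / L[ax]  # mV/Å
    drift[:, ax] = D * q * E * b * spec.dt_ns
    sigma = np.sqrt(2.0 * D * spec.dt_ns)[:, None]

    frames: list[Frame] = []

    def store(step: int, pos: np.ndarray) -> None:
        wrapped = pos.copy()
        wrapped[:, ax] = np.mod(wrapped[:, ax], L[ax])
        frames.append(
            Frame(
                index=len(frames),
                time_ns=step * spec.dt_ns,
                box_lengths=L.copy(),
                coords=wrapped,
            )
        )

    store(0, x)
    if confine is None:
        # Vectorized over steps, chunked to bound memory.
        chunk = max(1, min(50_000, spec.n_steps))
        step = 0
        while step < spec.n_steps:
            m = min(chunk, spec.n_steps - step)
            eta = rng.standard_normal(size=(m, n, 3))
            incr = drift[None, :, :] + sigma[None, :, :] * eta
            path = x[None, :, :] + np.cumsum(incr, axis=0)
            snum = step + 1 + np.arange(m)
            keep = (snum % spec.sample_every == 0) | (snum == spec.n_steps)
            for j in np.nonzero(keep)[0]:
                store(int(snum[j]), path[j])
            x = path[-1]
            step += m
    else:
        trans = [a for a in range(3) if a != ax]
        center = L[trans] / 2.0
        for s in range(1, spec.n_steps + 1):
            x = x + drift + sigma * rng.standard_normal(size=(n, 3))
            # reflect at the cylindrical wall about the field axis
            dvec = x[:, trans] - center
            r = np.linalg.norm(dvec, axis=1)
            outside = r > confine
            if np.any(outside):
                scale = (2 * confine - r[outside]) / r[outside]
                x[np.ix_(outside, trans)] = center + dvec[outside] * scale[:, None]
            if s % spec.sample_every == 0 or s == spec.n_steps:
                store(s, x)
    return Trajectory(top, frames)


# ---------------------------------------------------------------------------
# Pseudo-atom pore fixtures
# ---------------------------------------------------------------------------


def cylinder_profile(radius_A: float) -> Callable[[float], float]:
    """Constant ring radius: a straight cylindrical pore."""
    return lambda s: radius_A


def hourglass_profile(
    mouth_radius_A: float, waist_radius_A: float, length_A: float
) -> Callable[[float], float]:
    """Cosine-tapered hourglass: ``waist`` at mid-length, ``mouth`` at the ends.

    Station argument runs over [0, length_A].
    """
    half = length_A / 2.0

    def profile(s: float) -> float:
        t = np.cos(np.pi * (s - half) / length_A)  # 1 at waist, 0 at mouths
        return mouth_radius_A + (waist_radius_A - mouth_radius_A) * float(t)

    return profile


@dataclass
class PorePseudoAtomSpec:
    """Rings of pseudo-atoms along an axis with a prescribed radius profile."""

    axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    length_A: float = 30.0
    ring_spacing_A: float = 1.0
    atoms_per_ring: int = 12
    ring_radius_profile: Callable[[float], float] = field(
        default_factory=lambda: cylinder_profile(5.0)
    )
    atom_vdw_A: float = 1.65
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.atoms_per_ring < 6:
            raise ValueError("atoms_per_ring must be >= 6")
        a = np.asarray(self.axis, dtype=float)
        norm = np.linalg.norm(a)
        if norm == 0:
            raise ValueError("axis must be non-zero")
        self.axis = tuple(a / norm)


def build_pore_pseudoatoms(spec: PorePseudoAtomSpec) -> tuple[Topology, Frame]:
    """Place pseudo-atoms on rings; atom count = n_rings × atoms_per_ring.

    Per-atom vdW radii are stored in Atom.vdw_A so the pore profiler
    uses the construction's radius exactly.
    """
    axis = np.asarray(spec.axis)
    origin = np.asarray(spec.origin, dtype=float)
    # orthonormal in-plane basis
    helper = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(helper, axis)) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    u = np.cross(axis, helper)
    u /= np.linalg.norm(u)
    v = np.cross(axis, u)

    n_rings = int(np.floor(spec.length_A / spec.ring_spacing_A)) + 1
    atoms: list[Atom] = []
    coords: list[np.ndarray] = []
    aid = 1
    for i in range(n_rings):
        s = i * spec.ring_spacing_A
        radius = float(spec.ring_radius_profile(s))
        for k in range(spec.atoms_per_ring):
            phi = 2 * np.pi * k / spec.atoms_per_ring
            pos = origin + axis * s + radius * (np.cos(phi) * u + np.sin(phi) * v)
            atoms.append(
                Atom(
                    atom_id=aid,
                    name="PSD",
                    element="C",
                    residue_name="PSD",
                    residue_id=i + 1,
                    chain_id="P",
                    vdw_A=spec.atom_vdw_A,
                )
            )
            coords.append(pos)
            aid += 1
    xyz = np.asarray(coords)
    span = xyz.max(axis=0) - xyz.min(axis=0) + 40.0
    frame = Frame(index=0, time_ns=0.0, box_lengths=span, coords=xyz)
    return Topology(atoms), frame


# ---------------------------------------------------------------------------
# Hydration fixtures
# ---------------------------------------------------------------------------


def _random_directions(rng: np.random.Generator, n: int) -> np.ndarray:
    vec = rng.standard_normal(size=(n, 3))
    return vec / np.linalg.norm(vec, axis=1, keepdims=True)


def simulate_hydration_configuration(
    species: IonSpec,
    n_water: int,
    water_distance_A: float,
    n_protein_O: int = 0,
    protein_distance_A: float = 2.5,
    seed: int = 0,
    min_separation_A: float = 1.5,
) -> tuple[Topology, Frame]:
    """One ion at the origin with oxygens placed at exact distances.

    ``n_water`` water oxygens at ``water_distance_A`` and ``n_protein_O``
    protein (carbonyl/carboxylate) oxygens at ``protein_distance_A``, in
    random non-overlapping directions. Deterministic given seed; raises
    :class:`PlacementError` if directions cannot be found with at least
    ``min_separation_A`` between placed oxygens.
    """
    if water_distance_A <= 0 or protein_distance_A <= 0:
        raise ValueError("distances must be > 0")
    rng = np.random.default_rng(seed)
    placed: list[np.ndarray] = []
    specs = [(water_distance_A, "water")] * n_water + [
        (protein_distance_A, "protein")
    ] * n_protein_O
    kinds: list[str] = []
    for dist, kind in specs:
        for _ in range(2000):
            cand = dist * _random_directions(rng, 1)[0]
            if all(np.linalg.norm(cand - p) >= min_separation_A for p in placed):
                placed.append(cand)
                kinds.append(kind)
                break
        else:
            raise PlacementError(
                f"could not place {len(specs)} oxygens at the requested distances "
                f"with {min_separation_A} Å separation"
            )
    atoms = [
        Atom(
            atom_id=1,
            name=species.species[:4],
            element=species.species[:1],
            residue_name=species.species[:4],
            residue_id=1,
            chain_id="I",
            species=species.species,
        )
    ]
    coords = [np.zeros(3)]
    aid = 2
    resid_w = 100
    resid_p = 500
    for pos, kind in zip(placed, kinds):
        if kind == "water":
            atoms.append(
                Atom(aid, "OH2", "O", "TIP3", resid_w, "W")
            )
            resid_w += 1
        else:
            atoms.append(
                Atom(aid, "O", "O", "GLY", resid_p, "A")
            )
            resid_p += 1
        coords.append(pos)
        aid += 1
    xyz = np.asarray(coords)
    box = np.full(3, 2 * max(water_distance_A, protein_distance_A) + 30.0)
    return Topology(atoms), Frame(index=0, time_ns=0.0, box_lengths=box, coords=xyz)


# ---------------------------------------------------------------------------
# Noisy electrophysiology tables
# ---------------------------------------------------------------------------


@dataclass
class EphysSimSpec:
    """Forward-GHK measurement generator at known true β and γ."""

    true_beta: float = 0.3
    true_gamma: dict[str, float] = field(
        default_factory=lambda: {"K": 1.2, "CS": 1.0, "TMA": 0.2}
    )
    noise_sd_mV: float = 0.5
    n_replicates: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.noise_sd_mV < 0:
            raise ValueError("noise_sd_mV must be >= 0")


def simulate_ephys_measurements(
    spec: EphysSimSpec, p: EphysParams = EphysParams()
) -> pd.DataFrame:
    """Tidy table of noisy reversal potentials: dilution rows (species NA)
    plus one bi-ionic row set per test cation. Deterministic given seed."""
    rng = np.random.default_rng(spec.seed)
    rows = []
    v_dil = dilution_forward(spec.true_beta, p)
    for r in range(spec.n_replicates):
        rows.append(
            {
                "sample_id": f"dil-{r}",
                "condition": DILUTION_CONDITION,
                "species": "NA",
                "v_rev_mV": v_dil + rng.normal(0.0, spec.noise_sd_mV),
            }
        )
    for sp, g in spec.true_gamma.items():
        v_bi = biionic_forward(g, spec.true_beta, p)
        for r in range(spec.n_replicates):
            rows.append(
                {
                    "sample_id": f"{sp}-{r}",
                    "condition": BIIONIC_CONDITION,
                    "species": sp,
                    "v_rev_mV": v_bi + rng.normal(0.0, spec.noise_sd_mV),
                }
            )
    return pd.DataFrame(rows)


def default_brownian_spec(
    seed: int = 0,
    voltage_mV: float = 800.0,
    n_steps: int = 1_000_000,
    cation: str = "NA",
    n_each: int = 8,
    box: float = 80.0,
    sample_every: int = 200,
) -> BrownianSimSpec:
    """Study-condition Brownian run: an equimolar cation/Cl⁻ box at 333 K
    under a constant axial field, 0.5 ps time step."""
    return BrownianSimSpec(
        ions=[(SPECIES_TABLE[cation], n_each), (SPECIES_TABLE["CL"], n_each)],
        box_lengths=(box, box, box),
        field_axis="x",
        voltage_mV=voltage_mV,
        temperature_K=DEFAULT_TEMPERATURE_K,
        dt_ns=5e-4,
        n_steps=n_steps,
        seed=seed,
        sample_every=sample_every,
    )
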