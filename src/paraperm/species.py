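"""Ion species table.

Charges are in elementary-charge units, radii in Å, diffusion
coefficients in Å²/ns (1 Å²/ns = 1e-11 m²/s; infinite-dilution aqueous
values). Hydration cutoffs define the first-shell boundary used by the
coordination analysis: 3.5 Å for the small cations Li⁺ and Na⁺, 4.0 Å
for the larger alkali and alkylammonium cations.

Polyatomic cations (MA⁺ methylammonium, EA⁺ ethylammonium, TMA⁺
tetramethylammonium, TEA⁺ tetraethylammonium) are represented by their
central nitrogen for all distance measurements.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class IonSpec:
    """Per-species parameters for permeation analysis and simulation."""

    species: str
    charge_e: float
    ionic_radius_A: float
    hydration_cutoff_A: float
    diffusion_A2_per_ns: float

    def __post_init__(self) -> None:
        if self.hydration_cutoff_A <= self.ionic_radius_A:
            raise ValueError(
                f"{self.species}: hydration cutoff {self.hydration_cutoff_A} Å "
                f"must exceed ionic radius {self.ionic_radius_A} Å"
            )
        if self.diffusion_A2_per_ns < 0:
            raise ValueError(f"{self.species}: diffusion coefficient must be >= 0")


#: The nine monovalent cations of the permeability series, plus chloride.
SPECIES_TABLE: dict[str, IonSpec] = {
    s.species: s
    for s in [
        IonSpec("LI", +1.0, 0.60, 3.5, 103.0),
        IonSpec("NA", +1.0, 0.95, 3.5, 133.0),
        IonSpec("K", +1.0, 1.33, 4.0, 196.0),
        IonSpec("RB", +1.0, 1.48, 4.0, 207.0),
        IonSpec("CS", +1.0, 1.69, 4.0, 206.0),
        IonSpec("MA", +1.0, 2.17, 4.0, 156.0),
        IonSpec("EA", +1.0, 2.52, 4.0, 131.0),
        IonSpec("TMA", +1.0, 2.80, 4.0, 119.0),
        IonSpec("TEA", +1.0, 3.30, 4.0, 87.0),
        IonSpec("CL", -1.0, 1.81, 4.0, 203.0),
    ]
}

CATION_SPECIES = tuple(s for s, spec in SPECIES_TABLE.items() if spec.charge_e > 0)
ANION_SPECIES = tuple(s for s, spec in SPECIES_TABLE.items() if spec.charge_e < 0)

#: Common residue-name aliases (CHARMM / PDB) mapped onto species labels.
RESNAME_TO_SPECIES: dict[str, str] = {
    "LIT": "LI", "LI": "LI",
    "SOD": "NA", "NA": "NA",
    "POT": "K", "K": "K",
    "RUB": "RB", "RB": "RB",
    "CES": "CS", "CS": "CS",
    "MA": "MA", "MAM": "MA",
    "EA": "EA", "EAM": "EA",
    "TMA": "TMA", "TEA": "TEA",
    "CLA": "CL", "CL": "CL",
}


def charges(table: dict[str, IonSpec] = SPECIES_TABLE) -> dict[str, float]:
    """Species → charge (e) mapping, as consumed by displacement-charge analysis."""
    return {name: spec.charge_e for name, spec in table.items()}
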