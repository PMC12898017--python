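"""Goldman–Hodgkin–Katz reversal-potential analysis.

Transepithelial measurements across a monolayer expressing a
cation-selective paracellular channel yield two kinds of reversal
potentials:

* **dilution potentials** — basal NaCl halved (activity ratio α), giving
  the anion/cation permeability ratio β = P_Cl⁻/P_Na⁺ through

      V_rev = −(RT/F) · ln[(α + β) / (1 + αβ)]

* **bi-ionic potentials** — basal Na⁺ replaced by a test cation M⁺,
  giving γ = P_M⁺/P_Na⁺ (at known β) through

      V_rev = (RT/F) · ln[(γ + β) / (1 + β)]

Both inversions are closed-form. Defaults α = 1.9 (2-fold NaCl dilution
with activity correction) and RT/F = 26.6 mV. The sign convention is
basal-minus-apical potential at zero current with the basal side
modified, matching the equations as written; ``potential_sign`` flips
measured potentials at the boundary if the electrode orientation is
reversed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DomainError, NonPhysicalPotentialError


@dataclass(frozen=True)
class EphysParams:
    """GHK constants: dilution activity ratio α and thermal voltage RT/F (mV)."""

    alpha: float = 1.9
    rtf_mV: float = 26.6
    potential_sign: int = +1

    def __post_init__(self) -> None:
        if self.alpha <= 1:
            raise ValueError("alpha must exceed 1 (a genuine dilution)")
        if self.rtf_mV <= 0:
            raise ValueError("rtf_mV must be positive")
        if self.potential_sign not in (+1, -1):
            raise ValueError("potential_sign must be +1 or -1")


@dataclass
class PermeabilityRatios:
    """β = P_Cl⁻/P_Na⁺ and γ[M] = P_M⁺/P_Na⁺ for each test cation."""

    beta: float
    gamma: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ValueError("beta must be > 0")
        if any(g < 0 for g in self.gamma.values()):
            raise ValueError("gamma values must be >= 0")


@dataclass
class TERMeasurement:
    """Raw and blank (support-only) resistance, Ω, and membrane area, cm²."""

    raw_ohm: float
    blank_ohm: float
    area_cm2: float

    def __post_init__(self) -> None:
        if self.area_cm2 <= 0:
            raise ValueError("area_cm2 must be > 0")

    @property
    def suspect(self) -> bool:
        """True when raw < blank, i.e. a physically implausible monolayer."""
        return self.raw_ohm < self.blank_ohm


def correct_ter(m: TERMeasurement) -> float:
    """Blank-corrected transepithelial resistance, Ω·cm²: (raw − blank) × area.

    A raw resistance below the blank still returns the (negative) value
    but emits a warning — the measurement is flagged, not discarded.
    """
    if m.suspect:
        warnings.warn(
            f"raw resistance {m.raw_ohm} Ω below blank {m.blank_ohm} Ω; "
            "monolayer flagged as suspect",
            stacklevel=2,
        )
    return (m.raw_ohm - m.blank_ohm) * m.area_cm2


def dilution_forward(beta: float, p: EphysParams = EphysParams()) -> float:
    """Dilution reversal potential (mV) from β = P_Cl⁻/P_Na⁺."""
    if beta < 0:
        raise DomainError(f"beta must be >= 0, got {beta}")
    return -p.rtf_mV * math.log((p.alpha + beta) / (1.0 + p.alpha * beta))


def dilution_invert(v_rev_mV: float, p: EphysParams = EphysParams()) -> float:
    """β from a measured dilution potential: β = (u − α)/(1 − αu), u = e^(−V/rtf).

    Admissible potentials lie strictly inside (−RT/F·ln α, +RT/F·ln α);
    outside, no non-negative β exists.
    """
    v = p.potential_sign * v_rev_mV
    vmax = p.rtf_mV * math.log(p.alpha)
    if not (-vmax < v < vmax):
        raise NonPhysicalPotentialError(
            f"dilution potential {v_rev_mV} mV outside admissible "
            f"(−{vmax:.2f}, +{vmax:.2f}) mV"
        )
    u = math.exp(-v / p.rtf_mV)
    return (u - p.alpha) / (1.0 - p.alpha * u)


def biionic_forward(
    gamma: float, beta: float, p: EphysParams = EphysParams()
) -> float:
    """Bi-ionic reversal potential (mV) from γ = P_M⁺/P_Na⁺ at known β."""
    if gamma < 0:
        raise DomainError(f"gamma must be >= 0, got {gamma}")
    if beta <= 0 and gamma == 0:
        raise DomainError("gamma and beta cannot both be zero (log of 0)")
    if beta < 0:
        raise DomainError(f"beta must be >= 0, got {beta}")
    return p.rtf_mV * math.log((gamma + beta) / (1.0 + beta))


def biionic_invert(
    v_rev_mV: float, beta: float, p: EphysParams = EphysParams()
) -> float:
    """γ from a measured bi-ionic potential: γ = u(1 + β) − β, u = e^(V/rtf)."""
    if beta <= 0:
        raise DomainError(f"beta must be > 0, got {beta}")
    u = math.exp(p.potential_sign * v_rev_mV / p.rtf_mV)
    gamma = u * (1.0 + beta) - beta
    if gamma < 0:
        raise NonPhysicalPotentialError(
            f"bi-ionic potential {v_rev_mV} mV at beta={beta} implies "
            f"gamma={gamma:.4g} < 0"
        )
    return gamma


def relative_to_chloride(ratios: PermeabilityRatios) -> dict[str, float]:
    """Cation permeabilities normalized to chloride: P_M/P_Cl = γ[M]/β."""
    return {sp: g / ratios.beta for sp, g in ratios.gamma.items()}


def delta_permeability(
    expressing: dict[str, float],
    control: dict[str, float],
    normalize_to: str = "NA",
) -> dict[str, float]:
    """Channel-dependent permeability profile: per-species difference
    (expressing − control), normalized so the reference species maps to 1.

    Isolates the channel's own size-selectivity from the background
    (non-expressing) paracellular leak.
    """
    shared = set(expressing) & set(control)
    if normalize_to not in shared:
        raise DomainError(f"normalize_to species {normalize_to!r} missing from inputs")
    delta = {sp: expressing[sp] - control[sp] for sp in shared}
    norm = delta[normalize_to]
    if norm <= 0:
        raise DomainError(
            f"delta for {normalize_to!r} is {norm:.4g} <= 0; cannot normalize"
        )
    return {sp: d / norm for sp, d in delta.items()}


# ---------------------------------------------------------------------------
# Table-level analysis (CSV in / CSV out)
# ---------------------------------------------------------------------------

DILUTION_CONDITION = "dilution"
BIIONIC_CONDITION = "biionic"


def analyze_potentials(
    table: pd.DataFrame, p: EphysParams = EphysParams()
) -> tuple[PermeabilityRatios, pd.DataFrame]:
    """Recover permeability ratios from a tidy reversal-potential table.

    Expects columns ``(sample_id, condition, species, v_rev_mV)`` where
    condition is 'dilution' or 'biionic'. The dilution potential is
    averaged over replicates before inversion; each bi-ionic species is
    averaged likewise and inverted at the recovered β. Rows whose
    potential is outside the admissible range are flagged (``ok=False``)
    and excluded from the averages; the run continues.

    Returns the recovered ratios and a per-row audit table.
    """
    required = {"sample_id", "condition", "species", "v_rev_mV"}
    missing = required - set(table.columns)
    if missing:
        raise DomainError(f"potential table missing columns: {sorted(missing)}")
    audit = table.copy()
    audit["ok"] = True
    audit["flag"] = ""

    dil = audit[audit["condition"] == DILUTION_CONDITION]
    if dil.empty:
        raise DomainError("no dilution rows; beta cannot be recovered")
    vmax = p.rtf_mV * math.log(p.alpha)
    bad = ~dil["v_rev_mV"].map(
        lambda v: -vmax < p.potential_sign * v < vmax
    )
    audit.loc[dil.index[bad], ["ok", "flag"]] = [False, "non-physical potential"]
    good = audit.loc[dil.index[~bad], "v_rev_mV"]
    if good.empty:
        raise DomainError("all dilution rows non-physical; beta cannot be recovered")
    beta = dilution_invert(float(good.mean()), p)

    gamma: dict[str, float] = {}
    bi = audit[audit["condition"] == BIIONIC_CONDITION]
    for sp, grp in bi.groupby("species"):
        try:
            gamma[str(sp)] = biionic_invert(float(grp["v_rev_mV"].mean()), beta, p)
        except NonPhysicalPotentialError:
            audit.loc[grp.index, ["ok", "flag"]] = [False, "non-physical potential"]
    return PermeabilityRatios(beta=beta, gamma=gamma), audit


def summarize_ter(table: pd.DataFrame) -> pd.DataFrame:
    """Blank-correct a TER table with columns (sample_id, raw_ohm, blank_ohm,
    area_cm2); adds ``ter_ohm_cm2`` and a ``suspect`` flag per row."""
    required = {"sample_id", "raw_ohm", "blank_ohm", "area_cm2"}
    missing = required - set(table.columns)
    if missing:
        raise DomainError(f"TER table missing columns: {sorted(missing)}")
    out = table.copy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        out["ter_ohm_cm2"] = [
            correct_ter(TERMeasurement(r.raw_ohm, r.blank_ohm, r.area_cm2))
            for r in out.itertuples()
        ]
    out["suspect"] = out["raw_ohm"] < out["blank_ohm"]
    return out


def permeability_change_summary(
    expressing_betas: np.ndarray, control_betas: np.ndarray
) -> dict[str, float]:
    """Relative P_Na/P_Cl change of one condition versus another, computed
    both as a ratio of means and as a mean of per-pair ratios (the two
    conventions that a 'reduced to X% of control' statement may follow)."""
    pna_pcl_e = 1.0 / np.asarray(expressing_betas, dtype=float)
    pna_pcl_c = 1.0 / np.asarray(control_betas, dtype=float)
    n = min(len(pna_pcl_e), len(pna_pcl_c))
    return {
        "ratio_of_means": float(pna_pcl_e.mean() / pna_pcl_c.mean()),
        "mean_of_ratios": float(np.mean(pna_pcl_e[:n] / pna_pcl_c[:n])),
    }
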