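"""Synthesis-protocol arithmetic for the nanoparticle formulation.

Converts recipe lines (masses in ug, or volumes of stocks in uL at
mg/mL) into moles, molar percentages, counterion stoichiometric excess
and payload dose concentration, and aggregates everything into a recipe
report with warnings.  The default reagent registry carries the shell
formulation used throughout: POPC (760.1 g/mol), cholesterol (386.7),
DSPE-PEG (~2810), DSPE-PEG-MAN (~3000), the cationic lipid
DC-cholesterol (537.3) and the oligonucleotide payload.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

__all__ = [
    "ReagentRole",
    "Reagent",
    "RecipeLine",
    "FormulationReport",
    "moles_from_line",
    "mole_percentages",
    "counterion_excess",
    "dose_concentration",
    "recipe_report",
    "DEFAULT_REAGENTS",
    "shell_lipid_recipe",
]


class ReagentRole(str, enum.Enum):
    PAYLOAD = "payload"
    CATIONIC_LIPID = "cationic_lipid"
    HELPER = "helper"
    STABILIZER = "stabilizer"
    ADHESION = "adhesion"
    TARGETING = "targeting"


@dataclass(frozen=True)
class Reagent:
    name: str
    molar_mass: float  # g/mol
    role: ReagentRole
    stock_concentration: float | None = None  # mg/mL

    def __post_init__(self) -> None:
        if not self.molar_mass > 0:
            raise ValueError(f"molar_mass must be > 0 for {self.name}")
        if self.stock_concentration is not None and not self.stock_concentration > 0:
            raise ValueError(f"stock_concentration must be > 0 for {self.name}")


@dataclass(frozen=True)
class RecipeLine:
    """One addition: either a mass (ug) or a volume (uL) of stock."""

    reagent: Reagent
    mass_ug: float | None = None
    volume_uL: float | None = None

    def __post_init__(self) -> None:
        if (self.mass_ug is None) == (self.volume_uL is None):
            raise ValueError("specify exactly one of mass_ug or volume_uL")
        amount = self.mass_ug if self.mass_ug is not None else self.volume_uL
        if amount < 0:
            raise ValueError("amounts must be >= 0")


DEFAULT_REAGENTS: dict[str, Reagent] = {
    "GR": Reagent("GR", 16 * 330.0, ReagentRole.PAYLOAD),  # ~330 g/mol per base
    "DChol": Reagent("DChol", 537.3, ReagentRole.CATIONIC_LIPID, stock_concentration=18.0),
    "Chol": Reagent("Chol", 386.7, ReagentRole.HELPER, stock_concentration=10.0),
    "POPC": Reagent("POPC", 760.1, ReagentRole.STABILIZER, stock_concentration=10.0),
    "DSPE-PEG": Reagent("DSPE-PEG", 2810.0, ReagentRole.ADHESION, stock_concentration=10.0),
    "DSPE-PEG-MAN": Reagent("DSPE-PEG-MAN", 3000.0, ReagentRole.TARGETING, stock_concentration=10.0),
}


def shell_lipid_recipe() -> list[RecipeLine]:
    """The lipid-film mixing step of the protocol (shell lipids only).

    520 ug POPC, 130 ug cholesterol, 40 ug DSPE-PEG and 310 ug
    DSPE-PEG-MAN, i.e. a 60:30:1:9 molar shell composition.
    """
    r = DEFAULT_REAGENTS
    return [
        RecipeLine(r["POPC"], mass_ug=520.0),
        RecipeLine(r["Chol"], mass_ug=130.0),
        RecipeLine(r["DSPE-PEG"], mass_ug=40.0),
        RecipeLine(r["DSPE-PEG-MAN"], mass_ug=310.0),
    ]


def moles_from_line(line: RecipeLine) -> float:
    """Moles in a recipe line, in nmol.

    Mass lines use ``mass / molar_mass``; volume lines go through the
    reagent's stock concentration first (uL * mg/mL = ug).
    """
    if line.mass_ug is not None:
        mass_ug = line.mass_ug
    else:
        if line.reagent.stock_concentration is None:
            raise ValueError(
                f"volume line for {line.reagent.name} requires a stock concentration"
            )
        mass_ug = line.volume_uL * line.reagent.stock_concentration
    # ug / (g/mol) = umol * 1e-3 -> nmol = ug/MW * 1e3
    return mass_ug / line.reagent.molar_mass * 1e3


def mole_percentages(recipe: list[RecipeLine]) -> dict[str, object]:
    """Raw and integer-rounded molar percentages of a recipe.

    Raw percentages sum to 100 exactly (to floating precision); the
    rounded report values are nearest-integer.
    """
    if not recipe:
        raise ValueError("recipe must contain at least one line")
    moles = [moles_from_line(line) for line in recipe]
    total = sum(moles)
    if not total > 0:
        raise ValueError("total moles must be > 0")
    raw = [100.0 * m / total for m in moles]
    return {
        "names": [line.reagent.name for line in recipe],
        "raw_percent": raw,
        "report_percent": [round(p) for p in raw],
        "moles_nmol": moles,
    }


def counterion_excess(
    payload_monomer_umol: float,
    counterion_umol: float,
    stoich: float = 2.0,
) -> float:
    """Counterion excess relative to stoichiometric demand.

    ``counterion / (stoich * payload_monomers)``; values above 1 mean
    the cationic lipid is in excess of the per-monomer stoichiometry.
    """
    if not payload_monomer_umol > 0:
        raise ValueError("payload monomer moles must be > 0")
    return counterion_umol / (stoich * payload_monomer_umol)


def dose_concentration(payload_nmol: float, final_volume_uL: float) -> float:
    """Payload dose concentration in nmol/uL (full precision)."""
    if not final_volume_uL > 0:
        raise ValueError("final volume must be > 0")
    return payload_nmol / final_volume_uL


@dataclass(frozen=True)
class FormulationReport:
    names: tuple[str, ...]
    moles_nmol: tuple[float, ...]
    raw_percent: tuple[float, ...]
    report_percent: tuple[int, ...]
    counterion_excess: float | None
    dose_nmol_per_uL: float | None
    warnings: tuple[str, ...] = field(default=())


def recipe_report(
    recipe: list[RecipeLine],
    payload_monomer_umol: float | None = None,
    counterion_umol: float | None = None,
    stoich: float = 2.0,
    payload_nmol: float | None = None,
    final_volume_uL: float | None = None,
    target_percent: dict[str, float] | None = None,
    percent_tolerance: float = 2.0,
) -> FormulationReport:
    """Aggregate recipe arithmetic into a report with warnings.

    Warnings are emitted when the counterion excess falls below 1
    (sub-stoichiometric cationic lipid) and when any component's raw
    molar percentage deviates from a declared target formula by more
    than ``percent_tolerance`` points.
    """
    pct = mole_percentages(recipe)
    warnings: list[str] = []
    excess = None
    if payload_monomer_umol is not None and counterion_umol is not None:
        excess = counterion_excess(payload_monomer_umol, counterion_umol, stoich)
        if excess < 1.0:
            warnings.append(
                f"counterion excess {excess:.2f} < 1: sub-stoichiometric cationic lipid"
            )
    dose = None
    if payload_nmol is not None and final_volume_uL is not None:
        dose = dose_concentration(payload_nmol, final_volume_uL)
    if target_percent:
        for name, raw in zip(pct["names"], pct["raw_percent"]):
            if name in target_percent and abs(raw - target_percent[name]) > percent_tolerance:
                warnings.append(
                    f"{name}: {raw:.1f} mol% deviates from target "
                    f"{target_percent[name]:.1f} mol% by more than {percent_tolerance}"
                )
    return FormulationReport(
        names=tuple(pct["names"]),
        moles_nmol=tuple(pct["moles_nmol"]),
        raw_percent=tuple(pct["raw_percent"]),
        report_percent=tuple(pct["report_percent"]),
        counterion_excess=excess,
        dose_nmol_per_uL=dose,
        warnings=tuple(warnings),
    )
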