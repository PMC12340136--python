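"""Monoisotopic mass constants and m/z arithmetic.

All peptide masses in this package are monoisotopic (Orbitrap-class
precursor usage); average masses are never used. Residue masses are
the standard amino-acid *residue* masses (peptide-bond subtracted);
a peptide's neutral mass is the residue sum plus one water.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

# Standard monoisotopic residue masses, Da.
MONOISOTOPIC_RESIDUE_MASSES: dict[str, float] = {
    "G": 57.02146372057,
    "A": 71.03711378471,
    "S": 87.03202840427,
    "P": 97.05276384885,
    "V": 99.06841391299,
    "T": 101.04767846841,
    "C": 103.00918478471,
    "L": 113.08406397713,
    "I": 113.08406397713,
    "N": 114.04292744114,
    "D": 115.02694302383,
    "Q": 128.05857750528,
    "K": 128.09496301399,
    "E": 129.04259308797,
    "M": 131.04048491299,
    "H": 137.05891185845,
    "F": 147.06841391299,
    "R": 156.10111102359,
    "Y": 163.06332853255,
    "W": 186.07931294986,
}

WATER_MASS: float = 18.0105646863
PROTON_MASS: float = 1.00727646688

CANONICAL_RESIDUES = frozenset(MONOISOTOPIC_RESIDUE_MASSES)

# Monoisotopic element masses used to derive adduct deltas.
MONOISOTOPIC_ELEMENTS: dict[str, float] = {
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "S": 31.97207100,
}


def composition_mass(composition: Mapping[str, int]) -> float:
    """Monoisotopic mass of an elemental composition, e.g. ``{"C": 6, "H": 11, ...}``.

    Negative counts are allowed (net losses in adduct chemistry).
    """
    try:
        return sum(MONOISOTOPIC_ELEMENTS[el] * n for el, n in composition.items())
    except KeyError as exc:  # pragma: no cover - defensive
        raise ValueError(f"unknown element {exc.args[0]!r}") from exc


# Sulforaphane C6H11NOS2: the intact mono-adduct added across a cysteine
# thiol (dithiocarbamate intermediate).
SULFORAPHANE_MASS: float = composition_mass({"C": 6, "H": 11, "N": 1, "O": 1, "S": 2})

# Dithiolethione-type bridge between two cysteines: thiol addition of
# sulforaphane followed by attack of a second cysteine thiol expels the
# sulforaphane amine, leaving a one-carbon thiocarbonyl bridge.  Net
# change on the two peptides: +C +S -2H.
DITHIOLETHIONE_BRIDGE_MASS: float = composition_mass({"C": 1, "S": 1, "H": -2})


@dataclass(frozen=True)
class MassTable:
    """Residue/water/proton mass constants used for all mass arithmetic."""

    residue_monoisotopic: Mapping[str, float] = field(
        default_factory=lambda: dict(MONOISOTOPIC_RESIDUE_MASSES)
    )
    water: float = WATER_MASS
    proton: float = PROTON_MASS

    def __post_init__(self) -> None:
        if self.water <= 0 or self.proton <= 0:
            raise ValueError("water and proton masses must be positive")
        bad = [r for r, m in self.residue_monoisotopic.items() if m <= 0]
        if bad:
            raise ValueError(f"non-positive residue masses for {bad}")


DEFAULT_MASS_TABLE = MassTable()


@dataclass(frozen=True)
class ModificationSpec:
    """A fixed or variable mass modification targeting one residue type.

    ``mode='fixed'`` mods are applied to every (unblocked) target
    residue; ``mode='variable'`` mods are applied per configured
    combination by the caller.
    """

    name: str
    delta_mass: float
    target_residue: str
    mode: str = "fixed"

    def __post_init__(self) -> None:
        import math

        if not math.isfinite(self.delta_mass):
            raise ValueError("delta_mass must be finite")
        if self.target_residue not in CANONICAL_RESIDUES:
            raise ValueError(f"non-canonical target residue {self.target_residue!r}")
        if self.mode not in ("fixed", "variable"):
            raise ValueError(f"mode must be 'fixed' or 'variable', got {self.mode!r}")


# Maleimide Michael addition to cysteine, C4H3NO2.
MALEIMIDE_MOD = ModificationSpec(
    name="maleimide",
    delta_mass=composition_mass({"C": 4, "H": 3, "N": 1, "O": 2}),
    target_residue="C",
)


def mz_from_mass(neutral_mass: float, charge: int, proton: float = PROTON_MASS) -> float:
    """m/z of a neutral mass at a positive charge state."""
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    return (neutral_mass + charge * proton) / charge


def mass_from_mz(mz: float, charge: int, proton: float = PROTON_MASS) -> float:
    """Neutral mass from an observed m/z and charge (inverse of mz_from_mass)."""
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    return charge * mz - charge * proton


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed parts-per-million error of an observed vs. theoretical mass."""
    return 1e6 * (observed - theoretical) / theoretical
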