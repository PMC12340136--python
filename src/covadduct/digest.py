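"""Trypsin in-silico digestion and peptide mass arithmetic.

Digestion follows the strict trypsin rule used by the common search
engines: cleavage C-terminal to K or R, suppressed when the next
residue is P.  Peptides are reported with 1-based inclusive protein
coordinates (matching the field's residue numbering, e.g. Cys333),
their missed-cleavage count, and the protein coordinates of every
cysteine they contain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from covadduct.masses import (
    CANONICAL_RESIDUES,
    DEFAULT_MASS_TABLE,
    MassTable,
    ModificationSpec,
)


@dataclass(frozen=True)
class ProteinSequence:
    """A protein as an accession id plus canonical one-letter residues."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein id must be non-empty")
        if not self.residues:
            raise ValueError(f"protein {self.id!r}: empty sequence")
        for pos, aa in enumerate(self.residues, start=1):
            if aa not in CANONICAL_RESIDUES:
                raise ValueError(
                    f"protein {self.id!r}: non-canonical residue {aa!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class Peptide:
    """A tryptic fragment with protein coordinates (1-based inclusive)."""

    parent_id: str
    start: int
    end: int
    sequence: str
    missed_cleavages: int
    cys_positions: tuple[int, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"bad peptide coordinates {self.start}..{self.end}")
        if len(self.sequence) != self.end - self.start + 1:
            raise ValueError("sequence length disagrees with coordinates")
        for pos in self.cys_positions:
            if self.sequence[pos - self.start] != "C":
                raise ValueError(f"cys_position {pos} does not map to 'C'")

    def __len__(self) -> int:
        return len(self.sequence)


def cleavage_sites(residues: str) -> list[int]:
    """0-based indices i such that trypsin cuts between residues i and i+1.

    Cuts after K/R except when followed by P; the C-terminus is not a
    site.
    """
    return [
        i
        for i in range(len(residues) - 1)
        if residues[i] in "KR" and residues[i + 1] != "P"
    ]


def digest_trypsin(
    protein: ProteinSequence,
    max_missed: int = 3,
    min_len: int = 4,
    max_len: int = 60,
) -> list[Peptide]:
    """Enumerate tryptic peptides with 0..max_missed missed cleavages.

    Returns peptides ordered by (start, end).  A fully uncut protein
    with no internal K/R sites yields exactly one peptide.
    """
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")
    seq = protein.residues
    sites = cleavage_sites(seq)
    # Fragment boundaries: starts of fully cleaved fragments.
    starts = [0] + [i + 1 for i in sites]
    ends = [i for i in sites] + [len(seq) - 1]  # inclusive 0-based ends

    peptides: list[Peptide] = []
    n_frag = len(starts)
    for i in range(n_frag):
        for j in range(i, min(i + max_missed + 1, n_frag)):
            s0, e0 = starts[i], ends[j]
            length = e0 - s0 + 1
            if length < min_len or length > max_len:
                continue
            sub = seq[s0 : e0 + 1]
            cys = tuple(
                s0 + 1 + k for k, aa in enumerate(sub) if aa == "C"
            )
            peptides.append(
                Peptide(
                    parent_id=protein.id,
                    start=s0 + 1,
                    end=e0 + 1,
                    sequence=sub,
                    missed_cleavages=j - i,
                    cys_positions=cys,
                )
            )
    peptides.sort(key=lambda p: (p.start, p.end))
    return peptides


def cysteine_peptides(peptides: Iterable[Peptide]) -> list[Peptide]:
    """Subset of peptides carrying at least one cysteine."""
    return [p for p in peptides if p.cys_positions]


def peptide_monoisotopic_mass(
    peptide: "Peptide | str",
    mods: Sequence[ModificationSpec] = (),
    mass_table: MassTable = DEFAULT_MASS_TABLE,
) -> float:
    """Neutral monoisotopic peptide mass: residue sum + water + mod deltas.

    Fixed mods add their delta once per target residue occurrence;
    variable mods are expected to be pre-resolved by the caller into the
    applied combination and are treated identically here.
    """
    seq = peptide.sequence if isinstance(peptide, Peptide) else peptide
    table = mass_table.residue_monoisotopic
    try:
        mass = sum(table[aa] for aa in seq) + mass_table.water
    except KeyError as exc:
        raise ValueError(f"unknown residue {exc.args[0]!r} in {seq!r}") from exc
    for mod in mods:
        n_targets = seq.count(mod.target_residue)
        if n_targets == 0:
            raise ValueError(
                f"modification {mod.name!r} targets {mod.target_residue!r} "
                f"absent from {seq!r}"
            )
        mass += mod.delta_mass * n_targets
    return mass
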