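"""Non-cleavable-linker crosslink search for cysteine adducts.

Candidate space: every cysteine-containing tryptic peptide pair (plus
loop-links within a single peptide carrying two or more cysteines, and
optionally single-peptide mono-adducts), with the linker chemistry
contributing a fixed delta mass to the summed peptide masses.  MS1
precursor neutral masses are matched in ppm space; matched candidates
are then annotated against the MS2 peak list with b/y fragment ladders
in which the partner peptide plus linker is treated as one fixed mass
riding on the bridged cysteine (the non-cleavable model: the linker
never fragments).

The bridge chemistry shipped by default is the dithiolethione-type
modification formed when an isothiocyanate (sulforaphane) adds to one
cysteine thiol (dithiocarbamate intermediate) and a second cysteine
attacks, expelling the amine: net +CS -2H on the two peptides.  The
mono-adduct default is the intact sulforaphane addition (+C6H11NOS2).
Both deltas are configuration, not constants baked into the search.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from covadduct.digest import (
    Peptide,
    ProteinSequence,
    cysteine_peptides,
    digest_trypsin,
    peptide_monoisotopic_mass,
)
from covadduct.masses import (
    DEFAULT_MASS_TABLE,
    DITHIOLETHIONE_BRIDGE_MASS,
    SULFORAPHANE_MASS,
    MassTable,
    ModificationSpec,
    mass_from_mz,
    mz_from_mass,
    ppm_error,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LinkerSpec:
    """Linker chemistry: a delta mass added to the summed peptide masses.

    ``kind='bridge'`` joins two cysteines (on one peptide: loop-link;
    on two: crosslink).  ``kind='mono_adduct'`` modifies exactly one
    cysteine.
    """

    name: str
    delta_mass: float
    kind: str
    target_residue: str = "C"

    def __post_init__(self) -> None:
        if not math.isfinite(self.delta_mass):
            raise ValueError("delta_mass must be finite")
        if self.kind not in ("bridge", "mono_adduct"):
            raise ValueError(f"kind must be 'bridge' or 'mono_adduct', got {self.kind!r}")


DITHIOLETHIONE_LINKER = LinkerSpec(
    name="dithiolethione", delta_mass=DITHIOLETHIONE_BRIDGE_MASS, kind="bridge"
)
SULFORAPHANE_MONO_LINKER = LinkerSpec(
    name="sulforaphane_mono", delta_mass=SULFORAPHANE_MASS, kind="mono_adduct"
)


@dataclass(frozen=True)
class CrosslinkCandidate:
    """Two linked peptides (or one loop-linked/mono-modified peptide)."""

    peptide_a: Peptide
    peptide_b: Peptide | None
    bridged_cys: tuple[int, ...]
    linker: LinkerSpec
    neutral_mass: float

    @property
    def is_loop(self) -> bool:
        return self.peptide_b is None and len(self.bridged_cys) == 2

    def label(self) -> str:
        b = self.peptide_b.sequence if self.peptide_b is not None else "-"
        cys = "/".join(str(c) for c in self.bridged_cys)
        return f"{self.peptide_a.sequence}+{b}@{cys}"


@dataclass(frozen=True)
class SpectrumRecord:
    """One centroided MS2 spectrum with its precursor."""

    scan_id: str
    precursor_mz: float
    charge: int | None
    peaks: tuple[tuple[float, float], ...] = field(default=())

    def __post_init__(self) -> None:
        mzs = [mz for mz, _ in self.peaks]
        if any(b < a for a, b in zip(mzs, mzs[1:])):
            raise ValueError(f"scan {self.scan_id}: peaks not sorted by m/z")
        if any(i < 0 for _, i in self.peaks):
            raise ValueError(f"scan {self.scan_id}: negative intensity")


@dataclass(frozen=True)
class MatchResult:
    candidate: CrosslinkCandidate
    scan_id: str
    observed_neutral_mass: float
    ppm_error: float
    matched_fragments: int = 0
    theoretical_fragments: int = 0

    @property
    def score(self) -> float:
        if self.theoretical_fragments == 0:
            return 0.0
        return self.matched_fragments / self.theoretical_fragments


def _mass_with_fixed_mods(
    peptide: Peptide,
    fixed_mods: Sequence[ModificationSpec],
    n_blocked_cys: int,
    mass_table: MassTable,
) -> float:
    """Peptide mass with fixed mods applied; bridged Cys never carry a
    Cys-targeted fixed mod (an alkylated cysteine cannot be bridged)."""
    mass = peptide_monoisotopic_mass(peptide, mass_table=mass_table)
    for mod in fixed_mods:
        n = peptide.sequence.count(mod.target_residue)
        if mod.target_residue == "C":
            n -= n_blocked_cys
        mass += mod.delta_mass * max(n, 0)
    return mass


def enumerate_candidates(
    cys_peps: Sequence[Peptide],
    linker: LinkerSpec,
    fixed_mods: Sequence[ModificationSpec] = (),
    mass_table: MassTable = DEFAULT_MASS_TABLE,
) -> list[CrosslinkCandidate]:
    """All linker placements over cysteine-containing peptides.

    bridge kind: every unordered peptide pair (i <= j, so homodimeric
    pairs of one peptide with a second copy of itself are included)
    with every Cys-by-Cys placement, plus loop-links for peptides with
    two or more cysteines.  mono_adduct kind: every peptide-by-Cys
    placement.  Cys-targeted fixed mods are applied to non-bridged
    cysteines only.  Ordering is deterministic: by peptide coordinates
    then bridged positions.
    """
    peps = sorted(cys_peps, key=lambda p: (p.parent_id, p.start, p.end))
    out: list[CrosslinkCandidate] = []
    if linker.kind == "mono_adduct":
        for pep in peps:
            for cys in pep.cys_positions:
                mass = _mass_with_fixed_mods(pep, fixed_mods, 1, mass_table)
                out.append(
                    CrosslinkCandidate(
                        peptide_a=pep,
                        peptide_b=None,
                        bridged_cys=(cys,),
                        linker=linker,
                        neutral_mass=mass + linker.delta_mass,
                    )
                )
        return out

    if not peps:
        logger.warning("bridge linker %s: no cysteine peptides, empty candidate list",
                       linker.name)
        return []

    # Loop-links: both bridged residues within one peptide.
    for pep in peps:
        if len(pep.cys_positions) >= 2:
            for ca, cb in itertools.combinations(pep.cys_positions, 2):
                m = _mass_with_fixed_mods(pep, fixed_mods, 2, mass_table)
                out.append(
                    CrosslinkCandidate(
                        peptide_a=pep,
                        peptide_b=None,
                        bridged_cys=(ca, cb),
                        linker=linker,
                        neutral_mass=m + linker.delta_mass,
                    )
                )

    # Pairs, i <= j.
    for i in range(len(peps)):
        for j in range(i, len(peps)):
            pa, pb = peps[i], peps[j]
            mass_a = _mass_with_fixed_mods(pa, fixed_mods, 1, mass_table)
            mass_b = _mass_with_fixed_mods(pb, fixed_mods, 1, mass_table)
            for ca in pa.cys_positions:
                for cb in pb.cys_positions:
                    if i == j and cb < ca:
                        continue  # unordered placement within a homodimer
                    out.append(
                        CrosslinkCandidate(
                            peptide_a=pa,
                            peptide_b=pb,
                            bridged_cys=(ca, cb),
                            linker=linker,
                            neutral_mass=mass_a + mass_b + linker.delta_mass,
                        )
                    )
    return out


def match_precursors(
    spectra: Iterable[SpectrumRecord],
    candidates: Sequence[CrosslinkCandidate],
    ppm_tol: float = 10.0,
    mass_table: MassTable = DEFAULT_MASS_TABLE,
) -> list[MatchResult]:
    """MS1 precursor matching in ppm space, sorted by |ppm|.

    Observed neutral mass = charge * (precursor m/z - proton).  Spectra
    without a charge are skipped and logged.
    """
    if not candidates:
        raise ValueError("candidate list is empty")
    theo = np.array([c.neutral_mass for c in candidates])
    order = np.argsort(theo)
    theo_sorted = theo[order]
    results: list[MatchResult] = []
    for spec in spectra:
        if spec.charge is None:
            logger.warning("scan %s: missing precursor charge, skipped", spec.scan_id)
            continue
        observed = mass_from_mz(spec.precursor_mz, spec.charge, mass_table.proton)
        # slightly widened prefilter window; the exact ppm test below decides
        tol_da = abs(observed) * ppm_tol * 1e-6 * (1 + 2 * ppm_tol * 1e-6)
        lo = np.searchsorted(theo_sorted, observed - tol_da, side="left")
        hi = np.searchsorted(theo_sorted, observed + tol_da, side="right")
        for idx in order[lo:hi]:
            cand = candidates[idx]
            ppm = ppm_error(observed, cand.neutral_mass)
            if abs(ppm) <= ppm_tol:
                results.append(
                    MatchResult(
                        candidate=cand,
                        scan_id=spec.scan_id,
                        observed_neutral_mass=observed,
                        ppm_error=ppm,
                    )
                )
    results.sort(key=lambda r: (abs(r.ppm_error), r.scan_id, r.candidate.label()))
    return results


def _by_ladder(
    sequence: str,
    fixed_deltas: dict[int, float],
    mass_table: MassTable = DEFAULT_MASS_TABLE,
) -> list[tuple[str, float]]:
    """Singly-protonated-frame neutral fragment masses of the b/y series.

    ``fixed_deltas`` maps 0-based residue index -> extra mass riding on
    that residue (bridged partner + linker).  Returns (ion_label,
    neutral fragment mass) for b1..b(n-1), y1..y(n-1).
    """
    table = mass_table.residue_monoisotopic
    masses = [table[aa] for aa in sequence]
    for idx, delta in fixed_deltas.items():
        masses[idx] += delta
    n = len(masses)
    prefix = np.cumsum(masses)
    out: list[tuple[str, float]] = []
    for i in range(1, n):
        out.append((f"b{i}", float(prefix[i - 1])))
    total = float(prefix[-1])
    for i in range(1, n):
        out.append((f"y{i}", total - float(prefix[n - i - 1]) + mass_table.water))
    return out


def theoretical_fragments(
    candidate: CrosslinkCandidate,
    charges: Sequence[int] = (1, 2),
    mass_table: MassTable = DEFAULT_MASS_TABLE,
) -> list[tuple[str, int, float]]:
    """Theoretical (label, charge, m/z) fragments under the non-cleavable model.

    For a peptide pair each peptide fragments on its own backbone while
    the partner peptide plus linker rides as a fixed mass on the bridged
    cysteine.  For a loop-link only fragments spanning neither or both
    bridged residues are emitted (cleavage inside the loop would open
    the intact linker, which the non-cleavable model forbids).  For a
    mono-adduct the delta rides on the modified cysteine.
    """
    frags: list[tuple[str, int, float]] = []

    def add(prefix: str, ladder: list[tuple[str, float]]) -> None:
        for label, neutral in ladder:
            for z in charges:
                frags.append((f"{prefix}{label}", z, mz_from_mass(neutral, z, mass_table.proton)))

    pa = candidate.peptide_a
    if candidate.peptide_b is not None:
        pb = candidate.peptide_b
        ca, cb = candidate.bridged_cys
        mass_b = candidate.neutral_mass - peptide_monoisotopic_mass(pa, mass_table=mass_table)
        mass_a = candidate.neutral_mass - peptide_monoisotopic_mass(pb, mass_table=mass_table)
        add("A.", _by_ladder(pa.sequence, {ca - pa.start: mass_b}, mass_table))
        add("B.", _by_ladder(pb.sequence, {cb - pb.start: mass_a}, mass_table))
    elif candidate.is_loop:
        ca, cb = candidate.bridged_cys
        ia, ib = ca - pa.start, cb - pa.start
        ladder = _by_ladder(pa.sequence, {ia: candidate.linker.delta_mass}, mass_table)
        n = len(pa.sequence)
        kept: list[tuple[str, float]] = []
        for label, neutral in ladder:
            k = int(label[1:])
            if label.startswith("b"):
                span = set(range(k))  # residues 0..k-1
            else:
                span = set(range(n - k, n))
            inside = (ia in span) + (ib in span)
            if inside != 1:  # spanning neither or both bridged residues
                kept.append((label, neutral))
        add("A.", kept)
    else:  # mono-adduct
        (ca,) = candidate.bridged_cys
        delta = candidate.neutral_mass - peptide_monoisotopic_mass(pa, mass_table=mass_table)
        add("A.", _by_ladder(pa.sequence, {ca - pa.start: delta}, mass_table))
    return frags


def annotate_fragments(
    spectrum: SpectrumRecord,
    candidate: CrosslinkCandidate,
    frag_ppm_tol: float = 20.0,
    charges: Sequence[int] = (1, 2),
    mass_table: MassTable = DEFAULT_MASS_TABLE,
) -> MatchResult:
    """Count theoretical b/y fragments present in the peak list.

    Score = matched/theoretical fragment fraction (simple coverage
    score; no intensity weighting).
    """
    theo = theoretical_fragments(candidate, charges, mass_table)
    peak_mzs = np.array([mz for mz, _ in spectrum.peaks])
    matched = 0
    if peak_mzs.size:
        for _, _, mz in theo:
            tol = mz * frag_ppm_tol * 1e-6
            lo = np.searchsorted(peak_mzs, mz - tol, side="left")
            hi = np.searchsorted(peak_mzs, mz + tol, side="right")
            if hi > lo:
                matched += 1
    observed = (
        mass_from_mz(spectrum.precursor_mz, spectrum.charge, mass_table.proton)
        if spectrum.charge is not None
        else float("nan")
    )
    return MatchResult(
        candidate=candidate,
        scan_id=spectrum.scan_id,
        observed_neutral_mass=observed,
        ppm_error=ppm_error(observed, candidate.neutral_mass)
        if spectrum.charge is not None
        else float("nan"),
        matched_fragments=matched,
        theoretical_fragments=len(theo),
    )


REPORT_COLUMNS = [
    "scan_id",
    "peptide_a",
    "peptide_b",
    "cys_a",
    "cys_b",
    "linker",
    "theoretical_mass",
    "observed_mass",
    "ppm",
    "matched",
    "theoretical",
    "score",
]


def search(
    proteins: Sequence[ProteinSequence],
    spectra: Sequence[SpectrumRecord],
    linker: LinkerSpec = DITHIOLETHIONE_LINKER,
    mono_linker: LinkerSpec | None = None,
    fixed_mods: Sequence[ModificationSpec] = (),
    ms1_ppm: float = 10.0,
    ms2_ppm: float = 20.0,
    max_missed: int = 3,
    min_len: int = 4,
    max_len: int = 60,
    mass_table: MassTable = DEFAULT_MASS_TABLE,
) -> pd.DataFrame:
    """End-to-end search: digest -> candidates -> MS1 match -> MS2 annotate.

    Intra-protein candidates only (one candidate space per protein, the
    recombinant single-protein design).  Returns a ranked report: score
    descending, then |ppm| ascending.
    """
    candidates: list[CrosslinkCandidate] = []
    for protein in proteins:
        peps = cysteine_peptides(
            digest_trypsin(protein, max_missed=max_missed, min_len=min_len, max_len=max_len)
        )
        candidates.extend(enumerate_candidates(peps, linker, fixed_mods, mass_table))
        if mono_linker is not None:
            candidates.extend(
                enumerate_candidates(peps, mono_linker, fixed_mods, mass_table)
            )
    rows: list[dict] = []
    if candidates:
        ms1_hits = match_precursors(spectra, candidates, ms1_ppm, mass_table)
        spec_by_id = {s.scan_id: s for s in spectra}
        for hit in ms1_hits:
            ann = annotate_fragments(
                spec_by_id[hit.scan_id], hit.candidate, ms2_ppm, mass_table=mass_table
            )
            cand = hit.candidate
            cys = cand.bridged_cys
            rows.append(
                {
                    "scan_id": hit.scan_id,
                    "peptide_a": cand.peptide_a.sequence,
                    "peptide_b": cand.peptide_b.sequence if cand.peptide_b else "",
                    "cys_a": cys[0],
                    "cys_b": cys[1] if len(cys) > 1 else -1,
                    "linker": cand.linker.name,
                    "theoretical_mass": cand.neutral_mass,
                    "observed_mass": hit.observed_neutral_mass,
                    "ppm": hit.ppm_error,
                    "matched": ann.matched_fragments,
                    "theoretical": ann.theoretical_fragments,
                    "score": ann.score,
                }
            )
    report = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    if not report.empty:
        report["abs_ppm"] = report["ppm"].abs()
        report = (
            report.sort_values(
                ["score", "abs_ppm", "scan_id", "peptide_a", "peptide_b", "cys_a", "cys_b"],
                ascending=[False, True, True, True, True, True, True],
            )
            .drop(columns="abs_ppm")
            .reset_index(drop=True)
        )
    return report
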