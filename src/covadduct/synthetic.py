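"""Seeded synthetic-data generators with planted ground truth.

Every input the pipeline consumes can be generated here at desk scale:
4-vs-4 replicate PSM count tables with a minority of truly enriched
proteins, MGF spectra containing planted crosslinked-peptide precursors
and b/y fragments plus noise peaks, random protein FASTA, and noisy
one-phase-decay dose-response curves.  A single integer seed drives one
named pseudo-random stream per generator, so changing, say, spectra
noise never perturbs the count simulation.  Fixed seed implies
byte-identical output files.
"""

from __future__ import annotations


from dataclasses import dataclass

import numpy as np
import pandas as pd

from covadduct.digest import (
    ProteinSequence,
    cysteine_peptides,
    digest_trypsin,
)
from covadduct.masses import DEFAULT_MASS_TABLE, mz_from_mass
from covadduct.xlsearch import (
    DITHIOLETHIONE_LINKER,
    CrosslinkCandidate,
    LinkerSpec,
    SpectrumRecord,
    enumerate_candidates,
    theoretical_fragments,
)

# Fixed per-generator stream indices: the same seed gives independent,
# reproducible streams for each generator.
_STREAMS = {"psm": 1, "fasta": 2, "spectra": 3, "decay": 4, "standin": 5}


def stream_rng(seed: int, name: str) -> np.random.Generator:
    """Named, seed-derived pseudo-random stream."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), _STREAMS[name]]))


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the synthetic study, mirroring the 4-vs-4 design."""

    seed: int = 0
    # PSM table
    n_proteins: int = 100
    n_enriched: int = 10
    count_model: str = "poisson"
    baseline_mean: float = 2.0
    fold_change: float = 8.0
    n_replicates_per_group: int = 4
    nb_size: float = 10.0
    filter_fail_fraction: float = 0.05
    # spectra
    n_planted_crosslinks: int = 10
    noise_peaks_per_spectrum: int = 100
    ppm_jitter_sd: float = 5.0
    fragment_dropout_fraction: float = 0.2
    # dose-response
    decay_y0: float = 100.0
    decay_plateau: float = 10.0
    decay_k: float = 2.5
    decay_noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.n_enriched > self.n_proteins:
            raise ValueError("n_enriched must not exceed n_proteins")
        if self.baseline_mean <= 0 or self.fold_change <= 0:
            raise ValueError("baseline_mean and fold_change must be positive")
        if self.count_model not in ("poisson", "negative_binomial"):
            raise ValueError("count_model must be 'poisson' or 'negative_binomial'")
        if self.n_replicates_per_group < 2:
            raise ValueError("need at least two replicates per group")
        if self.decay_k < 0:
            raise ValueError("decay rate constant must be >= 0")


def _draw_counts(rng: np.random.Generator, mean: float, size: int,
                 model: str, nb_size: float) -> np.ndarray:
    if model == "poisson":
        return rng.poisson(mean, size=size)
    p = nb_size / (nb_size + mean)
    return rng.negative_binomial(nb_size, p, size=size)


def gen_psm_table(config: SimConfig) -> tuple[pd.DataFrame, dict]:
    """Simulate a PSM identification table with planted enriched proteins.

    The first ``n_enriched`` proteins draw treated counts at
    ``baseline_mean * fold_change``; all other draws use
    ``baseline_mean``.  Counts are expanded to one row per PSM.  A
    ``filter_fail_fraction`` of rows draw a peptide probability below
    the 90% acceptance rule (the rest pass); protein probabilities all
    pass the 99.9% rule so planted counts survive filtering intact on
    average.
    """
    rng = stream_rng(config.seed, "psm")
    n_rep = config.n_replicates_per_group
    samples_c = [f"ctrl_{i + 1}" for i in range(n_rep)]
    samples_t = [f"trt_{i + 1}" for i in range(n_rep)]
    enriched_ids = [f"P{i:04d}" for i in range(config.n_enriched)]

    rows: list[dict] = []
    for i in range(config.n_proteins):
        pid = f"P{i:04d}"
        enriched = i < config.n_enriched
        mean_t = config.baseline_mean * (config.fold_change if enriched else 1.0)
        counts_c = _draw_counts(rng, config.baseline_mean, n_rep,
                                config.count_model, config.nb_size)
        counts_t = _draw_counts(rng, mean_t, n_rep,
                                config.count_model, config.nb_size)
        prot_prob = float(rng.uniform(0.9992, 1.0))
        for sample, group, n in (
            [(s, "control", c) for s, c in zip(samples_c, counts_c)]
            + [(s, "treated", c) for s, c in zip(samples_t, counts_t)]
        ):
            for _ in range(int(n)):
                fails = rng.random() < config.filter_fail_fraction
                pep_prob = (
                    float(rng.uniform(0.50, 0.90))
                    if fails
                    else float(rng.uniform(0.905, 1.0))
                )
                rows.append(
                    {
                        "protein_id": pid,
                        "sample_id": sample,
                        "group": group,
                        "peptide_probability": round(pep_prob, 6),
                        "protein_probability": round(prot_prob, 6),
                    }
                )
    table = pd.DataFrame(
        rows,
        columns=[
            "protein_id",
            "sample_id",
            "group",
            "peptide_probability",
            "protein_probability",
        ],
    )
    truth = {
        "enriched_protein_ids": enriched_ids,
        "samples_control": samples_c,
        "samples_treated": samples_t,
        "baseline_mean": config.baseline_mean,
        "fold_change": config.fold_change,
    }
    return table, truth


_NON_CYS = "".join(sorted(set("ACDEFGHIKLMNPQRSTVWY") - {"C"}))


def gen_protein_fasta(
    n: int,
    length: int,
    cys_fraction: float,
    seed: int,
    include: list[ProteinSequence] | None = None,
) -> list[ProteinSequence]:
    """Random proteins with the stated expected cysteine fraction.

    Each position is 'C' with probability ``cys_fraction``, otherwise
    uniform over the 19 other canonical residues.  ``include`` appends
    user-supplied records (e.g. a real target protein) unchanged.
    """
    if length < 10:
        raise ValueError("length must be >= 10")
    if not 0 <= cys_fraction <= 1:
        raise ValueError("cys_fraction must lie in [0, 1]")
    rng = stream_rng(seed, "fasta")
    proteins: list[ProteinSequence] = []
    others = np.array(list(_NON_CYS))
    for i in range(n):
        is_cys = rng.random(length) < cys_fraction
        residues = others[rng.integers(0, len(others), size=length)]
        residues[is_cys] = "C"
        proteins.append(ProteinSequence(id=f"SYN{i:04d}", residues="".join(residues)))
    if include:
        proteins.extend(include)
    return proteins


def shp2_like_sequence() -> ProteinSequence:
    """SYNTHETIC stand-in for the human Shp2 phosphatase sequence.

    This is NOT the real protein: it is a deterministically generated
    593-residue surrogate whose only designed features are cysteines at
    positions 333, 367 and 459 (the residue numbering of the
    dithiolethione bridge site and the catalytic cysteine) embedded in
    tryptic contexts, so that digestion at <= 1 missed cleavage yields
    peptides containing Cys333 and Cys367 and the bridge candidate
    (333, 367) exists.  Substitute the real sequence (UniProt Q06124)
    wherever biological conclusions are needed.
    """
    rng = stream_rng(20240613, "standin")
    length = 593
    others = np.array(sorted(set(_NON_CYS) - set("KRP")))
    # Base: no C/K/R/P, then sprinkle K/R at ~10% to create tryptic sites.
    residues = others[rng.integers(0, len(others), size=length)]
    kr_mask = rng.random(length) < 0.10
    kr_choice = np.where(rng.random(length) < 0.5, "K", "R")
    residues[kr_mask] = kr_choice[kr_mask]
    residues[0] = "M"

    def carve(site_before: int, cys: int, site_at: int) -> None:
        # 1-based: cleavage site residue before the peptide, the Cys, and
        # the peptide's own C-terminal K/R.  Interior is kept K/R-free.
        residues[site_before - 1] = "R"
        for pos in range(site_before + 1, site_at):
            if residues[pos - 1] in "KR":
                residues[pos - 1] = "A"
        residues[cys - 1] = "C"
        residues[site_at - 1] = "K"
        if residues[site_at] == "P":  # would suppress the cleavage
            residues[site_at] = "A"

    carve(329, 333, 340)   # peptide 330..340 carries Cys333
    carve(360, 367, 372)   # peptide 361..372 carries Cys367
    carve(454, 459, 464)   # peptide 455..464 carries the catalytic Cys459
    seq = "".join(residues)
    assert seq[332] == "C" and seq[366] == "C" and seq[458] == "C"
    return ProteinSequence(id="SHP2_SYNTHETIC_STANDIN", residues=seq)


def gen_crosslink_spectra(
    proteins: list[ProteinSequence],
    linker: LinkerSpec = DITHIOLETHIONE_LINKER,
    config: SimConfig = SimConfig(),
    max_missed: int = 1,
    min_len: int = 4,
    max_len: int = 40,
) -> tuple[list[SpectrumRecord], dict]:
    """Plant crosslink precursors/fragments among noise peaks.

    For each planted candidate one spectrum is emitted: precursor m/z at
    the theoretical value plus Gaussian ppm jitter, charge drawn from
    {2, 3, 4}, the non-cleavable b/y ladder thinned by the dropout
    fraction, and uniform-m/z noise peaks.  The ground-truth dict lists
    every planted candidate with its scan id.
    """
    rng = stream_rng(config.seed, "spectra")
    candidates: list[CrosslinkCandidate] = []
    for protein in proteins:
        peps = cysteine_peptides(
            digest_trypsin(protein, max_missed=max_missed, min_len=min_len, max_len=max_len)
        )
        candidates.extend(enumerate_candidates(peps, linker))
    pair_candidates = [c for c in candidates if c.peptide_b is not None]
    if not pair_candidates:
        raise ValueError("no crosslink candidates to plant in the supplied proteins")
    n_plant = min(config.n_planted_crosslinks, len(pair_candidates))
    chosen_idx = rng.choice(len(pair_candidates), size=n_plant, replace=False)

    spectra: list[SpectrumRecord] = []
    truth_rows: list[dict] = []
    for scan_no, idx in enumerate(sorted(chosen_idx), start=1):
        cand = pair_candidates[idx]
        charge = int(rng.integers(2, 5))
        jitter_ppm = float(rng.normal(0.0, config.ppm_jitter_sd))
        obs_mz = mz_from_mass(
            cand.neutral_mass * (1.0 + jitter_ppm * 1e-6),
            charge,
            DEFAULT_MASS_TABLE.proton,
        )

        frags = theoretical_fragments(cand)
        keep = rng.random(len(frags)) >= config.fragment_dropout_fraction
        peak_list = [
            (mz, float(rng.uniform(1e3, 1e5)))
            for (_, _, mz), k in zip(frags, keep)
            if k
        ]
        noise_mz = rng.uniform(150.0, 1800.0, size=config.noise_peaks_per_spectrum)
        peak_list.extend(
            (float(mz), float(inten))
            for mz, inten in zip(noise_mz, rng.uniform(1e2, 1e4,
                                                       size=config.noise_peaks_per_spectrum))
        )
        peak_list.sort(key=lambda p: p[0])
        scan_id = f"scan_{scan_no:04d}"
        spectra.append(
            SpectrumRecord(
                scan_id=scan_id,
                precursor_mz=obs_mz,
                charge=charge,
                peaks=tuple(peak_list),
            )
        )
        truth_rows.append(
            {
                "scan_id": scan_id,
                "peptide_a": cand.peptide_a.sequence,
                "peptide_b": cand.peptide_b.sequence,
                "cys_a": cand.bridged_cys[0],
                "cys_b": cand.bridged_cys[1],
                "neutral_mass": cand.neutral_mass,
                "charge": charge,
                "jitter_ppm": jitter_ppm,
            }
        )
    truth = {"linker": linker.name, "planted": truth_rows}
    return spectra, truth


def gen_dose_response(config: SimConfig, n_doses: int = 9,
                      dose_min: float = 0.007, dose_max: float = 1.75) -> pd.DataFrame:
    """Noisy one-phase-decay dose series: zero dose plus log-spaced doses.

    The default dose range mirrors a sub-micromolar to low-micromolar
    inhibitor titration.
    """
    rng = stream_rng(config.seed, "decay")
    doses = np.concatenate([[0.0], np.geomspace(dose_min, dose_max, n_doses - 1)])
    y = config.decay_plateau + (config.decay_y0 - config.decay_plateau) * np.exp(
        -config.decay_k * doses
    )
    y = y + rng.normal(0.0, config.decay_noise_sd, size=doses.size)
    return pd.DataFrame({"concentration_uM": doses, "value": y})
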