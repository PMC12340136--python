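"""Crosslink candidate enumeration, ppm matching and fragment ladders."""

import itertools
import math

import numpy as np
import pytest

from covadduct.digest import (
    Peptide,
    ProteinSequence,
    cysteine_peptides,
    digest_trypsin,
    peptide_monoisotopic_mass,
)
from covadduct.masses import (
    DEFAULT_MASS_TABLE,
    MONOISOTOPIC_RESIDUE_MASSES,
    PROTON_MASS,
    WATER_MASS,
    MALEIMIDE_MOD,
    mz_from_mass,
)
from covadduct.xlsearch import (
    DITHIOLETHIONE_LINKER,
    SULFORAPHANE_MONO_LINKER,
    CrosslinkCandidate,
    LinkerSpec,
    SpectrumRecord,
    annotate_fragments,
    enumerate_candidates,
    match_precursors,
    search,
    theoretical_fragments,
)

LINKER = LinkerSpec(name="test", delta_mass=100.0, kind="bridge")


def make_peptide(seq, start=1, pid="p"):
    cys = tuple(start + i for i, aa in enumerate(seq) if aa == "C")
    return Peptide(pid, start, start + len(seq) - 1, seq, 0, cys)


# ------------------------------------------------------------ candidates

def test_no_cysteines_no_candidates():
    protein = ProteinSequence("p", "MAGKSTR")
    peps = cysteine_peptides(digest_trypsin(protein, min_len=1))
    assert enumerate_candidates(peps, LINKER) == []


def test_pair_mass_additivity():
    a, b = make_peptide("ACK"), make_peptide("GCR", start=10)
    cands = enumerate_candidates([a, b], LINKER)
    pairs = [c for c in cands if c.peptide_b is not None and c.peptide_a != c.peptide_b]
    assert len(pairs) == 1
    c = pairs[0]
    expected = (
        peptide_monoisotopic_mass(a) + peptide_monoisotopic_mass(b) + LINKER.delta_mass
    )
    assert c.neutral_mass == pytest.approx(expected, abs=1e-12)


def test_hand_arithmetic_pair_mass():
    d = 37.5
    linker = LinkerSpec(name="d", delta_mass=d, kind="bridge")
    a, b = make_peptide("ACK"), make_peptide("GCR", start=10)
    ma, mb = peptide_monoisotopic_mass(a), peptide_monoisotopic_mass(b)
    cands = [
        c
        for c in enumerate_candidates([a, b], linker)
        if c.peptide_b is not None and c.peptide_a != c.peptide_b
    ]
    assert cands[0].neutral_mass == pytest.approx(ma + mb + d, abs=1e-9)


@pytest.mark.parametrize("n", [1, 2, 3, 5])
def test_candidate_count_single_cys_peptides(n, rng):
    """n single-Cys peptides yield n(n+1)/2 pair candidates (self-pairs included)."""
    peps = [make_peptide("ACK", start=1 + 10 * i, pid="p") for i in range(n)]
    cands = enumerate_candidates(peps, LINKER)
    assert len(cands) == n * (n + 1) // 2
    # exhaustive oracle over unordered index pairs
    expected_pairs = {
        tuple(sorted((peps[i].start + 1, peps[j].start + 1)))
        for i, j in itertools.combinations_with_replacement(range(n), 2)
    }
    assert {tuple(sorted(c.bridged_cys)) for c in cands} == expected_pairs


def test_loop_link_enumerated_for_two_cys_peptide():
    pep = make_peptide("ACGCK")
    cands = enumerate_candidates([pep], LINKER)
    loops = [c for c in cands if c.is_loop]
    assert len(loops) == 1
    assert loops[0].bridged_cys == (2, 4)
    assert loops[0].neutral_mass == pytest.approx(
        peptide_monoisotopic_mass(pep) + LINKER.delta_mass, abs=1e-12
    )


def test_mono_adduct_per_cys_placement():
    mono = LinkerSpec(name="m", delta_mass=177.0, kind="mono_adduct")
    pep = make_peptide("ACGCK")
    cands = enumerate_candidates([pep], mono)
    assert [c.bridged_cys for c in cands] == [(2,), (4,)]
    for c in cands:
        assert c.neutral_mass == pytest.approx(
            peptide_monoisotopic_mass(pep) + 177.0, abs=1e-12
        )


def test_fixed_mods_skip_bridged_cysteines():
    """Maleimide blocks only the non-bridged cysteine of a two-Cys peptide pair."""
    a, b = make_peptide("ACGCK"), make_peptide("GCR", start=20)
    cands = [
        c
        for c in enumerate_candidates([a, b], LINKER, fixed_mods=[MALEIMIDE_MOD])
        if c.peptide_b is not None and c.peptide_a.sequence == "ACGCK"
        and c.peptide_b.sequence == "GCR"
    ]
    for c in cands:
        expected = (
            peptide_monoisotopic_mass(a)
            + MALEIMIDE_MOD.delta_mass  # one unbridged Cys on peptide a
            + peptide_monoisotopic_mass(b)
            + LINKER.delta_mass
        )
        assert c.neutral_mass == pytest.approx(expected, abs=1e-9)


# ------------------------------------------------------------ MS1 match

def spectrum_at(cand, charge, ppm_offset=0.0, scan="s1", peaks=()):
    # offset applied on the neutral-mass scale, where ppm error is defined
    mz = mz_from_mass(cand.neutral_mass * (1 + ppm_offset * 1e-6), charge)
    return SpectrumRecord(scan, mz, charge, tuple(peaks))


@pytest.fixture()
def simple_candidates():
    a, b = make_peptide("ACK"), make_peptide("GCR", start=10)
    return enumerate_candidates([a, b], LINKER)


def test_exact_precursor_matches_with_zero_ppm(simple_candidates):
    cand = simple_candidates[0]
    hits = match_precursors([spectrum_at(cand, 3)], simple_candidates)
    assert hits and hits[0].ppm_error == pytest.approx(0.0, abs=1e-9)


def test_offset_beyond_tolerance_misses(simple_candidates):
    cand = simple_candidates[0]
    spec = spectrum_at(cand, 3, ppm_offset=20.0)
    hits = match_precursors([spec], simple_candidates, ppm_tol=10.0)
    assert [h for h in hits if h.candidate is cand] == []


def test_tolerance_boundary_tight(simple_candidates):
    cand = simple_candidates[0]
    for sign in (+1, -1):
        at_tol = spectrum_at(cand, 2, ppm_offset=sign * 10.0 * (1 - 1e-9))
        hits = match_precursors([at_tol], simple_candidates, ppm_tol=10.0)
        assert any(h.candidate is cand for h in hits)
        beyond = spectrum_at(cand, 2, ppm_offset=sign * 10.5)
        hits = match_precursors([beyond], simple_candidates, ppm_tol=10.0)
        assert not any(h.candidate is cand for h in hits)


def test_missing_charge_skipped(simple_candidates, caplog):
    spec = SpectrumRecord("s1", 500.0, None, ())
    assert match_precursors([spec], simple_candidates) == []


def test_planted_precursors_match_brute_force_scan(rng):
    """Seeded noise + plants: recovered set equals an all-pairs ppm scan."""
    peps = [make_peptide("ACK", start=1 + 7 * i) for i in range(10)]
    cands = enumerate_candidates(peps, LINKER)
    spectra = []
    for i in range(50):
        cand = cands[int(rng.integers(len(cands)))]
        z = int(rng.integers(2, 5))
        spectra.append(
            spectrum_at(cand, z, ppm_offset=float(rng.normal(0, 3)), scan=f"plant{i}")
        )
    for i in range(500):
        z = int(rng.integers(2, 5))
        spectra.append(
            SpectrumRecord(f"noise{i}", float(rng.uniform(200, 2000)), z, ())
        )
    hits = match_precursors(spectra, cands, ppm_tol=10.0)
    got = {(h.scan_id, id(h.candidate)) for h in hits}
    expected = set()
    for s in spectra:
        observed = s.charge * s.precursor_mz - s.charge * PROTON_MASS
        for c in cands:
            if abs(1e6 * (observed - c.neutral_mass) / c.neutral_mass) <= 10.0:
                expected.add((s.scan_id, id(c)))
    assert got == expected


# -------------------------------------------------------------- MS2

def ladder_oracle(seq, deltas):
    """Independent prefix/suffix summation for b/y neutral masses."""
    masses = [MONOISOTOPIC_RESIDUE_MASSES[aa] for aa in seq]
    for i, d in deltas.items():
        masses[i] += d
    out = {}
    for k in range(1, len(seq)):
        out[f"b{k}"] = sum(masses[:k])
        out[f"y{k}"] = sum(masses[-k:]) + WATER_MASS
    return out


def test_fragment_ladder_matches_prefix_suffix_oracle():
    a, b = make_peptide("ACK"), make_peptide("GCR", start=10)
    cand = [
        c
        for c in enumerate_candidates([a, b], LINKER)
        if c.peptide_b is not None and c.peptide_a != c.peptide_b
    ][0]
    frags = theoretical_fragments(cand, charges=(1,))
    mass_b = peptide_monoisotopic_mass(b) + LINKER.delta_mass
    mass_a = peptide_monoisotopic_mass(a) + LINKER.delta_mass
    oracle_a = ladder_oracle("ACK", {1: mass_b})
    oracle_b = ladder_oracle("GCR", {1: mass_a})
    got = {label: mz for label, z, mz in frags if z == 1}
    for k, neutral in oracle_a.items():
        assert got[f"A.{k}"] == pytest.approx(neutral + PROTON_MASS, abs=1e-6)
    for k, neutral in oracle_b.items():
        assert got[f"B.{k}"] == pytest.approx(neutral + PROTON_MASS, abs=1e-6)


def test_loop_link_fragments_span_neither_or_both():
    pep = make_peptide("ACGCK")
    cand = [c for c in enumerate_candidates([pep], LINKER) if c.is_loop][0]
    labels = {label for label, _, _ in theoretical_fragments(cand, charges=(1,))}
    # Cys at 0-based 1 and 3: b1 spans neither bridged residue, b4 both;
    # b2/b3 open the loop and must be absent (same for the y series).
    assert "A.b1" in labels and "A.b4" in labels
    assert "A.b2" not in labels and "A.b3" not in labels
    assert "A.y1" in labels and "A.y4" in labels
    assert "A.y2" not in labels and "A.y3" not in labels


def test_complete_ladder_scores_one(simple_candidates):
    cand = simple_candidates[0]
    frags = theoretical_fragments(cand)
    peaks = tuple(sorted((mz, 100.0) for _, _, mz in frags))
    spec = spectrum_at(cand, 3, peaks=peaks)
    res = annotate_fragments(spec, cand)
    assert res.score == 1.0
    assert res.matched_fragments == res.theoretical_fragments


def test_empty_peak_list_scores_zero(simple_candidates):
    cand = simple_candidates[0]
    res = annotate_fragments(spectrum_at(cand, 3), cand)
    assert res.matched_fragments == 0
    assert res.score == 0.0


def test_pure_noise_scores_low_over_seeds(simple_candidates):
    """Uniform-m/z noise should rarely hit the 20 ppm fragment windows."""
    cand = simple_candidates[0]
    scores = []
    for seed in range(20):
        r = np.random.default_rng(seed)
        peaks = tuple(
            sorted((float(m), 10.0) for m in r.uniform(150, 1800, size=100))
        )
        res = annotate_fragments(spectrum_at(cand, 3, peaks=peaks), cand)
        scores.append(res.score)
    assert np.mean(scores) < 0.05


# ------------------------------------------------------------- pipeline

def test_search_plants_top_ranked(shp2_standin):
    peps = cysteine_peptides(digest_trypsin(shp2_standin, max_missed=1))
    cands = enumerate_candidates(peps, DITHIOLETHIONE_LINKER)
    cand = [c for c in cands if c.peptide_b is not None][0]
    frags = theoretical_fragments(cand)
    peaks = tuple(sorted((mz, 100.0) for _, _, mz in frags))
    spec = spectrum_at(cand, 3, peaks=peaks, scan="planted")
    report = search([shp2_standin], [spec], max_missed=1)
    top = report.iloc[0]
    assert top["scan_id"] == "planted"
    assert {top["cys_a"], top["cys_b"]} == set(cand.bridged_cys)
    assert top["score"] == 1.0


def test_search_no_match_empty_report(shp2_standin):
    spec = SpectrumRecord("s1", 123.456, 2, ())
    report = search([shp2_standin], [spec], max_missed=1)
    assert report.empty


def test_standin_bridge_333_367_recovered(shp2_standin):
    """A precursor at the Cys333-Cys367 bridge mass is reported at those residues."""
    peps = cysteine_peptides(digest_trypsin(shp2_standin, max_missed=1))
    cands = enumerate_candidates(peps, DITHIOLETHIONE_LINKER)
    bridge = [
        c for c in cands if c.peptide_b is not None and set(c.bridged_cys) == {333, 367}
    ]
    assert bridge
    cand = bridge[0]
    spec = spectrum_at(cand, 3, scan="bridge")
    report = search([shp2_standin], [spec], max_missed=1)
    assert ((report["cys_a"] == 333) & (report["cys_b"] == 367)).any()
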