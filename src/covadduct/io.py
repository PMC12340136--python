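"""Shared format readers/writers and run configuration.

Contract formats are plain text: FASTA for proteins, MGF for spectra
(the "CHARGE=3+" dialect), and TSV with '.' decimal separators, UTF-8
and LF endings for every table.  Writers are deterministic so a fixed
input and config reproduce output files byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml
from pyteomics import mgf as _mgf

from covadduct.digest import ProteinSequence
from covadduct.enrichment import PSM_COLUMNS, GroupDesign
from covadduct.xlsearch import SpectrumRecord

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.10g"


# ---------------------------------------------------------------- FASTA

def read_fasta(path: str | Path) -> list[ProteinSequence]:
    """Parse a protein FASTA; ids are headers up to the first whitespace.

    Sequences are uppercased; non-canonical residues and duplicate ids
    raise with the offending record named.
    """
    path = Path(path)
    proteins: list[ProteinSequence] = []
    seen: set[str] = set()
    header: str | None = None
    chunks: list[str] = []

    def flush() -> None:
        nonlocal header, chunks
        if header is None:
            return
        pid = header.split()[0] if header.split() else ""
        if pid in seen:
            raise ValueError(f"duplicate FASTA id {pid!r}")
        seen.add(pid)
        proteins.append(ProteinSequence(id=pid, residues="".join(chunks).upper()))
        header, chunks = None, []

    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:]
            else:
                if header is None:
                    raise ValueError(f"{path}: sequence data before first header")
                chunks.append(line)
    flush()
    if not proteins:
        raise ValueError(f"{path}: no FASTA records")
    return proteins


def write_fasta(proteins: list[ProteinSequence], path: str | Path, width: int = 60) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for protein in proteins:
            fh.write(f">{protein.id}\n")
            for i in range(0, len(protein.residues), width):
                fh.write(protein.residues[i : i + width] + "\n")


# ------------------------------------------------------------------ MGF

def read_mgf(path: str | Path) -> list[SpectrumRecord]:
    """Parse an MGF file into SpectrumRecords.

    Handles the "CHARGE=3+" dialect; spectra lacking a charge are kept
    with ``charge=None`` and flagged in the log.  Unterminated BEGIN
    IONS blocks raise with the line number.
    """
    path = Path(path)
    # Structural pre-check with line numbers (the library reader reports
    # neither).
    open_line: int | None = None
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            token = line.strip().upper()
            if token == "BEGIN IONS":
                if open_line is not None:
                    raise ValueError(
                        f"{path}:{lineno}: BEGIN IONS inside unterminated block "
                        f"opened at line {open_line}"
                    )
                open_line = lineno
            elif token == "END IONS":
                if open_line is None:
                    raise ValueError(f"{path}:{lineno}: END IONS without BEGIN IONS")
                open_line = None
    if open_line is not None:
        raise ValueError(f"{path}:{open_line}: unterminated BEGIN IONS block")

    records: list[SpectrumRecord] = []
    with _mgf.MGF(str(path), convert_arrays=1) as reader:
        for i, spec in enumerate(reader):
            params = spec["params"]
            title = str(params.get("title", params.get("scans", f"index_{i}")))
            pepmass = params.get("pepmass", (None,))[0]
            if pepmass is None:
                raise ValueError(f"{path}: spectrum {title!r} lacks PEPMASS")
            charge_field = params.get("charge")
            charge = int(charge_field[0]) if charge_field else None
            if charge is None:
                logger.warning("%s: spectrum %s lacks CHARGE", path, title)
            mz = spec["m/z array"]
            inten = spec["intensity array"]
            order = mz.argsort(kind="stable")
            peaks = tuple(
                (float(m), float(v)) for m, v in zip(mz[order], inten[order])
            )
            records.append(
                SpectrumRecord(
                    scan_id=title, precursor_mz=float(pepmass), charge=charge, peaks=peaks
                )
            )
    return records


def write_mgf(spectra: list[SpectrumRecord], path: str | Path) -> None:
    """Deterministic MGF writer (fixed peak formatting, LF endings)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for spec in spectra:
            fh.write("BEGIN IONS\n")
            fh.write(f"TITLE={spec.scan_id}\n")
            fh.write(f"PEPMASS={spec.precursor_mz:.6f}\n")
            if spec.charge is not None:
                fh.write(f"CHARGE={spec.charge}+\n")
            for mz, inten in spec.peaks:
                fh.write(f"{mz:.6f} {inten:.2f}\n")
            fh.write("END IONS\n")


# ------------------------------------------------------------------ TSV

def read_psm_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", dtype={"protein_id": str, "sample_id": str})
    missing = [c for c in PSM_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: PSM table missing columns {missing}")
    return table


def write_tsv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT,
                 lineterminator="\n", encoding="utf-8")


def read_design(path: str | Path) -> GroupDesign:
    """Design TSV: columns sample_id, group (control/treated)."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample_id", "group"):
        if col not in table.columns:
            raise ValueError(f"{path}: design file missing column {col!r}")
    bad = sorted(set(table["group"]) - {"control", "treated"})
    if bad:
        raise ValueError(f"{path}: unknown group labels {bad}")
    return GroupDesign(
        sample_ids_control=tuple(table.loc[table["group"] == "control", "sample_id"]),
        sample_ids_treated=tuple(table.loc[table["group"] == "treated", "sample_id"]),
    )


def write_design(design: GroupDesign, path: str | Path) -> None:
    rows = [{"sample_id": s, "group": "control"} for s in design.sample_ids_control]
    rows += [{"sample_id": s, "group": "treated"} for s in design.sample_ids_treated]
    write_tsv(pd.DataFrame(rows), path)


def read_dose_response(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    for col in ("concentration_uM", "value"):
        if col not in table.columns:
            raise ValueError(f"{path}: dose-response table missing column {col!r}")
    return table


# --------------------------------------------------------------- config

@dataclass(frozen=True)
class RunConfig:
    """Validated analysis thresholds; defaults are the printed study rules."""

    pseudocount: float = 0.1
    x_min: float = 2.0
    y_min: float = 1.3
    peptide_prob_min: float = 0.90
    protein_prob_min: float = 0.999
    min_psms: int = 2
    ms1_ppm: float = 10.0
    ms2_ppm: float = 20.0
    max_missed: int = 3
    min_len: int = 4
    max_len: int = 60
    log_base_y: str = "log10"
    y_cap: float = 16.0
    test: str = "student"
    seed: int = 0

    def __post_init__(self) -> None:
        checks = {
            "pseudocount": self.pseudocount > 0,
            "peptide_prob_min": 0 <= self.peptide_prob_min <= 1,
            "protein_prob_min": 0 <= self.protein_prob_min <= 1,
            "min_psms": self.min_psms >= 1,
            "ms1_ppm": self.ms1_ppm > 0,
            "ms2_ppm": self.ms2_ppm > 0,
            "max_missed": self.max_missed >= 0,
            "min_len": self.min_len >= 1,
            "max_len": self.max_len >= self.min_len,
            "log_base_y": self.log_base_y in ("log10", "ln"),
            "test": self.test in ("student", "welch"),
            "y_cap": self.y_cap > 0,
        }
        bad = [name for name, ok in checks.items() if not ok]
        if bad:
            raise ValueError(
                "invalid configuration value(s) for: " + ", ".join(bad)
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(data) - known)
        if unknown:
            raise ValueError(f"{path}: unknown configuration keys {unknown}")
        return cls(**data)


def write_provenance(out_dir: str | Path, config: object, seed: int | None = None) -> Path:
    """Record config hash, seed and versions next to every run's output."""
    import covadduct

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if dataclasses.is_dataclass(config) and not isinstance(config, type):
        payload = dataclasses.asdict(config)
    else:
        payload = dict(config) if isinstance(config, dict) else {"repr": repr(config)}
    blob = json.dumps(payload, sort_keys=True, default=str)
    record = {
        "config": payload,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "seed": seed,
        "covadduct_version": covadduct.__version__,
    }
    path = out_dir / "provenance.json"
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        json.dump(record, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return path
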