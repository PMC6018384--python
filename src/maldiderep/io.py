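"""Readers and writers for spectra, sample sheets and sequence sets.

Spectra come in as mzML (open standard; first MS1 spectrum per file) or as
plain two-column mass/intensity tables, one file per technical replicate.
Masses are in Da under the +1-ion convention of linear-mode whole-cell
MALDI-TOF; no charge deconvolution is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "Spectrum",
    "SampleRecord",
    "SequenceRecord",
    "read_spectrum",
    "write_spectrum",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_fasta",
]


@dataclass
class Spectrum:
    """A measured profile: strictly increasing mass axis plus intensities."""

    sample_id: str
    masses: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.masses = np.asarray(self.masses, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.masses.ndim != 1 or self.intensities.ndim != 1:
            raise ValueError("masses and intensities must be 1-D")
        if self.masses.size != self.intensities.size:
            raise ValueError("masses and intensities differ in length")
        if self.masses.size < 2:
            raise ValueError("a spectrum needs at least 2 data points")
        if not np.all(np.diff(self.masses) > 0):
            raise ValueError("masses must be strictly increasing")
        if np.any(~np.isfinite(self.masses)) or np.any(~np.isfinite(self.intensities)):
            raise ValueError("non-finite values in spectrum")
        if np.any(self.intensities < 0):
            raise ValueError("negative intensities are not allowed")

    def __len__(self) -> int:
        return int(self.masses.size)

    def replace_intensities(self, intensities: np.ndarray) -> "Spectrum":
        return Spectrum(self.sample_id, self.masses.copy(), intensities)


@dataclass(frozen=True)
class SampleRecord:
    """Provenance of one spectrum: culture, biological and technical replicate."""

    sample_id: str
    culture_id: str
    biological_replicate: int
    technical_replicate: int
    source_path: str = ""

    def __post_init__(self) -> None:
        if self.biological_replicate < 1 or self.technical_replicate < 1:
            raise ValueError("replicate indices are 1-based and must be >= 1")


@dataclass(frozen=True)
class SequenceRecord:
    """An (rRNA gene) nucleotide sequence; uppercase, ungapped, U mapped to T."""

    seq_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for {self.seq_id!r}")
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise ValueError(f"invalid characters in {self.seq_id!r}: {sorted(bad)}")


def _read_table_spectrum(path: Path, sample_id: str) -> Spectrum:
    masses: list[float] = []
    intens: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", " ").split()
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected two columns, got {line!r}")
            try:
                m, i = float(parts[0]), float(parts[1])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: unparsable row {line!r}") from exc
            masses.append(m)
            intens.append(i)
    if len(masses) < 2:
        raise ValueError(f"{path}: fewer than 2 data points")
    order = np.argsort(masses, kind="stable")
    return Spectrum(sample_id, np.asarray(masses)[order], np.asarray(intens)[order])


def _read_mzml_spectrum(path: Path, sample_id: str) -> Spectrum:
    from pyteomics import mzml as _mzml

    with _mzml.read(str(path)) as reader:
        for entry in reader:
            if entry.get("ms level", 1) != 1:
                continue
            masses = np.asarray(entry["m/z array"], dtype=float)
            intens = np.asarray(entry["intensity array"], dtype=float)
            order = np.argsort(masses, kind="stable")
            return Spectrum(sample_id, masses[order], intens[order])
    raise ValueError(f"{path}: no MS1 spectrum found")


def read_spectrum(path: str | Path, format: str = "table", sample_id: str | None = None) -> Spectrum:
    """Read one spectrum from ``path``.

    Parameters
    ----------
    path:
        File to read.
    format:
        ``"table"`` for whitespace/comma-delimited two-column text
        (``# comment`` lines skipped) or ``"mzml"`` for mzML (first MS1
        spectrum of the file).
    sample_id:
        Identifier for the spectrum; defaults to the file stem.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sid = sample_id if sample_id is not None else path.stem
    if format == "table":
        return _read_table_spectrum(path, sid)
    if format == "mzml":
        return _read_mzml_spectrum(path, sid)
    raise ValueError(f"unknown spectrum format {format!r}")


def write_spectrum(spectrum: Spectrum, path: str | Path) -> None:
    """Write a spectrum as a two-column table (round-trips with read_spectrum)."""
    with open(path, "w") as fh:
        fh.write(f"# sample_id: {spectrum.sample_id}\n")
        for m, i in zip(spectrum.masses, spectrum.intensities):
            fh.write(f"{m:.10g}\t{i:.10g}\n")


_SHEET_COLUMNS = ["sample_id", "culture_id", "bio_rep", "tech_rep", "path"]


def read_sample_sheet(path: str | Path) -> list[SampleRecord]:
    """Read the TSV/CSV sheet that maps each spectrum file to its replicate slot."""
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    missing = [c for c in _SHEET_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"sample sheet missing column(s): {missing}")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            SampleRecord(
                sample_id=str(row.sample_id),
                culture_id=str(row.culture_id),
                biological_replicate=int(row.bio_rep),
                technical_replicate=int(row.tech_rep),
                source_path=str(row.path) if not pd.isna(row.path) else "",
            )
        )
    triples = [(r.culture_id, r.biological_replicate, r.technical_replicate) for r in records]
    if len(set(triples)) != len(triples):
        dupes = sorted({t for t in triples if triples.count(t) > 1})
        raise ValueError(f"duplicate (culture, bio_rep, tech_rep) triple(s): {dupes}")
    ids = [r.sample_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample_id in sample sheet")
    return records


def write_sample_sheet(records: Iterable[SampleRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "sample_id": r.sample_id,
                "culture_id": r.culture_id,
                "bio_rep": r.biological_replicate,
                "tech_rep": r.technical_replicate,
                "path": r.source_path,
            }
            for r in records
        ]
    )
    df.to_csv(path, sep="\t", index=False)


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read nucleotide FASTA; sequences are upper-cased and U is mapped to T."""
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper().replace("U", "T").replace("-", "")
        records.append(SequenceRecord(rec.id, seq))
    return records
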