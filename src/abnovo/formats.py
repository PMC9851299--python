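"""Readers and writers for the on-disk artifacts.

MGF spectra go through pyteomics, FASTA through Biopython; prediction and
ground-truth tables are plain TSV (UTF-8, header row required) so that
any tool's output can be adapted with a one-line conversion.  All loaders
validate type invariants on the way in — no invalid object escapes I/O.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from pyteomics import mgf as _mgf

from .masses import ModifiedPeptide

__all__ = [
    "Spectrum",
    "GroundTruthRecord",
    "PredictionRecord",
    "read_mgf",
    "write_mgf",
    "read_fasta",
    "write_fasta",
    "read_predictions",
    "write_predictions",
    "read_ground_truth",
    "write_ground_truth",
    "read_defect_log",
    "write_defect_log",
    "write_report",
]


@dataclass
class Spectrum:
    """A tandem mass spectrum: precursor descriptor plus peak list.

    Peaks are kept sorted ascending by m/z; intensities are non-negative.
    The spectrum is identified by its MGF TITLE string, matched exactly.
    """

    spectrum_id: str
    precursor_mz: float
    charge: int
    mz: np.ndarray
    intensity: np.ndarray
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity arrays must have the same length")
        if self.charge < 1:
            raise ValueError(f"charge must be >= 1, got {self.charge}")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")
        order = np.argsort(self.mz, kind="stable")
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]

    def __len__(self) -> int:
        return len(self.mz)


def read_mgf(path: str | Path) -> list[Spectrum]:
    """Read all spectra from a Mascot Generic Format file.

    Both "2+" and "+2" charge dialects are accepted.  Unknown header keys
    are preserved in ``Spectrum.params`` and written back on round-trip.
    """
    path = Path(path)
    spectra = []
    if path.stat().st_size == 0:
        return spectra
    with _mgf.MGF(str(path)) as reader:
        for entry in reader:
            params = dict(entry["params"])
            title = str(params.pop("title", ""))
            pepmass = params.pop("pepmass", (0.0,))
            charge_field = params.pop("charge", [1])
            charge = int(charge_field[0]) if charge_field else 1
            spectra.append(
                Spectrum(
                    spectrum_id=title,
                    precursor_mz=float(pepmass[0]),
                    charge=abs(charge),
                    mz=entry["m/z array"],
                    intensity=entry["intensity array"],
                    params=params,
                )
            )
    return spectra


def write_mgf(spectra: Iterable[Spectrum], path: str | Path) -> None:
    """Write spectra as MGF; m/z to 5 decimals, intensity to 2."""
    entries = []
    for s in spectra:
        params = {
            "title": s.spectrum_id,
            "pepmass": s.precursor_mz,
            "charge": f"{s.charge}+",
            **s.params,
        }
        entries.append(
            {"params": params, "m/z array": s.mz, "intensity array": s.intensity}
        )
    with open(path, "w") as handle:
        _mgf.write(entries, handle, fragment_format="{:.5f} {:.2f}")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read (id, sequence) pairs; tolerant of wrapping and CRLF dialects."""
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    seq_records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


@dataclass(frozen=True)
class GroundTruthRecord:
    """The reference (pseudo-ground-truth) peptide call for one spectrum."""

    spectrum_id: str
    peptide: ModifiedPeptide
    source: str = ""


@dataclass(frozen=True)
class PredictionRecord:
    """One tool's peptide call for a spectrum, with confidence scores.

    ``peptide_score`` and the per-residue ``positional_scores`` live on a
    0-100 scale; the positional score list has one entry per residue.
    """

    spectrum_id: str
    peptide: ModifiedPeptide
    peptide_score: float
    positional_scores: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.positional_scores) != len(self.peptide):
            raise ValueError(
                f"{self.spectrum_id}: {len(self.positional_scores)} positional "
                f"scores for a {len(self.peptide)}-residue peptide"
            )
        scores = (self.peptide_score, *self.positional_scores)
        if any(not 0 <= s <= 100 for s in scores):
            raise ValueError(f"{self.spectrum_id}: scores must lie in [0, 100]")


def read_ground_truth(path: str | Path) -> list[GroundTruthRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, ("spectrum_id", "peptide"), path)
    dupes = df["spectrum_id"][df["spectrum_id"].duplicated()]
    if not dupes.empty:
        row = dupes.index[0] + 2  # 1-based, after header
        raise ValueError(
            f"{path}: duplicate ground-truth spectrum_id {dupes.iloc[0]!r} "
            f"at line {row}"
        )
    records = []
    for idx, row in df.iterrows():
        try:
            peptide = ModifiedPeptide.parse(row["peptide"])
        except ValueError as exc:
            raise ValueError(f"{path}: line {idx + 2}: {exc}") from exc
        records.append(
            GroundTruthRecord(row["spectrum_id"], peptide, row.get("source", ""))
        )
    return records


def write_ground_truth(records: Iterable[GroundTruthRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "spectrum_id": [r.spectrum_id for r in records],
            "peptide": [str(r.peptide) for r in records],
            "source": [r.source for r in records],
        }
    ).to_csv(path, sep="\t", index=False)


def read_predictions(path: str | Path) -> list[PredictionRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(
        df, ("spectrum_id", "peptide", "peptide_score", "positional_scores"), path
    )
    records = []
    for idx, row in df.iterrows():
        try:
            peptide = ModifiedPeptide.parse(row["peptide"])
            positional = tuple(
                float(x) for x in row["positional_scores"].split(",") if x != ""
            )
            records.append(
                PredictionRecord(
                    row["spectrum_id"], peptide, float(row["peptide_score"]), positional
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path}: line {idx + 2}: {exc}") from exc
    return records


def write_predictions(records: Iterable[PredictionRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "spectrum_id": [r.spectrum_id for r in records],
            "peptide": [str(r.peptide) for r in records],
            "peptide_score": [f"{r.peptide_score:.4f}" for r in records],
            "positional_scores": [
                ",".join(f"{s:.4f}" for s in r.positional_scores) for r in records
            ],
        }
    ).to_csv(path, sep="\t", index=False)


def write_defect_log(rows: Iterable[dict], path: str | Path) -> None:
    """Simulator ground truth: per-spectrum dropped sites and noise count."""
    df = pd.DataFrame(rows)
    if "dropped_sites" in df.columns:
        df["dropped_sites"] = [
            ",".join(str(s) for s in sites) for sites in df["dropped_sites"]
        ]
    df.to_csv(path, sep="\t", index=False)


def read_defect_log(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"spectrum_id": str}, keep_default_na=False)
    df["dropped_sites"] = [
        tuple(int(x) for x in str(v).split(",") if x != "")
        for v in df["dropped_sites"]
    ]
    return df


def write_report(report: dict, path: str | Path) -> None:
    """Write a JSON report with a stable key order."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)

    def _coerce(obj):
        if isinstance(obj, np.integer):
            return int(obj)
        if isinstance(obj, np.floating):
            return float(obj)
        raise TypeError(f"not JSON serializable: {type(obj)}")

    with open(path, "w") as handle:
        json.dump(report, handle, indent=2, sort_keys=True, default=_coerce)
        handle.write("\n")


def _require_columns(df: pd.DataFrame, columns: Sequence[str], path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
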