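"""Fragment-ion annotation and spectrum quality measures.

Given a spectrum and its ground-truth peptide, every peak within 0.5 Da of
a theoretical ion of any of the eight HCD ion types (b, b2+, b-NH3, b-H2O,
y, y2+, y-NH3, y-H2O) is a fragment peak; a cleavage site with no matched
ion of any type is *missing*.  The remaining peaks are noise; the noise
factor of a spectrum is the number of noise peaks whose intensity strictly
exceeds the dataset-wide median noise intensity, divided by the number of
fragment peaks.  These two quantities — missing cleavage sites and noise
factor — are the spectrum-quality axes along which peptide recall is
stratified.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from .formats import Spectrum
from .masses import (
    DEFAULT_MASS_TABLE,
    ION_TYPES,
    MassTable,
    ModifiedPeptide,
    ToleranceConfig,
    theoretical_fragments,
)

__all__ = [
    "SpectrumAnnotation",
    "annotate_spectrum",
    "dataset_median_noise",
    "noise_factor",
    "annotate_dataset",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SpectrumAnnotation:
    """Per-spectrum fragment evidence and quality measures.

    ``site_evidence`` maps each cleavage site (1..len-1) to the ion types
    matched there with the index of the matched peak.  A peak matched by
    several theoretical ions is still a single fragment peak.  The noise
    fields are filled once the dataset median is known (``noise_factor``);
    a spectrum with zero fragment peaks has an undefined noise factor
    (None) and is binned separately downstream.
    """

    spectrum_id: str
    peptide_length: int
    site_evidence: dict[int, dict[str, int]]
    missing_sites: int
    fragment_peak_count: int
    fragment_peak_indices: frozenset[int]
    total_peaks: int
    noise_peak_count: int
    high_noise_peak_count: int | None = None
    noise_factor: float | None = None
    median_reference: float | None = None


def annotate_spectrum(
    spectrum: Spectrum,
    peptide: ModifiedPeptide,
    tol: ToleranceConfig = ToleranceConfig(),
    table: MassTable = DEFAULT_MASS_TABLE,
) -> SpectrumAnnotation:
    """Match the eight ion types at every cleavage site against the peaks.

    For each (site, ion type) the nearest peak within ``tol.fragment_tol``
    is recorded; a site with no matched ion type of any kind is missing.
    """
    mz = spectrum.mz
    theo = theoretical_fragments(peptide, table)
    site_evidence: dict[int, dict[str, int]] = {}
    fragment_indices: set[int] = set()
    missing = 0
    for site, ions in theo.items():
        matched: dict[str, int] = {}
        for ion_type, ion_mz in ions.items():
            # site evidence records the nearest in-tolerance peak, but every
            # peak within tolerance of the ion is fragment evidence — two
            # near-coincident ions may share a nearest peak while a second
            # peak still sits inside the tolerance window
            within = _peaks_within(mz, ion_mz, tol.fragment_tol)
            if within:
                matched[ion_type] = min(
                    within, key=lambda idx: abs(mz[idx] - ion_mz)
                )
                fragment_indices.update(within)
        site_evidence[site] = matched
        if not matched:
            missing += 1

    return SpectrumAnnotation(
        spectrum_id=spectrum.spectrum_id,
        peptide_length=len(peptide),
        site_evidence=site_evidence,
        missing_sites=missing,
        fragment_peak_count=len(fragment_indices),
        fragment_peak_indices=frozenset(fragment_indices),
        total_peaks=len(spectrum),
        noise_peak_count=len(spectrum) - len(fragment_indices),
    )


def _peaks_within(mz: np.ndarray, target: float, tol: float) -> list[int]:
    lo = int(np.searchsorted(mz, target - tol, side="right"))
    hi = int(np.searchsorted(mz, target + tol, side="left"))
    return [idx for idx in range(lo, hi) if abs(mz[idx] - target) < tol]


def dataset_median_noise(
    annotations: Sequence[SpectrumAnnotation],
    spectra: Sequence[Spectrum],
) -> float:
    """Median intensity of all non-fragment peaks, pooled over the dataset.

    Returns 0 with a warning when every peak in the dataset is fragment
    evidence.
    """
    if not annotations:
        raise ValueError("need at least one annotated spectrum")
    by_id = {s.spectrum_id: s for s in spectra}
    noise_intensities: list[np.ndarray] = []
    for ann in annotations:
        spectrum = by_id[ann.spectrum_id]
        mask = np.ones(len(spectrum), dtype=bool)
        mask[list(ann.fragment_peak_indices)] = False
        noise_intensities.append(spectrum.intensity[mask])
    pooled = np.concatenate(noise_intensities) if noise_intensities else np.array([])
    if pooled.size == 0:
        logger.warning("no non-fragment peaks in dataset; median noise set to 0")
        return 0.0
    return float(np.median(pooled))


def noise_factor(
    annotation: SpectrumAnnotation,
    median_reference: float,
    spectrum: Spectrum,
) -> SpectrumAnnotation:
    """Fill the noise fields: supra-median noise peaks over fragment peaks.

    Only noise peaks whose intensity strictly exceeds the median reference
    count as high-intensity.  With zero fragment peaks the ratio is
    undefined and left as None.
    """
    mask = np.ones(len(spectrum), dtype=bool)
    mask[list(annotation.fragment_peak_indices)] = False
    high = int(np.sum(spectrum.intensity[mask] > median_reference))
    factor: float | None
    if annotation.fragment_peak_count == 0:
        factor = None
    else:
        factor = high / annotation.fragment_peak_count
    return replace(
        annotation,
        high_noise_peak_count=high,
        noise_factor=factor,
        median_reference=median_reference,
    )


def annotate_dataset(
    spectra: Sequence[Spectrum],
    peptides: dict[str, ModifiedPeptide],
    tol: ToleranceConfig = ToleranceConfig(),
    table: MassTable = DEFAULT_MASS_TABLE,
) -> list[SpectrumAnnotation]:
    """Annotate all spectra with a ground-truth call, then compute the
    dataset median noise intensity and each spectrum's noise factor."""
    annotated_spectra = [s for s in spectra if s.spectrum_id in peptides]
    annotations = [
        annotate_spectrum(s, peptides[s.spectrum_id], tol, table)
        for s in annotated_spectra
    ]
    if not annotations:
        return []
    median = dataset_median_noise(annotations, annotated_spectra)
    return [
        noise_factor(ann, median, spectrum)
        for ann, spectrum in zip(annotations, annotated_spectra)
    ]
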