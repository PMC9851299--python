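"""Synthetic antibody-digest benchmark generator.

Everything the evaluation consumes can be produced offline by this module:
reference chains with realistic residue composition, multi-enzyme digests,
HCD-style b/y fragment spectra with controlled missing cleavage sites and
noise peaks, and mock de novo predictions carrying a controlled mixture of
sequencing-error types with confidence scores correlated with correctness.

The defect log written alongside the spectra records the *observable*
ground truth — which cleavage sites ended up without any fragment-ion
evidence, and how many noise peaks were injected — so annotation and
stratification can be checked exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .digestion import DigestPeptide, digest, get_enzyme
from .errors import ErrorType, classify_error
from .formats import GroundTruthRecord, PredictionRecord, Spectrum
from .masses import (
    DEFAULT_MASS_TABLE,
    ION_TYPES,
    MassTable,
    ModifiedPeptide,
    ToleranceConfig,
    precursor_mz,
    theoretical_fragments,
)

__all__ = [
    "ConfidenceModel",
    "SimulationConfig",
    "SpectrumDefects",
    "SimulatedDataset",
    "random_protein",
    "simulate_spectrum",
    "corrupt_peptide",
    "simulate_tool_output",
    "simulate_dataset",
    "SYNTHETIC_LIGHT_CHAIN",
    "SYNTHETIC_HEAVY_CHAIN",
]


class CorruptionError(ValueError):
    """The peptide cannot carry the requested error type; caller resamples."""


# Average residue frequencies of vertebrate proteins, used for synthetic
# reference chains.
_AA_FREQUENCIES = {
    "A": 0.083, "R": 0.057, "N": 0.044, "D": 0.053, "C": 0.018,
    "Q": 0.040, "E": 0.062, "G": 0.072, "H": 0.022, "I": 0.052,
    "L": 0.090, "K": 0.057, "M": 0.024, "F": 0.039, "P": 0.051,
    "S": 0.069, "T": 0.058, "W": 0.013, "Y": 0.032, "V": 0.066,
}


def random_protein(length: int, rng: np.random.Generator) -> str:
    """A random protein with realistic overall residue composition."""
    codes = list(_AA_FREQUENCIES)
    probs = np.array(list(_AA_FREQUENCIES.values()))
    probs = probs / probs.sum()
    return "".join(rng.choice(codes, size=length, p=probs))


@dataclass(frozen=True)
class ConfidenceModel:
    """Links prediction correctness to the emitted confidence score.

    Correct predictions draw peptide scores from Beta(correct_alpha,
    correct_beta) and incorrect ones from Beta(incorrect_alpha,
    incorrect_beta), scaled to [0, scale]; the defaults make correct
    predictions stochastically dominate incorrect ones without separating
    them, so PR curves are non-degenerate.  Setting ``constant_correct`` /
    ``constant_incorrect`` replaces the draw with a fixed score (a
    perfectly calibrated oracle uses 100 / 0).
    """

    correct_alpha: float = 8.0
    correct_beta: float = 2.0
    incorrect_alpha: float = 2.0
    incorrect_beta: float = 8.0
    scale: float = 100.0
    constant_correct: float | None = None
    constant_incorrect: float | None = None

    def draw(self, correct: bool, rng: np.random.Generator) -> float:
        if correct:
            if self.constant_correct is not None:
                return self.constant_correct
            return self.scale * rng.beta(self.correct_alpha, self.correct_beta)
        if self.constant_incorrect is not None:
            return self.constant_incorrect
        return self.scale * rng.beta(self.incorrect_alpha, self.incorrect_beta)


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic benchmark.

    The defaults describe a clean multi-enzyme antibody digest: three
    proteases at zero missed cleavages, per-site fragment dropout of 0.15
    (so most longer peptides miss at least one cleavage site), a Poisson
    noise load, and a Beta confidence model.  ``error_mixture`` maps error
    types to proportions summing to <= 1; the remainder are correct
    predictions.
    """

    enzymes: tuple[str, ...] = ("trypsin", "chymotrypsin", "asp-n")
    max_missed_cleavages: int = 0
    peptide_length_range: tuple[int, int] = (7, 30)
    site_dropout_prob: float = 0.15
    other_ion_prob: float = 0.5
    noise_peak_mean: float = 60.0
    noise_intensity_scale: float = 1.0
    signal_intensity_mean_log: float = 2.3
    signal_intensity_sigma_log: float = 0.6
    charge_states: tuple[int, ...] = (2, 3)
    error_mixture: dict = field(default_factory=dict)
    confidence_model: ConfidenceModel = ConfidenceModel()
    collision_free_noise: bool = False
    mz_range: tuple[float, float] = (100.0, 2000.0)

    def __post_init__(self) -> None:
        for p in (self.site_dropout_prob, self.other_ion_prob):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        total = sum(self.error_mixture.values())
        if total > 1 + 1e-9:
            raise ValueError(f"error mixture proportions sum to {total} > 1")
        if not all(0 <= v <= 1 for v in self.error_mixture.values()):
            raise ValueError("error mixture proportions must lie in [0, 1]")


@dataclass(frozen=True)
class SpectrumDefects:
    """Observable simulation ground truth for one spectrum."""

    spectrum_id: str
    dropped_sites: tuple[int, ...]
    noise_count: int


def simulate_spectrum(
    peptide: ModifiedPeptide,
    charge: int,
    config: SimulationConfig,
    rng: np.random.Generator,
    spectrum_id: str = "sim|0",
    tol: ToleranceConfig = ToleranceConfig(),
    table: MassTable = DEFAULT_MASS_TABLE,
) -> tuple[Spectrum, SpectrumDefects]:
    """Simulate an HCD-style fragment spectrum for one peptide.

    Each cleavage site independently drops out with probability
    ``site_dropout_prob``; a retained site always emits its b and y singly
    charged peaks and each of the six other ion types with probability
    ``other_ion_prob``.  Peak m/z values deviate from theory by at most
    ``tol.fragment_sim_tol`` (0.02 Da).  Noise peaks are placed uniformly
    over the m/z range; with ``collision_free_noise`` their positions are
    resampled until they are well clear of every theoretical ion so the
    annotation ground truth stays exact.

    The defect log records the sites that are *observably* missing (no
    signal peak within ``tol.fragment_tol`` of any of the eight ion types
    at that site) — fragment ions of neighbouring sites occasionally cover
    for a dropped site, and the observable count is what annotation and
    the recall stratification see.
    """
    if charge not in config.charge_states:
        raise ValueError(f"charge {charge} not in configured states {config.charge_states}")
    theo = theoretical_fragments(peptide, table)
    n_sites = len(peptide) - 1

    signal_mz: list[float] = []
    dropped: list[int] = []
    for site in range(1, n_sites + 1):
        if rng.random() < config.site_dropout_prob:
            dropped.append(site)
            continue
        for ion_type, ion_mz in theo[site].items():
            if ion_type not in ("b", "y") and rng.random() >= config.other_ion_prob:
                continue
            jitter = rng.uniform(-tol.fragment_sim_tol, tol.fragment_sim_tol)
            signal_mz.append(ion_mz + jitter)
    if dropped:
        # a dropped site must stay observably missing: suppress emitted
        # ions of other sites that happen to fall inside a dropped site's
        # matching window (ion series of different sites can coincide)
        dropped_ions = np.array(
            [m for site in dropped for m in theo[site].values()]
        )
        signal_mz = [
            m
            for m in signal_mz
            if np.min(np.abs(dropped_ions - m)) >= tol.fragment_tol
        ]

    all_theoretical = np.array(
        [m for ions in theo.values() for m in ions.values()], dtype=float
    )
    n_noise = int(rng.poisson(config.noise_peak_mean))
    noise_mz = _draw_noise_mz(
        n_noise, all_theoretical, config, rng, tol.fragment_tol
    )

    signal_intensity = rng.lognormal(
        config.signal_intensity_mean_log,
        config.signal_intensity_sigma_log,
        size=len(signal_mz),
    )
    noise_intensity = rng.exponential(
        config.noise_intensity_scale, size=len(noise_mz)
    )

    spectrum = Spectrum(
        spectrum_id=spectrum_id,
        precursor_mz=precursor_mz(peptide, charge, table),
        charge=charge,
        mz=np.concatenate([signal_mz, noise_mz]),
        intensity=np.concatenate([signal_intensity, noise_intensity]),
    )

    observed_missing = _observably_missing_sites(
        np.asarray(signal_mz), theo, tol.fragment_tol
    )
    defects = SpectrumDefects(
        spectrum_id=spectrum_id,
        dropped_sites=tuple(observed_missing),
        noise_count=len(noise_mz),
    )
    return spectrum, defects


def _draw_noise_mz(
    n: int,
    theoretical: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
    fragment_tol: float,
) -> np.ndarray:
    lo, hi = config.mz_range
    if not config.collision_free_noise or theoretical.size == 0:
        return rng.uniform(lo, hi, size=n)
    # keep noise a comfortable margin beyond the matching tolerance away
    # from every theoretical ion, so no noise peak can pass as a fragment
    margin = 1.5 * fragment_tol
    out = np.empty(n)
    for i in range(n):
        for _ in range(1000):
            candidate = rng.uniform(lo, hi)
            if np.min(np.abs(theoretical - candidate)) > margin:
                out[i] = candidate
                break
        else:  # pragma: no cover - the m/z range is never that crowded
            raise RuntimeError("could not place collision-free noise peak")
    return out


def _observably_missing_sites(
    signal_mz: np.ndarray,
    theo: dict[int, dict[str, float]],
    fragment_tol: float,
) -> list[int]:
    """Sites with no signal peak within tolerance of any of their ions.

    Deliberately a plain nested scan, independent of the annotation
    module's search-based matcher.
    """
    missing = []
    for site, ions in theo.items():
        found = False
        for ion_mz in ions.values():
            if signal_mz.size and np.min(np.abs(signal_mz - ion_mz)) < fragment_tol:
                found = True
                break
        if not found:
            missing.append(site)
    return missing


# ---------------------------------------------------------------------------
# prediction corruption
# ---------------------------------------------------------------------------

#: Near-isobaric single-residue-to-pair rewrites (mass delta < 0.5 Da),
#: mirroring the ambiguities de novo tools actually confuse: Q vs GA/AG,
#: K vs GA/AG, N vs GG, R vs GV/VG, W vs SV/VS.
MASS_MATCHED_SPLITS: dict[str, tuple[str, ...]] = {
    "Q": ("GA", "AG"),
    "K": ("GA", "AG"),
    "N": ("GG",),
    "R": ("GV", "VG"),
    "W": ("SV", "VS"),
}

_MIN_LENGTH = {
    ErrorType.INVERSION_FIRST_3: 4,
    ErrorType.INVERSION_LAST_3: 4,
    ErrorType.INVERSION_FIRST_AND_LAST_3: 7,
    ErrorType.REPLACE_1_BY_1_OR_2: 2,
    ErrorType.REPLACE_2_BY_2: 2,
    ErrorType.REPLACE_3_BY_3: 3,
    ErrorType.REPLACE_4_BY_4: 4,
    ErrorType.REPLACE_5_BY_5: 5,
    ErrorType.REPLACE_6_BY_6: 6,
    ErrorType.MORE_THAN_6_WRONG: 7,
    ErrorType.OTHER: 4,
}


def corrupt_peptide(
    peptide: ModifiedPeptide,
    error_type: ErrorType,
    rng: np.random.Generator,
    table: MassTable = DEFAULT_MASS_TABLE,
    tol: ToleranceConfig = ToleranceConfig(),
) -> ModifiedPeptide:
    """Apply one sequencing-error type to a (ground-truth) peptide.

    The construction guarantees the error classifier recovers exactly the
    requested category: terminal inversions permute the first/last three
    residues into a mass-visibly different order, n-for-n replacements
    rewrite a window with residues mass-distinct from the originals, the
    1-for-2 case uses the near-isobaric split pool when the site allows,
    and "other" rewrites two residues into four.  Raises
    ``CorruptionError`` when the peptide is too short or its composition
    cannot carry the error (e.g. inverting "III"); callers resample.
    """
    if error_type is ErrorType.CORRECT:
        return peptide
    if len(peptide) < _MIN_LENGTH[error_type]:
        raise CorruptionError(
            f"peptide of length {len(peptide)} too short for {error_type.value}"
        )
    for _ in range(50):
        corrupted = _corrupt_once(peptide, error_type, rng, table, tol)
        if corrupted is not None and (
            classify_error(corrupted, peptide, tol, table) is error_type
        ):
            return corrupted
    raise CorruptionError(
        f"could not realize {error_type.value} on {peptide.plain_sequence}"
    )


def _corrupt_once(
    peptide: ModifiedPeptide,
    error_type: ErrorType,
    rng: np.random.Generator,
    table: MassTable,
    tol: ToleranceConfig,
) -> ModifiedPeptide | None:
    residues = list(peptide.residues)
    n = len(residues)

    if error_type in (
        ErrorType.INVERSION_FIRST_3,
        ErrorType.INVERSION_LAST_3,
        ErrorType.INVERSION_FIRST_AND_LAST_3,
    ):
        out = residues[:]
        if error_type in (ErrorType.INVERSION_FIRST_3, ErrorType.INVERSION_FIRST_AND_LAST_3):
            window = _permute_window(residues[:3], rng, table, tol)
            if window is None:
                return None
            out[:3] = window
        if error_type in (ErrorType.INVERSION_LAST_3, ErrorType.INVERSION_FIRST_AND_LAST_3):
            window = _permute_window(residues[-3:], rng, table, tol)
            if window is None:
                return None
            out[-3:] = window
        return ModifiedPeptide(tuple(out))

    if error_type is ErrorType.REPLACE_1_BY_1_OR_2:
        start = int(rng.integers(0, n))
        code = residues[start][0]
        splits = MASS_MATCHED_SPLITS.get(code)
        if splits is not None and rng.random() < 0.5:
            split = splits[int(rng.integers(0, len(splits)))]
            replacement = [(aa, None) for aa in split]
        else:
            replacement = [_distinct_residue([residues[start]], rng, table, tol)]
        return ModifiedPeptide(
            tuple(residues[:start] + replacement + residues[start + 1 :])
        )

    if error_type in (
        ErrorType.REPLACE_2_BY_2,
        ErrorType.REPLACE_3_BY_3,
        ErrorType.REPLACE_4_BY_4,
        ErrorType.REPLACE_5_BY_5,
        ErrorType.REPLACE_6_BY_6,
    ):
        width = int(error_type.value.split("_")[1])
        start = int(rng.integers(0, n - width + 1))
        window = residues[start : start + width]
        replacement = [
            _distinct_residue(window, rng, table, tol) for _ in range(width)
        ]
        return ModifiedPeptide(
            tuple(residues[:start] + replacement + residues[start + width :])
        )

    if error_type is ErrorType.MORE_THAN_6_WRONG:
        width = 7
        start = int(rng.integers(0, n - width + 1))
        window = residues[start : start + width]
        replacement = [
            _distinct_residue(window, rng, table, tol) for _ in range(width)
        ]
        return ModifiedPeptide(
            tuple(residues[:start] + replacement + residues[start + width :])
        )

    if error_type is ErrorType.OTHER:
        # the canonical out-of-category pattern: 2 residues become 4
        start = int(rng.integers(0, n - 1))
        window = residues[start : start + 2]
        replacement = [_distinct_residue(window, rng, table, tol) for _ in range(4)]
        return ModifiedPeptide(
            tuple(residues[:start] + replacement + residues[start + 2 :])
        )

    raise ValueError(f"unsupported error type {error_type}")


def _permute_window(window, rng, table, tol):
    """Reorder a 3-residue window so at least one position changes mass."""
    masses = [table.residue_mass(c, m) for c, m in window]
    orders = [
        p
        for p in _permutations3()
        if any(
            abs(masses[p[i]] - masses[i]) >= tol.aa_mass_tol for i in range(3)
        )
    ]
    if not orders:
        return None
    order = orders[int(rng.integers(0, len(orders)))]
    return [window[i] for i in order]


def _permutations3():
    return (
        (0, 2, 1), (1, 0, 2), (1, 2, 0), (2, 0, 1), (2, 1, 0),
    )


def _distinct_residue(avoid, rng, table, tol):
    """A random unmodified residue mass-distinct from every residue in avoid."""
    avoid_masses = [table.residue_mass(c, m) for c, m in avoid]
    candidates = [
        aa
        for aa, mass in table.residue_masses.items()
        if all(abs(mass - am) > 2 * tol.aa_mass_tol for am in avoid_masses)
    ]
    return (candidates[int(rng.integers(0, len(candidates)))], None)


def simulate_tool_output(
    ground_truth: Sequence[GroundTruthRecord],
    config: SimulationConfig,
    rng: np.random.Generator,
    table: MassTable = DEFAULT_MASS_TABLE,
    tol: ToleranceConfig = ToleranceConfig(),
) -> tuple[list[PredictionRecord], list[ErrorType]]:
    """Mock a de novo tool: one scored prediction per ground-truth spectrum.

    The error type of each prediction is drawn from ``config.error_mixture``
    (remaining probability mass yields a correct prediction); peptide and
    positional confidences come from the configured confidence model.
    Returns the predictions and the intended per-spectrum error labels.
    """
    mixture = {ErrorType(k): v for k, v in config.error_mixture.items()}
    types = list(mixture)
    probs = np.array([mixture[t] for t in types], dtype=float)
    p_correct = 1.0 - probs.sum()

    predictions: list[PredictionRecord] = []
    labels: list[ErrorType] = []
    choices = [ErrorType.CORRECT] + types
    weights = np.concatenate(([p_correct], probs))
    for record in ground_truth:
        error = choices[int(rng.choice(len(choices), p=weights))]
        try:
            peptide = corrupt_peptide(record.peptide, error, rng, table, tol)
        except CorruptionError:
            error = ErrorType.CORRECT
            peptide = record.peptide
        score = config.confidence_model.draw(error is ErrorType.CORRECT, rng)
        positional = tuple(
            float(np.clip(score + rng.uniform(-5, 5), 0, 100))
            for _ in range(len(peptide))
        )
        predictions.append(
            PredictionRecord(record.spectrum_id, peptide, float(score), positional)
        )
        labels.append(error)
    return predictions, labels


# ---------------------------------------------------------------------------
# dataset-level simulation
# ---------------------------------------------------------------------------


@dataclass
class SimulatedDataset:
    """Everything one simulated benchmark run produces."""

    reference: tuple[str, str]  # (chain id, sequence)
    spectra: list[Spectrum]
    ground_truth: list[GroundTruthRecord]
    defects: list[SpectrumDefects]
    predictions: list[PredictionRecord]
    true_errors: list[ErrorType]


def simulate_dataset(
    config: SimulationConfig,
    rng: np.random.Generator,
    reference: tuple[str, str] | None = None,
    table: MassTable = DEFAULT_MASS_TABLE,
    tol: ToleranceConfig = ToleranceConfig(),
) -> SimulatedDataset:
    """Digest a reference chain, simulate spectra and mock tool output.

    Each digest peptide within the configured length range yields one
    spectrum with a charge drawn from the configured states.  Peptides are
    taken from every configured enzyme's digest, so overlapping products
    from different proteases tile the chain — the property the de Bruijn
    assembly relies on.
    """
    if reference is None:
        reference = ("synthetic-light-chain", SYNTHETIC_LIGHT_CHAIN)
    chain_id, protein = reference

    lo, hi = config.peptide_length_range
    spectra: list[Spectrum] = []
    ground_truth: list[GroundTruthRecord] = []
    defects: list[SpectrumDefects] = []
    index = 0
    for enzyme_name in config.enzymes:
        get_enzyme(enzyme_name)  # fail early on unknown enzymes
        for product in digest(protein, enzyme_name, config.max_missed_cleavages):
            if not lo <= len(product.sequence) <= hi:
                continue
            peptide = ModifiedPeptide.from_plain(product.sequence)
            charge = int(
                config.charge_states[int(rng.integers(0, len(config.charge_states)))]
            )
            spectrum_id = (
                f"sim|{chain_id}|{enzyme_name}|{index}|{product.start}-{product.end}"
            )
            spectrum, defect = simulate_spectrum(
                peptide, charge, config, rng, spectrum_id, tol, table
            )
            spectra.append(spectrum)
            defects.append(defect)
            ground_truth.append(
                GroundTruthRecord(spectrum_id, peptide, source="simulator")
            )
            index += 1

    predictions, true_errors = simulate_tool_output(
        ground_truth, config, rng, table, tol
    )
    return SimulatedDataset(
        reference=reference,
        spectra=spectra,
        ground_truth=ground_truth,
        defects=defects,
        predictions=predictions,
        true_errors=true_errors,
    )


# ---------------------------------------------------------------------------
# bundled synthetic reference chains
# ---------------------------------------------------------------------------

# Generated once from the residue frequencies above, with the light chain
# screened so that a trypsin + chymotrypsin + asp-N digest at zero missed
# cleavages tiles every position with peptides of length >= 7 and
# reassembles to full coverage (see docs/methods.md).  Lengths mirror
# typical immunoglobulin chains: ~220 residues (light), ~450 (heavy).
SYNTHETIC_LIGHT_CHAIN = (
    "RGAWAWPHTDYYPMNKSVTDVDLQTGRAGGQKHQIQFVLTIGRQKKNAGEICVQGTPSKGNKGAVRLA"
    "QGYYCMYTHPMDGFKPGTNVLGAASSSSQNECEVCTPYHAANNKDYTYLEHDTTKNQKPDCFLDCAGD"
    "ESSCHGGPPGEALVKQVLDPLFFMWKIPVRTGITLVTPLYKLVTPKVTSYKAKGKQSIEGVGKYIGRY"
    "VEERNRDYHVGTAKML"
)
SYNTHETIC_HEAVY_CHAIN = (
    "RAVLDTMNNRKRLTVAGPPDSQRQTTGHLGPQLLVEIVQDPKSYACGEQAKITWKAVVTVHTKMRLQR"
    "LLGSLRETWEEPPTSVTTFKEQVTTTQPVRVRALFVTWVTNTVPVPTKPSFYYKADRPLDVELARSRV"
    "WNNPKVRTRANELGHGYLERVETGRGKLHLAVETGSSMLSEDVSNGHGRPEEGEGGGPIGISFGLDLE"
    "QIGNDEMPFIGTDRYAFQVAGGMPFLSPQDPEFFALAEKIDWQLEIQFSSFSDNNASQNRMQQVARSH"
    "RKNFSLPVILIILACLEIVIKLFPLDGFKIVGICELHFQSENTEVRAWEVRYTDFDEENIRDNAFRHE"
    "IQIPDTAHNTEQYAVAGCRECRGGLCEIKHGTDRMSGIQIALFSPYKMLNRRADCKGIACTLIPGLLQ"
    "LDEIQLASSPLTDAQTSETLSPHIVDAPNRKIEHRVKELESI"
)
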