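"""Synthetic MS/MS spectra and cohort PSM tables with known ground truth.

Two generators:

* CID-like spectra of A-beta(1-16) norm/isoAsp7 binary mixtures in which the
  marker-fragment intensities (b6, b7, y10) rise linearly with the iso
  fraction while the base fragments (b11, y11) stay put — the structure the
  ratio-calibration method relies on. Multiplicative log-normal intensity
  noise, optional m/z jitter and random background peaks.

* A 5xFAD-like ageing cohort: per-animal PSM tables with configurable
  truncation, missed-cleavage and PTM probabilities, plus replicate MS/MS
  spectra at each animal's true iso fraction. Trajectories: logistic total
  A-beta accumulation per species, linear isoAsp7 growth (constant rate over
  the lifespan), a mid-life peak for deamidation, and age-constant oxidation
  and pyroGlu levels.

All outputs are pure functions of (config, seed).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Tuple, Union

import numpy as np

from .reference import (
    Species,
    classify_peptide,
    get_sequence,
    precursor_mh,
    theoretical_ladder,
)
from .proteoforms import PsmRecord, records_to_frame
from .spectra import Peak, Spectrum, write_mgf

__all__ = [
    "DEFAULT_MARKER_ENHANCEMENT",
    "DEFAULT_N_SPECTRA_PER_SAMPLE",
    "SpectrumSimConfig",
    "LogisticTrajectory",
    "LinearTrajectory",
    "CohortConfig",
    "CohortSimResult",
    "simulate_spectrum",
    "simulate_calibration_series",
    "simulate_cohort",
    "write_fixture_bundle",
    "HUMAN_AD_ISO_PCT",
]

#: Replicate MS/MS spectra accumulated per sample in the default design.
DEFAULT_N_SPECTRA_PER_SAMPLE: int = 20

#: Default per-channel intensity enhancement of the marker fragments in the
#: pure-iso profile. Chosen (arbitrarily — no reference spectra exist) so the
#: b6/b11 ratio doubles between 0% and 100% iso.
DEFAULT_MARKER_ENHANCEMENT: float = 2.0

#: Single "high-iso" preset for a human AD-like comparison sample.
HUMAN_AD_ISO_PCT: float = 76.0

_MARKERS = ("b6", "b7", "y10")
_BASES = ("b11", "y11")


def _default_norm_profile() -> Dict[str, float]:
    # generic mid-range intensities for the full singly charged b/y ladder,
    # with the quantification channels set explicitly
    seq = get_sequence(Species.human, 1, 16)
    profile = {ion.label: 25.0 for ion in theoretical_ladder(seq)}
    profile.update(
        {"b6": 40.0, "b7": 30.0, "y10": 35.0, "b11": 100.0, "y11": 80.0}
    )
    return profile


def _default_iso_profile(
    enhancement: float = DEFAULT_MARKER_ENHANCEMENT,
) -> Dict[str, float]:
    profile = _default_norm_profile()
    for label in _MARKERS:
        profile[label] *= enhancement
    return profile


@dataclass(frozen=True)
class SpectrumSimConfig:
    """Generative model of one CID spectrum of an A-beta(1-16) mixture."""

    pure_norm_profile: Mapping[str, float] = field(
        default_factory=_default_norm_profile
    )
    pure_iso_profile: Mapping[str, float] = field(
        default_factory=_default_iso_profile
    )
    noise_cv: float = 0.10
    n_background_peaks: int = 10
    mz_jitter_da: float = 0.005
    species: Species = Species.human

    def __post_init__(self):
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.n_background_peaks < 0:
            raise ValueError("n_background_peaks must be >= 0")
        if self.mz_jitter_da < 0:
            raise ValueError("mz_jitter_da must be >= 0")
        for label in _BASES:
            if not np.isclose(
                self.pure_norm_profile[label], self.pure_iso_profile[label]
            ):
                raise ValueError(
                    f"base fragment {label} must have equal mean intensity "
                    "in both profiles"
                )
        for label in _MARKERS:
            if self.pure_iso_profile[label] <= self.pure_norm_profile[label]:
                raise ValueError(
                    f"marker enhancement for {label} must exceed 1"
                )


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_spectrum(
    iso_fraction_pct: float,
    config: Optional[SpectrumSimConfig] = None,
    seed=None,
    sample_id: str = "sim",
    replicate: int = 1,
) -> Spectrum:
    """One simulated CID spectrum of a norm/iso binary mixture.

    Each fragment's mean intensity is the linear mixture
    ``(1 - f) * norm + f * iso`` (f the iso fraction), multiplied by
    mean-one log-normal noise of the configured CV. Background peaks fall
    at uniform random m/z at least 0.1 Da away from every theoretical ion.
    """
    if not 0.0 <= iso_fraction_pct <= 100.0:
        raise ValueError(
            f"iso_fraction_pct must lie in [0, 100], got {iso_fraction_pct}"
        )
    config = config or SpectrumSimConfig()
    rng = _as_rng(seed)
    f = iso_fraction_pct / 100.0
    seq = get_sequence(config.species, 1, 16)
    ladder = theoretical_ladder(seq)
    mh = precursor_mh(seq)
    theoretical = np.array([ion.mz for ion in ladder])
    if config.noise_cv > 0:
        sigma = np.sqrt(np.log1p(config.noise_cv**2))
        noise = rng.lognormal(-0.5 * sigma**2, sigma, size=len(ladder))
    else:
        noise = np.ones(len(ladder))
    peaks = []
    for ion, factor in zip(ladder, noise):
        mean = (
            (1.0 - f) * config.pure_norm_profile[ion.label]
            + f * config.pure_iso_profile[ion.label]
        )
        mz = ion.mz
        if config.mz_jitter_da > 0:
            mz += rng.normal(0.0, config.mz_jitter_da)
        peaks.append(Peak(mz, mean * factor))
    lo, hi = 100.0, mh + 50.0
    guard = 0.1  # 2 x the default 0.05 Da matching tolerance
    placed = 0
    while placed < config.n_background_peaks:
        mz = rng.uniform(lo, hi)
        if np.min(np.abs(theoretical - mz)) <= guard:
            continue
        peaks.append(Peak(mz, rng.uniform(0.5, 15.0)))
        placed += 1
    peaks.sort(key=lambda p: p.mz)
    # collisions are vanishingly rare but would violate strict ordering
    deduped = [peaks[0]]
    for peak in peaks[1:]:
        if peak.mz <= deduped[-1].mz:
            deduped[-1] = Peak(
                deduped[-1].mz, deduped[-1].intensity + peak.intensity
            )
        else:
            deduped.append(peak)
    return Spectrum(
        sample_id=sample_id,
        replicate=replicate,
        precursor_mz=mh,
        peaks=deduped,
        metadata={"ISO_FRACTION_PCT": f"{iso_fraction_pct:g}"},
    )


def simulate_calibration_series(
    step_pct: float = 10.0,
    reps: int = 1,
    config: Optional[SpectrumSimConfig] = None,
    seed=None,
) -> List[Tuple[float, Spectrum]]:
    """Replicate spectra over the binary-mixture design 0..100% in ``step_pct`` steps."""
    if step_pct <= 0:
        raise ValueError("step_pct must be > 0")
    if not np.isclose(100.0 / step_pct, round(100.0 / step_pct)):
        raise ValueError(f"step_pct must divide 100, got {step_pct}")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = _as_rng(seed)
    fractions = np.arange(0.0, 100.0 + step_pct / 2, step_pct)
    out = []
    for fraction in fractions:
        for rep in range(1, reps + 1):
            out.append(
                (
                    float(fraction),
                    simulate_spectrum(
                        float(fraction),
                        config,
                        rng,
                        sample_id=f"cal{fraction:g}",
                        replicate=rep,
                    ),
                )
            )
    return out


@dataclass(frozen=True)
class LogisticTrajectory:
    """plateau / (1 + exp(-rate * (age - midpoint)))"""

    plateau: float
    midpoint: float
    rate: float

    def __call__(self, age) -> np.ndarray:
        age = np.asarray(age, dtype=float)
        return self.plateau / (1.0 + np.exp(-self.rate * (age - self.midpoint)))


@dataclass(frozen=True)
class LinearTrajectory:
    """Straight line through (age0, value0) and (age1, value1), clipped to bounds."""

    age0: float
    value0: float
    age1: float
    value1: float
    lower: float = 0.0
    upper: float = 100.0

    def __call__(self, age) -> np.ndarray:
        age = np.asarray(age, dtype=float)
        slope = (self.value1 - self.value0) / (self.age1 - self.age0)
        return np.clip(
            self.value0 + slope * (age - self.age0), self.lower, self.upper
        )


def _default_animals() -> Tuple[Tuple[float, int], ...]:
    # 24 animals: two each at 2, 8, 9, 10, 12, 14, 16 months; three at 3
    # and 7; one each at 4, 17, 18, 23.
    return (
        (2, 2), (3, 3), (4, 1), (7, 3), (8, 2), (9, 2), (10, 2),
        (12, 2), (14, 2), (16, 2), (17, 1), (18, 1), (23, 1),
    )


def _default_nterm_starts() -> Dict[int, float]:
    return {1: 0.78, 2: 0.04, 3: 0.08, 4: 0.02, 5: 0.04, 8: 0.02, 9: 0.02}


def _default_cterm_ends() -> Dict[int, float]:
    return {42: 0.94, 40: 0.04, 41: 0.01, 43: 0.01}


@dataclass(frozen=True)
class CohortConfig:
    """Study design and generative parameters for a 5xFAD-like cohort."""

    animals: Tuple[Tuple[float, int], ...] = field(
        default_factory=_default_animals
    )
    # total A-beta accumulation (arbitrary intensity units scaled to a
    # ~10 ng/mg-equivalent plateau), nonlinear with a mid-life ramp
    human_trajectory: LogisticTrajectory = LogisticTrajectory(
        plateau=10.0, midpoint=10.5, rate=0.8
    )
    murine_trajectory: LogisticTrajectory = LogisticTrajectory(
        plateau=0.8, midpoint=7.0, rate=1.2
    )
    # isoAsp7 percentage grows at a constant rate: 8% at 7 mo -> 30% at 23 mo
    iso_trajectory: LinearTrajectory = LinearTrajectory(
        age0=7.0, value0=8.0, age1=23.0, value1=30.0
    )
    oxidation_level: float = 0.13
    pyroglu_e3_level: float = 0.07
    deamidation_peak_level: float = 0.06
    deamidation_peak_age: float = 12.0
    deamidation_width: float = 4.0
    nterm_start_probs: Mapping[int, float] = field(
        default_factory=_default_nterm_starts
    )
    cterm_end_probs: Mapping[int, float] = field(
        default_factory=_default_cterm_ends
    )
    # missed-cleavage share of PSMs: low baseline, jumps after ~16 months
    missed_cleavage_base: float = 0.04
    missed_cleavage_late: float = 0.25
    missed_cleavage_onset_age: float = 16.0
    family_weights: Tuple[float, float, float] = (0.45, 0.25, 0.30)
    n_psms_per_sample: int = 300
    n_spectra_per_sample: int = DEFAULT_N_SPECTRA_PER_SAMPLE
    iso_sample_sd_pct: float = 5.0
    intensity_sigma: float = 0.3
    spectrum_config: SpectrumSimConfig = field(
        default_factory=SpectrumSimConfig
    )

    def __post_init__(self):
        for age, count in self.animals:
            if count < 1:
                raise ValueError(f"animal count at age {age} must be >= 1")
            if age <= 0:
                raise ValueError(f"age must be positive, got {age}")
        for name in (
            "oxidation_level", "pyroglu_e3_level", "deamidation_peak_level",
            "missed_cleavage_base", "missed_cleavage_late",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {value}")
        for probs, label in (
            (self.nterm_start_probs, "nterm_start_probs"),
            (self.cterm_end_probs, "cterm_end_probs"),
        ):
            total = sum(probs.values())
            if not np.isclose(total, 1.0):
                raise ValueError(f"{label} must sum to 1, got {total}")
        for age, _ in self.animals:
            iso = float(self.iso_trajectory(age))
            if not 0.0 <= iso <= 100.0:
                raise ValueError(
                    f"invalid trajectory: iso fraction {iso:.2f}% out of "
                    f"range at age {age}"
                )
            for traj in (self.human_trajectory, self.murine_trajectory):
                if traj(age) < 0:
                    raise ValueError(
                        f"invalid trajectory: negative abundance at age {age}"
                    )

    @property
    def n_animals(self) -> int:
        return sum(count for _, count in self.animals)

    def deamidation_level(self, age) -> np.ndarray:
        """Deamidation occupancy: Gaussian bump peaking mid-life."""
        age = np.asarray(age, dtype=float)
        return self.deamidation_peak_level * np.exp(
            -0.5 * ((age - self.deamidation_peak_age) / self.deamidation_width)
            ** 2
        )

    def missed_cleavage_rate(self, age) -> np.ndarray:
        age = np.asarray(age, dtype=float)
        ramp = 1.0 / (1.0 + np.exp(-2.0 * (age - self.missed_cleavage_onset_age)))
        return self.missed_cleavage_base + (
            self.missed_cleavage_late - self.missed_cleavage_base
        ) * ramp


@dataclass
class CohortSimResult:
    """Simulated cohort: PSM records, per-animal spectra, and ground truth."""

    records: List[PsmRecord]
    spectra: Dict[str, List[Spectrum]]
    truth: dict
    config: CohortConfig

    @property
    def psm_table(self):
        return records_to_frame(self.records)


def _sample_categorical(rng, probs: Mapping[int, float]) -> int:
    keys = sorted(probs)
    weights = np.array([probs[k] for k in keys], dtype=float)
    return int(rng.choice(keys, p=weights / weights.sum()))


def _make_psm(
    rng: np.random.Generator,
    config: CohortConfig,
    sample_id: str,
    age: float,
    human_share: float,
    base_intensity: float,
) -> PsmRecord:
    missed = rng.random() < config.missed_cleavage_rate(age)
    if missed:
        start, end = [(1, 28), (17, 42), (1, 42)][
            rng.choice(3, p=[0.5, 0.3, 0.2])
        ]
    else:
        family = rng.choice(3, p=np.asarray(config.family_weights))
        if family == 0:  # N-terminal (X-16)
            start, end = _sample_categorical(rng, config.nterm_start_probs), 16
        elif family == 1:  # mid (17-28)
            start, end = 17, 28
        else:  # C-terminal (29-X)
            start, end = 29, _sample_categorical(rng, config.cterm_end_probs)
    # species only matters (and is only distinguishable) inside 1-16
    species = (
        Species.human if rng.random() < human_share else Species.murine
    )
    seq = get_sequence(species, start, end)
    mods: List[Tuple[int, str]] = []
    if start == 3 and rng.random() < config.pyroglu_e3_level:
        mods.append((3, "pyroglutamate_E"))
    deam = float(config.deamidation_level(age))
    if start <= 15 <= end and rng.random() < deam:
        mods.append((15, "deamidation"))
    if start <= 27 <= end and rng.random() < deam:
        mods.append((27, "deamidation"))
    if start <= 35 <= end and rng.random() < config.oxidation_level:
        mods.append((35, "oxidation"))
    intensity = base_intensity * rng.lognormal(
        -0.5 * config.intensity_sigma**2, config.intensity_sigma
    )
    return PsmRecord(
        sample_id=sample_id,
        age_months=age,
        peptide=seq.residues,
        start=start,
        end=end,
        species=classify_peptide(seq.residues),
        mods=tuple(mods),
        intensity=float(intensity),
    )


def simulate_cohort(
    config: Optional[CohortConfig] = None,
    seed=None,
    with_spectra: bool = True,
) -> CohortSimResult:
    """Simulate the full cohort: PSM table, replicate spectra, ground truth.

    Per animal: a true isoAsp7 fraction from the linear trajectory at its
    age, ``n_psms_per_sample`` PSM records drawn with the configured
    truncation/missed-cleavage/PTM probabilities, and (optionally)
    ``n_spectra_per_sample`` MS/MS spectra of A-beta(1-16) simulated at the
    true fraction. The returned ground truth carries every generating
    parameter and all per-animal true values for recovery testing.
    """
    config = config or CohortConfig()
    rng = _as_rng(seed)
    records: List[PsmRecord] = []
    spectra: Dict[str, List[Spectrum]] = {}
    per_animal = []
    for age, count in config.animals:
        human_level = float(config.human_trajectory(age))
        murine_level = float(config.murine_trajectory(age))
        human_share = human_level / (human_level + murine_level)
        true_iso = float(config.iso_trajectory(age))
        for index in range(1, count + 1):
            animal_id = f"m{int(age):02d}_{index}"
            base_intensity = (human_level + murine_level) * 1e4
            base_intensity /= config.n_psms_per_sample
            for _ in range(config.n_psms_per_sample):
                records.append(
                    _make_psm(
                        rng, config, animal_id, age, human_share,
                        base_intensity,
                    )
                )
            if with_spectra:
                spectra[animal_id] = [
                    simulate_spectrum(
                        true_iso,
                        config.spectrum_config,
                        rng,
                        sample_id=animal_id,
                        replicate=rep,
                    )
                    for rep in range(1, config.n_spectra_per_sample + 1)
                ]
            per_animal.append(
                {
                    "animal_id": animal_id,
                    "age_months": age,
                    "true_iso_pct": true_iso,
                    "human_level": human_level,
                    "murine_level": murine_level,
                    "missed_cleavage_rate": float(
                        config.missed_cleavage_rate(age)
                    ),
                    "deamidation_level": float(config.deamidation_level(age)),
                }
            )
    truth = {
        "animals": per_animal,
        "oxidation_level": config.oxidation_level,
        "pyroglu_e3_level": config.pyroglu_e3_level,
        "nterm_start_probs": dict(config.nterm_start_probs),
        "cterm_end_probs": dict(config.cterm_end_probs),
        "iso_trajectory": asdict(config.iso_trajectory),
        "human_trajectory": asdict(config.human_trajectory),
        "murine_trajectory": asdict(config.murine_trajectory),
        "iso_sample_sd_pct": config.iso_sample_sd_pct,
    }
    return CohortSimResult(
        records=records, spectra=spectra, truth=truth, config=config
    )


def write_fixture_bundle(
    outdir: Union[str, Path],
    config: Optional[CohortConfig] = None,
    seed=None,
    calibration_reps: int = 3,
) -> dict:
    """Write a complete offline fixture: MGFs, PSM CSV, design CSV, truth JSON.

    Layout::

        outdir/
          calibration/design.csv        fraction_pct,path
          calibration/cal<frac>.mgf     replicate calibration spectra
          cohort/<animal>.mgf           per-animal replicate spectra
          psm_table.csv                 the simulated PSM table
          ground_truth.json             generating parameters + true values
          config.json                   the config used
          manifest.json                 this manifest

    Deterministic: the same (config, seed) reproduces identical file content.
    """
    config = config or CohortConfig()
    outdir = Path(outdir)
    rng = np.random.default_rng(seed)
    (outdir / "calibration").mkdir(parents=True, exist_ok=True)
    (outdir / "cohort").mkdir(parents=True, exist_ok=True)

    series = simulate_calibration_series(
        10.0, calibration_reps, config.spectrum_config, rng
    )
    by_fraction: Dict[float, list] = {}
    for fraction, spectrum in series:
        by_fraction.setdefault(fraction, []).append(spectrum)
    design_rows = ["fraction_pct,path"]
    calibration_files = []
    for fraction in sorted(by_fraction):
        name = f"cal{fraction:g}.mgf"
        write_mgf(by_fraction[fraction], outdir / "calibration" / name)
        design_rows.append(f"{fraction:g},{name}")
        calibration_files.append(f"calibration/{name}")
    (outdir / "calibration" / "design.csv").write_text(
        "\n".join(design_rows) + "\n"
    )

    cohort = simulate_cohort(config, rng, with_spectra=True)
    cohort_files = []
    for animal_id in sorted(cohort.spectra):
        name = f"{animal_id}.mgf"
        write_mgf(cohort.spectra[animal_id], outdir / "cohort" / name)
        cohort_files.append(f"cohort/{name}")
    table = cohort.psm_table
    table.to_csv(outdir / "psm_table.csv", index=False, float_format="%.6g")
    (outdir / "ground_truth.json").write_text(
        json.dumps(cohort.truth, indent=2, sort_keys=True)
    )
    config_payload = asdict(config)
    config_payload["spectrum_config"]["species"] = (
        config.spectrum_config.species.value
    )
    (outdir / "config.json").write_text(
        json.dumps(config_payload, indent=2, sort_keys=True, default=str)
    )
    manifest = {
        "calibration_design": "calibration/design.csv",
        "calibration_files": calibration_files,
        "cohort_files": cohort_files,
        "psm_table": "psm_table.csv",
        "ground_truth": "ground_truth.json",
        "config": "config.json",
        "n_animals": config.n_animals,
        "n_psms": len(cohort.records),
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True)
    )
    return manifest
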