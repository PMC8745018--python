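"""Centroided MS/MS peak lists: MGF I/O, spectrum accumulation, fragment matching."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np

from .reference import FragmentIon

__all__ = [
    "DEFAULT_FRAGMENT_TOLERANCE_DA",
    "Peak",
    "Spectrum",
    "FragmentMatchSet",
    "MgfParseError",
    "read_mgf",
    "write_mgf",
    "read_peak_list",
    "accumulate",
    "match_fragments",
]

#: Default fragment-ion mass tolerance (Da), matching common TOF search settings.
DEFAULT_FRAGMENT_TOLERANCE_DA: float = 0.05


@dataclass(frozen=True)
class Peak:
    mz: float
    intensity: float

    def __post_init__(self):
        if not (np.isfinite(self.mz) and self.mz > 0):
            raise ValueError(f"peak mz must be finite and > 0, got {self.mz}")
        if not (np.isfinite(self.intensity) and self.intensity >= 0):
            raise ValueError(
                f"peak intensity must be finite and >= 0, got {self.intensity}"
            )


@dataclass
class Spectrum:
    """A centroided MS/MS spectrum with strictly ascending peak m/z."""

    sample_id: str
    replicate: int
    precursor_mz: float
    peaks: Sequence[Peak]
    metadata: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        self.peaks = tuple(self.peaks)
        if not self.peaks:
            raise ValueError("a spectrum must contain at least one peak")
        mz = self.mz_array
        if np.any(np.diff(mz) <= 0):
            raise ValueError("peak m/z values must be strictly ascending")

    @property
    def mz_array(self) -> np.ndarray:
        return np.array([p.mz for p in self.peaks])

    @property
    def intensity_array(self) -> np.ndarray:
        return np.array([p.intensity for p in self.peaks])

    @property
    def total_intensity(self) -> float:
        return float(self.intensity_array.sum())


class MgfParseError(ValueError):
    """Malformed MGF content; carries the offending line number."""

    def __init__(self, message: str, line_number: int):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


def _parse_title(title: str) -> tuple:
    # convention: TITLE=<sample_id>:<replicate>; otherwise kept verbatim
    if ":" in title:
        head, _, tail = title.rpartition(":")
        if head and tail.isdigit():
            return head, int(tail)
    return title, 1


def read_mgf(path: Union[str, Path]) -> list:
    """Read an MGF file into a list of :class:`Spectrum`.

    One spectrum per BEGIN IONS/END IONS block. PEPMASS is required;
    TITLE of the form ``sample:replicate`` is split, anything else is kept
    verbatim as the sample id (replicate 1). Unrecognised KEY=VALUE lines
    go into ``metadata``.
    """
    path = Path(path)
    spectra = []
    in_block = False
    block_start = 0
    title = ""
    pepmass: Optional[float] = None
    metadata: dict = {}
    peaks: list = []
    with path.open() as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line == "BEGIN IONS":
                if in_block:
                    raise MgfParseError("nested BEGIN IONS", lineno)
                in_block = True
                block_start = lineno
                title, pepmass, metadata, peaks = "", None, {}, []
            elif line == "END IONS":
                if not in_block:
                    raise MgfParseError("END IONS without BEGIN IONS", lineno)
                if pepmass is None:
                    raise MgfParseError(
                        f"block starting at line {block_start} has no PEPMASS",
                        lineno,
                    )
                sample_id, replicate = _parse_title(title)
                try:
                    spectra.append(
                        Spectrum(
                            sample_id=sample_id,
                            replicate=replicate,
                            precursor_mz=pepmass,
                            peaks=sorted(peaks, key=lambda p: p.mz),
                            metadata=metadata,
                        )
                    )
                except ValueError as exc:
                    raise MgfParseError(str(exc), lineno) from exc
                in_block = False
            elif not in_block:
                raise MgfParseError(
                    f"unexpected content outside BEGIN IONS block: {line!r}",
                    lineno,
                )
            elif "=" in line:
                key, _, value = line.partition("=")
                key = key.strip().upper()
                value = value.strip()
                if key == "TITLE":
                    title = value
                elif key == "PEPMASS":
                    try:
                        pepmass = float(value.split()[0])
                    except ValueError:
                        raise MgfParseError(
                            f"unparseable PEPMASS {value!r}", lineno
                        ) from None
                else:
                    metadata[key] = value
            else:
                fields = line.split()
                if len(fields) < 2:
                    raise MgfParseError(
                        f"expected 'mz intensity' peak line, got {line!r}",
                        lineno,
                    )
                try:
                    peaks.append(Peak(float(fields[0]), float(fields[1])))
                except ValueError as exc:
                    raise MgfParseError(str(exc), lineno) from exc
    if in_block:
        raise MgfParseError(
            f"unterminated block starting at line {block_start}", lineno
        )
    if not spectra:
        warnings.warn(f"no spectra found in {path}", stacklevel=2)
    return spectra


def write_mgf(spectra: Iterable[Spectrum], path: Union[str, Path]) -> None:
    """Write spectra to MGF with the ``sample:replicate`` TITLE convention."""
    path = Path(path)
    with path.open("w") as handle:
        for spectrum in spectra:
            handle.write("BEGIN IONS\n")
            handle.write(
                f"TITLE={spectrum.sample_id}:{spectrum.replicate}\n"
            )
            handle.write(f"PEPMASS={spectrum.precursor_mz:.5f}\n")
            for key, value in spectrum.metadata.items():
                handle.write(f"{key.upper()}={value}\n")
            for peak in spectrum.peaks:
                handle.write(f"{peak.mz:.5f} {peak.intensity:.6g}\n")
            handle.write("END IONS\n")


def read_peak_list(path: Union[str, Path]) -> list:
    """Read a bare two-column (mz <TAB> intensity) centroid list."""
    path = Path(path)
    peaks = []
    with path.open() as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 2:
                raise ValueError(
                    f"{path}:{lineno}: expected two columns, got {line!r}"
                )
            peaks.append(Peak(float(fields[0]), float(fields[1])))
    return sorted(peaks, key=lambda p: p.mz)


def accumulate(
    spectra: Sequence[Spectrum], bin_tolerance_da: float = 0.05
) -> Spectrum:
    """Sum a set of replicate spectra into one accumulated spectrum.

    All input centroids are pooled and clustered greedily along ascending
    m/z; a gap larger than ``bin_tolerance_da`` starts a new cluster. Each
    cluster becomes one peak at the intensity-weighted mean m/z with the
    summed intensity, so total intensity is conserved exactly.
    """
    if not spectra:
        raise ValueError("accumulate requires at least one spectrum")
    if bin_tolerance_da <= 0:
        raise ValueError("bin_tolerance_da must be > 0")
    precursors = np.array([s.precursor_mz for s in spectra])
    if precursors.max() - precursors.min() > bin_tolerance_da:
        raise ValueError(
            "mixed precursors: spread "
            f"{precursors.max() - precursors.min():.4f} Da exceeds "
            f"tolerance {bin_tolerance_da} Da"
        )
    mz = np.concatenate([s.mz_array for s in spectra])
    intensity = np.concatenate([s.intensity_array for s in spectra])
    order = np.argsort(mz, kind="stable")
    mz, intensity = mz[order], intensity[order]
    # gap > tolerance starts a new cluster
    new_cluster = np.empty(mz.size, dtype=bool)
    new_cluster[0] = True
    new_cluster[1:] = np.diff(mz) > bin_tolerance_da
    cluster_id = np.cumsum(new_cluster) - 1
    n_clusters = cluster_id[-1] + 1
    total = np.bincount(cluster_id, weights=intensity, minlength=n_clusters)
    weighted = np.bincount(
        cluster_id, weights=mz * intensity, minlength=n_clusters
    )
    plain = np.bincount(cluster_id, weights=mz, minlength=n_clusters)
    counts = np.bincount(cluster_id, minlength=n_clusters)
    with np.errstate(invalid="ignore", divide="ignore"):
        centroid = np.where(total > 0, weighted / total, plain / counts)
    peaks = [Peak(float(m), float(i)) for m, i in zip(centroid, total)]
    first = spectra[0]
    return Spectrum(
        sample_id=first.sample_id,
        replicate=0,
        precursor_mz=float(precursors.mean()),
        peaks=peaks,
        metadata={"ACCUMULATED_FROM": str(len(spectra))},
    )


@dataclass
class FragmentMatchSet:
    """Assignment of theoretical fragment ions to observed peaks."""

    spectrum: Spectrum
    tolerance_da: float
    matches: Mapping[FragmentIon, Optional[Peak]]

    def peak_for(self, label: str) -> Optional[Peak]:
        """The matched peak for an ion label such as ``'b6'``, or None."""
        for ion, peak in self.matches.items():
            if ion.label == label:
                return peak
        raise KeyError(f"no ion labelled {label!r} in the matched ladder")

    def intensity(self, label: str) -> float:
        peak = self.peak_for(label)
        return peak.intensity if peak is not None else 0.0

    @property
    def n_matched(self) -> int:
        return sum(1 for p in self.matches.values() if p is not None)


def match_fragments(
    spectrum: Spectrum,
    ladder: Sequence[FragmentIon],
    tolerance_da: float = DEFAULT_FRAGMENT_TOLERANCE_DA,
) -> FragmentMatchSet:
    """Match each theoretical ion to its nearest observed peak within tolerance.

    A peak is assigned to at most one ion. Candidate (ion, peak) pairs are
    taken in order of increasing |delta m/z|, ties broken toward the more
    intense then lower-m/z peak, which makes the matched-ion count monotone
    non-decreasing in the tolerance.
    """
    if not ladder:
        raise ValueError("ladder must be non-empty")
    if tolerance_da <= 0:
        raise ValueError("tolerance_da must be > 0")
    mz = spectrum.mz_array
    candidates = []
    for ion_idx, ion in enumerate(ladder):
        lo = np.searchsorted(mz, ion.mz - tolerance_da, side="left")
        hi = np.searchsorted(mz, ion.mz + tolerance_da, side="right")
        for peak_idx in range(lo, hi):
            peak = spectrum.peaks[peak_idx]
            candidates.append(
                (abs(peak.mz - ion.mz), -peak.intensity, peak.mz, ion_idx,
                 peak_idx)
            )
    candidates.sort()
    assigned: dict = {}
    used_peaks: set = set()
    used_ions: set = set()
    for _, _, _, ion_idx, peak_idx in candidates:
        if ion_idx in used_ions or peak_idx in used_peaks:
            continue
        assigned[ion_idx] = peak_idx
        used_ions.add(ion_idx)
        used_peaks.add(peak_idx)
    matches = {
        ion: (
            spectrum.peaks[assigned[i]] if i in assigned else None
        )
        for i, ion in enumerate(ladder)
    }
    return FragmentMatchSet(
        spectrum=spectrum, tolerance_da=tolerance_da, matches=matches
    )
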