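"""Proteoform summaries from PSM-level quantification tables.

Consumes search-engine-style peptide quantification exports (one row per
peptide-spectrum match with sequence, A-beta coordinates, modification list
and intensity) and produces terminal truncation distributions, PTM site
occupancies, missed-cleavage fractions, and per-age abundance series.

Quantification basis is summed PSM intensity; spectral counting is exposed
via ``weighting="count"`` where it makes sense.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .reference import MODIFICATIONS, classify_peptide, span_length

__all__ = [
    "PSM_COLUMNS",
    "PsmRecord",
    "ProteoformProfile",
    "read_psm_table",
    "records_to_frame",
    "parse_mods",
    "format_mods",
    "terminal_distribution",
    "ptm_occupancy",
    "missed_cleavage_fraction",
    "abundance_timeseries",
    "build_profile",
]

PSM_COLUMNS = (
    "sample_id",
    "age_months",
    "peptide",
    "start",
    "end",
    "mods",
    "intensity",
)

#: LysC cleaves C-terminal to lysine; the A-beta lysines sit at 16 and 28,
#: so fully cleaved products are (X-16), (17-28), (29-X).
LYSC_SITES = (16, 28)

# PTM sites flagged as low-confidence in output (site localization of
# phosphorylation could not be confirmed upstream).
LOW_CONFIDENCE_MODS = frozenset({"phosphorylation"})


@dataclass(frozen=True)
class PsmRecord:
    """One peptide-spectrum match with A-beta coordinates and intensity."""

    sample_id: str
    age_months: float
    peptide: str
    start: int
    end: int
    species: str
    mods: Tuple[Tuple[int, str], ...] = ()
    intensity: float = 1.0

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"start {self.start} > end {self.end}")
        expected = span_length(self.start, self.end)
        if len(self.peptide) != expected:
            raise ValueError(
                f"peptide length {len(self.peptide)} inconsistent with span "
                f"{self.start}..{self.end} (expected {expected})"
            )
        if self.species not in ("human", "murine", "shared"):
            raise ValueError(f"invalid species {self.species!r}")
        if classify_peptide(self.peptide) != self.species:
            raise ValueError(
                f"species {self.species!r} inconsistent with peptide "
                f"{self.peptide!r} "
                f"(classified {classify_peptide(self.peptide)!r})"
            )
        if not np.isfinite(self.intensity) or self.intensity < 0:
            raise ValueError("intensity must be finite and >= 0")
        for position, name in self.mods:
            if name not in MODIFICATIONS:
                raise ValueError(f"unknown modification {name!r}")
            if not self.covers(position):
                raise ValueError(
                    f"modification {name} at {position} outside span "
                    f"{self.start}..{self.end}"
                )

    def covers(self, position: int) -> bool:
        return self.start <= position <= self.end and position != 0

    def has_mod(self, position: int, name: str) -> bool:
        return (position, name) in self.mods

    @property
    def missed_cleavage(self) -> bool:
        """True when the span strictly contains a LysC site (K16 or K28)."""
        return any(
            self.start <= site and self.end > site for site in LYSC_SITES
        )


def parse_mods(text) -> Tuple[Tuple[int, str], ...]:
    """Parse ``"pos:name;pos:name"`` into ((pos, name), ...)."""
    if text is None or (isinstance(text, float) and np.isnan(text)):
        return ()
    text = str(text).strip()
    if not text:
        return ()
    out = []
    for token in text.split(";"):
        token = token.strip()
        if not token:
            continue
        position, _, name = token.partition(":")
        out.append((int(position), name.strip()))
    return tuple(out)


def format_mods(mods: Iterable[Tuple[int, str]]) -> str:
    return ";".join(f"{p}:{n}" for p, n in mods)


def read_psm_table(
    path: Union[str, Path],
    return_rejects: bool = False,
):
    """Read and validate a delimited PSM quantification table.

    The delimiter is sniffed from the header (comma or tab). The species of
    every row is recomputed from the peptide sequence; rows violating any
    record invariant are collected into a rejects report (and warned about)
    rather than aborting the load.
    """
    path = Path(path)
    sep = "\t" if "\t" in path.open().readline() else ","
    frame = pd.read_csv(path, sep=sep)
    missing = [c for c in PSM_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    records: List[PsmRecord] = []
    rejects: List[dict] = []
    for row_index, row in enumerate(frame.itertuples(index=False)):
        try:
            records.append(
                PsmRecord(
                    sample_id=str(row.sample_id),
                    age_months=float(row.age_months),
                    peptide=str(row.peptide),
                    start=int(row.start),
                    end=int(row.end),
                    species=classify_peptide(str(row.peptide)),
                    mods=parse_mods(row.mods),
                    intensity=float(row.intensity),
                )
            )
        except (ValueError, TypeError) as exc:
            rejects.append({"row": row_index, "reason": str(exc)})
    if rejects:
        warnings.warn(
            f"{len(rejects)} of {len(frame)} rows rejected while reading "
            f"{path.name}",
            stacklevel=2,
        )
    if return_rejects:
        return records, rejects
    return records


def records_to_frame(records: Sequence[PsmRecord]) -> pd.DataFrame:
    """Serialize records back to the tidy PSM table layout."""
    return pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in records],
            "age_months": [r.age_months for r in records],
            "peptide": [r.peptide for r in records],
            "start": [r.start for r in records],
            "end": [r.end for r in records],
            "mods": [format_mods(r.mods) for r in records],
            "intensity": [r.intensity for r in records],
            "species": [r.species for r in records],
        }
    )


def _weights(records: Sequence[PsmRecord], weighting: str) -> np.ndarray:
    if weighting == "intensity":
        return np.array([r.intensity for r in records])
    if weighting == "count":
        return np.ones(len(records))
    raise ValueError(f"unknown weighting {weighting!r}")


def terminal_distribution(
    records: Sequence[PsmRecord],
    terminus: str,
    species_filter: Optional[str] = None,
    weighting: str = "intensity",
) -> Dict[int, float]:
    """Fraction of terminal-family intensity at each start (N) or end (C) position.

    The N-terminal family is anchored at end == 16 (LysC A-beta(X-16)
    peptides); the C-terminal family at start == 29 (A-beta(29-X)). Returns
    a mapping position -> fraction, normalized to 1.
    """
    if terminus not in ("N", "C"):
        raise ValueError(f"terminus must be 'N' or 'C', got {terminus!r}")
    if species_filter is not None:
        records = [r for r in records if r.species == species_filter]
    if terminus == "N":
        family = [r for r in records if r.end == 16]
        keys = [r.start for r in family]
    else:
        family = [r for r in records if r.start == 29]
        keys = [r.end for r in family]
    if not family:
        raise ValueError(
            f"no {terminus}-terminal family records after filtering"
        )
    weights = _weights(family, weighting)
    total = weights.sum()
    if total <= 0:
        raise ValueError("terminal family has zero total weight")
    out: Dict[int, float] = {}
    for key, weight in zip(keys, weights):
        out[key] = out.get(key, 0.0) + weight / total
    return dict(sorted(out.items()))


def ptm_occupancy(
    records: Sequence[PsmRecord],
    site: int,
    mod: str,
    weighting: str = "intensity",
) -> float:
    """Occupancy of a modification at a site: modified / total covering intensity.

    For N-terminus-restricted modifications (pyroglutamate) only peptides
    that actually start at the site can carry the modification, so the
    denominator is restricted to those records; for all other modifications
    every record covering the site counts.
    """
    if mod not in MODIFICATIONS:
        raise ValueError(f"unknown modification {mod!r}")
    from .reference import PositionalRule

    if MODIFICATIONS[mod].positional_rule is PositionalRule.peptide_nterm_only:
        covering = [r for r in records if r.start == site]
    else:
        covering = [r for r in records if r.covers(site)]
    if not covering:
        raise ValueError(f"site not covered: no records span position {site}")
    weights = _weights(covering, weighting)
    total = weights.sum()
    if total <= 0:
        raise ValueError(f"site not covered: zero weight at position {site}")
    modified = np.array(
        [w for r, w in zip(covering, weights) if r.has_mod(site, mod)]
    )
    return float(modified.sum() / total)


def missed_cleavage_fraction(
    records: Sequence[PsmRecord], weighting: str = "intensity"
) -> float:
    """Intensity-weighted share of records spanning an internal LysC site."""
    if not records:
        raise ValueError("missed_cleavage_fraction requires >= 1 record")
    weights = _weights(records, weighting)
    total = weights.sum()
    if total <= 0:
        return 0.0
    missed = sum(
        w for r, w in zip(records, weights) if r.missed_cleavage
    )
    return float(missed / total)


_SERIES_NAMES = ("Ab1_16", "AbX_16", "total_Nterm")


def _in_series(record: PsmRecord, series: str) -> bool:
    if series == "Ab1_16":
        return record.start == 1 and record.end == 16
    if series == "AbX_16":
        return record.end == 16
    if series == "total_Nterm":
        return record.start <= 16
    raise ValueError(
        f"unknown series {series!r}; expected one of {_SERIES_NAMES}"
    )


def abundance_timeseries(
    records: Sequence[PsmRecord],
    series: str = "AbX_16",
    species: Optional[str] = None,
) -> pd.Series:
    """Per-age summed intensity of an N-terminal peptide family.

    Families nest: Ab1_16 (exactly 1-16) within AbX_16 (any start, end 16)
    within total_Nterm (any peptide starting at or before 16). Shared
    peptides (identical between species) are excluded from species-specific
    series and counted only when ``species`` is None.
    """
    if series not in _SERIES_NAMES:
        raise ValueError(
            f"unknown series {series!r}; expected one of {_SERIES_NAMES}"
        )
    selected = [r for r in records if _in_series(r, series)]
    if species is not None:
        selected = [r for r in selected if r.species == species]
    ages = sorted({r.age_months for r in records})
    if len(ages) < 2:
        warnings.warn("timeseries over fewer than 2 ages", stacklevel=2)
    totals = {age: 0.0 for age in ages}
    for record in selected:
        totals[record.age_months] += record.intensity
    return pd.Series(totals, name=series).sort_index()


@dataclass
class ProteoformProfile:
    """Per-sample proteoform summary."""

    sample_id: str
    n_term_fractions: Dict[int, float]
    c_term_fractions: Dict[int, float]
    ptm_occupancy: Dict[Tuple[int, str], float]
    missed_cleavage_fraction: float
    totals: Dict[str, float]
    low_confidence: Tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "n_term_fractions": {
                str(k): v for k, v in self.n_term_fractions.items()
            },
            "c_term_fractions": {
                str(k): v for k, v in self.c_term_fractions.items()
            },
            "ptm_occupancy": {
                f"{site}:{name}": value
                for (site, name), value in self.ptm_occupancy.items()
            },
            "missed_cleavage_fraction": self.missed_cleavage_fraction,
            "totals": self.totals,
            "low_confidence": list(self.low_confidence),
        }


#: Default (site, modification) pairs summarized by build_profile.
DEFAULT_PTM_SITES = (
    (35, "oxidation"),
    (3, "pyroglutamate_E"),
    (15, "deamidation"),
    (27, "deamidation"),
    (8, "phosphorylation"),
)


def build_profile(
    records: Sequence[PsmRecord],
    sample_id: str,
    ptm_sites: Sequence[Tuple[int, str]] = DEFAULT_PTM_SITES,
) -> ProteoformProfile:
    """Assemble the full proteoform summary for one sample."""
    mine = [r for r in records if r.sample_id == sample_id]
    if not mine:
        raise ValueError(f"no records for sample {sample_id!r}")
    occupancies: Dict[Tuple[int, str], float] = {}
    flagged = set()
    for site, mod in ptm_sites:
        try:
            occupancies[(site, mod)] = ptm_occupancy(mine, site, mod)
        except ValueError:
            continue
        if mod in LOW_CONFIDENCE_MODS:
            flagged.add(mod)
    totals: Dict[str, float] = {}
    for record in mine:
        totals[record.species] = (
            totals.get(record.species, 0.0) + record.intensity
        )

    def _safe_terminal(terminus: str) -> Dict[int, float]:
        try:
            return terminal_distribution(mine, terminus)
        except ValueError:
            return {}

    return ProteoformProfile(
        sample_id=sample_id,
        n_term_fractions=_safe_terminal("N"),
        c_term_fractions=_safe_terminal("C"),
        ptm_occupancy=occupancies,
        missed_cleavage_fraction=missed_cleavage_fraction(mine),
        totals=totals,
        low_confidence=tuple(sorted(flagged)),
    )
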