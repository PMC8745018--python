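"""Amyloid-beta sequence constants, modification definitions, and fragment-mass arithmetic.

Coordinates are 1-based A-beta numbering throughout. The methionine
immediately preceding D1 is written as position -1 (there is no position 0),
mirroring the M(-1) proteoform nomenclature. APP numbering is not used.

All ions are singly protonated monoisotopic species (MALDI conditions).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence, Union

__all__ = [
    "PROTON_MASS",
    "WATER_MASS",
    "RESIDUE_MASSES",
    "MODIFICATIONS",
    "Species",
    "PositionalRule",
    "ModificationSpec",
    "ResidueSequence",
    "FragmentIon",
    "get_sequence",
    "classify_peptide",
    "fragment_mz",
    "precursor_mh",
    "theoretical_ladder",
    "span_length",
    "span_positions",
    "residue_at",
    "constants_as_json",
]

PROTON_MASS: float = 1.00727646688
WATER_MASS: float = 18.0105646863

#: Monoisotopic residue (i.e. dehydrated amino acid) masses, Da.
RESIDUE_MASSES: Mapping[str, float] = {
    "G": 57.02146372,
    "A": 71.03711378,
    "S": 87.03202840,
    "P": 97.05276385,
    "V": 99.06841391,
    "T": 101.04767847,
    "C": 103.00918478,
    "L": 113.08406398,
    "I": 113.08406398,
    "N": 114.04292744,
    "D": 115.02694302,
    "Q": 128.05857751,
    "K": 128.09496301,
    "E": 129.04259309,
    "M": 131.04048491,
    "H": 137.05891186,
    "F": 147.06841391,
    "R": 156.10111102,
    "Y": 163.06332853,
    "W": 186.07931295,
}

AMINO_ACIDS = frozenset(RESIDUE_MASSES)

# A-beta region 1..43 (position 43 = T, the Abeta43 terminus); the two
# species differ only at positions 5, 10 and 13, all within 1..16.
_HUMAN_1_43 = "DAEFRHDSGYEVHHQKLVFFAEDVGSNKGAIIGLMVGGVVIAT"
_MURINE_1_43 = "DAEFGHDSGFEVRHQK" + _HUMAN_1_43[16:]
_PRE_MET = "M"  # residue at position -1

MIN_POSITION = -1
MAX_POSITION = 43


class Species(str, Enum):
    human = "human"
    murine = "murine"


class PositionalRule(str, Enum):
    any = "any"
    peptide_nterm_only = "peptide_nterm_only"


@dataclass(frozen=True)
class ModificationSpec:
    """A variable modification: name, legal target residues, and mass shift."""

    name: str
    target_residues: frozenset
    mono_delta: float
    positional_rule: PositionalRule = PositionalRule.any


#: Registry of the supported variable modifications. iso_asp is mass-silent:
#: Asp -> isoAsp isomerization does not change the elemental composition,
#: which is exactly why it must be quantified from fragmentation behaviour
#: rather than from a mass shift.
MODIFICATIONS: Mapping[str, ModificationSpec] = {
    "deamidation": ModificationSpec(
        "deamidation", frozenset("NQ"), 0.98402
    ),
    "oxidation": ModificationSpec("oxidation", frozenset("M"), 15.99491),
    "phosphorylation": ModificationSpec(
        "phosphorylation", frozenset("STY"), 79.96633
    ),
    "pyroglutamate_E": ModificationSpec(
        "pyroglutamate_E",
        frozenset("E"),
        -18.01056,
        PositionalRule.peptide_nterm_only,
    ),
    "pyroglutamate_Q": ModificationSpec(
        "pyroglutamate_Q",
        frozenset("Q"),
        -17.02655,
        PositionalRule.peptide_nterm_only,
    ),
    "iso_asp": ModificationSpec("iso_asp", frozenset("D"), 0.0),
}

ModLike = Union[str, ModificationSpec]


def _resolve_mod(mod: ModLike) -> ModificationSpec:
    if isinstance(mod, ModificationSpec):
        return mod
    try:
        return MODIFICATIONS[mod]
    except KeyError:
        raise ValueError(f"unknown modification {mod!r}") from None


def span_positions(start: int, end: int) -> list:
    """Coordinates covered by [start, end], skipping the nonexistent 0."""
    if start == 0 or end == 0:
        raise ValueError("position 0 does not exist in A-beta numbering")
    if start > end:
        raise ValueError(f"start {start} > end {end}")
    return [p for p in range(start, end + 1) if p != 0]


def span_length(start: int, end: int) -> int:
    """Number of residues in the coordinate span [start, end]."""
    return len(span_positions(start, end))


@dataclass(frozen=True)
class ResidueSequence:
    """A peptide in A-beta coordinates."""

    residues: str
    species: Species
    start_position: int = 1

    def __post_init__(self):
        bad = set(self.residues) - AMINO_ACIDS
        if bad:
            raise ValueError(f"non-standard residues: {sorted(bad)}")
        if not self.residues:
            raise ValueError("empty residue string")
        if self.start_position == 0:
            raise ValueError("position 0 does not exist in A-beta numbering")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def positions(self) -> list:
        """A-beta coordinate for each residue, in order."""
        out = []
        p = self.start_position
        for _ in self.residues:
            out.append(p)
            p = 1 if p == -1 else p + 1
        return out

    @property
    def end_position(self) -> int:
        return self.positions[-1]

    def residue_at(self, position: int) -> str:
        try:
            return self.residues[self.positions.index(position)]
        except ValueError:
            raise ValueError(
                f"position {position} outside span "
                f"{self.start_position}..{self.end_position}"
            ) from None


def residue_at(species: Union[Species, str], position: int) -> str:
    """The canonical residue at an A-beta coordinate for the given species."""
    species = Species(species)
    if position == -1:
        return _PRE_MET
    ref = _HUMAN_1_43 if species is Species.human else _MURINE_1_43
    if not 1 <= position <= MAX_POSITION:
        raise ValueError(
            f"position {position} outside supported range "
            f"[{MIN_POSITION}, {MAX_POSITION}]"
        )
    return ref[position - 1]


def get_sequence(
    species: Union[Species, str], start: int, end: int
) -> ResidueSequence:
    """Canonical A-beta sub-sequence between two coordinates (inclusive).

    Positions 1-16 are species specific; 17-43 are shared between human and
    murine A-beta; -1 denotes the Met preceding D1.
    """
    species = Species(species)
    if start > end:
        raise ValueError(f"empty range: start {start} > end {end}")
    if start < MIN_POSITION:
        raise ValueError(f"start {start} below minimum position {MIN_POSITION}")
    if end > MAX_POSITION:
        raise ValueError(f"end {end} above maximum position {MAX_POSITION}")
    residues = "".join(
        residue_at(species, p) for p in span_positions(start, end)
    )
    return ResidueSequence(residues, species, start)


def classify_peptide(residues: str) -> str:
    """Classify a peptide as 'human', 'murine', 'shared', or 'unknown'.

    A peptide matching only the human reference (including M(-1)) is human;
    only the murine reference, murine; both (i.e. lying entirely within the
    identical 17-43 region, or trivially short) is 'shared'; neither is
    'unknown'.
    """
    if not residues:
        raise ValueError("empty peptide")
    in_human = residues in _PRE_MET + _HUMAN_1_43
    in_murine = residues in _PRE_MET + _MURINE_1_43
    if in_human and in_murine:
        return "shared"
    if in_human:
        return "human"
    if in_murine:
        return "murine"
    return "unknown"


@dataclass(frozen=True)
class FragmentIon:
    """A singly/multiply protonated b- or y-series fragment ion."""

    series: str
    index: int
    charge: int
    mz: float
    modifications: tuple = ()

    def __post_init__(self):
        if self.series not in ("b", "y"):
            raise ValueError(f"unsupported ion series {self.series!r}")
        if self.index < 1:
            raise ValueError("fragment index must be >= 1")
        if self.charge < 1:
            raise ValueError("charge must be >= 1")

    @property
    def label(self) -> str:
        suffix = "" if self.charge == 1 else f"^{self.charge}"
        return f"{self.series}{self.index}{suffix}"


def _validate_mods(
    seq: ResidueSequence, mods: Iterable
) -> list:
    """Resolve and positionally validate (position, modification) pairs."""
    resolved = []
    for position, mod in mods:
        spec = _resolve_mod(mod)
        residue = seq.residue_at(position)
        if residue not in spec.target_residues:
            raise ValueError(
                f"{spec.name} not allowed on residue {residue!r} at "
                f"position {position} (targets "
                f"{sorted(spec.target_residues)})"
            )
        if (
            spec.positional_rule is PositionalRule.peptide_nterm_only
            and position != seq.start_position
        ):
            raise ValueError(
                f"{spec.name} only allowed at the peptide N-terminus "
                f"(position {seq.start_position}), got {position}"
            )
        resolved.append((position, spec))
    return resolved


def fragment_mz(
    seq: ResidueSequence,
    series: str,
    index: int,
    mods: Iterable = (),
    charge: int = 1,
) -> float:
    """Monoisotopic m/z of the b- or y-ion of the given index.

    b_n = sum of the first n residue masses + charge protons;
    y_n = sum of the last n residue masses + water + charge protons.
    Modification deltas are added when the modified position falls inside
    the fragment.
    """
    length = len(seq)
    if not 1 <= index < length:
        raise ValueError(
            f"fragment index must be in [1, {length - 1}], got {index}"
        )
    resolved = _validate_mods(seq, mods)
    positions = seq.positions
    if series == "b":
        covered = positions[:index]
        residues = seq.residues[:index]
        extra = 0.0
    elif series == "y":
        covered = positions[-index:]
        residues = seq.residues[-index:]
        extra = WATER_MASS
    else:
        raise ValueError(f"unsupported ion series {series!r}")
    covered_set = set(covered)
    mass = sum(RESIDUE_MASSES[r] for r in residues) + extra
    mass += sum(s.mono_delta for p, s in resolved if p in covered_set)
    return (mass + charge * PROTON_MASS) / charge


def precursor_mh(seq: ResidueSequence, mods: Iterable = ()) -> float:
    """Singly protonated precursor mass MH+ including modification deltas."""
    resolved = _validate_mods(seq, mods)
    mass = sum(RESIDUE_MASSES[r] for r in seq.residues) + WATER_MASS
    mass += sum(s.mono_delta for _, s in resolved)
    return mass + PROTON_MASS


def theoretical_ladder(
    seq: ResidueSequence, mods: Iterable = (), charge: int = 1
) -> list:
    """All b_1..b_{L-1} and y_1..y_{L-1} ions of a peptide, sorted by m/z.

    Every complementary pair satisfies mz(b_n) + mz(y_{L-n}) = MH+ + proton
    for singly charged ions.
    """
    resolved = tuple(_validate_mods(seq, mods))
    length = len(seq)
    positions = seq.positions
    ions = []
    for series in ("b", "y"):
        for index in range(1, length):
            covered = (
                set(positions[:index]) if series == "b"
                else set(positions[-index:])
            )
            ion_mods = tuple(
                (p, s.name) for p, s in resolved if p in covered
            )
            ions.append(
                FragmentIon(
                    series,
                    index,
                    charge,
                    fragment_mz(seq, series, index, resolved, charge),
                    ion_mods,
                )
            )
    ions.sort(key=lambda ion: ion.mz)
    return ions


def constants_as_json() -> str:
    """Sequence and modification constants, serialized for documentation."""
    payload = {
        "human_1_43": _HUMAN_1_43,
        "murine_1_43": _MURINE_1_43,
        "pre_met": _PRE_MET,
        "proton_mass": PROTON_MASS,
        "water_mass": WATER_MASS,
        "residue_masses": dict(RESIDUE_MASSES),
        "modifications": {
            name: {
                "target_residues": sorted(spec.target_residues),
                "mono_delta": spec.mono_delta,
                "positional_rule": spec.positional_rule.value,
            }
            for name, spec in MODIFICATIONS.items()
        },
    }
    return json.dumps(payload, indent=2, sort_keys=True)
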