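"""Independent brute-force oracles used to cross-check the package.

These deliberately avoid the code paths they validate: fragment masses are
re-derived from elemental compositions and math.fsum, and the rank
statistics are computed by exhaustive pair/permutation enumeration.
"""

from __future__ import annotations

import itertools
import math
from math import fsum

# monoisotopic element masses (CODATA-derived standard values)
_H = 1.00782503207
_C = 12.0
_N = 14.0030740048
_O = 15.9949146196
_S = 31.97207100

_PROTON = 1.00727646688

#: residue elemental compositions (C, H, N, O, S)
_COMPOSITIONS = {
    "G": (2, 3, 1, 1, 0),
    "A": (3, 5, 1, 1, 0),
    "S": (3, 5, 1, 2, 0),
    "P": (5, 7, 1, 1, 0),
    "V": (5, 9, 1, 1, 0),
    "T": (4, 7, 1, 2, 0),
    "C": (3, 5, 1, 1, 1),
    "L": (6, 11, 1, 1, 0),
    "I": (6, 11, 1, 1, 0),
    "N": (4, 6, 2, 2, 0),
    "D": (4, 5, 1, 3, 0),
    "Q": (5, 8, 2, 2, 0),
    "K": (6, 12, 2, 1, 0),
    "E": (5, 7, 1, 3, 0),
    "M": (5, 9, 1, 1, 1),
    "H": (6, 7, 3, 1, 0),
    "F": (9, 9, 1, 1, 0),
    "R": (6, 12, 4, 1, 0),
    "Y": (9, 9, 1, 2, 0),
    "W": (11, 10, 2, 1, 0),
}


def residue_mass(residue: str) -> float:
    c, h, n, o, s = _COMPOSITIONS[residue]
    return fsum((c * _C, h * _H, n * _N, o * _O, s * _S))


WATER = 2 * _H + _O
PROTON = _PROTON


def fragment_mz_oracle(
    residues: str,
    series: str,
    index: int,
    mod_deltas=(),
    charge: int = 1,
) -> float:
    """b/y fragment m/z by direct summation.

    ``mod_deltas`` is a list of (residue_index_0based, delta_da) already
    resolved to mass shifts; deltas on residues inside the fragment are
    added.
    """
    if series == "b":
        covered = range(index)
        extra = 0.0
    else:
        covered = range(len(residues) - index, len(residues))
        extra = WATER
    terms = [residue_mass(residues[i]) for i in covered]
    terms.append(extra)
    terms.extend(d for i, d in mod_deltas if i in set(covered))
    terms.append(charge * PROTON)
    return fsum(terms) / charge


def precursor_mh_oracle(residues: str, mod_deltas=()) -> float:
    terms = [residue_mass(r) for r in residues]
    terms.append(WATER)
    terms.extend(d for _, d in mod_deltas)
    terms.append(PROTON)
    return fsum(terms)


def kendall_tau_b_oracle(x, y):
    """Tau-b by exhaustive pair enumeration with tie correction."""
    n = len(x)
    concordant = discordant = 0
    ties_x = ties_y = 0
    for i, j in itertools.combinations(range(n), 2):
        dx = x[i] - x[j]
        dy = y[i] - y[j]
        if dx == 0 and dy == 0:
            ties_x += 1
            ties_y += 1
        elif dx == 0:
            ties_x += 1
        elif dy == 0:
            ties_y += 1
        elif dx * dy > 0:
            concordant += 1
        else:
            discordant += 1
    n0 = n * (n - 1) // 2
    denom = math.sqrt((n0 - ties_x) * (n0 - ties_y))
    if denom == 0:
        return float("nan")
    return (concordant - discordant) / denom


def kendall_exact_p_oracle(x, y):
    """Exact two-sided permutation p-value of |tau| (tie-free inputs only)."""
    observed = abs(kendall_tau_b_oracle(x, y))
    count = 0
    total = 0
    for perm in itertools.permutations(y):
        total += 1
        if abs(kendall_tau_b_oracle(x, perm)) >= observed - 1e-12:
            count += 1
    return count / total


def mann_whitney_u_oracle(a, b):
    """U as the count of (a < b) pairs, ties counted one half."""
    u = 0.0
    for x in a:
        for y in b:
            if x < y:
                u += 1.0
            elif x == y:
                u += 0.5
    return u


def mann_whitney_exact_p_oracle(a, b):
    """Exact two-sided p by enumerating all group assignments (tie-free)."""
    pooled = list(a) + list(b)
    n_a = len(a)
    observed = mann_whitney_u_oracle(a, b)
    mu = n_a * len(b) / 2.0
    count = total = 0
    for combo in itertools.combinations(range(len(pooled)), n_a):
        total += 1
        group_a = [pooled[i] for i in combo]
        group_b = [pooled[i] for i in range(len(pooled)) if i not in combo]
        u = mann_whitney_u_oracle(group_a, group_b)
        if abs(u - mu) >= abs(observed - mu) - 1e-12:
            count += 1
    return count / total
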