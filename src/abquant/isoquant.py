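"""Label-free isoAsp7 quantification from marker/base fragment-ion intensity ratios.

Asp7 isomerization is mass silent, but it enhances backbone cleavage near
the modified residue, raising the intensities of the b6, b7 and y10 ions of
the A-beta(1-16) peptide relative to iso-insensitive "base" ions (b11, y11).
The ratio marker/base therefore encodes the isomerized fraction, and a
calibration curve built from designed binary norm/iso mixtures converts an
observed ratio into a percentage by inverse prediction.

Calibration functional form: for a binary mixture in which the base-ion
yield is the same for both species, the expected marker/base ratio is a
linear function of the mixed fraction, so the default fit is ordinary least
squares. When replicate-mean ratios are non-monotone beyond what the linear
residual scatter explains, a shape-constrained monotone interpolant
(isotonic means + PCHIP) is used instead.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.optimize import isotonic_regression
from scipy.stats import norm

from .reference import Species, get_sequence, theoretical_ladder
from .spectra import (
    DEFAULT_FRAGMENT_TOLERANCE_DA,
    FragmentMatchSet,
    Spectrum,
    match_fragments,
)

__all__ = [
    "MARKER_LABELS",
    "BASE_LABELS",
    "DEFAULT_MARKER",
    "DEFAULT_BASE",
    "RatioMeasurement",
    "CalibrationCurve",
    "IsoEstimate",
    "MatrixEffectReport",
    "marker_ratio",
    "fit_calibration",
    "predict_fraction",
    "estimate_sample",
    "matrix_effect_check",
]

#: Fragment ions of A-beta(1-16) whose intensity is enhanced by isoAsp7.
MARKER_LABELS = ("b6", "b7", "y10")
#: Fragment ions insensitive to Asp7 isomerization.
BASE_LABELS = ("b11", "y11")
DEFAULT_MARKER = "b6"
DEFAULT_BASE = "b11"

_GRID = np.linspace(0.0, 100.0, 2001)


@dataclass(frozen=True)
class RatioMeasurement:
    sample_id: str
    marker: str
    base: str
    ratio: float
    n_spectra: int = 1
    ratio_sd: float = 0.0

    def __post_init__(self):
        if self.marker not in MARKER_LABELS:
            raise ValueError(
                f"marker must be one of {MARKER_LABELS}, got {self.marker!r}"
            )
        if self.base not in BASE_LABELS:
            raise ValueError(
                f"base must be one of {BASE_LABELS}, got {self.base!r}"
            )
        if not np.isfinite(self.ratio) or self.ratio < 0:
            raise ValueError(f"ratio must be finite and >= 0, got {self.ratio}")
        if self.n_spectra < 1:
            raise ValueError("n_spectra must be >= 1")
        if self.ratio_sd < 0:
            raise ValueError("ratio_sd must be >= 0")


@dataclass
class CalibrationCurve:
    """Fitted ratio-vs-fraction relation over a binary mixture design."""

    design_fractions: np.ndarray
    mean_ratios: np.ndarray
    slope: float
    intercept: float
    fit_kind: str  # "linear" | "monotone"
    residual_sd: float
    points: np.ndarray = field(repr=False)  # (n, 2): fraction_pct, ratio
    marker: str = DEFAULT_MARKER
    base: str = DEFAULT_BASE
    _interp: Optional[PchipInterpolator] = field(
        default=None, repr=False, compare=False
    )

    def predict_ratio(self, fraction_pct) -> np.ndarray:
        fraction_pct = np.asarray(fraction_pct, dtype=float)
        if self.fit_kind == "linear":
            return self.slope * fraction_pct + self.intercept
        return self._interp(np.clip(fraction_pct, 0.0, 100.0))

    def local_slope(self, fraction_pct: float) -> float:
        if self.fit_kind == "linear":
            return self.slope
        return float(self._interp.derivative()(np.clip(fraction_pct, 0, 100)))

    def to_json(self, path: Union[str, Path, None] = None) -> str:
        payload = {
            "design_fractions": self.design_fractions.tolist(),
            "mean_ratios": self.mean_ratios.tolist(),
            "slope": self.slope,
            "intercept": self.intercept,
            "fit_kind": self.fit_kind,
            "residual_sd": self.residual_sd,
            "points": self.points.tolist(),
            "marker": self.marker,
            "base": self.base,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: Union[str, Path]) -> "CalibrationCurve":
        path = Path(source)
        text = path.read_text() if path.exists() else str(source)
        payload = json.loads(text)
        curve = cls(
            design_fractions=np.asarray(payload["design_fractions"], float),
            mean_ratios=np.asarray(payload["mean_ratios"], float),
            slope=payload["slope"],
            intercept=payload["intercept"],
            fit_kind=payload["fit_kind"],
            residual_sd=payload["residual_sd"],
            points=np.asarray(payload["points"], float),
            marker=payload.get("marker", DEFAULT_MARKER),
            base=payload.get("base", DEFAULT_BASE),
        )
        if curve.fit_kind == "monotone":
            curve._interp = _monotone_interpolant(
                curve.design_fractions, curve.mean_ratios
            )
        return curve


@dataclass(frozen=True)
class IsoEstimate:
    """Inverse-predicted isoAsp7 percentage for one sample."""

    fraction_pct: float
    sd_pct: float
    n_spectra: int
    marker_used: str = DEFAULT_MARKER
    clamped: bool = False
    sample_id: str = ""
    mean_ratio: float = float("nan")
    ratio_sd: float = float("nan")

    def __post_init__(self):
        if not 0.0 <= self.fraction_pct <= 100.0:
            raise ValueError("fraction_pct must lie in [0, 100]")
        if self.sd_pct < 0:
            raise ValueError("sd_pct must be >= 0")


def marker_ratio(
    matches: FragmentMatchSet,
    marker: str = DEFAULT_MARKER,
    base: str = DEFAULT_BASE,
) -> float:
    """Intensity ratio marker/base from one matched spectrum."""
    if marker not in MARKER_LABELS:
        raise ValueError(f"marker must be one of {MARKER_LABELS}")
    if base not in BASE_LABELS:
        raise ValueError(f"base must be one of {BASE_LABELS}")
    base_peak = matches.peak_for(base)
    if base_peak is None or base_peak.intensity <= 0:
        raise ValueError(f"base fragment missing: {base} unmatched or zero")
    marker_peak = matches.peak_for(marker)
    if marker_peak is None:
        warnings.warn(
            f"marker fragment {marker} unmatched; ratio set to 0",
            stacklevel=2,
        )
        return 0.0
    return marker_peak.intensity / base_peak.intensity


def _monotone_interpolant(
    fractions: np.ndarray, means: np.ndarray
) -> PchipInterpolator:
    iso = isotonic_regression(means).x
    # PCHIP needs strictly increasing ordinates for a usable inverse; nudge
    # flat isotonic blocks by a negligible epsilon.
    eps = max(1e-12, 1e-9 * (iso.max() - iso.min() + 1.0))
    iso = iso + eps * np.arange(iso.size)
    return PchipInterpolator(fractions, iso)


def fit_calibration(
    measurements: Iterable[Tuple[float, float]],
    marker: str = DEFAULT_MARKER,
    base: str = DEFAULT_BASE,
) -> CalibrationCurve:
    """Fit the ratio-vs-fraction calibration from (fraction_pct, ratio) pairs.

    Requires >= 3 distinct design fractions spanning >= 50 percentage
    points. Default fit: ordinary least squares line. If the replicate-mean
    ratios are non-monotone beyond the linear residual scatter, a monotone
    interpolant through isotonic-regressed means is used instead
    (``fit_kind == "monotone"``). A non-positive fitted slope under both
    routes is rejected as non-informative.
    """
    points = np.asarray(list(measurements), dtype=float)
    if points.ndim != 2 or points.shape[1] != 2:
        raise ValueError("measurements must be (fraction_pct, ratio) pairs")
    fractions = points[:, 0]
    ratios = points[:, 1]
    if np.any((fractions < 0) | (fractions > 100)):
        raise ValueError("design fractions must lie in [0, 100]")
    unique = np.unique(fractions)
    if unique.size < 3:
        raise ValueError(
            f"need >= 3 distinct design fractions, got {unique.size}"
        )
    if unique.max() - unique.min() < 50:
        raise ValueError(
            "design must span >= 50 percentage points, got "
            f"{unique.max() - unique.min():.1f}"
        )
    means = np.array([ratios[fractions == f].mean() for f in unique])
    reps = np.array([(fractions == f).sum() for f in unique])

    slope, intercept = np.polyfit(fractions, ratios, 1)
    fitted = slope * fractions + intercept
    dof = max(points.shape[0] - 2, 1)
    residual_sd = float(np.sqrt(np.sum((ratios - fitted) ** 2) / dof))

    # largest decrease between any ordered pair of design means, compared
    # against the pure (within-replicate) noise; the linear residual SD is
    # only used as a proxy when the design has no replicates, because it
    # also absorbs lack-of-fit.
    drops = means[:, None] - means[None, :]
    max_drop = float(np.triu(drops, k=1).max(initial=0.0))
    if np.any(reps > 1):
        pooled_ss = sum(
            np.sum((ratios[fractions == f] - m) ** 2)
            for f, m in zip(unique, means)
        )
        pure_dof = int(np.sum(reps - 1))
        pure_sd = float(np.sqrt(pooled_ss / max(pure_dof, 1)))
    else:
        pure_sd = residual_sd
    noise_allowance = 3.0 * pure_sd * np.sqrt(2.0 / max(reps.min(), 1))
    monotone_needed = max_drop > max(noise_allowance, 1e-12)

    # the line is informative only if it rises meaningfully over the design
    scale = max(float(np.abs(ratios).max()), 1e-12)
    span = unique.max() - unique.min()
    informative_linear = slope * span > 1e-9 * scale

    fit_kind = "linear"
    interp = None
    if monotone_needed or not informative_linear:
        iso_means = isotonic_regression(means).x
        if iso_means[-1] - iso_means[0] <= 1e-9 * scale:
            raise ValueError(
                "non-monotone calibration: ratios carry no increasing trend "
                f"(fitted slope {slope:.3g})"
            )
        interp = _monotone_interpolant(unique, means)
        fit_kind = "monotone"
        fitted = interp(fractions)
        residual_sd = float(
            np.sqrt(np.sum((ratios - fitted) ** 2) / dof)
        )
    return CalibrationCurve(
        design_fractions=unique,
        mean_ratios=means,
        slope=float(slope),
        intercept=float(intercept),
        fit_kind=fit_kind,
        residual_sd=residual_sd,
        points=points,
        marker=marker,
        base=base,
        _interp=interp,
    )


def predict_fraction(
    curve: CalibrationCurve,
    ratio: float,
    n_spectra: int = 1,
    ratio_sem: float = 0.0,
    sample_id: str = "",
    ratio_sd: float = float("nan"),
) -> IsoEstimate:
    """Invert the calibration: observed ratio -> isoAsp7 percentage.

    Predictions outside [0, 100] are clamped (a fraction is physically
    bounded) and flagged. The SD combines the curve residual scatter and the
    standard error of the observed ratio, both propagated through the local
    inverse slope.
    """
    if curve.fit_kind == "linear":
        raw = (ratio - curve.intercept) / curve.slope
    else:
        grid_ratio = curve.predict_ratio(_GRID)
        raw = float(np.interp(ratio, grid_ratio, _GRID))
        if ratio < grid_ratio[0]:
            raw = -1.0  # force the clamp flag below
        elif ratio > grid_ratio[-1]:
            raw = 101.0
    clamped = not 0.0 <= raw <= 100.0
    fraction = float(np.clip(raw, 0.0, 100.0))
    slope = abs(curve.local_slope(fraction))
    if slope <= 0:
        slope = abs(curve.slope) or 1e-12
    sd = float(np.hypot(curve.residual_sd, ratio_sem) / slope)
    return IsoEstimate(
        fraction_pct=fraction,
        sd_pct=sd,
        n_spectra=n_spectra,
        marker_used=curve.marker,
        clamped=clamped,
        sample_id=sample_id,
        mean_ratio=ratio,
        ratio_sd=ratio_sd,
    )


def estimate_sample(
    spectra: Sequence[Spectrum],
    curve: CalibrationCurve,
    marker: str = DEFAULT_MARKER,
    base: str = DEFAULT_BASE,
    tolerance_da: float = DEFAULT_FRAGMENT_TOLERANCE_DA,
    species: Union[Species, str] = Species.human,
    averaging: str = "mean_of_ratios",
) -> IsoEstimate:
    """Estimate a sample's isoAsp7 percentage from its replicate MS/MS spectra.

    Default averaging follows the mean-of-per-spectrum-ratios convention
    (one ratio per replicate spectrum, then the arithmetic mean is
    inverse-predicted). ``averaging="ratio_of_sums"`` instead accumulates
    all replicates into one spectrum and ratios the summed intensities.
    """
    if not spectra:
        raise ValueError("estimate_sample requires at least one spectrum")
    if averaging not in ("mean_of_ratios", "ratio_of_sums"):
        raise ValueError(f"unknown averaging mode {averaging!r}")
    seq = get_sequence(species, 1, 16)
    ladder = theoretical_ladder(seq)
    if averaging == "ratio_of_sums":
        from .spectra import accumulate

        pooled = accumulate(list(spectra), bin_tolerance_da=tolerance_da)
        pooled_matches = match_fragments(pooled, ladder, tolerance_da)
        ratios = [marker_ratio(pooled_matches, marker, base)]
    else:
        ratios = []
        failures = 0
        for spectrum in spectra:
            matches = match_fragments(spectrum, ladder, tolerance_da)
            try:
                ratios.append(marker_ratio(matches, marker, base))
            except ValueError:
                failures += 1
        if not ratios:
            raise ValueError(
                f"base fragment missing: {base} unmatched in all "
                f"{failures} spectra"
            )
    ratios = np.asarray(ratios)
    mean_ratio = float(ratios.mean())
    ratio_sd = float(ratios.std(ddof=1)) if ratios.size > 1 else 0.0
    ratio_sem = ratio_sd / np.sqrt(ratios.size)
    return predict_fraction(
        curve,
        mean_ratio,
        n_spectra=len(spectra),
        ratio_sem=ratio_sem,
        sample_id=spectra[0].sample_id,
        ratio_sd=ratio_sd,
    )


def _ols_with_se(x: np.ndarray, y: np.ndarray):
    n = x.size
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    s2 = np.sum(resid**2) / max(n - 2, 1)
    sxx = np.sum((x - x.mean()) ** 2)
    se_slope = np.sqrt(s2 / sxx)
    se_intercept = np.sqrt(s2 * (1.0 / n + x.mean() ** 2 / sxx))
    return slope, intercept, se_slope, se_intercept


@dataclass
class MatrixEffectReport:
    """Pairwise slope/intercept comparison across calibration conditions."""

    comparisons: list  # dicts with indices, deltas, p-values
    alpha: float
    comparable: bool

    def __str__(self) -> str:
        verdict = "comparable" if self.comparable else "different"
        lines = [f"matrix-effect check (alpha={self.alpha}): {verdict}"]
        for c in self.comparisons:
            lines.append(
                f"  curves {c['pair'][0]} vs {c['pair'][1]}: "
                f"d_slope={c['slope_delta']:.4g} (p={c['slope_p']:.3g}), "
                f"d_intercept={c['intercept_delta']:.4g} "
                f"(p={c['intercept_p']:.3g})"
            )
        return "\n".join(lines)


def matrix_effect_check(
    curves: Sequence[CalibrationCurve], alpha: float = 0.05
) -> MatrixEffectReport:
    """Test whether calibration curves from different backgrounds agree.

    For every pair of curves the OLS slope and intercept differences are
    z-tested against their combined standard errors. The verdict is
    "comparable" when no comparison is significant at ``alpha``.
    """
    if len(curves) < 2:
        raise ValueError("matrix_effect_check requires >= 2 curves")
    design = curves[0].design_fractions
    for i, curve in enumerate(curves[1:], start=1):
        if (
            curve.design_fractions.size != design.size
            or not np.allclose(curve.design_fractions, design)
        ):
            raise ValueError(
                f"mismatched designs: curve 0 vs curve {i} use different "
                "fraction grids"
            )
    fits = [
        _ols_with_se(c.points[:, 0], c.points[:, 1]) for c in curves
    ]
    comparisons = []
    comparable = True
    for i in range(len(curves)):
        for j in range(i + 1, len(curves)):
            s_i, b_i, se_si, se_bi = fits[i]
            s_j, b_j, se_sj, se_bj = fits[j]
            slope_se = np.hypot(se_si, se_sj)
            intercept_se = np.hypot(se_bi, se_bj)
            z_slope = (s_i - s_j) / slope_se if slope_se > 0 else 0.0
            z_int = (b_i - b_j) / intercept_se if intercept_se > 0 else 0.0
            p_slope = float(2 * norm.sf(abs(z_slope)))
            p_int = float(2 * norm.sf(abs(z_int)))
            if p_slope < alpha or p_int < alpha:
                comparable = False
            comparisons.append(
                {
                    "pair": (i, j),
                    "slope_delta": float(s_i - s_j),
                    "slope_p": p_slope,
                    "intercept_delta": float(b_i - b_j),
                    "intercept_p": p_int,
                }
            )
    return MatrixEffectReport(
        comparisons=comparisons, alpha=alpha, comparable=comparable
    )
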