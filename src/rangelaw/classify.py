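"""Decay-type classification of exceedance curves.

Each of the three decay models is linear in one coordinate system: linear
decay in the plain plot, exponential decay in the semilog plot (log10 of the
proportion), and power-law decay in the log-log plot.  The test transforms a
trimmed exceedance curve into each candidate coordinate system, fits a
straight line by ordinary least squares, and picks the transform with the
highest coefficient of determination.

For duration curves there are three candidates.  For range curves the plain
and semilog fits are run separately against range width (km) and range area
(km^2), while the log-log fit collapses the two axes (log area is an affine
function of log width, and R^2 is invariant under affine changes of x), so
there are five candidates rather than six.

Labels follow the field's shorthand: LAW = Type II / memoryless decay (Van
Valen's law), Pln = Type I / plain-linear decay, Pow = Type III / power law.
A "2" suffix marks a best fit on the area axis rather than the width axis;
parentheses in formatted output mark a statistically weak best fit
(R^2 < 0.9).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .curves import FittingCurve

COORDS = ("plain", "semilog", "loglog")
AXES = ("duration", "width", "area")

WEAK_R2 = 0.9
R2_TIE_TOL = 1e-9

#: Map from decay label to survivorship-curve type number.
LABEL_TYPES = {"Pln": "I", "Pln2": "I", "LAW": "II", "LAW2": "II", "Pow": "III"}


class InsufficientDataError(ValueError):
    """Raised when a fit is attempted on too few points."""


@dataclass(frozen=True)
class Transform:
    """A candidate coordinate system: plain/semilog/loglog on a given axis."""

    coords: str
    axis: str

    def __post_init__(self):
        if self.coords not in COORDS:
            raise ValueError(f"unknown coords {self.coords!r}")
        if self.axis not in AXES:
            raise ValueError(f"unknown axis {self.axis!r}")

    def __str__(self) -> str:
        return f"{self.coords}-{self.axis}"


@dataclass(frozen=True)
class FitResult:
    transform: Transform
    slope: float
    intercept: float
    r2: float
    n_points: int


@dataclass(frozen=True)
class DecayClass:
    """Outcome of the best-transform test for one curve.

    label is one of LAW / LAW2 / Pln / Pln2 / Pow / insufficient; weak flags
    a best fit with R^2 < 0.9.
    """

    label: str
    weak: bool
    fits: tuple[FitResult, ...] = field(default=())
    best: FitResult | None = None

    @property
    def formatted(self) -> str:
        """Table-style rendering: parentheses when weak, dash when missing."""
        if self.label == "insufficient":
            return "-"
        return f"({self.label})" if self.weak else self.label


def _axis_values(curve: FittingCurve, axis: str) -> np.ndarray:
    """Thresholds of ``curve`` converted to the requested axis."""
    t = curve.thresholds
    kind = curve.axis_kind
    if axis == "duration":
        if kind != "duration_My":
            raise ValueError(f"axis 'duration' incompatible with curve axis {kind}")
        return t
    if kind == "duration_My":
        raise ValueError(f"axis {axis!r} incompatible with a duration curve")
    if axis == "width":
        return t if kind == "width_km" else np.sqrt(t)
    # axis == "area"
    return t if kind == "area_km2" else np.square(t)


def transform_curve(curve: FittingCurve, transform: Transform):
    """Project a trimmed curve into a candidate coordinate system.

    Returns ``(x, y)`` arrays ready for straight-line fitting.  Proportions
    must lie strictly in (0, 1); thresholds must be strictly positive when a
    log is taken of the x axis.
    """
    p = curve.proportions
    if np.any(p <= 0) or np.any(p >= 1):
        raise ValueError("proportions must be strictly inside (0, 1); trim the curve first")
    x = _axis_values(curve, transform.axis)
    if transform.coords == "plain":
        return x, p.copy()
    if transform.coords == "semilog":
        return x, np.log10(p)
    if np.any(x <= 0):
        raise ValueError("log-log transform requires strictly positive thresholds")
    return np.log10(x), np.log10(p)


def ols_fit(x, y, transform: Transform | None = None) -> FitResult:
    """Ordinary least squares straight-line fit with R^2.

    R^2 is 1 - SS_res/SS_tot.  A response with zero variance is assigned
    R^2 = 0 (no explanatory power) rather than the indeterminate 0/0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise InsufficientDataError(f"need at least 3 points, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in x; cannot fit a line")
    if np.ptp(y) == 0:
        return FitResult(transform=transform, slope=0.0, intercept=float(y[0]),
                         r2=0.0, n_points=x.size)
    res = stats.linregress(x, y)
    return FitResult(transform=transform, slope=float(res.slope),
                     intercept=float(res.intercept),
                     r2=float(res.rvalue) ** 2, n_points=x.size)


def fit_transform(curve: FittingCurve, transform: Transform) -> FitResult:
    x, y = transform_curve(curve, transform)
    return ols_fit(x, y, transform)


# Candidate transforms in tie-break priority order (semilog, then plain,
# then loglog; width before area), with their labels.
DURATION_CANDIDATES = (
    (Transform("semilog", "duration"), "LAW"),
    (Transform("plain", "duration"), "Pln"),
    (Transform("loglog", "duration"), "Pow"),
)
RANGE_CANDIDATES = (
    (Transform("semilog", "width"), "LAW"),
    (Transform("semilog", "area"), "LAW2"),
    (Transform("plain", "width"), "Pln"),
    (Transform("plain", "area"), "Pln2"),
    (Transform("loglog", "width"), "Pow"),
)


def _classify(curve: FittingCurve, candidates) -> DecayClass:
    if not curve.sufficient or len(curve) < 3:
        return DecayClass(label="insufficient", weak=False)
    fits = []
    best_fit = None
    best_label = None
    for transform, label in candidates:
        fit = fit_transform(curve, transform)
        fits.append(fit)
        # a later candidate wins only if strictly better beyond the tie
        # tolerance, biasing ties toward the memoryless null
        if best_fit is None or fit.r2 > best_fit.r2 + R2_TIE_TOL:
            best_fit, best_label = fit, label
    return DecayClass(label=best_label, weak=best_fit.r2 < WEAK_R2,
                      fits=tuple(fits), best=best_fit)


def classify_duration_curve(curve: FittingCurve) -> DecayClass:
    """Best-transform test for a survivorship (duration) curve."""
    return _classify(curve, DURATION_CANDIDATES)


def classify_range_curve(curve: FittingCurve) -> DecayClass:
    """Best-transform test for a range-expansion curve over five candidates."""
    if curve.axis_kind == "duration_My":
        raise ValueError("classify_range_curve requires a range-axis curve")
    return _classify(curve, RANGE_CANDIDATES)


def fits_to_frame(decay: DecayClass):
    """Per-transform fit report as a table."""
    import pandas as pd

    rows = [{
        "transform": str(f.transform),
        "slope": f.slope,
        "intercept": f.intercept,
        "r2": f.r2,
        "n_points": f.n_points,
        "best": f is decay.best,
    } for f in decay.fits]
    return pd.DataFrame(rows)
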