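"""Exceedance (survivorship / expansion) curve assembly.

A survivorship curve plots, for each duration threshold, the proportion of
taxa that persisted strictly longer than that threshold.  An expansion curve
is the spatial analogue: the proportion of taxa whose maximum range size
strictly exceeds each range threshold.  Both are complementary cumulative
distributions evaluated at the observed unique values, with a strict
greater-than count so that singleton taxa (duration or range exactly zero)
contribute a leading row at threshold zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

AXIS_KINDS = ("duration_My", "width_km", "area_km2")

DEFAULT_MIN_POINTS = 10


@dataclass(frozen=True)
class ExceedanceCurve:
    """Proportion of taxa exceeding each observed unique threshold.

    Attributes
    ----------
    axis_kind : str
        One of ``duration_My``, ``width_km``, ``area_km2``.
    thresholds : np.ndarray
        Strictly increasing unique observed values.  The first threshold is
        the minimum observed value.
    proportions : np.ndarray
        ``count(values > threshold) / n_total`` for each threshold; strictly
        decreasing, ending at 0.
    n_total : int
        Number of taxa the proportions are normalised by.  Taxa with zero
        duration or range stay in this denominator even though they never
        appear as a positive threshold.
    """

    axis_kind: str
    thresholds: np.ndarray
    proportions: np.ndarray
    n_total: int

    def __len__(self) -> int:  # number of rows
        return len(self.thresholds)


@dataclass(frozen=True)
class FittingCurve:
    """An exceedance curve with its first and last rows discarded.

    The first row is dropped because the leading zero threshold is an
    artifact of singletons, and the last because its proportion is exactly
    zero (undefined under log transforms).  ``sufficient`` records whether
    enough rows remain for a meaningful fit.
    """

    axis_kind: str
    thresholds: np.ndarray
    proportions: np.ndarray
    n_total: int
    sufficient: bool

    def __len__(self) -> int:
        return len(self.thresholds)


def exceedance_curve(values, axis_kind: str) -> ExceedanceCurve:
    """Build the exceedance curve of ``values``.

    Thresholds are the sorted unique values; the proportion at threshold *t*
    is the fraction of all values strictly greater than *t*.

    Parameters
    ----------
    values : array-like of nonnegative floats
        Per-taxon durations (My) or range sizes (km or km^2).
    axis_kind : str
        Which quantity the values measure (``duration_My``, ``width_km`` or
        ``area_km2``).
    """
    if axis_kind not in AXIS_KINDS:
        raise ValueError(f"unknown axis_kind {axis_kind!r}; expected one of {AXIS_KINDS}")
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot build an exceedance curve from no values")
    if np.any(~np.isfinite(v)) or np.any(v < 0):
        raise ValueError("values must be finite and nonnegative")
    v_sorted = np.sort(v)
    thresholds = np.unique(v_sorted)
    n = v.size
    # count(values > t) via right-bisection into the sorted sample
    exceed = n - np.searchsorted(v_sorted, thresholds, side="right")
    proportions = exceed / n
    return ExceedanceCurve(axis_kind=axis_kind, thresholds=thresholds,
                           proportions=proportions, n_total=n)


def trim_for_fitting(curve: ExceedanceCurve,
                     min_points: int = DEFAULT_MIN_POINTS) -> FittingCurve:
    """Drop the first and last rows of ``curve`` for robust model fitting.

    Raises
    ------
    ValueError
        If the curve has fewer than two rows (nothing can be trimmed).
    """
    if len(curve) < 2:
        raise ValueError("curve must have at least 2 rows to trim")
    thresholds = curve.thresholds[1:-1]
    proportions = curve.proportions[1:-1]
    return FittingCurve(
        axis_kind=curve.axis_kind,
        thresholds=thresholds,
        proportions=proportions,
        n_total=curve.n_total,
        sufficient=len(thresholds) >= min_points,
    )


def curve_to_frame(curve):
    """Two-column tabular view (threshold, proportion) of a curve."""
    import pandas as pd

    return pd.DataFrame({
        "threshold": curve.thresholds,
        "proportion": curve.proportions,
    })


def write_curve_tsv(curve, path) -> None:
    """Serialise a curve as TSV with a small metadata header."""
    frame = curve_to_frame(curve)
    with open(path, "w") as fh:
        fh.write(f"# axis_kind={curve.axis_kind}\tn_total={curve.n_total}\n")
        frame.to_csv(fh, sep="\t", index=False)
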