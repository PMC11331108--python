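"""Per-order analysis pipeline and summary report assembly.

For every taxonomic order (the operational proxy for an adaptive zone) the
pipeline filters the occurrence table, groups taxa at the requested level,
estimates durations and maximum ranges, assembles exceedance curves, trims
them, and classifies the decay type of each curve.  Orders contributing
fewer than ``min_points`` distinct thresholds after trimming are reported
with a dash.  Genus-level and species-level analyses are fully independent
runs over the same table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import occurrences as occ
from .classify import DecayClass, classify_duration_curve, classify_range_curve
from .curves import DEFAULT_MIN_POINTS, exceedance_curve, trim_for_fitting
from .geometry import bounding_box_area, taxon_duration

log = logging.getLogger(__name__)

LEVELS = ("genus", "species")


@dataclass(frozen=True)
class AnalysisConfig:
    levels: tuple = LEVELS
    max_age_span: float = occ.DEFAULT_MAX_AGE_SPAN_MY
    exclusions: tuple = occ.DEFAULT_AQUATIC_EXCLUSIONS
    min_points: int = DEFAULT_MIN_POINTS
    range_method: str = "bounding_box"
    correct_longitude: bool = False


@dataclass
class OrderResult:
    """Decay classes for one order at one level from one source table."""

    order: str
    level: str
    source_kind: str
    n_occurrences: int
    n_taxa: int
    survivorship: DecayClass | None = None
    range_class: DecayClass | None = None
    duration_values: np.ndarray | None = None
    width_values: np.ndarray | None = None


def _insufficient() -> DecayClass:
    return DecayClass(label="insufficient", weak=False)


def _classify_values(values, axis_kind, classifier, min_points) -> DecayClass:
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size == 0:
        return _insufficient()
    curve = exceedance_curve(values, axis_kind)
    try:
        fitting = trim_for_fitting(curve, min_points)
    except ValueError:
        return _insufficient()
    return classifier(fitting)


def prepare_table(table: occ.OccurrenceTable, level: str,
                  config: AnalysisConfig) -> occ.OccurrenceTable:
    """Apply the standard filter cascade for one analysis level."""
    out = occ.filter_identifications(table, level)
    if table.source_kind == "fossil":
        out = occ.filter_age_span(out, config.max_age_span)
    out = occ.exclude_taxa(out, config.exclusions)
    return out


def analyze_order_table(table: occ.OccurrenceTable, level: str,
                        config: AnalysisConfig = AnalysisConfig()) -> list[OrderResult]:
    """Filter, group and classify one source table at one level, per order."""
    filtered = prepare_table(table, level, config)
    results = []
    for order_name, sub in filtered.df.groupby("order", sort=True):
        sub_table = filtered.with_rows(sub.reset_index(drop=True))
        taxa = occ.group_by_taxon(sub_table)
        res = OrderResult(order=order_name, level=level,
                          source_kind=table.source_kind,
                          n_occurrences=len(sub), n_taxa=len(taxa))
        widths = []
        for taxon in taxa:
            try:
                widths.append(bounding_box_area(
                    taxon, correct_longitude=config.correct_longitude).width)
            except ValueError:
                log.debug("taxon %s has no coordinates; skipped in range analysis",
                          taxon.taxon_id)
        res.width_values = np.asarray(widths, dtype=float)
        res.range_class = _classify_values(widths, "width_km",
                                           classify_range_curve, config.min_points)
        if table.source_kind == "fossil":
            durations = []
            for taxon in taxa:
                try:
                    durations.append(taxon_duration(taxon).duration)
                except ValueError:
                    pass
            res.duration_values = np.asarray(durations, dtype=float)
            res.survivorship = _classify_values(durations, "duration_My",
                                                classify_duration_curve,
                                                config.min_points)
        results.append(res)
    return results


def run_full_analysis(fossil_table: occ.OccurrenceTable | None = None,
                      present_table: occ.OccurrenceTable | None = None,
                      config: AnalysisConfig = AnalysisConfig()) -> pd.DataFrame:
    """Assemble the per-order summary report across sources and levels.

    Columns mirror the standard summary layout: genus-level fossil
    occurrence counts, survivorship classes (genus/species), fossil range
    classes (genus/species) and present-day range classes (species/genus).
    Rows are sorted by fossil occurrence count descending.  Empty cells are
    dashes.
    """
    if fossil_table is None and present_table is None:
        raise ValueError("at least one of fossil_table/present_table is required")
    report: dict[str, dict] = {}

    def cell(res: OrderResult, which: str) -> str:
        decay = res.survivorship if which == "survivorship" else res.range_class
        return decay.formatted if decay is not None else "-"

    if fossil_table is not None:
        for level in config.levels:
            for res in analyze_order_table(fossil_table, level, config):
                row = report.setdefault(res.order, {})
                if level == "genus":
                    row["n_occurrences"] = res.n_occurrences
                row[f"survivorship_{level}"] = cell(res, "survivorship")
                row[f"range_fossil_{level}"] = cell(res, "range")
    if present_table is not None:
        for level in config.levels:
            for res in analyze_order_table(present_table, level, config):
                row = report.setdefault(res.order, {})
                row[f"range_present_{level}"] = cell(res, "range")

    columns = ["n_occurrences",
               "survivorship_genus", "survivorship_species",
               "range_fossil_genus", "range_fossil_species",
               "range_present_species", "range_present_genus"]
    frame = pd.DataFrame.from_dict(report, orient="index").reindex(columns=columns)
    frame.index.name = "order"
    frame["n_occurrences"] = frame["n_occurrences"].fillna(0).astype(int)
    frame = frame.sort_values("n_occurrences", ascending=False, kind="mergesort")
    for col in columns[1:]:
        frame[col] = frame[col].fillna("-")
    return frame.reset_index()


def order_fit_details(results: list[OrderResult]) -> pd.DataFrame:
    """Machine-readable per-transform fit table across order results."""
    from .classify import fits_to_frame

    frames = []
    for res in results:
        for kind, decay in (("survivorship", res.survivorship),
                            ("range", res.range_class)):
            if decay is None or not decay.fits:
                continue
            frame = fits_to_frame(decay)
            frame.insert(0, "order", res.order)
            frame.insert(1, "level", res.level)
            frame.insert(2, "curve", kind)
            frame["label"] = decay.formatted
            frames.append(frame)
    if not frames:
        return pd.DataFrame()
    return pd.concat(frames, ignore_index=True)
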