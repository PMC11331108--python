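"""Synthetic occurrence tables with known ground-truth decay structure.

Generates fossil occurrence tables (in the tab-separated export dialect the
reader consumes) and present-day hexagonal-grid presence tables whose
per-taxon durations and range widths follow configurable distributions.
Localities are placed so that the pipeline's estimators recover the truth
exactly in the noise-free configuration: the oldest and youngest localities
sit at the ends of the species' time span with symmetric dating
uncertainty (so age-range midpoints are unbiased), and two localities sit
at opposite corners of a square of the species' true width (so the
bounding box recovers the width exactly); remaining localities scatter
uniformly inside.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import HEXAGON_AREA_KM2, KM_PER_DEGREE
from .occurrences import OccurrenceTable, CANONICAL_COLUMNS, EXACT, INDETERMINATE, UNCERTAIN


@dataclass(frozen=True)
class Dist:
    """A small distribution spec: kind plus parameters.

    kinds: exponential(mean), pareto(alpha, xm), uniform(lo, hi),
    constant(value), poisson_plus1(lam)  [1 + Poisson(lam), for counts].
    """

    kind: str
    params: tuple

    def sample(self, size: int, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "exponential":
            (mean,) = self.params
            return rng.exponential(mean, size=size)
        if self.kind == "pareto":
            alpha, xm = self.params
            return xm * (1.0 + rng.pareto(alpha, size=size))
        if self.kind == "uniform":
            lo, hi = self.params
            return rng.uniform(lo, hi, size=size)
        if self.kind == "constant":
            (value,) = self.params
            return np.full(size, value, dtype=float)
        if self.kind == "poisson_plus1":
            (lam,) = self.params
            return 1 + rng.poisson(lam, size=size)
        raise ValueError(f"unknown distribution kind {self.kind!r}")

    @property
    def mean(self) -> float:
        if self.kind == "exponential":
            return self.params[0]
        if self.kind == "pareto":
            alpha, xm = self.params
            return xm * alpha / (alpha - 1) if alpha > 1 else float("inf")
        if self.kind == "uniform":
            return sum(self.params) / 2
        if self.kind == "constant":
            return self.params[0]
        return 1 + self.params[0]


@dataclass(frozen=True)
class GeneratorConfig:
    """Ground-truth structure of a synthetic occurrence table.

    Defaults emulate a Cenozoic large-mammal order: memoryless (exponential)
    species durations with mean 3.33 My and exponential peak range widths
    with mean sqrt(694) ~ 26.3 km, localities with dating uncertainty up to
    2 My (inside the 3 My screening threshold), spread over an
    Old-World-sized region.
    """

    n_species: int = 2000
    order: str = "Synthodonta"
    duration_dist: Dist = Dist("exponential", (3.33,))       # My
    width_dist: Dist = Dist("exponential", (26.3,))          # km
    localities_dist: Dist = Dist("poisson_plus1", (4.0,))    # count per species
    age_span_dist: Dist = Dist("uniform", (0.0, 2.0))        # My locality dating span
    region: tuple = (-30.0, 60.0, -25.0, 60.0)               # lat_min, lat_max, lon_min, lon_max
    qualifier_noise: float = 0.0  # fraction of rows downgraded to indet.
    cf_fraction: float = 0.0      # fraction of rows marked cf. (kept by filters)


def _species_names(config: GeneratorConfig, n: int):
    genera = [f"Gen{i:05d}" for i in range(n)]
    species = [f"sp{i:05d}" for i in range(n)]
    return genera, species


def generate_fossil_table(config: GeneratorConfig,
                          rng: np.random.Generator) -> tuple[OccurrenceTable, pd.DataFrame]:
    """Generate a fossil occurrence table plus its ground truth.

    Returns the canonical table (as the reader would produce it) and a
    per-species ground-truth frame with true durations, widths and locality
    counts.
    """
    n = config.n_species
    lat_min, lat_max, lon_min, lon_max = config.region
    durations = config.duration_dist.sample(n, rng)
    widths = config.width_dist.sample(n, rng)
    n_locs = config.localities_dist.sample(n, rng).astype(int)
    max_span = config.age_span_dist.params[-1] if config.age_span_dist.kind == "uniform" else 3.0

    w_deg = widths / KM_PER_DEGREE
    if np.any(w_deg > lat_max - lat_min) or np.any(w_deg > lon_max - lon_min):
        raise ValueError("region too small for the requested range widths")

    genera, species = _species_names(config, n)
    rows = []
    lid = 0
    for i in range(n):
        k = max(1, n_locs[i])
        d, w = durations[i], w_deg[i]
        base_age = d + rng.uniform(max_span / 2 + 0.1, 40.0)
        if k == 1:
            times = np.array([rng.uniform(0, d)])
            lat0 = rng.uniform(lat_min, lat_max)
            lon0 = rng.uniform(lon_min, lon_max)
            lats = np.array([lat0])
            lons = np.array([lon0])
        else:
            times = np.concatenate([[0.0, d], rng.uniform(0, d, size=k - 2)])
            lat0 = rng.uniform(lat_min, lat_max - w)
            lon0 = rng.uniform(lon_min, lon_max - w)
            lats = np.concatenate([[lat0, lat0 + w], rng.uniform(lat0, lat0 + w, size=k - 2)])
            lons = np.concatenate([[lon0, lon0 + w], rng.uniform(lon0, lon0 + w, size=k - 2)])
        spans = config.age_span_dist.sample(k, rng)
        ages = base_age - times
        for j in range(k):
            rows.append({
                "locality_id": f"L{lid:07d}",
                "lat": lats[j], "lon": lons[j],
                "age_min": ages[j] - spans[j] / 2.0,
                "age_max": ages[j] + spans[j] / 2.0,
                "order": config.order, "family": "Synthfam",
                "genus": genera[i], "species": species[i],
                "genus_qualifier": EXACT, "species_qualifier": EXACT,
            })
            lid += 1
    df = pd.DataFrame(rows, columns=CANONICAL_COLUMNS)

    # identification noise: indet. rows are dropped by filtering; cf. rows kept
    if len(df) and (config.qualifier_noise > 0 or config.cf_fraction > 0):
        u = rng.uniform(size=len(df))
        indet = u < config.qualifier_noise
        cf = (~indet) & (u < config.qualifier_noise + config.cf_fraction)
        df.loc[indet, "species_qualifier"] = INDETERMINATE
        df.loc[indet, "species"] = ""
        df.loc[cf, "species_qualifier"] = UNCERTAIN

    truth = pd.DataFrame({
        "taxon": [f"{config.order} {g} {s}" for g, s in zip(genera, species)],
        "genus": genera, "species": species,
        "duration_My": durations, "width_km": widths,
        "n_localities": np.maximum(1, n_locs),
    })
    table = OccurrenceTable(df=df, level="species", source_kind="fossil",
                            n_input_rows=len(df))
    return table, truth


def generate_hexgrid_table(config: GeneratorConfig,
                           rng: np.random.Generator) -> tuple[OccurrenceTable, pd.DataFrame]:
    """Generate a present-day hexagon-grid presence table plus ground truth.

    Each species occupies ``max(1, round(width^2 / hex_area))`` hexagons;
    two of the occupied cell centers sit at opposite corners of the species'
    true square range so the bounding-box estimator recovers the width.
    """
    n = config.n_species
    lat_min, lat_max, lon_min, lon_max = config.region
    widths = config.width_dist.sample(n, rng)
    n_hex = np.maximum(1, np.rint(widths ** 2 / HEXAGON_AREA_KM2)).astype(int)
    w_deg = widths / KM_PER_DEGREE
    if np.any(w_deg > lat_max - lat_min) or np.any(w_deg > lon_max - lon_min):
        raise ValueError("region too small for the requested range widths")

    genera, species = _species_names(config, n)
    rows = []
    hid = 0
    for i in range(n):
        k = n_hex[i]
        w = w_deg[i]
        if k == 1:
            lats = np.array([rng.uniform(lat_min, lat_max)])
            lons = np.array([rng.uniform(lon_min, lon_max)])
        else:
            lat0 = rng.uniform(lat_min, lat_max - w)
            lon0 = rng.uniform(lon_min, lon_max - w)
            lats = np.concatenate([[lat0, lat0 + w], rng.uniform(lat0, lat0 + w, size=k - 2)])
            lons = np.concatenate([[lon0, lon0 + w], rng.uniform(lon0, lon0 + w, size=k - 2)])
        for j in range(len(lats)):
            rows.append({
                "locality_id": f"H{hid:07d}",
                "lat": lats[j], "lon": lons[j],
                "age_min": np.nan, "age_max": np.nan,
                "order": config.order, "family": "",
                "genus": genera[i], "species": species[i],
                "genus_qualifier": EXACT, "species_qualifier": EXACT,
            })
            hid += 1
    df = pd.DataFrame(rows, columns=CANONICAL_COLUMNS)
    if df.empty:
        df = pd.DataFrame(columns=CANONICAL_COLUMNS)
    truth = pd.DataFrame({
        "taxon": [f"{config.order} {g} {s}" for g, s in zip(genera, species)],
        "genus": genera, "species": species,
        "width_km": widths, "n_hexagons": n_hex,
        "hexagon_area_km2": n_hex * HEXAGON_AREA_KM2,
    })
    table = OccurrenceTable(df=df, level="species", source_kind="present_day",
                            n_input_rows=len(df))
    return table, truth


def write_ground_truth(truth: pd.DataFrame, path) -> None:
    """Ground-truth sidecar as JSON records."""
    with open(path, "w") as fh:
        json.dump(truth.to_dict(orient="records"), fh, indent=1)


PRESETS = {
    "exponential": GeneratorConfig(),
    "pareto": GeneratorConfig(order="Paretotheria",
                              width_dist=Dist("pareto", (1.5, 15.0)),
                              duration_dist=Dist("pareto", (1.5, 0.4))),
}
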