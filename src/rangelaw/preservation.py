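"""Preservation-bias simulator for the fossil record.

A world of species with memoryless (exponential) durations and exponential
peak range sizes is simulated under a constant speciation rate.  Each
species' range rises linearly from zero at origination to its peak at
mid-duration and declines linearly back to zero.  Individuals live at a
uniform density inside the range, die after a fixed expected lifespan and
are immediately replaced, and each death fossilizes with a small fixed
probability.  The question the simulator answers: if the true survivorship
law is Type II but preservation favours widespread, long-lived species, is
the law still recoverable from first/last fossil occurrences?

The death process within a species is a Poisson process in time whose rate
is proportional to the instantaneous range area; fossilization is an
independent thinning of that process.  Fossil events are therefore drawn
exactly as an inhomogeneous Poisson process with triangular intensity: a
Poisson-distributed count with the analytic expected yield, and event times
from the (truncated) triangular density.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import DecayClass, classify_duration_curve
from .curves import DEFAULT_MIN_POINTS, ExceedanceCurve, exceedance_curve, trim_for_fitting


@dataclass(frozen=True)
class PreservationSimParams:
    """World parameters for the preservation simulation.

    Defaults describe an adaptive zone of large herbivores (~75 kg adult
    body size): individual lifespan 14 y at 10 individuals/km^2; one new
    species every 2,000 y over 12 million simulated years; species durations
    exponential with mean 3.33 My and peak ranges exponential with mean
    694 km^2.
    """

    lifespan_y: float = 14.0
    density_per_km2: float = 10.0
    speciation_interval_y: float = 2000.0
    mean_duration_My: float = 3.33
    mean_peak_area_km2: float = 694.0
    total_years: float = 12e6

    def __post_init__(self):
        for name in ("lifespan_y", "density_per_km2", "speciation_interval_y",
                     "mean_duration_My", "mean_peak_area_km2", "total_years"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class SpeciesPool:
    """Ground-truth species: origination times, durations, peak ranges.

    Species whose duration extends past the end of the simulated window are
    flagged censored; their fossil-sampling window is truncated at the
    boundary but their true duration is retained.
    """

    params: PreservationSimParams
    origination_y: np.ndarray
    duration_y: np.ndarray
    peak_area_km2: np.ndarray
    censored: np.ndarray

    def __len__(self) -> int:
        return len(self.origination_y)

    def trajectory_area(self, i: int, t: float) -> float:
        """Range area (km^2) of species ``i`` at time ``t`` years after origination."""
        d = self.duration_y[i]
        if t < 0 or t > d or d == 0:
            return 0.0
        return float(self.peak_area_km2[i] * (1.0 - abs(2.0 * t / d - 1.0)))


def simulate_species_pool(params: PreservationSimParams,
                          rng: np.random.Generator) -> SpeciesPool:
    """Draw the true species pool under a constant speciation rate."""
    n = int(params.total_years // params.speciation_interval_y)
    origination = np.arange(n) * params.speciation_interval_y
    duration = rng.exponential(params.mean_duration_My * 1e6, size=n)
    peak = rng.exponential(params.mean_peak_area_km2, size=n)
    censored = origination + duration > params.total_years
    return SpeciesPool(params=params, origination_y=origination,
                       duration_y=duration, peak_area_km2=peak,
                       censored=censored)


def death_rate(pool: SpeciesPool, i: int, year: float) -> float:
    """Deaths per year for species ``i`` at absolute ``year``.

    rate = area(t) * density / lifespan; individuals are replaced on death
    so the standing abundance is area * density throughout.
    """
    p = pool.params
    t = year - pool.origination_y[i]
    if year > p.total_years:
        return 0.0
    return pool.trajectory_area(i, t) * p.density_per_km2 / p.lifespan_y


def _integrated_area(duration: np.ndarray, peak: np.ndarray,
                     window: np.ndarray) -> np.ndarray:
    """Integral of the triangular area trajectory over [0, window] (km^2*y)."""
    d = duration
    u = np.minimum(window, d)
    half = d / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        rising = peak * u ** 2 / d
        falling = peak * d / 4.0 + (2.0 * peak / d) * (d * u - u ** 2 / 2.0 - 3.0 * d ** 2 / 8.0)
    out = np.where(u <= half, rising, falling)
    return np.where(d > 0, out, 0.0)


def expected_fossils(pool: SpeciesPool, fossilization_prob: float) -> np.ndarray:
    """Analytic expected fossil count per species."""
    p = pool.params
    window = p.total_years - pool.origination_y
    integral = _integrated_area(pool.duration_y, pool.peak_area_km2, window)
    return fossilization_prob * p.density_per_km2 / p.lifespan_y * integral


@dataclass
class FossilRecord:
    """Sampled fossil events and the per-species observed durations."""

    events: pd.DataFrame  # columns: species (index into pool), year
    observed_duration_y: pd.Series = field(default=None)  # indexed by species

    def __post_init__(self):
        if self.observed_duration_y is None:
            if self.events.empty:
                self.observed_duration_y = pd.Series(dtype=float)
            else:
                grouped = self.events.groupby("species")["year"]
                self.observed_duration_y = grouped.max() - grouped.min()

    @property
    def n_species(self) -> int:
        return len(self.observed_duration_y)


def sample_fossil_record(pool: SpeciesPool, fossilization_prob: float,
                         rng: np.random.Generator) -> FossilRecord:
    """Draw the fossil record as a thinned death process.

    Per species the fossil count is Poisson with the analytic expected
    yield, and event times follow the triangular area trajectory (rejection
    sampling against the full triangle for boundary-censored species).
    """
    if not 0.0 <= fossilization_prob <= 1.0:
        raise ValueError("fossilization_prob must be a probability")
    lam = expected_fossils(pool, fossilization_prob)
    counts = rng.poisson(lam)
    species_idx = []
    years = []
    window = pool.params.total_years - pool.origination_y
    for i in np.nonzero(counts)[0]:
        k = counts[i]
        d = pool.duration_y[i]
        u = min(window[i], d)
        times = np.empty(0)
        while len(times) < k:
            draw = rng.triangular(0.0, d / 2.0, d, size=k)
            times = np.concatenate([times, draw[draw <= u]])
        times = times[:k]
        species_idx.extend([i] * k)
        years.extend(pool.origination_y[i] + times)
    events = pd.DataFrame({"species": np.array(species_idx, dtype=int),
                           "year": np.array(years, dtype=float)})
    return FossilRecord(events=events)


@dataclass
class RecoverabilityReport:
    """Paired true/observed survivorship curves and their decay classes."""

    true_curve: ExceedanceCurve
    observed_curve: ExceedanceCurve | None
    true_class: DecayClass
    observed_class: DecayClass
    n_fossil_species: int
    mean_true_duration_My: float
    mean_fossil_species_true_duration_My: float

    @property
    def preservation_biased_long(self) -> bool:
        """Whether fossilized species are longer-lived than the pool average."""
        return (self.mean_fossil_species_true_duration_My
                >= self.mean_true_duration_My)


def recoverability_report(pool: SpeciesPool, record: FossilRecord,
                          min_points: int = DEFAULT_MIN_POINTS) -> RecoverabilityReport:
    """Compare survivorship inferred from the full pool vs the fossil record.

    True durations of all species yield the ground-truth curve; observed
    durations (first-to-last fossil occurrence, zero for single-occurrence
    species) yield the preservation-filtered curve.
    """
    true_my = pool.duration_y / 1e6
    true_curve = exceedance_curve(true_my, "duration_My")
    true_class = classify_duration_curve(trim_for_fitting(true_curve, min_points))

    fossil_species = record.observed_duration_y.index.to_numpy()
    n_fossil = len(fossil_species)
    if n_fossil >= 2:
        obs_my = record.observed_duration_y.to_numpy() / 1e6
        observed_curve = exceedance_curve(obs_my, "duration_My")
        try:
            observed_class = classify_duration_curve(
                trim_for_fitting(observed_curve, min_points))
        except ValueError:
            observed_class = DecayClass(label="insufficient", weak=False)
    else:
        observed_curve = None
        observed_class = DecayClass(label="insufficient", weak=False)

    mean_all = float(true_my.mean())
    mean_fossil = float(true_my[fossil_species].mean()) if n_fossil else float("nan")
    return RecoverabilityReport(
        true_curve=true_curve,
        observed_curve=observed_curve,
        true_class=true_class,
        observed_class=observed_class,
        n_fossil_species=n_fossil,
        mean_true_duration_My=mean_all,
        mean_fossil_species_true_duration_My=mean_fossil,
    )
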