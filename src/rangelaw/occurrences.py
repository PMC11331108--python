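"""Reading, validation and filtering of occurrence tables.

Fossil input follows the tab-separated export dialect of large fossil-mammal
occurrence databases (one row per taxon occurrence at a locality, with
locality coordinates and an age range in Ma).  Present-day input is a
hexagonal-grid presence table (one row per species per occupied grid cell).
Both are parsed into a single canonical pandas representation so that the
downstream duration/range estimators and curve assembly are agnostic to the
source.
"""

from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

# canonical column order of the internal representation
CANONICAL_COLUMNS = [
    "locality_id", "lat", "lon", "age_min", "age_max",
    "order", "family", "genus", "species",
    "genus_qualifier", "species_qualifier",
]

DEFAULT_COLUMN_MAP = {
    "locality_id": "LIDNUM",
    "lat": "LAT",
    "lon": "LONG",
    "age_max": "MAX_AGE",
    "age_min": "MIN_AGE",
    "order": "ORDER",
    "family": "FAMILY",
    "genus": "GENUS",
    "species": "SPECIES",
}

HEXGRID_COLUMN_MAP = {
    "species": "species",
    "order": "order",
    "locality_id": "hex_id",
    "lat": "hex_lat",
    "lon": "hex_lon",
}

#: Aquatic taxa excluded from present-day analyses: one fully aquatic order
#: plus the pinniped families (Pinnipedia is a clade, not an order, so it is
#: expressed as its member families).
DEFAULT_AQUATIC_EXCLUSIONS = ("Sirenia", "Otariidae", "Phocidae", "Odobenidae")

DEFAULT_MAX_AGE_SPAN_MY = 3.0

# qualifier categories
EXACT = "exact"
UNCERTAIN = "uncertain"      # cf. / aff. — kept in analyses
INDETERMINATE = "indeterminate"  # indet. — discarded
UNNAMED = "unnamed"          # sp. / gen. placeholders — discarded


@dataclass(frozen=True)
class QualifierDialect:
    """Configurable tokenisation of identification qualifiers.

    Database exports vary; the defaults cover the common spellings.  Tokens
    are compared lowercase and without a trailing period.
    """

    indeterminate_tokens: frozenset = frozenset({"indet", "\\n", "incertae sedis"})
    unnamed_tokens: frozenset = frozenset({"sp", "gen", "spp", "gen. et sp. nov"})
    uncertain_prefixes: tuple = ("cf", "aff")

    def parse(self, name) -> tuple[str, str]:
        """Classify a taxonomic name string -> (qualifier, cleaned name)."""
        if name is None or (isinstance(name, float) and np.isnan(name)):
            return INDETERMINATE, ""
        text = str(name).strip()
        if not text:
            return INDETERMINATE, ""
        token = text.lower().rstrip(".")
        if token in self.indeterminate_tokens:
            return INDETERMINATE, ""
        if token in self.unnamed_tokens:
            return UNNAMED, ""
        m = re.match(r"^(\w+)\.?\s+(.+)$", text)
        if m and m.group(1).lower() in self.uncertain_prefixes:
            return UNCERTAIN, m.group(2).strip()
        return EXACT, text


DEFAULT_DIALECT = QualifierDialect()


@dataclass(frozen=True)
class ValidationIssue:
    row: int
    field: str
    message: str


@dataclass
class OccurrenceTable:
    """Canonical occurrence rows plus parse-time bookkeeping.

    ``df`` holds only rows that satisfy the hard invariants (ordered ages,
    in-range coordinates); rows that violated them are kept aside in
    ``invalid_rows`` with their issues listed in ``issues`` — reported, not
    silently dropped.  Rows with *missing* coordinates stay in ``df``: they
    are usable for duration analysis and are skipped by range estimators.
    """

    df: pd.DataFrame
    level: str = "species"  # genus | species
    source_kind: str = "fossil"  # fossil | present_day
    issues: list = field(default_factory=list)
    invalid_rows: pd.DataFrame | None = None
    n_input_rows: int = 0

    def __len__(self) -> int:
        return len(self.df)

    def with_rows(self, df: pd.DataFrame) -> "OccurrenceTable":
        return replace(self, df=df)


@dataclass(frozen=True)
class TaxonOccurrences:
    """All retained occurrences of one taxon (genus or species level)."""

    taxon_id: str
    occurrences: pd.DataFrame


def _validate(df: pd.DataFrame, source_kind: str):
    """Split rows into valid/invalid and collect row-level issues."""
    issues = []
    bad = pd.Series(False, index=df.index)
    lat_bad = df["lat"].notna() & ~df["lat"].between(-90, 90)
    lon_bad = df["lon"].notna() & ~df["lon"].between(-180, 180)
    for idx in df.index[lat_bad]:
        issues.append(ValidationIssue(idx, "lat", f"latitude {df.at[idx, 'lat']} out of [-90, 90]"))
    for idx in df.index[lon_bad]:
        issues.append(ValidationIssue(idx, "lon", f"longitude {df.at[idx, 'lon']} out of [-180, 180]"))
    bad |= lat_bad | lon_bad
    if source_kind == "fossil":
        inverted = (df["age_min"].notna() & df["age_max"].notna()
                    & (df["age_min"] > df["age_max"]))
        for idx in df.index[inverted]:
            issues.append(ValidationIssue(
                idx, "age", f"age_min {df.at[idx, 'age_min']} > age_max {df.at[idx, 'age_max']}"))
        bad |= inverted
    return df[~bad].reset_index(drop=True), df[bad], issues


def read_occurrence_table(source, column_map: dict | None = None,
                          source_kind: str = "fossil",
                          level: str = "species",
                          dialect: QualifierDialect = DEFAULT_DIALECT) -> OccurrenceTable:
    """Parse a tab-separated occurrence export into the canonical table.

    Parameters
    ----------
    source : path or text stream
        TSV with a header row.
    column_map : dict, optional
        Canonical-name -> file-column mapping; defaults to the fossil export
        dialect or, for ``source_kind='present_day'``, the hexagon-grid
        dialect.
    """
    if column_map is None:
        column_map = DEFAULT_COLUMN_MAP if source_kind == "fossil" else HEXGRID_COLUMN_MAP
    raw = pd.read_csv(source, sep="\t", dtype=str, keep_default_na=False)
    missing = [col for col in column_map.values() if col not in raw.columns]
    if missing:
        raise KeyError(f"mapped columns missing from input: {missing}")

    df = pd.DataFrame(index=raw.index)
    for canon, src_col in column_map.items():
        df[canon] = raw[src_col]
    for col in CANONICAL_COLUMNS:
        if col not in df.columns:
            df[col] = ""

    for col in ("lat", "lon", "age_min", "age_max"):
        df[col] = pd.to_numeric(df[col], errors="coerce")

    if source_kind == "present_day":
        # species given as a binomial; split off the genus
        parts = df["species"].str.split(n=1)
        df["genus"] = parts.str[0].fillna("")
        df["species"] = parts.str[1].fillna("")

    gq = df["genus"].map(lambda s: dialect.parse(s))
    sq = df["species"].map(lambda s: dialect.parse(s))
    df["genus_qualifier"] = [q for q, _ in gq]
    df["genus"] = [name for _, name in gq]
    df["species_qualifier"] = [q for q, _ in sq]
    df["species"] = [name for _, name in sq]
    df = df[CANONICAL_COLUMNS]

    valid, invalid, issues = _validate(df, source_kind)
    if issues:
        log.warning("%d row(s) failed validation and were set aside", len(invalid))
    return OccurrenceTable(df=valid, level=level, source_kind=source_kind,
                           issues=issues, invalid_rows=invalid,
                           n_input_rows=len(raw))


def write_occurrence_table(table: OccurrenceTable, target) -> None:
    """Write a canonical table back out in its source TSV dialect."""
    df = table.df
    if table.source_kind == "fossil":
        out = pd.DataFrame({
            "LIDNUM": df["locality_id"],
            "LAT": df["lat"],
            "LONG": df["lon"],
            "MAX_AGE": df["age_max"],
            "MIN_AGE": df["age_min"],
            "ORDER": df["order"],
            "FAMILY": df["family"],
            "GENUS": _requalify(df["genus"], df["genus_qualifier"]),
            "SPECIES": _requalify(df["species"], df["species_qualifier"]),
        })
    else:
        binomial = (_requalify(df["genus"], df["genus_qualifier"]) + " "
                    + _requalify(df["species"], df["species_qualifier"])).str.strip()
        out = pd.DataFrame({
            "species": binomial,
            "order": df["order"],
            "hex_id": df["locality_id"],
            "hex_lat": df["lat"],
            "hex_lon": df["lon"],
        })
    out.to_csv(target, sep="\t", index=False)


def _requalify(names: pd.Series, qualifiers: pd.Series) -> pd.Series:
    out = names.copy().astype(str)
    out[qualifiers == UNCERTAIN] = "cf. " + out[qualifiers == UNCERTAIN]
    out[qualifiers == INDETERMINATE] = "indet."
    out[qualifiers == UNNAMED] = "sp."
    return out


def _qualifier_ok(df: pd.DataFrame, level: str) -> pd.Series:
    """Rows identified well enough for analysis at ``level``.

    Indeterminate or unnamed names are discarded at the analysis level;
    cf./aff. identifications are kept.  A species-level analysis also needs
    a determinate genus, since the taxon identity includes the genus.
    """
    genus_ok = ~df["genus_qualifier"].isin([INDETERMINATE, UNNAMED])
    if level == "genus":
        return genus_ok
    species_ok = ~df["species_qualifier"].isin([INDETERMINATE, UNNAMED])
    return genus_ok & species_ok


def filter_identifications(table: OccurrenceTable, level: str | None = None) -> OccurrenceTable:
    """Drop rows not identified to the analysis level; keep cf./aff. rows."""
    level = level or table.level
    if level not in ("genus", "species"):
        raise ValueError(f"level must be 'genus' or 'species', got {level!r}")
    keep = _qualifier_ok(table.df, level)
    removed = int((~keep).sum())
    if removed:
        log.info("identification filter removed %d of %d rows at %s level",
                 removed, len(table.df), level)
    out = replace(table, df=table.df[keep].reset_index(drop=True))
    out.level = level
    return out


def filter_age_span(table: OccurrenceTable,
                    max_span: float = DEFAULT_MAX_AGE_SPAN_MY) -> OccurrenceTable:
    """Keep rows from localities whose dating uncertainty is acceptable.

    A locality age range wider than ``max_span`` My indicates time averaging
    or dating uncertainty and is removed; spans exactly equal to the
    threshold are kept (the bound is inclusive).  Rows without ages cannot be vetted
    and are removed too (logged).
    """
    if table.source_kind != "fossil":
        raise ValueError("age-span filtering applies to fossil tables only")
    span = table.df["age_max"] - table.df["age_min"]
    keep = span.notna() & (span <= max_span)
    removed = int((~keep).sum())
    if removed:
        log.info("age-span filter removed %d of %d rows (max span %.2f My)",
                 removed, len(table.df), max_span)
    return table.with_rows(table.df[keep].reset_index(drop=True))


def exclude_taxa(table: OccurrenceTable,
                 exclusions=DEFAULT_AQUATIC_EXCLUSIONS) -> OccurrenceTable:
    """Remove rows whose order or family matches an excluded name."""
    if not exclusions:
        return table
    excl = {e.lower() for e in exclusions}
    hit = (table.df["order"].str.lower().isin(excl)
           | table.df["family"].str.lower().isin(excl))
    return table.with_rows(table.df[~hit].reset_index(drop=True))


def group_by_taxon(table: OccurrenceTable) -> list[TaxonOccurrences]:
    """Partition retained rows into per-taxon groups at the table's level.

    Taxon identity is order + genus (+ species at species level).
    """
    keys = ["order", "genus"]
    if table.level == "species":
        keys.append("species")
    groups = []
    for key, sub in table.df.groupby(keys, sort=True):
        taxon_id = " ".join(k for k in key if k)
        groups.append(TaxonOccurrences(taxon_id=taxon_id,
                                       occurrences=sub.reset_index(drop=True)))
    return groups


def read_table_text(table: OccurrenceTable) -> str:
    """Render a table to its TSV dialect as a string (round-trip helper)."""
    buf = io.StringIO()
    write_occurrence_table(table, buf)
    return buf.getvalue()
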