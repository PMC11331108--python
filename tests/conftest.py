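import numpy as np
import pandas as pd
import pytest

from rangelaw.occurrences import CANONICAL_COLUMNS, TaxonOccurrences


#: The ten genus durations (My) of the worked dataset-assembly example.
TABLE3A_DURATIONS = [0, 0, 0, 0.18, 0.18, 1.45, 2.62, 3.03, 3.03, 3.12]


@pytest.fixture
def table3a_durations():
    return list(TABLE3A_DURATIONS)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_taxon(coords=None, ages=None, taxon_id="Testorder Genus species"):
    """Build a TaxonOccurrences from (lat, lon) pairs and/or (min, max) ages."""
    n = max(len(coords or []), len(ages or []), 1)
    df = pd.DataFrame({col: [""] * n for col in CANONICAL_COLUMNS})
    df["locality_id"] = [f"L{i}" for i in range(n)]
    df["lat"] = [c[0] for c in coords] if coords else np.nan
    df["lon"] = [c[1] for c in coords] if coords else np.nan
    df["age_min"] = [a[0] for a in ages] if ages else np.nan
    df["age_max"] = [a[1] for a in ages] if ages else np.nan
    return TaxonOccurrences(taxon_id=taxon_id, occurrences=df)


@pytest.fixture
def fossil_tsv_text():
    """A tiny hand-written fossil export with assorted qualifiers."""
    rows = [
        "LIDNUM\tLAT\tLONG\tMAX_AGE\tMIN_AGE\tORDER\tFAMILY\tGENUS\tSPECIES",
        "L1\t10.0\t20.0\t12.0\t10.0\tArtiodactyla\tBovidae\tBison\tprimus",
        "L2\t11.0\t21.0\t12.5\t10.5\tArtiodactyla\tBovidae\tBison\tcf. primus",
        "L3\t12.0\t22.0\t13.0\t11.0\tArtiodactyla\tBovidae\tBison\tindet.",
        "L4\t13.0\t23.0\t14.0\t12.0\tArtiodactyla\tBovidae\tBison\tsp.",
        "L5\t14.0\t24.0\t20.0\t10.0\tArtiodactyla\tBovidae\tOvis\taries",
        "L6\t15.0\t25.0\t15.0\t12.0\tSirenia\tDugongidae\tDugong\tdugon",
        "L7\t16.0\t26.0\t15.0\t12.0\tCarnivora\tPhocidae\tPhoca\tvitulina",
    ]
    return "\n".join(rows) + "\n"
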