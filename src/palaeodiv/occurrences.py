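"""Reading, validating, normalising and cleaning fossil occurrence tables.

An *occurrence* is one record of a taxon at a geographic locality in a
dated stratigraphic context.  The canonical in-memory container is a
pandas DataFrame with one row per occurrence and a fixed column schema
(:data:`S1_COLUMNS`), wrapped in :class:`OccurrenceTable` together with
provenance and a cleaning log.

Cleaning follows the compilation protocol for literature-derived
Palaeozoic fish occurrence data: taxonomically indeterminate records
(those that cannot be confidently assigned to a valid genus or species)
are dropped, as are records represented solely by scales or teeth, so
that only body fossils remain.  Records determinate at genus level but
not species level are *retained* — they still inform genus-level
richness.  Open-nomenclature qualifiers (cf., aff.) and quoted
"waste-basket" genus names (e.g. 'Elonichthys') are preserved as a
qualifier flag and count toward the named taxon.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "S1_COLUMNS",
    "REGIONS",
    "OccurrenceTable",
    "DatasetSummary",
    "OccurrenceReadError",
    "read_occurrences",
    "write_occurrences",
    "normalize_names",
    "clean_occurrences",
    "summarize",
    "locality_keys",
    "load_country_regions",
]

#: the canonical column order of the native ("s1") CSV dialect
S1_COLUMNS = [
    "occurrence_id", "genus", "species", "qualifier", "locality_name",
    "latitude", "longitude", "country", "region", "geological_unit",
    "stage", "substage", "max_ma", "min_ma", "environment", "material",
    "authority", "year_described",
]

_TEXT_COLUMNS = [c for c in S1_COLUMNS if c not in
                 ("latitude", "longitude", "max_ma", "min_ma", "year_described")]

#: the nine present-day regions used for geographic breakdowns
REGIONS = (
    "UK & Ireland", "Western Europe", "Central Europe", "Eastern Europe",
    "North America", "Africa", "Asia", "South America", "Oceania",
)

QUALIFIERS = ("none", "cf", "aff", "quoted", "indet")
ENVIRONMENTS = ("marine", "freshwater", "unknown")
MATERIALS = ("body", "scales_only", "teeth_only", "other")

#: PBDB occurrence-download column names mapped onto the native schema
PBDB_COLUMN_MAP = {
    "occurrence_no": "occurrence_id",
    "collection_name": "locality_name",
    "lat": "latitude",
    "lng": "longitude",
    "cc": "country",
    "formation": "geological_unit",
    "early_interval": "stage",
    "max_ma": "max_ma",
    "min_ma": "min_ma",
    "environment": "environment",
    "ref_author": "authority",
    "ref_pubyr": "year_described",
}


class OccurrenceReadError(ValueError):
    """Raised for unparseable rows when reading in fail-fast mode."""


@dataclass
class DatasetSummary:
    n_occurrences: int
    n_species: int
    n_genera: int
    n_localities: int

    def as_dict(self) -> dict[str, int]:
        return {
            "n_occurrences": self.n_occurrences,
            "n_species": self.n_species,
            "n_genera": self.n_genera,
            "n_localities": self.n_localities,
        }


@dataclass
class OccurrenceTable:
    """Occurrence records plus provenance and a cleaning log.

    ``df`` always carries the full :data:`S1_COLUMNS` schema; text columns
    hold ``""`` (never NaN) when empty.
    """

    df: pd.DataFrame
    provenance: list[str] = field(default_factory=list)
    cleaning_log: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        missing = [c for c in S1_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"occurrence table missing columns {missing}")
        self.df = self.df[S1_COLUMNS].reset_index(drop=True)
        if self.df["occurrence_id"].duplicated().any():
            dups = self.df["occurrence_id"][
                self.df["occurrence_id"].duplicated()].tolist()[:5]
            raise ValueError(f"duplicate occurrence_id values, e.g. {dups}")

    def __len__(self) -> int:
        return len(self.df)

    def copy(self) -> "OccurrenceTable":
        return OccurrenceTable(self.df.copy(), list(self.provenance),
                               [dict(e) for e in self.cleaning_log])

    def with_df(self, df: pd.DataFrame, note: str) -> "OccurrenceTable":
        return OccurrenceTable(df.reset_index(drop=True),
                               self.provenance + [note],
                               [dict(e) for e in self.cleaning_log])


def _coerce_schema(df: pd.DataFrame) -> pd.DataFrame:
    """Force canonical dtypes: floats for coords/ages, Int64 year, str text."""
    def _float(v):
        # Python's float() is correctly rounded; pd.to_numeric is not
        # always, which would break bit-exact CSV round trips
        try:
            return float(v)
        except (TypeError, ValueError):
            return np.nan

    out = df.copy()
    for c in _TEXT_COLUMNS:
        out[c] = out[c].fillna("").astype(str).replace({"nan": ""})
    for c in ("latitude", "longitude", "max_ma", "min_ma"):
        out[c] = out[c].map(_float).astype(float)
    out["year_described"] = pd.to_numeric(
        out["year_described"], errors="coerce").round().astype("Int64")
    return out


def normalize_longitude(lon):
    """Map any longitude to the canonical [-180, 180) range.

    In-range values pass through untouched (bit-exactly), so repeated
    normalisation is a no-op.
    """
    arr = np.asarray(lon, dtype=float)
    wrapped = (arr + 180.0) % 360.0 - 180.0
    return np.where((arr >= -180.0) & (arr < 180.0), arr, wrapped)


def _split_binomial(name: str) -> tuple[str, str]:
    parts = str(name).strip().split()
    if not parts:
        return "", ""
    genus = parts[0]
    species = parts[1] if len(parts) > 1 else ""
    return genus, species


def _validate_rows(df: pd.DataFrame) -> list[str]:
    """Row-numbered diagnostics for out-of-range or inconsistent values."""
    problems = []
    bad_lat = ~df["latitude"].between(-90, 90) & df["latitude"].notna()
    for i in df.index[bad_lat]:
        problems.append(f"row {i}: latitude {df.at[i, 'latitude']} outside [-90, 90]")
    both = df["max_ma"].notna() & df["min_ma"].notna()
    bad_age = both & (df["max_ma"] <= df["min_ma"])
    for i in df.index[bad_age]:
        problems.append(
            f"row {i}: max_ma {df.at[i, 'max_ma']} <= min_ma {df.at[i, 'min_ma']}")
    return problems


def read_occurrences(path: str | Path, dialect: str = "s1",
                     on_error: str = "raise") -> OccurrenceTable:
    """Read an occurrence CSV in the native ("s1") or PBDB dialect.

    Parameters
    ----------
    dialect
        ``"s1"`` expects exactly the :data:`S1_COLUMNS` header;
        ``"pbdb"`` maps standard PBDB occurrence-download column names via
        :data:`PBDB_COLUMN_MAP` and splits ``accepted_name`` into genus and
        species.
    on_error
        ``"raise"`` aborts on the first invalid row; ``"skip"`` drops
        invalid rows and records them in the cleaning log.
    """
    path = Path(path)
    if dialect == "s1":
        raw = pd.read_csv(path, dtype=str, keep_default_na=False,
                          na_values=[""])
        missing = [c for c in S1_COLUMNS if c not in raw.columns]
        if missing:
            raise OccurrenceReadError(
                f"{path.name}: s1 dialect requires columns {missing}")
        df = _coerce_schema(raw)
    elif dialect == "pbdb":
        raw = pd.read_csv(path, dtype=str, keep_default_na=False,
                          na_values=[""])
        if "accepted_name" not in raw.columns:
            raise OccurrenceReadError(
                f"{path.name}: pbdb dialect requires an accepted_name column")
        df = pd.DataFrame(index=raw.index, columns=S1_COLUMNS, dtype=object)
        for src, dst in PBDB_COLUMN_MAP.items():
            if src in raw.columns:
                df[dst] = raw[src]
        gen_sp = raw["accepted_name"].fillna("").map(_split_binomial)
        df["genus"] = [g for g, _ in gen_sp]
        df["species"] = [s for _, s in gen_sp]
        df["qualifier"] = "none"
        df["material"] = "body"
        env = df["environment"].fillna("").astype(str).str.lower()
        df["environment"] = np.select(
            [env.str.contains("fluvial|lacustrine|freshwater|pond|lake"),
             env.str.contains("marine|reef|shelf|basin|coastal|delta")],
            ["freshwater", "marine"], default="unknown")
        df = _coerce_schema(df)
        df["region"] = map_countries_to_regions(df["country"])
    else:
        raise OccurrenceReadError(f"unknown dialect {dialect!r}")

    df["longitude"] = normalize_longitude(df["longitude"])
    problems = _validate_rows(df)
    log: list[dict] = []
    if problems:
        if on_error == "raise":
            raise OccurrenceReadError(
                f"{path.name}: {len(problems)} invalid rows; first: {problems[0]}")
        bad = set(int(p.split()[1].rstrip(":")) for p in problems)
        df = df.drop(index=sorted(bad))
        log.append({"rule": "invalid_rows_skipped", "n_removed": len(bad),
                    "detail": "; ".join(problems[:20])})
    t = OccurrenceTable(df, provenance=[f"read {path} dialect={dialect}"])
    t.cleaning_log.extend(log)
    return t


def write_occurrences(t: OccurrenceTable, path: str | Path) -> None:
    """Write the native-dialect CSV (round-trips bit-exactly through read)."""
    t.df.to_csv(path, index=False)


def load_country_regions() -> pd.DataFrame:
    """The packaged, editable country-to-region lookup (nine regions)."""
    with resources.as_file(
            resources.files("palaeodiv.data").joinpath("country_regions.csv")) as p:
        return pd.read_csv(p)


def map_countries_to_regions(countries: pd.Series) -> pd.Series:
    lut = load_country_regions()
    mapping = {str(c).strip().lower(): r
               for c, r in zip(lut["country"], lut["region"])}
    return countries.fillna("").astype(str).str.strip().str.lower().map(
        mapping).fillna("")


_WS = re.compile(r"\s+")
# straight and typographic quotes that flag waste-basket genus usage
_QUOTES = "'\"‘’“”"
_INDET_SPECIES = {"sp", "spp", "indet", "indeterminate", "gen", "nov"}
_INDET_GENUS = {"", "indet", "indeterminate", "incertae", "gen"}


def _canonical_text(s: str) -> str:
    return _WS.sub(" ", unicodedata.normalize("NFC", str(s))).strip()


def _normalize_one(genus: str, species: str, qualifier: str) -> tuple[str, str, str]:
    qual = qualifier if qualifier in QUALIFIERS else "none"
    # tokenise the full name so qualifiers are caught wherever they sit,
    # including a complete "cf. Genus sp." string in the genus field
    tokens = _canonical_text(f"{genus} {species}").split()
    names: list[str] = []
    for tok in tokens:
        low = tok.lower().rstrip(".")
        if low in ("cf", "aff"):
            qual = low
            continue
        if tok[0] in _QUOTES and not names:
            qual = "quoted"  # quoted waste-basket genus
        tok = tok.strip(_QUOTES)
        if tok:
            names.append(tok)
    g = names[0] if names else ""
    s = names[1].rstrip(".") if len(names) > 1 else ""
    if s.lower() in _INDET_SPECIES:
        s = ""
    g = g[:1].upper() + g[1:].lower() if g else ""
    s = s.lower()
    if g.lower().rstrip(".") in _INDET_GENUS:
        g, s, qual = "", "", "indet"
    return g, s, qual


def normalize_names(t: OccurrenceTable) -> OccurrenceTable:
    """Canonicalise taxon names and move open nomenclature into ``qualifier``.

    Quoted genera ('Elonichthys') become ``qualifier="quoted"`` but keep the
    name; "cf."/"aff." prefixes become the corresponding qualifier; "sp."
    and friends empty the species field; records whose genus cannot be
    resolved become ``qualifier="indet"``.  Pure normalisation: no records
    are dropped.
    """
    df = t.df.copy()
    out = [_normalize_one(g, s, q) for g, s, q in
           zip(df["genus"], df["species"], df["qualifier"])]
    df["genus"] = [g for g, _, _ in out]
    df["species"] = [s for _, s, _ in out]
    df["qualifier"] = [q for _, _, q in out]
    for c in ("locality_name", "geological_unit", "stage", "substage",
              "country", "region", "authority"):
        df[c] = df[c].map(_canonical_text)
    for c in ("environment", "material"):
        df[c] = df[c].map(lambda v: _canonical_text(v).lower())
    df["environment"] = df["environment"].where(
        df["environment"].isin(ENVIRONMENTS), "unknown")
    df["material"] = df["material"].where(df["material"].isin(MATERIALS), "other")
    return t.with_df(df, "normalize_names")


def clean_occurrences(t: OccurrenceTable,
                      drop_indeterminate: bool = True,
                      drop_scales_only: bool = True,
                      drop_teeth_only: bool = True) -> OccurrenceTable:
    """Apply the compilation cleaning rules; idempotent.

    Drops taxonomically indeterminate records and records known solely
    from scales or teeth.  Counts removed per rule are appended to the
    cleaning log.
    """
    df = t.df
    out = t.with_df(df, "clean_occurrences")
    rules = []
    if drop_indeterminate:
        rules.append(("indeterminate", df["qualifier"] == "indet"))
    if drop_scales_only:
        rules.append(("scales_only", df["material"] == "scales_only"))
    if drop_teeth_only:
        rules.append(("teeth_only", df["material"] == "teeth_only"))
    drop = pd.Series(False, index=df.index)
    for rule, mask in rules:
        newly = mask & ~drop
        out.cleaning_log.append({"rule": rule, "n_removed": int(newly.sum())})
        drop |= mask
    out.df = df[~drop].reset_index(drop=True)
    return out


def locality_keys(df: pd.DataFrame) -> pd.Series:
    """Locality identity: canonical name + coordinates rounded to 2 dp.

    The 2-decimal-degree rounding (~1 km) tolerates coordinate jitter
    between literature sources reporting the same site.
    """
    name = df["locality_name"].map(_canonical_text).str.lower()
    lat = df["latitude"].round(2).map(lambda v: f"{v:.2f}" if pd.notna(v) else "?")
    lon = df["longitude"].round(2).map(lambda v: f"{v:.2f}" if pd.notna(v) else "?")
    return name + "|" + lat + "|" + lon


def species_determinate(df: pd.DataFrame) -> pd.Series:
    return (df["genus"] != "") & (df["species"] != "") & (df["qualifier"] != "indet")


def summarize(t: OccurrenceTable) -> DatasetSummary:
    """Distinct-entity counts: occurrences, species, genera, localities."""
    df = t.df
    det = species_determinate(df)
    binomials = (df.loc[det, "genus"] + " " + df.loc[det, "species"]).unique()
    genera = df.loc[df["genus"] != "", "genus"].unique()
    return DatasetSummary(
        n_occurrences=len(df),
        n_species=len(binomials),
        n_genera=len(genera),
        n_localities=int(locality_keys(df).nunique()) if len(df) else 0,
    )


def cleaning_log_frame(t: OccurrenceTable) -> pd.DataFrame:
    return pd.DataFrame(t.cleaning_log, columns=["rule", "n_removed", "detail"])
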