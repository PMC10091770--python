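"""Reading, name normalisation, cleaning and summarising occurrence tables."""

import numpy as np
import pandas as pd
import pandas.testing as pdt
import pytest

from conftest import make_table
from oracles import distinct_count

from palaeodiv.occurrences import (OccurrenceReadError, clean_occurrences,
                                   normalize_longitude, normalize_names,
                                   read_occurrences, summarize,
                                   write_occurrences)


def test_read_three_row_fixture(tmp_path):
    t = make_table([{"genus": f"G{i}"} for i in range(3)])
    p = tmp_path / "occ.csv"
    write_occurrences(t, p)
    back = read_occurrences(p, dialect="s1")
    assert len(back) == 3
    assert list(back.df["genus"]) == ["G0", "G1", "G2"]


def test_round_trip_is_bit_exact(tmp_path):
    t = make_table([
        {"genus": "Aa", "latitude": -12.345678, "longitude": 91.5,
         "max_ma": 330.9, "min_ma": 323.2},
        {"genus": "Bb", "species": "", "year_described": pd.NA,
         "substage": "Asbian"},
    ])
    p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
    write_occurrences(t, p1)
    once = read_occurrences(p1, dialect="s1")
    write_occurrences(once, p2)
    assert p1.read_bytes() == p2.read_bytes()
    pdt.assert_frame_equal(once.df, read_occurrences(p2).df)


@pytest.mark.parametrize("lon,expected", [
    (270.0, -90.0), (-180.0, -180.0), (180.0, -180.0), (359.0, -1.0),
    (45.5, 45.5),
])
def test_longitude_normalisation(lon, expected):
    assert normalize_longitude(lon) == pytest.approx(expected)


def test_pbdb_dialect_splits_accepted_name(tmp_path):
    p = tmp_path / "pbdb.csv"
    pd.DataFrame({
        "occurrence_no": [101], "accepted_name": ["Cheirolepis trailli"],
        "collection_name": ["Tynet Burn"], "lat": [57.6], "lng": [-3.0],
        "cc": ["UK"], "formation": ["Tynet Burn beds"],
        "early_interval": ["Givetian"], "max_ma": [387.7], "min_ma": [382.7],
        "environment": ["lacustrine"], "ref_author": ["Agassiz"],
        "ref_pubyr": [1835],
    }).to_csv(p, index=False)
    t = read_occurrences(p, dialect="pbdb")
    row = t.df.iloc[0]
    assert (row["genus"], row["species"]) == ("Cheirolepis", "trailli")
    assert row["region"] == "UK & Ireland"
    assert row["environment"] == "freshwater"


def test_unknown_dialect_rejected(tmp_path):
    p = tmp_path / "x.csv"
    p.write_text("a,b\n1,2\n")
    with pytest.raises(OccurrenceReadError, match="unknown dialect"):
        read_occurrences(p, dialect="excel")


def test_invalid_rows_reported_with_row_numbers(tmp_path):
    t = make_table([{"genus": "Ok"}, {"latitude": 123.0}])
    p = tmp_path / "bad.csv"
    write_occurrences(t, p)
    with pytest.raises(OccurrenceReadError, match="row 1: latitude"):
        read_occurrences(p)
    skipped = read_occurrences(p, on_error="skip")
    assert len(skipped) == 1
    assert skipped.cleaning_log[0]["n_removed"] == 1


@pytest.mark.parametrize("genus,species,out_genus,out_species,out_qual", [
    ("'Elonichthys'", "macropercularis", "Elonichthys", "macropercularis",
     "quoted"),
    ("ELONICHTHYS", "robisoni ", "Elonichthys", "robisoni", "none"),
    ("cf. Platysomus sp.", "", "Platysomus", "", "cf"),
    ("aff. Amblypterus", "latus", "Amblypterus", "latus", "aff"),
    ("indet.", "", "", "", "indet"),
])
def test_name_normalisation_rules(genus, species, out_genus, out_species,
                                  out_qual):
    t = normalize_names(make_table([{"genus": genus, "species": species}]))
    row = t.df.iloc[0]
    assert (row["genus"], row["species"], row["qualifier"]) == (
        out_genus, out_species, out_qual)


def _dirty_table():
    rows = [{"genus": f"G{i}"} for i in range(7)]
    rows += [{"genus": "", "qualifier": "indet"},
             {"genus": "", "qualifier": "indet"},
             {"genus": "G0", "material": "scales_only"}]
    return make_table(rows)


def test_cleaning_drops_indet_and_scales_only():
    cleaned = clean_occurrences(_dirty_table())
    assert len(cleaned) == 7
    removed = {e["rule"]: e["n_removed"] for e in cleaned.cleaning_log}
    assert removed == {"indeterminate": 2, "scales_only": 1, "teeth_only": 0}


def test_cleaning_is_idempotent_and_conserves_counts():
    t = _dirty_table()
    once = clean_occurrences(t)
    twice = clean_occurrences(once)
    pdt.assert_frame_equal(once.df, twice.df)
    removed = sum(e["n_removed"] for e in once.cleaning_log)
    assert len(once) + removed == len(t)


def test_determinate_body_fossil_untouched():
    t = make_table([{"genus": "Cheirolepis", "species": "trailli"}])
    cleaned = clean_occurrences(t)
    pdt.assert_frame_equal(cleaned.df, t.df)


def test_summary_against_nested_loop_oracle():
    rng = np.random.default_rng(7)
    rows = []
    for i in range(60):
        rows.append({
            "genus": f"G{rng.integers(5)}",
            "species": ["alpha", "beta", ""][rng.integers(3)],
            "locality_name": f"L{rng.integers(8)}",
            "latitude": float(rng.integers(4)), "longitude": 0.0,
        })
    t = make_table(rows)
    s = summarize(t)
    df = t.df
    binomials = [g + " " + sp if sp else ""
                 for g, sp in zip(df["genus"], df["species"])]
    locs = [f"{n}|{la}|{lo}" for n, la, lo in
            zip(df["locality_name"], df["latitude"], df["longitude"])]
    assert s.n_occurrences == 60
    assert s.n_species == distinct_count(binomials)
    assert s.n_genera == distinct_count(list(df["genus"]))
    assert s.n_localities == distinct_count(locs)


def test_empty_table_summary_is_zero():
    t = make_table([{"genus": "X"}])
    t.df = t.df.iloc[:0]
    s = summarize(t)
    assert (s.n_occurrences, s.n_species, s.n_genera, s.n_localities) == (
        0, 0, 0, 0)


def test_duplicate_occurrence_ids_rejected():
    with pytest.raises(ValueError, match="duplicate occurrence_id"):
        make_table([{"occurrence_id": "same"}, {"occurrence_id": "same"}])
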