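"""Dataset types, packaged reference tables, and file round-trips."""

import hashlib
from pathlib import Path

import pytest

from heteropka import (Availability, HARTREE_TO_KJ_PER_MOL, Microstate,
                       ParseError, Phase, Step, ValidationError, load_dataset,
                       simulate_dataset, slugify, write_dataset)
from heteropka.chem_data import (_data_path, read_microstates, read_pka,
                                 write_microstates, write_pka)

# Frozen transcription checksums: any edit to the shipped reference tables
# must be deliberate.
_CHECKSUMS = {
    "table1.csv": "be55a3133040b23ad966ffe9e602afc6eb6864076f0c98253748cc013d411854",
    "table2.csv": "b40ffb6c2a000bcbd3b762cfe9ed9f4cac929f3d66b04fd9dbc112a946d6fc75",
    "table3.csv": "fd35ac7614339d3bbf1b740a0c51b931fb3a438e10c50890736878b5cdebf00b",
    "table4.csv": "9ac29807016776ca43d82257edaddaee4e7772e68382cf3c1a0801323553f645",
}


def test_fixture_transcription_is_frozen():
    for name, digest in _CHECKSUMS.items():
        assert hashlib.sha256(
            _data_path(name).read_bytes()).hexdigest() == digest, name


def test_fixture_row_counts(tables):
    assert len(tables.table1) == 31
    assert len(tables.table2) == 6
    assert len(tables.table3) == 22
    assert len(tables.table4) == 21


def test_fixture_counts_of_numeric_experimental_values(tables):
    # rows eligible for calibration, i.e. numeric experimental value AND a
    # numeric (non-qualitative) estimate
    n1 = sum(1 for r in tables.table3
             if r.exp is not None and r.calc_is_numeric)
    n2 = sum(1 for r in tables.table4
             if r.exp is not None and r.calc_is_numeric)
    assert (n1, n2) == (17, 12)


def test_uracil_reference_delta_e(tables):
    row = {r.compound_id: r for r in tables.table4}["uracil"]
    assert row.delta_e == -1200.0
    assert row.exp == 9.44


def test_sentinels_distinguish_missing_from_no_proton(tables):
    by_id = {r.compound_id: r for r in tables.table1}
    # azauracil pKa1 was never measured; predictions may still be attached
    assert by_id["azauracil"].availability[Step.PKA1] is Availability.NOT_MEASURED
    # 1-methylimidazole has no dissociable proton for pKa2
    assert by_id["1-methylimidazole"].availability[Step.PKA2] is Availability.NO_PROTON
    assert by_id["aziridine"].availability[Step.PKA1] is Availability.MEASURED


def test_formula_typos_stored_as_printed(tables):
    # two apparent transcription slips in the source table are preserved:
    # isoxazole and oxazole share a (wrong) formula and pyridazine's H count
    # is corrupt; identifiers, not formulas, key all analysis
    by_id = {r.compound_id: r for r in tables.table1}
    assert by_id["isoxazole"].formula == by_id["oxazole"].formula == "C3H6NO"
    assert by_id["pyridazine"].formula == "C4H43N2"


def test_external_predictions_with_uncertainty(tables):
    by_id = {r.compound_id: r for r in tables.table1}
    acd = by_id["aziridine"].external_for(Step.PKA1)
    assert (acd.value, acd.uncertainty) == (8.1, 0.2)
    assert by_id["5-bromouracil"].external_for(Step.PKA1) is None


def test_slugify():
    assert slugify("1-Methylimidazole") == "1-methylimidazole"
    assert slugify("  5 Nitrouracil ") == "5-nitrouracil"


def test_load_empty_file_gives_empty_collection(tmp_path):
    p = tmp_path / "empty.csv"
    p.write_text("compound_id,charge,tautomer_id,phase,energy,unit\n")
    assert load_dataset(p) == []


def test_hartree_energies_converted_on_load(tmp_path):
    p = tmp_path / "ms.csv"
    p.write_text("compound_id,charge,tautomer_id,phase,energy,unit\n"
                 "x,0,t1,aqueous,-2.0,hartree\n"
                 "x,-1,t1,aqueous,-5251.0,kj/mol\n")
    ms = read_microstates(p)
    assert ms[0].energy == pytest.approx(-2.0 * HARTREE_TO_KJ_PER_MOL)
    assert ms[1].energy == -5251.0


def test_duplicate_microstate_key_rejected(tmp_path):
    p = tmp_path / "ms.csv"
    p.write_text("compound_id,charge,tautomer_id,phase,energy,unit\n"
                 "x,0,t1,aqueous,-1.0,kj/mol\n"
                 "x,0,t1,aqueous,-2.0,kj/mol\n")
    with pytest.raises(ValidationError, match="duplicate microstate"):
        read_microstates(p)


def test_malformed_row_names_line_and_column(tmp_path):
    p = tmp_path / "ms.csv"
    p.write_text("compound_id,charge,tautomer_id,phase,energy,unit\n"
                 "x,0,t1,aqueous,-1.0,kj/mol\n"
                 "x,0,t2,aqueous,not-a-number,kj/mol\n")
    with pytest.raises(ParseError) as err:
        read_microstates(p)
    assert "line 3" in str(err.value) and "column 'energy'" in str(err.value)


def test_implausible_literature_value_rejected_at_parse(tmp_path):
    p = tmp_path / "t.csv"
    p.write_text("no,name,formula,pka1,acd_pka1,acd_pka1_unc,"
                 "pka2,acd_pka2,acd_pka2_unc\n"
                 "1,bogusol,C0,44.0 [1],-,-,-,-,-\n")
    with pytest.raises(ParseError, match="plausible"):
        load_dataset(p)


def test_microstate_invariants():
    with pytest.raises(ValidationError, match="charge"):
        Microstate("x", 2, "t1", Phase.GAS, -1.0)
    with pytest.raises(ValidationError, match="finite"):
        Microstate("x", 0, "t1", Phase.GAS, float("nan"))


def test_json_round_trip_preserves_all_fields(tmp_path):
    records = simulate_dataset(n_compounds=5, seed=11).records
    path = tmp_path / "ds.json"
    write_dataset(records, path, format="json")
    back = load_dataset(path, format="json")
    assert back == records  # dataclass equality: exact strings and floats


def test_csv_round_trip_preserves_measured_content(tmp_path):
    records = simulate_dataset(n_compounds=5, seed=11).records
    out = tmp_path / "ds"
    write_dataset(records, out, format="csv")
    back = load_dataset(out, format="csv")
    assert [r.compound_id for r in back] == [r.compound_id for r in records]
    for a, b in zip(back, records):
        assert a.microstates == b.microstates
        assert a.literature == b.literature
        assert a.external == b.external


def test_pka_round_trip_and_range_validation(tmp_path):
    records = simulate_dataset(n_compounds=5, seed=3).records
    values = [p for r in records for p in r.literature]
    p = tmp_path / "pka.csv"
    write_pka(values, p)
    assert read_pka(p) == values
    extreme = [v for v in values if not -10 <= v.value <= 25]
    if extreme:  # synthetic truth extends beyond the measurable window
        with pytest.raises(ParseError, match="plausible"):
            read_pka(p, validate_range=True)


def test_load_dataset_schema_dispatch(tmp_path, tables):
    # thermo schema recognised from its header
    records = load_dataset(_data_path("table2.csv"))
    assert len(records) == 6 and records[0].compound_id == "pyridine"
    # microstates schema groups into compound records
    ms = [m for r in simulate_dataset(n_compounds=4, seed=2).records
          for m in r.microstates]
    p = tmp_path / "ms.csv"
    write_microstates(ms, p)
    grouped = load_dataset(p)
    assert len(grouped) == 4
    assert sum(len(r.microstates) for r in grouped) == len(ms)
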