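"""Core data model: CSV readers, aliasing, aggregation, HQ normalisation."""

import numpy as np
import pandas as pd
import pytest

import sedsource as ss
from sedsource.data import aggregate_to_matrix, canonical_positions, compute_hq


SAMPLES_CSV = """sample_id,point_id,campaign_id,metal_a,pah_b,hc_c
units,-,-,mg/kg,ug/kg,mg/kg
s1,F2bis,c1,5.0,400,10
s2,P1,c1,2.5,<100,20
s3,P1,c2,7.5,200,
"""

CHEMICALS_CSV = """name,class,lcl_limit,pnec_water,kp,endpoints
metal_a,heavy_metal,10,0.05,100,
pah_b,pah,0.5,,1000,10:1000;2:1000
hc_c,hydrocarbon,50,,,"""

ALIAS_CSV = """raw_name,canonical_name
F2bis,F2
"""


@pytest.fixture
def csv_paths(tmp_path):
    sp = tmp_path / "samples.csv"
    cp = tmp_path / "chemicals.csv"
    ap = tmp_path / "aliases.csv"
    sp.write_text(SAMPLES_CSV)
    cp.write_text(CHEMICALS_CSV)
    ap.write_text(ALIAS_CSV)
    return sp, cp, ap


class TestReadDataset:
    def test_parses_records_units_and_bdl(self, csv_paths):
        sp, cp, ap = csv_paths
        records, registry, aliases = ss.read_dataset(sp, cp, ap)
        assert len(records) == 3
        assert set(registry.names) == {"metal_a", "pah_b", "hc_c"}
        # ug/kg column converted to mg/kg
        assert records[0].concentrations["pah_b"] == pytest.approx(0.4)
        # "<100" flags BDL and stores the detection limit (converted)
        assert "pah_b" in records[1].bdl
        assert records[1].concentrations["pah_b"] == pytest.approx(0.1)
        # blank cell -> not measured
        assert records[2].concentrations["hc_c"] is None
        # alias resolves F2bis onto F2
        assert aliases.resolve("F2bis") == "F2"

    def test_negative_concentration_names_sample(self, csv_paths):
        sp, cp, _ = csv_paths
        sp.write_text(SAMPLES_CSV.replace("2.5", "-1"))
        with pytest.raises(ss.ValidationError, match="s2"):
            ss.read_dataset(sp, cp)

    def test_missing_column_is_schema_error(self, csv_paths, tmp_path):
        sp, cp, _ = csv_paths
        bad = tmp_path / "bad.csv"
        bad.write_text(SAMPLES_CSV.replace("campaign_id", "campaign"))
        with pytest.raises(ss.SchemaError, match="campaign_id"):
            ss.read_dataset(bad, cp)

    def test_unknown_chemical_rejected(self, csv_paths):
        sp, cp, _ = csv_paths
        sp.write_text(SAMPLES_CSV.replace("hc_c", "mystery"))
        with pytest.raises(ss.SchemaError, match="mystery"):
            ss.read_dataset(sp, cp)


def _rec(sample_id, point, campaign, **conc):
    return ss.SampleRecord(sample_id, point, campaign, dict(conc))


class TestCanonicalPositions:
    def test_alias_and_repeat_dedup(self):
        records = [
            _rec("a", "F2", "c1", x=1.0),
            _rec("b", "F2bis", "c2", x=2.0),
            _rec("c", "P9", "c1", x=3.0),
            _rec("d", "P9", "c4", x=4.0),
        ]
        aliases = ss.AliasTable({"F2bis": "F2"})
        assert canonical_positions(records, aliases) == ["F2", "P9"]

    def test_identity_without_aliases(self):
        records = [_rec(f"s{i}", f"P{i}", "c1", x=1.0) for i in range(5)]
        assert len(canonical_positions(records)) == 5

    def test_idempotent(self):
        records = [_rec("a", "F2bis", "c1", x=1.0), _rec("b", "Q", "c2", x=1.0)]
        aliases = ss.AliasTable({"F2bis": "F2"})
        first = canonical_positions(records, aliases)
        again = canonical_positions(
            [_rec(f"r{i}", p, "c1", x=1.0) for i, p in enumerate(first)], aliases
        )
        assert again == first


class TestAggregate:
    def test_mean_and_median(self):
        records = [
            _rec("a", "P1", "c1", x=10.0),
            _rec("b", "P1", "c2", x=20.0),
            _rec("c", "P2", "c1", x=1.0),
            _rec("d", "P2", "c2", x=2.0),
            _rec("e", "P2", "c3", x=100.0),
        ]
        mat = aggregate_to_matrix(records, aggregator="mean")
        assert mat.data.loc["P1", "x"] == pytest.approx(15.0)
        med = aggregate_to_matrix(records, aggregator="median")
        assert med.data.loc["P2", "x"] == pytest.approx(2.0)

    def test_single_record_identity(self):
        records = [_rec("a", "P1", "c1", x=3.5, y=0.2)]
        mat = aggregate_to_matrix(records)
        assert mat.data.loc["P1", "x"] == pytest.approx(3.5)
        assert mat.data.loc["P1", "y"] == pytest.approx(0.2)
        assert mat.value_kind == "raw"

    def test_bdl_substitution_and_mask(self):
        r1 = ss.SampleRecord("a", "P1", "c1", {"x": 0.1}, bdl=frozenset({"x"}))
        r2 = ss.SampleRecord("b", "P2", "c1", {"x": 0.4})
        mat = aggregate_to_matrix([r1, r2])
        assert mat.data.loc["P1", "x"] == pytest.approx(0.05)  # DL/2
        assert bool(mat.bdl_mask.loc["P1", "x"]) is True
        assert bool(mat.bdl_mask.loc["P2", "x"]) is False

    def test_all_null_column_warns_but_stays(self):
        records = [
            ss.SampleRecord("a", "P1", "c1", {"x": 1.0, "y": None}),
            ss.SampleRecord("b", "P2", "c1", {"x": 2.0, "y": None}),
        ]
        with pytest.warns(UserWarning, match="'y'"):
            mat = aggregate_to_matrix(records)
        assert "y" in mat.chemicals
        assert mat.data["y"].isna().all()


class TestComputeHQ:
    def test_definition_and_edge_cases(self, small_registry, matrix_factory):
        raw = matrix_factory(
            [[5.0, 0.5, 0.0], [10.0, 0.25, 50.0]],
            chemicals=["metal_a", "pah_b", "hc_c"],
            kind="raw",
        )
        hq = compute_hq(raw, small_registry)
        assert hq.value_kind == "hq"
        assert hq.data.iloc[0, 0] == pytest.approx(0.5)  # 5 / limit 10
        assert hq.data.iloc[1, 0] == pytest.approx(1.0)  # at the limit
        assert hq.data.iloc[0, 2] == 0.0  # zero stays zero

    def test_missing_limit_names_chemical(self, matrix_factory):
        registry = ss.ChemicalRegistry(
            [ss.ChemicalProfile("x", ss.ChemClass.PAH)]  # no lcl_limit
        )
        raw = matrix_factory([[1.0, 2.0]], chemicals=["x", "y"], kind="raw")
        with pytest.raises(ss.ValidationError, match="x|y"):
            compute_hq(raw, registry)

    def test_round_trip_recovers_raw(self, small_registry):
        rng = np.random.default_rng(5)
        vals = rng.uniform(0.1, 20.0, size=(6, 3))
        raw = pd.DataFrame(vals, columns=["metal_a", "pah_b", "hc_c"])
        mat = ss.ContaminationMatrix(raw, value_kind="raw")
        hq = compute_hq(mat, small_registry)
        limits = pd.Series({c: small_registry[c].lcl_limit for c in mat.chemicals})
        back = hq.data * limits
        assert np.allclose(back.to_numpy(), vals, rtol=1e-12, atol=0.0)


class TestContaminationMatrix:
    def test_negative_values_rejected(self):
        df = pd.DataFrame([[1.0, -0.1]], columns=["a", "b"])
        with pytest.raises(ss.ValidationError):
            ss.ContaminationMatrix(df, value_kind="raw")

    def test_subset_and_drop(self, matrix_factory):
        mat = matrix_factory([[1.0, 2.0, 3.0]], chemicals=["a", "b", "c"])
        assert mat.subset(["b", "c"]).chemicals == ["b", "c"]
        assert mat.drop_chemical("a").chemicals == ["b", "c"]
        with pytest.raises(KeyError):
            mat.drop_chemical("zz")
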