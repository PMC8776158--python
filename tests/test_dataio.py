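import numpy as np
import pytest

from excompose import dataio
from excompose.errors import FormatError, ParseError, ValidationError
from excompose.freqscale import ShiftRecord
from excompose.synthetic import make_chain_structure


def write(path, text):
    path.write_text(text)
    return path


class TestEnergyTable:
    def test_partial_row_maps_missing_not_zero(self, tmp_path):
        p = write(
            tmp_path / "e.csv",
            "system,conformer,method,e_vert_eV,e_ad_eV,e00_eV\nFa,B,CC2,,,4.770\n",
        )
        (rec,) = dataio.read_energy_table(p)
        assert rec.e_00 == pytest.approx(4.770)
        assert rec.e_vert is None and rec.e_ad is None
        assert rec.conformer.key == ("Fa", "B")
        assert rec.method.name == "CC2" and rec.method.family == "wavefunction"

    def test_empty_file_with_header(self, tmp_path):
        p = write(tmp_path / "e.csv", "system,conformer,method,e_vert_eV,e_ad_eV,e00_eV\n")
        assert dataio.read_energy_table(p) == []

    def test_non_numeric_cell_cites_row(self, tmp_path):
        p = write(
            tmp_path / "e.csv",
            "system,conformer,method,e_vert_eV,e_ad_eV,e00_eV\nFa,B,CC2,,,abc\n",
        )
        with pytest.raises(ParseError, match="row 2"):
            dataio.read_energy_table(p)

    def test_missing_column_named(self, tmp_path):
        p = write(tmp_path / "e.csv", "system,conformer,method,e_vert_eV,e_ad_eV\n")
        with pytest.raises(FormatError, match="e00_eV"):
            dataio.read_energy_table(p)

    def test_hartree_unit_column(self, tmp_path):
        p = write(
            tmp_path / "e.csv",
            "system,conformer,method,e_vert_eV,e_ad_eV,e00_eV,unit\n"
            "Fa,A,CC2,,,0.5,hartree\n",
        )
        (rec,) = dataio.read_energy_table(p)
        assert rec.e_00 == pytest.approx(0.5 * dataio.HARTREE_TO_EV)

    def test_round_trip_six_decimals(self, tmp_path):
        records = [
            dataio.EnergyTerms(
                conformer=dataio.ConformerRecord("Fa", "A", 1),
                method=dataio.method_level("CC2"),
                e_vert=5.259123,
                e_ad=4.912345,
                e_00=4.754001,
            )
        ]
        p = tmp_path / "e.csv"
        dataio.write_energy_table(records, p)
        back = dataio.read_energy_table(p)
        for orig, new in zip(records, back):
            assert new.e_vert == pytest.approx(orig.e_vert, abs=1e-6)
            assert new.e_ad == pytest.approx(orig.e_ad, abs=1e-6)
            assert new.e_00 == pytest.approx(orig.e_00, abs=1e-6)


class TestFrequencyTable:
    HEADER = (
        "system,conformer,method,state,mode_class,site_label,"
        "value_cm1,coupled,experimental_cm1\n"
    )

    def test_coupled_flag_parsed(self, tmp_path):
        p = write(
            tmp_path / "f.csv", self.HEADER + "GFa,A,wB97X-D,S1,NH,NH_Phe,3440,true,\n"
        )
        (rec,) = dataio.read_frequency_table(p)
        assert rec.coupled is True
        assert rec.experimental is None

    def test_coupled_defaults_false(self, tmp_path):
        p = write(tmp_path / "f.csv", self.HEADER + "GFa,A,CC2,S0,NH,NH_Phe,3440,,\n")
        (rec,) = dataio.read_frequency_table(p)
        assert rec.coupled is False

    def test_negative_frequency_rejected(self, tmp_path):
        p = write(tmp_path / "f.csv", self.HEADER + "Fa,A,CC2,S0,NH,NH_Phe,-10,,\n")
        with pytest.raises(ValidationError):
            dataio.read_frequency_table(p)

    def test_unknown_mode_class_lists_tokens(self, tmp_path):
        p = write(tmp_path / "f.csv", self.HEADER + "Fa,A,CC2,S0,CH,CH_x,3000,,\n")
        with pytest.raises(FormatError, match="NH, NH2sym, NH2anti"):
            dataio.read_frequency_table(p)

    def test_round_trip_five_records(self, tmp_path):
        records = [
            dataio.FrequencyRecord(
                conformer=dataio.ConformerRecord("GFa", "A", 2),
                method=dataio.method_level("wB97X-D"),
                state=state,
                mode_class=mode,
                site_label=site,
                value=value,
                coupled=coupled,
                experimental=exp,
            )
            for state, mode, site, value, coupled, exp in [
                ("S0", "NH", "NH_Phe", 3524.1, False, 3450.0),
                ("S1", "NH", "NH_Phe", 3480.2, True, 3432.0),
                ("S0", "NH2sym", "NH2_sym", 3440.5, False, None),
                ("S1", "NH2sym", "NH2_sym", 3436.0, False, None),
                ("S1", "NH2anti", "NH2_anti", 3550.25, False, 3545.0),
            ]
        ]
        p = tmp_path / "f.csv"
        dataio.write_frequency_table(records, p)
        assert dataio.read_frequency_table(p) == records


class TestXyz:
    def test_water(self, tmp_path):
        p = write(
            tmp_path / "w.xyz",
            "3\nwater\nO 0.0 0.0 0.0\nH 0.96 0.0 0.0\nh -0.24 0.93 0.0\n",
        )
        s = dataio.read_xyz(p)
        assert s.n_atoms == 3
        assert s.elements == ["O", "H", "H"]  # symbols normalized

    def test_count_mismatch(self, tmp_path):
        p = write(tmp_path / "bad.xyz", "5\nx\nC 0 0 0\nC 1 0 0\nC 2 0 0\nC 3 0 0\n")
        with pytest.raises(FormatError, match="declared 5"):
            dataio.read_xyz(p)

    def test_peptide_round_trip(self, tmp_path):
        base = make_chain_structure(seed=1)
        assert base.n_atoms == 30
        p = tmp_path / "pep.xyz"
        dataio.write_xyz(base, p)
        back = dataio.read_xyz(p)
        assert back.elements == base.elements
        assert np.allclose(back.coords, base.coords, atol=1e-6)


class TestAnnotations:
    def test_round_trip(self, tmp_path):
        ann = make_chain_structure(seed=0).annotations
        p = tmp_path / "ann.txt"
        dataio.write_annotations(ann, p)
        back = dataio.read_annotations(p)
        assert back == ann

    def test_unknown_kind(self, tmp_path):
        p = write(tmp_path / "ann.txt", "angle theta 0 1 2\n")
        with pytest.raises(FormatError, match="unknown annotation kind"):
            dataio.read_annotations(p)

    def test_bad_arity(self, tmp_path):
        p = write(tmp_path / "ann.txt", "dihedral chi 0 1 2\n")
        with pytest.raises(FormatError, match="4 indices"):
            dataio.read_annotations(p)


class TestBundledBenchmark:
    def test_conformer_count(self, benchmark):
        assert len(benchmark.conformers) == 11

    def test_residue_count_split(self, benchmark):
        counts = [c.residue_count for c in benchmark.conformers]
        assert counts.count(1) == 4
        assert counts.count(2) == 7

    def test_known_values(self, benchmark):
        assert benchmark.e00("FFa", "C", "wB97X-D") == pytest.approx(4.219)
        assert benchmark.e00("QFa", "A", "experiment") == pytest.approx(4.662)
        assert benchmark.e00("Fa", "B", "CC2") == pytest.approx(4.770)
        assert benchmark.e00("Fa", "A", "CAM-B3LYP") == pytest.approx(5.168)

    def test_alternate_experimental_value(self, benchmark):
        # the two source tables disagree on Fa C experiment; the alternate
        # is retained alongside the default
        assert benchmark.e00("Fa", "C", "experiment") == pytest.approx(4.663)
        assert benchmark.alternates[("Fa", "C", "experiment")] == pytest.approx(4.653)

    def test_methods_cover_all_conformers(self, benchmark):
        for method in ("CC2", "wB97X-D", "P1", "P2", "experiment"):
            assert len(benchmark.e00_series(method)) == 11
        assert len(benchmark.e00_series("CAM-B3LYP")) == 4

    def test_shift_records_typed(self, benchmark):
        assert all(isinstance(s, ShiftRecord) for s in benchmark.shifts)
        coupled = {(s.system, s.conformer, s.site_label)
                   for s in benchmark.shifts if s.coupled}
        assert ("GFa", "A", "NH_Phe") in coupled
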