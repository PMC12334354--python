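"""Readers, normalization invariants, cache round trips, exporters."""

import base64
import json
import struct
import subprocess
import textwrap
import zlib

import numpy as np
import pandas as pd
import pytest

from helpers import make_scan, make_table
from massql.spectra import (
    CacheChecksumError,
    CacheVersionError,
    SpectraCache,
    export_spectra,
    load_cache,
    load_spectra,
    load_spectra_cached,
    records_from_table,
    save_cache,
    write_mzml,
    write_result_table,
)


@pytest.fixture
def mixed_records():
    return [
        make_scan(1, 1, peaks=[(100.0 + k, 1e3 * (k + 1)) for k in range(10)], rt=1.0),
        make_scan(2, 2, peaks=[(50.0 + k, 2e3 * (k + 1)) for k in range(5)],
                  rt=1.1, precmz=488.1, charge=2),
        make_scan(3, 1, peaks=[(200.0 + k, 5e3 * (k + 1)) for k in range(10)],
                  rt=2.0, mobility=1.4),
        make_scan(4, 2, peaks=[(60.0 + k, 3e3 * (k + 1)) for k in range(5)],
                  rt=2.1, precmz=300.25, charge=-1, polarity=-1),
        make_scan(5, 1, peaks=[(300.0 + k, 7e3 * (k + 1)) for k in range(10)], rt=3.0),
    ]


@pytest.fixture
def mzml_file(tmp_path, mixed_records):
    path = tmp_path / "mixed.mzML"
    write_mzml(mixed_records, path)
    return path


class TestLoadSpectra:
    def test_row_counts_match_planted_scans(self, mzml_file):
        table = load_spectra(mzml_file)
        assert len(table.ms1) == 30  # 3 MS1 scans x 10 peaks
        assert len(table.ms2) == 10  # 2 MS2 scans x 5 peaks

    def test_ms2_metadata_round_trips(self, mzml_file):
        table = load_spectra(mzml_file)
        by_scan = table.ms2.drop_duplicates("scan").set_index("scan")
        assert by_scan.loc[2, "precmz"] == pytest.approx(488.1)
        assert by_scan.loc[2, "charge"] == 2
        assert by_scan.loc[2, "ms1scan"] == 1
        assert by_scan.loc[4, "polarity"] == -1
        assert by_scan.loc[4, "charge"] == -1
        assert by_scan.loc[4, "ms1scan"] == 3

    def test_mobility_preserved(self, mzml_file):
        table = load_spectra(mzml_file)
        scan3 = table.ms1[table.ms1["scan"] == 3]
        assert scan3["mobility"].to_numpy() == pytest.approx(1.4)

    def test_mgf_carries_ms2_only(self, tmp_path):
        path = tmp_path / "one.mgf"
        path.write_text(textwrap.dedent("""\
            BEGIN IONS
            TITLE=demo
            PEPMASS=488.1
            CHARGE=1+
            RTINSECONDS=120.0
            SCANS=7
            100.1 10.0
            200.2 20.0
            300.3 30.0
            400.4 40.0
            END IONS
        """))
        table = load_spectra(path)
        assert len(table.ms1) == 0
        assert len(table.ms2) == 4
        assert table.ms2["precmz"].to_numpy() == pytest.approx(488.1)
        assert table.ms2["scan"].unique().tolist() == [7]
        assert table.ms2["rt"].iloc[0] == pytest.approx(2.0)  # minutes

    def test_unsupported_extension(self, tmp_path):
        bad = tmp_path / "x.csv"
        bad.write_text("mz,i\n")
        with pytest.raises(ValueError, match="unsupported"):
            load_spectra(bad)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_spectra(tmp_path / "nope.mzML")

    def test_mzxml_reader(self, tmp_path):
        mz = np.array([100.5, 200.25, 300.125], dtype=">f4")
        i = np.array([1e3, 5e4, 2e4], dtype=">f4")
        interleaved = np.empty(6, dtype=">f4")
        interleaved[0::2], interleaved[1::2] = mz, i
        b64 = base64.b64encode(interleaved.tobytes()).decode()
        frag = np.array([88.2, 1e2, 99.5, 3e2], dtype=">f4")
        b64_2 = base64.b64encode(frag.tobytes()).decode()
        path = tmp_path / "tiny.mzXML"
        path.write_text(textwrap.dedent(f"""\
            <mzXML xmlns="http://sashimi.sourceforge.net/schema_revision/mzXML_3.2">
             <msRun scanCount="2">
              <scan num="1" msLevel="1" retentionTime="PT90S" polarity="+" peaksCount="3">
               <peaks precision="32" byteOrder="network" contentType="m/z-int"
                      compressionType="none">{b64}</peaks>
              </scan>
              <scan num="2" msLevel="2" retentionTime="PT95.5S" polarity="+" peaksCount="2">
               <precursorMz precursorCharge="2">300.125</precursorMz>
               <peaks precision="32" byteOrder="network" contentType="m/z-int"
                      compressionType="none">{b64_2}</peaks>
              </scan>
             </msRun>
            </mzXML>
        """))
        table = load_spectra(path)
        assert table.ms1["mz"].tolist() == pytest.approx([100.5, 200.25, 300.125])
        assert table.ms1["rt"].iloc[0] == pytest.approx(1.5)
        ms2 = table.ms2.drop_duplicates("scan")
        assert ms2["precmz"].iloc[0] == pytest.approx(300.125)
        assert ms2["charge"].iloc[0] == 2
        assert ms2["ms1scan"].iloc[0] == 1

    def test_missing_polarity_defaults_positive_with_warning(self, tmp_path):
        path = tmp_path / "nopol.mzXML"
        pair = np.array([150.0, 1e4], dtype=">f4")
        b64 = base64.b64encode(pair.tobytes()).decode()
        path.write_text(
            f'<mzXML><msRun><scan num="1" msLevel="1" retentionTime="PT1S">'
            f'<peaks precision="32" compressionType="none">{b64}</peaks>'
            f"</scan></msRun></mzXML>"
        )
        with pytest.warns(UserWarning, match="polarity"):
            table = load_spectra(path)
        assert (table.ms1["polarity"] == 1).all()


class TestNormalization:
    def test_base_peak_and_tic_invariants(self, mzml_file):
        table = load_spectra(mzml_file)
        for df in (table.ms1, table.ms2):
            g = df.groupby(["file_id", "scan"])
            assert (g["i_norm"].max() == 1.0).all()
            assert np.allclose(g["i_tic_norm"].sum(), 1.0, rtol=1e-9)

    def test_tied_maxima_all_normalize_to_one(self):
        table = make_table([make_scan(1, 1, peaks=[(100.0, 5e4), (200.0, 5e4), (300.0, 1e3)])])
        top = table.ms1[table.ms1["i_norm"] == 1.0]
        assert len(top) == 2


class TestCache:
    def test_bit_exact_round_trip(self, mzml_file, tmp_path):
        table = load_spectra(mzml_file)
        cache = SpectraCache(tmp_path / "cache")
        key = cache.key_for(mzml_file)
        save_cache(table, cache, key)
        out = load_cache(key, cache)
        pd.testing.assert_frame_equal(table.ms1, out.ms1, check_exact=True)
        pd.testing.assert_frame_equal(table.ms2, out.ms2, check_exact=True)

    def test_warm_load_equals_cold_parse(self, mzml_file, tmp_path):
        cache = SpectraCache(tmp_path / "cache")
        cold = load_spectra_cached(mzml_file, cache)
        warm = load_spectra_cached(mzml_file, cache)
        pd.testing.assert_frame_equal(cold.ms1, warm.ms1, check_exact=True)
        pd.testing.assert_frame_equal(cold.ms2, warm.ms2, check_exact=True)

    def test_truncated_blob_raises_checksum_error(self, mzml_file, tmp_path):
        cache = SpectraCache(tmp_path / "cache")
        key = cache.key_for(mzml_file)
        cache.save(load_spectra(mzml_file), key)
        blob = tmp_path / "cache" / key / "ms1.parquet"
        blob.write_bytes(blob.read_bytes()[:-20])
        with pytest.raises(CacheChecksumError):
            cache.load(key)

    def test_stale_version_signals_regeneration(self, mzml_file, tmp_path):
        old = SpectraCache(tmp_path / "cache", version=1)
        key = old.key_for(mzml_file)
        old.save(load_spectra(mzml_file), key)
        new = SpectraCache(tmp_path / "cache", version=2)
        with pytest.raises(CacheVersionError):
            new.load(key)
        # the convenience path regenerates instead of failing
        table = load_spectra_cached(mzml_file, new)
        assert len(table.ms1) == 30


class TestResultWriters:
    def test_empty_result_is_header_only(self, tmp_path):
        df = pd.DataFrame(columns=["file_id", "scan", "rt"])
        out = tmp_path / "empty.tsv"
        write_result_table(df, out, "tsv")
        assert out.read_text() == "file_id\tscan\trt\n"

    def test_tsv_line_count(self, tmp_path):
        df = pd.DataFrame({"file_id": ["a", "a", "b"], "scan": [1, 2, 1]})
        out = tmp_path / "r.tsv"
        write_result_table(df, out, "tsv")
        assert len(out.read_text().splitlines()) == 4

    def test_json_round_trip(self, tmp_path):
        df = pd.DataFrame(
            {"file_id": ["a"], "scan": [3], "rt": [1.25], "X": [500.123456789012]}
        )
        out = tmp_path / "r.json"
        write_result_table(df, out, "json")
        rows = json.loads(out.read_text())
        assert rows == [{"file_id": "a", "scan": 3, "rt": 1.25, "X": 500.123456789012}]


class TestExportSpectra:
    def test_mgf_block_count(self, mzml_file, tmp_path):
        table = load_spectra(mzml_file)
        out = tmp_path / "two.mgf"
        export_spectra(table, [(str(mzml_file), 2), (str(mzml_file), 4)], out, "mgf")
        assert out.read_text().count("BEGIN IONS") == 2

    def test_export_then_load_round_trip(self, mzml_file, tmp_path):
        table = load_spectra(mzml_file)
        out = tmp_path / "roundtrip.mzML"
        export_spectra(table, None, out, "mzml")
        again = load_spectra(out)
        for orig, back in zip(
            records_from_table(table), records_from_table(again)
        ):
            np.testing.assert_allclose(back[1].mz, orig[1].mz, rtol=1e-6)
            np.testing.assert_allclose(back[1].i, orig[1].i, rtol=1e-6)

    def test_empty_selection_yields_valid_file(self, mzml_file, tmp_path):
        table = load_spectra(mzml_file)
        out = tmp_path / "none.mgf"
        export_spectra(table, [], out, "mgf")
        assert out.exists()
        assert load_spectra(out).ms2.empty

    def test_json_export_carries_peaks(self, mzml_file, tmp_path):
        table = load_spectra(mzml_file)
        out = tmp_path / "spectra.json"
        export_spectra(table, [(str(mzml_file), 2)], out, "json")
        rows = json.loads(out.read_text())
        assert len(rows) == 1
        assert rows[0]["precmz"] == pytest.approx(488.1)
        assert len(rows[0]["mz"]) == 5


class TestMzmlConformance:
    def test_independent_reader_agrees(self, mzml_file):
        """Bioconductor's mzR (an independent mzML implementation) must
        read our exported file to the same scans and peaks."""
        script = (
            'suppressMessages(library(mzR));'
            f'h <- openMSfile("{mzml_file}");'
            'hd <- header(h);'
            'cat(nrow(hd), sum(hd$msLevel==1), sum(hd$msLevel==2), "\\n");'
            'p <- peaks(h, 1);'
            'cat(sprintf("%.9g", p[,1]), "\\n");'
            'cat(sprintf("%.9g", hd$precursorMZ[hd$msLevel==2]), "\\n")'
        )
        proc = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, timeout=240
        )
        assert proc.returncode == 0, proc.stderr
        lines = [ln for ln in proc.stdout.strip().splitlines() if ln.strip()]
        assert lines[0].split() == ["5", "3", "2"]
        mz1 = [float(v) for v in lines[1].split()]
        assert mz1 == pytest.approx([100.0 + k for k in range(10)])
        precs = [float(v) for v in lines[2].split()]
        assert precs == pytest.approx([488.1, 300.25])
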