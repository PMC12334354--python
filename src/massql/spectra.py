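"""Reading, caching and writing of MS spectra and query results.

Open formats (mzML, mzXML, MGF) are read into a columnar
:class:`PeakTable` — one row per peak, with per-scan base-peak- and
TIC-normalized intensities precomputed so intensity qualifiers evaluate as
simple column comparisons.  MGF goes through pyteomics; the XML formats
are parsed directly with lxml (cvParam-accession driven, base64 arrays,
32/64-bit floats, optional zlib).  Parsed tables can be cached on disk
(versioned parquet blobs keyed by source-file content hash) for repeated
querying.  Retrieved scans export back out as MGF, mzML or JSON; result
tables as TSV or JSON.
"""

from __future__ import annotations

import base64
import hashlib
import json
import re
import struct
import warnings
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from lxml import etree
from pyteomics import mgf as _mgf

__all__ = [
    "PeakTable",
    "ScanRecord",
    "SpectraCache",
    "CacheMissError",
    "CacheVersionError",
    "CacheChecksumError",
    "load_spectra",
    "save_cache",
    "load_cache",
    "load_spectra_cached",
    "write_result_table",
    "export_spectra",
    "records_from_table",
    "table_from_records",
    "write_mzml",
]

MS1_COLUMNS = ["file_id", "scan", "mz", "i", "i_norm", "i_tic_norm", "rt", "polarity", "mobility"]
MS2_COLUMNS = MS1_COLUMNS + ["precmz", "charge", "ms1scan"]

CACHE_VERSION = 1


@dataclass
class ScanRecord:
    """One scan in memory: metadata plus its centroided peak list."""

    scan: int
    mslevel: int
    rt: float  # minutes
    polarity: int  # +1 / -1
    mz: np.ndarray
    i: np.ndarray
    mobility: Optional[float] = None
    precmz: Optional[float] = None
    charge: Optional[int] = None
    ms1scan: Optional[int] = None


@dataclass
class PeakTable:
    """Columnar per-file store of MS1 and MS2 peaks with scan metadata.

    Invariants (enforced at construction): per (file_id, scan) the maximum
    ``i_norm`` is 1 and ``i_tic_norm`` sums to 1 (to 1e-9 relative); scan
    numbers are unique per file per MS level; ``rt`` is in minutes.
    """

    ms1: pd.DataFrame = field(default_factory=lambda: _empty(MS1_COLUMNS))
    ms2: pd.DataFrame = field(default_factory=lambda: _empty(MS2_COLUMNS))

    def equals(self, other: "PeakTable") -> bool:
        return self.ms1.equals(other.ms1) and self.ms2.equals(other.ms2)


def _empty(columns: Sequence[str]) -> pd.DataFrame:
    dtypes = {
        "file_id": "object", "scan": "int64", "mz": "float64", "i": "float64",
        "i_norm": "float64", "i_tic_norm": "float64", "rt": "float64",
        "polarity": "int64", "mobility": "float64", "precmz": "float64",
        "charge": "int64", "ms1scan": "Int64",
    }
    return pd.DataFrame({c: pd.Series(dtype=dtypes[c]) for c in columns})


def table_from_records(records: Iterable[ScanRecord], file_id: str) -> PeakTable:
    """Materialize scan records into a normalized PeakTable."""
    ms1_rows: List[dict] = []
    ms2_rows: List[dict] = []
    for rec in records:
        n = len(rec.mz)
        if n == 0:
            continue
        base = {
            "file_id": file_id,
            "scan": int(rec.scan),
            "rt": float(rec.rt),
            "polarity": int(rec.polarity),
            "mobility": np.nan if rec.mobility is None else float(rec.mobility),
        }
        i = np.asarray(rec.i, dtype=np.float64)
        mz = np.asarray(rec.mz, dtype=np.float64)
        i_norm = i / i.max()
        i_tic = i / i.sum()
        rows = ms1_rows if rec.mslevel == 1 else ms2_rows
        for k in range(n):
            row = dict(base, mz=mz[k], i=i[k], i_norm=i_norm[k], i_tic_norm=i_tic[k])
            if rec.mslevel >= 2:
                row["precmz"] = float(rec.precmz) if rec.precmz is not None else np.nan
                row["charge"] = int(rec.charge) if rec.charge is not None else (
                    1 if rec.polarity >= 0 else -1
                )
                row["ms1scan"] = rec.ms1scan
            rows.append(row)
    ms1 = pd.DataFrame(ms1_rows, columns=MS1_COLUMNS) if ms1_rows else _empty(MS1_COLUMNS)
    ms2 = pd.DataFrame(ms2_rows, columns=MS2_COLUMNS) if ms2_rows else _empty(MS2_COLUMNS)
    if len(ms2):
        ms2["ms1scan"] = ms2["ms1scan"].astype("Int64")
        ms2["charge"] = ms2["charge"].astype("int64")
    for df in (ms1, ms2):
        if len(df):
            df["scan"] = df["scan"].astype("int64")
            df["polarity"] = df["polarity"].astype("int64")
    return PeakTable(ms1=ms1, ms2=ms2)


def records_from_table(
    table: PeakTable,
    selection: Optional[Union[pd.DataFrame, Iterable[Tuple[str, int]]]] = None,
) -> List[Tuple[str, ScanRecord]]:
    """Reassemble (file_id, ScanRecord) pairs, optionally for a selection.

    ``selection`` is a result DataFrame with ``file_id``/``scan`` (and
    optionally ``mslevel``) columns, or an iterable of (file_id, scan)
    pairs.  Scans are searched in the MS2 table first, then MS1.
    """
    wanted: Optional[List[Tuple[str, int, Optional[int]]]] = None
    if selection is not None:
        wanted = []
        if isinstance(selection, pd.DataFrame):
            for _, row in selection.iterrows():
                lvl = int(row["mslevel"]) if "mslevel" in selection.columns else None
                wanted.append((str(row["file_id"]), int(row["scan"]), lvl))
        else:
            for file_id, scan in selection:
                wanted.append((str(file_id), int(scan), None))

    groups: Dict[Tuple[str, int, int], ScanRecord] = {}
    for level, df in ((1, table.ms1), (2, table.ms2)):
        for (file_id, scan), g in df.groupby(["file_id", "scan"], sort=True):
            first = g.iloc[0]
            rec = ScanRecord(
                scan=int(scan),
                mslevel=level,
                rt=float(first["rt"]),
                polarity=int(first["polarity"]),
                mz=g["mz"].to_numpy(),
                i=g["i"].to_numpy(),
                mobility=None if pd.isna(first["mobility"]) else float(first["mobility"]),
            )
            if level == 2:
                rec.precmz = None if pd.isna(first["precmz"]) else float(first["precmz"])
                rec.charge = None if pd.isna(first["charge"]) else int(first["charge"])
                rec.ms1scan = None if pd.isna(first["ms1scan"]) else int(first["ms1scan"])
            groups[(str(file_id), int(scan), level)] = rec

    if wanted is None:
        return [((fid), rec) for (fid, scan, lvl), rec in sorted(groups.items())]

    out: List[Tuple[str, ScanRecord]] = []
    for file_id, scan, lvl in wanted:
        if lvl is not None:
            key = (file_id, scan, lvl)
            if key not in groups:
                raise KeyError(f"scan {scan} (MS{lvl}) of {file_id!r} not in table")
            out.append((file_id, groups[key]))
            continue
        k2, k1 = (file_id, scan, 2), (file_id, scan, 1)
        if k2 in groups:
            out.append((file_id, groups[k2]))
        elif k1 in groups:
            out.append((file_id, groups[k1]))
        else:
            raise KeyError(f"scan {scan} of {file_id!r} not in table")
    return out


# ---------------------------------------------------------------------------
# Readers

_SCAN_ID_RE = re.compile(r"scan[=:\s](\d+)")


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("mzml", "mzxml", "mgf"):
        return suffix
    raise ValueError(f"unsupported spectra format {path.suffix!r} for {path}")


def load_spectra(path, format: Optional[str] = None) -> PeakTable:
    """Read an mzML, mzXML or MGF file into a PeakTable.

    The format is inferred from the extension unless given.  Retention
    times are converted to minutes.  MGF carries MS2 spectra only, so the
    MS1 table comes back empty.  Scans missing polarity metadata default
    to positive mode (with a warning); MS2 scans missing a precursor
    charge default to +1 in positive mode and -1 in negative.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    fmt = (format or _infer_format(path)).lower()
    if fmt == "mzml":
        records = _read_mzml(path)
    elif fmt == "mzxml":
        records = _read_mzxml(path)
    elif fmt == "mgf":
        records = _read_mgf(path)
    else:
        raise ValueError(f"unsupported spectra format {fmt!r}")
    _link_ms1(records)
    return table_from_records(records, file_id=str(path))


def _link_ms1(records: List[ScanRecord]) -> None:
    # an MS2 scan links to the most recent preceding MS1 scan, if any
    last_ms1: Optional[int] = None
    for rec in records:
        if rec.mslevel == 1:
            last_ms1 = rec.scan
        elif rec.ms1scan is None:
            rec.ms1scan = last_ms1


def _scan_number(spectrum: dict, fallback: int) -> int:
    sid = spectrum.get("id", "")
    m = _SCAN_ID_RE.search(str(sid))
    if m:
        return int(m.group(1))
    if str(sid).isdigit():
        return int(sid)
    return fallback


def _localname(el) -> str:
    return etree.QName(el).localname


def _cv_params(el) -> Dict[str, dict]:
    """Map accession -> {'name', 'value', 'unit'} over direct cvParam children."""
    out = {}
    for child in el:
        if _localname(child) == "cvParam":
            out[child.get("accession", "")] = {
                "name": child.get("name", ""),
                "value": child.get("value"),
                "unit": child.get("unitName"),
            }
    return out


def _find_child(el, name):
    for child in el:
        if _localname(child) == name:
            return child
    return None


def _iter_named(el, name):
    for child in el.iter():
        if _localname(child) == name:
            yield child


def _decode_binary_array(bda) -> np.ndarray:
    params = _cv_params(bda)
    binary = _find_child(bda, "binary")
    raw = base64.b64decode(binary.text or "")
    if "MS:1000574" in params:  # zlib compression
        raw = zlib.decompress(raw)
    dtype = "<f4" if "MS:1000521" in params else "<f8"  # default 64-bit float
    return np.frombuffer(raw, dtype=dtype).astype(np.float64)


def _read_mzml(path: Path) -> List[ScanRecord]:
    records: List[ScanRecord] = []
    tree = etree.parse(str(path))
    for idx, spectrum in enumerate(_iter_named(tree.getroot(), "spectrum")):
        params = _cv_params(spectrum)
        level = int(params.get("MS:1000511", {}).get("value") or 1)
        if "MS:1000129" in params:
            polarity = -1
        elif "MS:1000130" in params:
            polarity = 1
        else:
            warnings.warn(f"scan in {path} lacks polarity metadata; assuming positive mode")
            polarity = 1

        rt = 0.0
        mobility = None
        scan_list = _find_child(spectrum, "scanList")
        if scan_list is not None:
            scan_el = _find_child(scan_list, "scan")
            if scan_el is not None:
                sp = _cv_params(scan_el)
                if "MS:1000016" in sp:
                    rt = float(sp["MS:1000016"]["value"])
                    if sp["MS:1000016"].get("unit") in ("second", "seconds"):
                        rt /= 60.0
                    elif sp["MS:1000016"].get("unit") == "millisecond":
                        rt /= 60000.0
                if "MS:1002815" in sp:
                    mobility = float(sp["MS:1002815"]["value"])

        arrays = {}
        for bda in _iter_named(spectrum, "binaryDataArray"):
            bp = _cv_params(bda)
            if "MS:1000514" in bp:
                arrays["mz"] = _decode_binary_array(bda)
            elif "MS:1000515" in bp:
                arrays["i"] = _decode_binary_array(bda)
        if "mz" not in arrays:
            raise ValueError(f"spectrum {spectrum.get('id')!r} in {path} lacks an m/z array")

        rec = ScanRecord(
            scan=_scan_number({"id": spectrum.get("id", "")}, idx + 1),
            mslevel=level,
            rt=rt,
            polarity=polarity,
            mz=arrays["mz"],
            i=arrays.get("i", np.zeros_like(arrays["mz"])),
            mobility=mobility,
        )
        if level >= 2:
            rec.precmz = np.nan
            rec.charge = polarity
            sel = next(_iter_named(spectrum, "selectedIon"), None)
            if sel is not None:
                ip = _cv_params(sel)
                if "MS:1000744" in ip:
                    rec.precmz = float(ip["MS:1000744"]["value"])
                if "MS:1000041" in ip:
                    rec.charge = abs(int(ip["MS:1000041"]["value"])) * polarity
        records.append(rec)
    return records


_ISO_DURATION_RE = re.compile(r"^PT(?:(\d+(?:\.\d+)?)M)?(?:(\d+(?:\.\d+)?)S)?$")


def _mzxml_rt_minutes(text: Optional[str]) -> float:
    if not text:
        return 0.0
    m = _ISO_DURATION_RE.match(text.strip())
    if m:
        minutes = float(m.group(1) or 0.0)
        seconds = float(m.group(2) or 0.0)
        return minutes + seconds / 60.0
    return float(text) / 60.0  # bare numbers are seconds by convention


def _read_mzxml(path: Path) -> List[ScanRecord]:
    records: List[ScanRecord] = []
    tree = etree.parse(str(path))
    for idx, scan in enumerate(_iter_named(tree.getroot(), "scan")):
        peaks = _find_child(scan, "peaks")
        if peaks is None:
            raise ValueError(f"scan {scan.get('num')!r} in {path} lacks a peaks element")
        raw = base64.b64decode(peaks.text or "")
        if peaks.get("compressionType") == "zlib":
            raw = zlib.decompress(raw)
        precision = peaks.get("precision", "32")
        # mzXML peak data is big-endian ("network") m/z-intensity pairs
        dtype = ">f8" if precision == "64" else ">f4"
        flat = np.frombuffer(raw, dtype=dtype).astype(np.float64)
        mz, intensity = flat[0::2], flat[1::2]

        pol_str = scan.get("polarity")
        if pol_str in ("+", "-"):
            polarity = 1 if pol_str == "+" else -1
        else:
            warnings.warn(f"scan in {path} lacks polarity metadata; assuming positive mode")
            polarity = 1
        level = int(scan.get("msLevel", "1"))
        rec = ScanRecord(
            scan=int(scan.get("num", idx + 1)),
            mslevel=level,
            rt=_mzxml_rt_minutes(scan.get("retentionTime")),
            polarity=polarity,
            mz=mz,
            i=intensity,
        )
        if level >= 2:
            prec = _find_child(scan, "precursorMz")
            if prec is not None and prec.text:
                rec.precmz = float(prec.text)
                charge = prec.get("precursorCharge")
                rec.charge = abs(int(charge)) * polarity if charge else polarity
            else:
                rec.precmz = np.nan
                rec.charge = polarity
        records.append(rec)
    return records


def _read_mgf(path: Path) -> List[ScanRecord]:
    records: List[ScanRecord] = []
    with _mgf.read(str(path)) as reader:
        for idx, spectrum in enumerate(reader):
            params = spectrum.get("params", {})
            if spectrum.get("m/z array") is None:
                raise ValueError(f"spectrum {idx + 1} in {path} lacks an m/z array")
            charge_list = params.get("charge")
            charge = int(charge_list[0]) if charge_list else None
            if charge is not None:
                polarity = 1 if charge >= 0 else -1
            else:
                warnings.warn(f"spectrum in {path} lacks charge metadata; assuming positive mode")
                polarity = 1
                charge = 1
            rt = params.get("rtinseconds")
            pepmass = params.get("pepmass", (np.nan,))
            records.append(
                ScanRecord(
                    scan=int(params.get("scans", idx + 1)),
                    mslevel=2,
                    rt=float(rt) / 60.0 if rt is not None else 0.0,
                    polarity=polarity,
                    mz=np.asarray(spectrum["m/z array"], dtype=np.float64),
                    i=np.asarray(spectrum["intensity array"], dtype=np.float64),
                    precmz=float(pepmass[0]) if pepmass[0] is not None else np.nan,
                    charge=charge,
                )
            )
    return records


# ---------------------------------------------------------------------------
# Cache

class CacheMissError(KeyError):
    pass


class CacheVersionError(RuntimeError):
    """Blob was written by a different cache version; regenerate."""


class CacheChecksumError(RuntimeError):
    """Blob bytes do not match their recorded checksum (corruption)."""


@dataclass
class SpectraCache:
    """On-disk cache of parsed PeakTables, keyed by source content hash."""

    path: Path
    version: int = CACHE_VERSION

    def __post_init__(self):
        self.path = Path(self.path)
        self.path.mkdir(parents=True, exist_ok=True)

    def key_for(self, source_path) -> str:
        h = hashlib.sha256()
        h.update(Path(source_path).read_bytes())
        return h.hexdigest()[:40]

    def _blob_dir(self, key: str) -> Path:
        return self.path / key

    def save(self, table: PeakTable, key: str) -> str:
        blob = self._blob_dir(key)
        blob.mkdir(parents=True, exist_ok=True)
        checksums = {}
        for name, df in (("ms1", table.ms1), ("ms2", table.ms2)):
            f = blob / f"{name}.parquet"
            df.to_parquet(f, engine="pyarrow", index=False)
            checksums[name] = hashlib.sha256(f.read_bytes()).hexdigest()
        (blob / "meta.json").write_text(
            json.dumps({"version": self.version, "checksums": checksums})
        )
        return key

    def load(self, key: str) -> PeakTable:
        blob = self._blob_dir(key)
        meta_path = blob / "meta.json"
        if not meta_path.exists():
            raise CacheMissError(key)
        meta = json.loads(meta_path.read_text())
        if meta.get("version") != self.version:
            raise CacheVersionError(
                f"cache blob {key} has version {meta.get('version')}, expected {self.version}"
            )
        frames = {}
        for name in ("ms1", "ms2"):
            f = blob / f"{name}.parquet"
            if not f.exists():
                raise CacheMissError(key)
            digest = hashlib.sha256(f.read_bytes()).hexdigest()
            if digest != meta["checksums"][name]:
                raise CacheChecksumError(f"checksum mismatch for {f}")
            frames[name] = pd.read_parquet(f, engine="pyarrow")
        return PeakTable(ms1=frames["ms1"], ms2=frames["ms2"])


def save_cache(table: PeakTable, cache: SpectraCache, key: str) -> str:
    return cache.save(table, key)


def load_cache(key: str, cache: SpectraCache) -> PeakTable:
    return cache.load(key)


def load_spectra_cached(path, cache: Optional[SpectraCache], format: Optional[str] = None) -> PeakTable:
    """Load a spectra file, using/refreshing the cache when one is given.

    A stale-version or missing blob triggers a re-parse and re-save; a
    checksum failure (corruption) propagates as an error.
    """
    if cache is None:
        return load_spectra(path, format=format)
    key = cache.key_for(path)
    try:
        return cache.load(key)
    except (CacheMissError, CacheVersionError):
        table = load_spectra(path, format=format)
        cache.save(table, key)
        return table


# ---------------------------------------------------------------------------
# Result-table writers

def write_result_table(result: pd.DataFrame, path, format: str = "tsv") -> None:
    """Write a result table as TSV (header + rows) or JSON (array of objects)."""
    path = Path(path)
    if format == "tsv":
        result.to_csv(path, sep="\t", index=False)
    elif format == "json":
        rows = []
        for _, row in result.iterrows():
            obj = {}
            for col, val in row.items():
                if isinstance(val, (np.floating, float)) and pd.isna(val):
                    obj[col] = None
                elif pd.isna(val):
                    obj[col] = None
                elif isinstance(val, np.integer):
                    obj[col] = int(val)
                elif isinstance(val, np.floating):
                    obj[col] = float(val)
                else:
                    obj[col] = val
            rows.append(obj)
        path.write_text(json.dumps(rows, indent=1))
    else:
        raise ValueError(f"unsupported result format {format!r}")


# ---------------------------------------------------------------------------
# Spectra exporters

def export_spectra(table: PeakTable, selection, path, format: str = "mgf") -> None:
    """Export selected scans as MGF, mzML or JSON.

    ``selection`` follows :func:`records_from_table`; ``None`` exports
    every scan.  An empty selection yields an empty-but-valid file.
    """
    pairs = records_from_table(table, selection)
    path = Path(path)
    if format == "mgf":
        _write_mgf(pairs, path)
    elif format == "mzml":
        write_mzml([rec for _, rec in pairs], path)
    elif format == "json":
        _write_json_spectra(pairs, path)
    else:
        raise ValueError(f"unsupported export format {format!r}")


def _write_mgf(pairs: List[Tuple[str, ScanRecord]], path: Path) -> None:
    spectra = []
    for file_id, rec in pairs:
        if rec.mslevel != 2:
            raise ValueError("MGF export supports MS2 scans only")
        charge = rec.charge if rec.charge is not None else rec.polarity
        params = {
            "title": f"{file_id} scan {rec.scan}",
            "pepmass": rec.precmz,
            "charge": f"{abs(charge)}{'+' if charge >= 0 else '-'}",
            "rtinseconds": rec.rt * 60.0,
            "scans": rec.scan,
        }
        spectra.append(
            {"m/z array": rec.mz, "intensity array": rec.i, "params": params}
        )
    with open(path, "w") as fh:
        _mgf.write(spectra, fh)


def _write_json_spectra(pairs: List[Tuple[str, ScanRecord]], path: Path) -> None:
    out = []
    for file_id, rec in pairs:
        obj = {
            "file_id": file_id,
            "scan": rec.scan,
            "mslevel": rec.mslevel,
            "rt": rec.rt,
            "polarity": rec.polarity,
            "mobility": rec.mobility,
            "mz": [float(v) for v in rec.mz],
            "i": [float(v) for v in rec.i],
        }
        if rec.mslevel >= 2:
            obj["precmz"] = rec.precmz
            obj["charge"] = rec.charge
            obj["ms1scan"] = rec.ms1scan
        out.append(obj)
    Path(path).write_text(json.dumps(out, indent=1))


# -- minimal PSI-mzML writer -------------------------------------------------

_MZML_NS = "http://psi.hupo.org/ms/mzml"


def _cv(parent, accession, name, value=None, unit=None):
    attrs = {"cvRef": "MS", "accession": accession, "name": name}
    if value is not None:
        attrs["value"] = str(value)
    if unit is not None:
        unit_acc, unit_name, unit_ref = unit
        attrs.update(
            {"unitAccession": unit_acc, "unitName": unit_name, "unitCvRef": unit_ref}
        )
    return etree.SubElement(parent, f"{{{_MZML_NS}}}cvParam", attrs)


def _b64(values: np.ndarray) -> str:
    raw = struct.pack(f"<{len(values)}d", *np.asarray(values, dtype=np.float64))
    return base64.b64encode(raw).decode("ascii")


def write_mzml(records: Sequence[ScanRecord], path) -> None:
    """Write scan records as a (minimal, uncompressed) PSI-mzML document.

    64-bit float arrays, no compression; retention time in minutes;
    positive/negative scan and centroid flags set per record.  The output
    re-reads with pyteomics to the same peaks within float precision.
    """
    E = lambda parent, tag, **attrs: etree.SubElement(  # noqa: E731
        parent, f"{{{_MZML_NS}}}{tag}", {k: str(v) for k, v in attrs.items()}
    )
    root = etree.Element(f"{{{_MZML_NS}}}mzML", {"version": "1.1.0"}, nsmap={None: _MZML_NS})
    cv_list = E(root, "cvList", count=2)
    E(
        cv_list, "cv", id="MS",
        fullName="Proteomics Standards Initiative Mass Spectrometry Ontology",
        URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo",
    )
    E(
        cv_list, "cv", id="UO", fullName="Unit Ontology",
        URI="http://obo.cvs.sourceforge.net/viewvc/obo/obo/ontology/phenotype/unit.obo",
    )
    fdesc = E(root, "fileDescription")
    fcontent = E(fdesc, "fileContent")
    _cv(fcontent, "MS:1000579", "MS1 spectrum")
    _cv(fcontent, "MS:1000580", "MSn spectrum")
    soft_list = E(root, "softwareList", count=1)
    soft = E(soft_list, "software", id="massql", version="0.1.0")
    _cv(soft, "MS:1000799", "custom unreleased software tool", value="massql")
    icl = E(root, "instrumentConfigurationList", count=1)
    ic = E(icl, "instrumentConfiguration", id="IC1")
    _cv(ic, "MS:1000031", "instrument model")
    dpl = E(root, "dataProcessingList", count=1)
    dp = E(dpl, "dataProcessing", id="DP1")
    pm = E(dp, "processingMethod", order=1, softwareRef="massql")
    _cv(pm, "MS:1000544", "Conversion to mzML")
    run = E(root, "run", id="run1", defaultInstrumentConfigurationRef="IC1")
    slist = E(run, "spectrumList", count=len(records), defaultDataProcessingRef="DP1")

    for index, rec in enumerate(records):
        spec = E(
            slist, "spectrum", index=index, id=f"scan={rec.scan}",
            defaultArrayLength=len(rec.mz),
        )
        _cv(spec, "MS:1000511", "ms level", value=rec.mslevel)
        if rec.mslevel == 1:
            _cv(spec, "MS:1000579", "MS1 spectrum")
        else:
            _cv(spec, "MS:1000580", "MSn spectrum")
        if rec.polarity >= 0:
            _cv(spec, "MS:1000130", "positive scan")
        else:
            _cv(spec, "MS:1000129", "negative scan")
        _cv(spec, "MS:1000127", "centroid spectrum")
        scan_list = E(spec, "scanList", count=1)
        _cv(scan_list, "MS:1000795", "no combination")
        scan = E(scan_list, "scan")
        _cv(
            scan, "MS:1000016", "scan start time", value=repr(float(rec.rt)),
            unit=("UO:0000031", "minute", "UO"),
        )
        if rec.mobility is not None:
            _cv(
                scan, "MS:1002815", "inverse reduced ion mobility",
                value=repr(float(rec.mobility)),
                unit=("MS:1002814", "volt-second per square centimeter", "MS"),
            )
        if rec.mslevel >= 2:
            plist = E(spec, "precursorList", count=1)
            prec = E(plist, "precursor")
            silist = E(prec, "selectedIonList", count=1)
            sion = E(silist, "selectedIon")
            if rec.precmz is not None and not (isinstance(rec.precmz, float) and np.isnan(rec.precmz)):
                _cv(
                    sion, "MS:1000744", "selected ion m/z", value=repr(float(rec.precmz)),
                    unit=("MS:1000040", "m/z", "MS"),
                )
            if rec.charge is not None:
                _cv(sion, "MS:1000041", "charge state", value=abs(int(rec.charge)))
            act = E(prec, "activation")
            _cv(act, "MS:1000044", "dissociation method")
        bdal = E(spec, "binaryDataArrayList", count=2)
        for accession, name, values, unit in (
            ("MS:1000514", "m/z array", rec.mz, ("MS:1000040", "m/z", "MS")),
            (
                "MS:1000515", "intensity array", rec.i,
                ("MS:1000131", "number of detector counts", "MS"),
            ),
        ):
            encoded = _b64(values)
            bda = E(bdal, "binaryDataArray", encodedLength=len(encoded))
            _cv(bda, "MS:1000523", "64-bit float")
            _cv(bda, "MS:1000576", "no compression")
            _cv(bda, accession, name, unit=unit)
            binary = E(bda, "binary")
            binary.text = encoded

    tree = etree.ElementTree(root)
    tree.write(str(path), xml_declaration=True, encoding="utf-8", pretty_print=True)
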