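"""Ground-truth synthetic MS datasets for testing pattern queries.

The generator plants two kinds of patterns among random decoy scans:

* ``iron_ms1`` — an MS1 isotope/adduct pattern characteristic of
  iron-bound compounds: the 56Fe monoisotopic apex at m/z x, the 54Fe
  isotope at x - 1.995327 with 6.3% of the apex intensity (the stable
  54Fe/56Fe ratio), the 13C satellite at x + 1.003355, and the metal-free
  (apo, proton-bound) species at x - 52.911462.
* ``phosphate_ms2`` — an MS/MS spectrum carrying the diagnostic
  phosphate fragment H4O4P+ at m/z 98.984172 above 50% of the base peak,
  as used to screen for organophosphate esters.

Planted peaks sit at the *theoretical* masses while the canonical screen
queries (:mod:`massql.queries`) use the printed four-/two-decimal
constants, so tests also exercise that printed-precision queries tolerate
theoretical data within their ppm windows.

Every decoy scan is certified pattern-free by the naive reference
evaluator; an accidental pattern match triggers a bounded resample.  The
resulting manifest therefore predicts the *exact* result set of both
screen queries, giving precision = recall = 1 by construction.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import masses
from .language import parse
from .naive import naive_execute
from .spectra import ScanRecord, PeakTable, table_from_records, export_spectra, write_mzml

__all__ = [
    "DELTA_54FE",
    "DELTA_13C",
    "DELTA_APO",
    "PHOSPHATE_FRAGMENT_MZ",
    "NoiseModel",
    "PlantedPattern",
    "FixtureManifest",
    "GenerationError",
    "plant_iron_pattern",
    "plant_phosphate_ms2",
    "generate_dataset",
]

#: theoretical mass deltas, derived from the embedded isotope table
DELTA_54FE = masses.mass_delta("56Fe", "54Fe")  # 1.995327 Da
DELTA_13C = masses.mass_delta("13C", "12C")  # 1.003355 Da
DELTA_APO = masses.mass_delta("56Fe-3H", "0")  # 52.911462 Da
PHOSPHATE_FRAGMENT_MZ = masses.formula_ion_mz("H4O4P")  # 98.984172

#: anchor m/z range used by the dataset generator.  The lower bound keeps
#: the printed-constant query windows (10 ppm around x - 1.993) wide
#: enough to capture the theoretical 54Fe spacing.
IRON_X_RANGE = (300.0, 880.0)

_RETRY_CAP = 100


class GenerationError(RuntimeError):
    """Raised when decoy resampling cannot produce a pattern-free scan."""


@dataclass
class NoiseModel:
    """Decoy peaks: log-uniform intensities over an m/z window."""

    n_decoy_peaks: int = 30
    mz_range: Tuple[float, float] = (100.0, 1000.0)
    intensity_range: Tuple[float, float] = (1e3, 1e6)

    def sample(self, rng: np.random.Generator, n: Optional[int] = None,
               exclude: Sequence[Tuple[float, float]] = ()) -> List[Tuple[float, float]]:
        """Draw decoy peaks, resampling any that land in an excluded
        (mz_lo, mz_hi) window."""
        n = self.n_decoy_peaks if n is None else n
        lo, hi = self.mz_range
        ilo, ihi = self.intensity_range
        peaks = []
        for _ in range(n):
            for _attempt in range(_RETRY_CAP):
                mz = float(rng.uniform(lo, hi))
                if not any(wlo <= mz <= whi for wlo, whi in exclude):
                    break
            else:
                raise GenerationError("could not sample a decoy peak outside excluded windows")
            intensity = float(np.exp(rng.uniform(np.log(ilo), np.log(ihi))))
            peaks.append((mz, intensity))
        return peaks


@dataclass
class PlantedPattern:
    kind: str  # "iron_ms1" | "phosphate_ms2"
    file: str  # mzML path
    scan: int
    x: float  # anchor m/z (iron) or fragment m/z (phosphate)
    y: float  # anchor/fragment raw intensity
    peaks: List[Tuple[float, float]] = field(default_factory=list)


@dataclass
class FixtureManifest:
    """Ground truth of a generated dataset: what was planted where."""

    seed: int
    files: List[Dict[str, str]] = field(default_factory=list)  # {"mzml":…, "mgf":…}
    patterns: List[PlantedPattern] = field(default_factory=list)
    noise: Dict = field(default_factory=dict)

    def planted_keys(self, kind: str, file_key: str = "mzml") -> set:
        lookup = {f["mzml"]: f for f in self.files}
        return {
            (lookup[p.file][file_key], p.scan)
            for p in self.patterns
            if p.kind == kind
        }

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "FixtureManifest":
        raw = json.loads(Path(path).read_text())
        patterns = [
            PlantedPattern(**{**p, "peaks": [tuple(pk) for pk in p["peaks"]]})
            for p in raw["patterns"]
        ]
        return cls(seed=raw["seed"], files=raw["files"], patterns=patterns, noise=raw["noise"])


# ---------------------------------------------------------------------------
# Pattern builders

def plant_iron_pattern(
    x: float,
    base_intensity: float,
    ratio54: float = 0.063,
    ratio13C: float = 0.30,
    apo_fraction: float = 0.5,
) -> List[Tuple[float, float]]:
    """Peak list of one iron-bound isotope/adduct pattern.

    Four peaks: the apex at ``x``, the 54Fe isotope at ``x - 1.995327``
    at ``ratio54`` of the apex (default 6.3%, the natural 54Fe/56Fe
    abundance ratio), the 13C satellite at ``x + 1.003355``, and the apo
    (iron-free, proton-bound) species at ``x - 52.911462``.  A zero
    fraction drops the corresponding peak.
    """
    if not 200.0 <= x <= 900.0:
        raise ValueError(f"anchor m/z {x} outside the supported range [200, 900]")
    peaks = [(x, base_intensity)]
    if ratio54 > 0:
        peaks.append((x - DELTA_54FE, ratio54 * base_intensity))
    if ratio13C > 0:
        peaks.append((x + DELTA_13C, ratio13C * base_intensity))
    if apo_fraction > 0:
        peaks.append((x - DELTA_APO, apo_fraction * base_intensity))
    return sorted(peaks)


def plant_phosphate_ms2(
    precursor_mz: float,
    fragment_rel_intensity: float = 0.8,
    n_noise: int = 20,
    rng: Optional[np.random.Generator] = None,
    noise: Optional[NoiseModel] = None,
    scan: int = 1,
    rt: float = 0.0,
) -> ScanRecord:
    """One MS2 scan with the diagnostic phosphate fragment planted.

    The fragment lands at the theoretical H4O4P+ m/z with
    ``fragment_rel_intensity`` of the scan's base-peak intensity; decoy
    peaks stay clear of the fragment's 50 ppm window.
    """
    if not 0.0 < fragment_rel_intensity <= 1.0:
        raise ValueError("fragment_rel_intensity must be in (0, 1]")
    rng = rng or np.random.default_rng(0)
    noise = noise or NoiseModel(n_decoy_peaks=n_noise)
    window = PHOSPHATE_FRAGMENT_MZ * 50e-6 * 2  # generous guard band
    decoys = noise.sample(
        rng, n=n_noise,
        exclude=[(PHOSPHATE_FRAGMENT_MZ - window, PHOSPHATE_FRAGMENT_MZ + window)],
    )
    base = max((i for _, i in decoys), default=1e5)
    fragment_i = fragment_rel_intensity * base
    peaks = sorted(decoys + [(PHOSPHATE_FRAGMENT_MZ, fragment_i)])
    mz = np.array([p[0] for p in peaks])
    intensity = np.array([p[1] for p in peaks])
    return ScanRecord(
        scan=scan, mslevel=2, rt=rt, polarity=1, mz=mz, i=intensity,
        precmz=precursor_mz, charge=1,
    )


# ---------------------------------------------------------------------------
# Dataset generation

def _split(total: int, parts: int) -> List[int]:
    base, rem = divmod(total, parts)
    return [base + (1 if k < rem else 0) for k in range(parts)]


def _certify(record: ScanRecord, query, expect: set) -> bool:
    """Check a single scan against a query with the naive evaluator."""
    table = table_from_records([record], file_id="certify")
    hits = naive_execute(query, table)
    return {k[1:] for k in hits} == expect  # drop file_id


def generate_dataset(
    outdir,
    n_files: int = 3,
    k_iron: int = 20,
    k_phosphate: int = 12,
    n_decoy_ms1: int = 500,
    n_decoy_ms2: int = 200,
    noise: Optional[NoiseModel] = None,
    seed: int = 0,
    iron_base_intensity: float = 2e6,
    write_manifest: bool = True,
) -> Tuple[List[Dict[str, str]], FixtureManifest]:
    """Write a ground-truth dataset (mzML + MGF renderings) and its manifest.

    Counts are totals across ``n_files`` and are split as evenly as
    possible.  Deterministic for a given seed.  Decoy scans (and planted
    scans' noise) are certified against both canonical screen queries by
    the naive evaluator; accidental matches are resampled up to 100 times
    per scan before generation fails.
    """
    from .queries import IRON_BINDING_QUERY, PHOSPHATE_FRAGMENT_QUERY

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    noise = noise or NoiseModel()
    iron_q = parse(IRON_BINDING_QUERY)
    phos_q = parse(PHOSPHATE_FRAGMENT_QUERY)

    manifest = FixtureManifest(
        seed=seed,
        noise={
            "n_decoy_peaks": noise.n_decoy_peaks,
            "mz_range": list(noise.mz_range),
            "intensity_range": list(noise.intensity_range),
        },
    )
    files: List[Dict[str, str]] = []

    iron_per = _split(k_iron, n_files)
    phos_per = _split(k_phosphate, n_files)
    dms1_per = _split(n_decoy_ms1, n_files)
    dms2_per = _split(n_decoy_ms2, n_files)

    for f in range(n_files):
        rng = np.random.default_rng([seed % (2**31), f])
        mzml_path = outdir / f"fixture_{f:02d}.mzML"
        mgf_path = outdir / f"fixture_{f:02d}.mgf"

        n_ms1 = dms1_per[f] + iron_per[f]
        n_ms2 = dms2_per[f] + phos_per[f]
        iron_slots = set(rng.choice(n_ms1, size=iron_per[f], replace=False).tolist())
        phos_slots = set(rng.choice(n_ms2, size=phos_per[f], replace=False).tolist())

        # MS1 scans first in acquisition order, MS2 interleaved after their
        # share of survey scans is unnecessary for query semantics; MS2
        # scans follow all MS1 scans and link to the last survey scan.
        total = n_ms1 + n_ms2
        rts = np.sort(rng.uniform(0.0, 20.0, size=total))

        records: List[ScanRecord] = []
        file_patterns: List[PlantedPattern] = []

        for k in range(n_ms1):
            scan_no = k + 1
            rt = float(rts[k])
            planted = k in iron_slots
            for attempt in range(_RETRY_CAP):
                if planted:
                    x = float(rng.uniform(*IRON_X_RANGE))
                    pattern = plant_iron_pattern(x, iron_base_intensity)
                    guard = [(mz - 0.02, mz + 0.02) for mz, _ in pattern]
                    peaks = sorted(pattern + noise.sample(rng, exclude=guard))
                else:
                    peaks = sorted(noise.sample(rng))
                rec = ScanRecord(
                    scan=scan_no, mslevel=1, rt=rt, polarity=1,
                    mz=np.array([p[0] for p in peaks]),
                    i=np.array([p[1] for p in peaks]),
                )
                expect = {(scan_no, x)} if planted else set()
                if _certify(rec, iron_q, expect):
                    break
            else:
                raise GenerationError(
                    f"scan {scan_no} of file {f} failed certification {_RETRY_CAP} times"
                )
            records.append(rec)
            if planted:
                file_patterns.append(
                    PlantedPattern(
                        kind="iron_ms1", file=str(mzml_path), scan=scan_no,
                        x=x, y=iron_base_intensity, peaks=pattern,
                    )
                )

        for k in range(n_ms2):
            scan_no = n_ms1 + k + 1
            rt = float(rts[n_ms1 + k])
            planted = k in phos_slots
            precursor = float(rng.uniform(200.0, 900.0))
            for attempt in range(_RETRY_CAP):
                if planted:
                    rec = plant_phosphate_ms2(
                        precursor, fragment_rel_intensity=0.8,
                        n_noise=noise.n_decoy_peaks, rng=rng, noise=noise,
                        scan=scan_no, rt=rt,
                    )
                    expect = {(scan_no,)}
                else:
                    decoys = sorted(noise.sample(rng))
                    rec = ScanRecord(
                        scan=scan_no, mslevel=2, rt=rt, polarity=1,
                        mz=np.array([p[0] for p in decoys]),
                        i=np.array([p[1] for p in decoys]),
                        precmz=precursor, charge=1,
                    )
                    expect = set()
                if _certify(rec, phos_q, expect):
                    break
            else:
                raise GenerationError(
                    f"scan {scan_no} of file {f} failed certification {_RETRY_CAP} times"
                )
            records.append(rec)
            if planted:
                frag_i = float(rec.i[np.argmin(np.abs(rec.mz - PHOSPHATE_FRAGMENT_MZ))])
                file_patterns.append(
                    PlantedPattern(
                        kind="phosphate_ms2", file=str(mzml_path), scan=scan_no,
                        x=PHOSPHATE_FRAGMENT_MZ, y=frag_i,
                        peaks=list(zip(rec.mz.tolist(), rec.i.tolist())),
                    )
                )

        # link MS2 scans to the most recent survey scan
        last_ms1 = None
        for rec in records:
            if rec.mslevel == 1:
                last_ms1 = rec.scan
            elif rec.ms1scan is None:
                rec.ms1scan = last_ms1

        write_mzml(records, mzml_path)
        table = table_from_records(records, file_id=str(mzml_path))
        ms2_keys = [(str(mzml_path), r.scan) for r in records if r.mslevel == 2]
        export_spectra(table, ms2_keys, mgf_path, format="mgf")

        files.append({"mzml": str(mzml_path), "mgf": str(mgf_path)})
        manifest.patterns.extend(file_patterns)

    manifest.files = files
    if write_manifest:
        manifest.to_json(outdir / "manifest.json")
    return files, manifest
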