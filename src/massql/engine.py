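"""Query evaluation over peak tables.

The engine takes a validated :class:`~massql.language.ParsedQuery` and a
:class:`~massql.spectra.PeakTable` and returns the scans (and, for
variable-anchored multi-peak patterns, the bindings of the anchor variable
X) whose peaks and metadata satisfy the Boolean condition tree.

Semantics in brief:

* A peak matches an m/z condition iff it lies within the condition's
  tolerance window (TOLERANCEMZ, or TOLERANCEPPM computed on the target
  m/z, or the configured default) and passes every intensity / mass-defect
  qualifier.
* AND across peak conditions means "same scan, each condition satisfied by
  at least one (possibly different) peak", with one consistent binding of
  X across all conditions of the query.
* EXCLUDED retains a scan iff *zero* peaks match the condition, all other
  qualifiers applied first.
* MS2NL=L matches a scan iff a product ion lies within tolerance of
  (precursor m/z - L) — the singly-charged neutral-loss reading.
* MS1MZ conditions inside an MS2DATA query are evaluated against the
  linked survey (MS1) scan.
* All range comparisons (RT, scan number, mobility, mass defect) are
  inclusive on both ends.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .language import (
    Condition,
    ConditionNode,
    ConditionType,
    NumericExpr,
    ParsedQuery,
    QualifierSet,
    validate,
)
from .spectra import PeakTable

__all__ = [
    "ExecutionConfig",
    "Binding",
    "ScanPeaks",
    "QueryValidationError",
    "execute",
    "peak_matches",
    "enumerate_bindings",
    "filter_metadata",
    "apply_excluded",
    "RESULT_COLUMNS",
]

RESULT_COLUMNS = [
    "file_id", "scan", "rt", "polarity", "mslevel",
    "precmz", "charge", "ms1scan", "matched_intensity",
]


class QueryValidationError(ValueError):
    def __init__(self, diagnostics):
        super().__init__("; ".join(d.message for d in diagnostics))
        self.diagnostics = diagnostics


@dataclass(frozen=True)
class ExecutionConfig:
    """Engine-wide defaults; the m/z window used when a condition names
    neither TOLERANCEMZ nor TOLERANCEPPM."""

    default_tolerance_mz: float = 0.1  # Da

    def __post_init__(self):
        if self.default_tolerance_mz <= 0:
            raise ValueError("default_tolerance_mz must be positive")


@dataclass(frozen=True)
class ScanPeaks:
    """The peak arrays of one scan."""

    mz: np.ndarray
    i: np.ndarray
    i_norm: np.ndarray
    i_tic_norm: np.ndarray

    def __len__(self) -> int:
        return len(self.mz)


@dataclass
class Binding:
    """One assignment of the query variable: X is the anchor peak's m/z,
    Y its raw intensity."""

    x: float
    y: float
    matched: Dict[int, np.ndarray] = field(default_factory=dict)


@dataclass
class _Scan:
    file_id: str
    scan: int
    mslevel: int
    rt: float
    polarity: int
    mobility: float  # NaN when absent
    peaks: ScanPeaks
    precmz: float = math.nan
    charge: Optional[int] = None
    ms1scan: Optional[int] = None
    ms1_peaks: Optional[ScanPeaks] = None  # linked survey scan (MS2 only)

    @property
    def key(self) -> Tuple[str, int]:
        return (self.file_id, self.scan)


_EMPTY_PEAKS = ScanPeaks(
    np.empty(0), np.empty(0), np.empty(0), np.empty(0)
)


def _group_peaks(df: pd.DataFrame) -> Dict[Tuple[str, int], ScanPeaks]:
    out: Dict[Tuple[str, int], ScanPeaks] = {}
    for (file_id, scan), g in df.groupby(["file_id", "scan"], sort=True):
        out[(str(file_id), int(scan))] = ScanPeaks(
            g["mz"].to_numpy(),
            g["i"].to_numpy(),
            g["i_norm"].to_numpy(),
            g["i_tic_norm"].to_numpy(),
        )
    return out


def _scan_index(table: PeakTable, datatype: str) -> List[_Scan]:
    if datatype == "MS1DATA":
        peaks = _group_peaks(table.ms1)
        scans = []
        meta = table.ms1.drop_duplicates(subset=["file_id", "scan"])
        for _, row in meta.iterrows():
            key = (str(row["file_id"]), int(row["scan"]))
            scans.append(
                _Scan(
                    file_id=key[0], scan=key[1], mslevel=1,
                    rt=float(row["rt"]), polarity=int(row["polarity"]),
                    mobility=float(row["mobility"]), peaks=peaks[key],
                )
            )
        return sorted(scans, key=lambda s: s.key)

    peaks2 = _group_peaks(table.ms2)
    peaks1 = _group_peaks(table.ms1)
    scans = []
    meta = table.ms2.drop_duplicates(subset=["file_id", "scan"])
    for _, row in meta.iterrows():
        key = (str(row["file_id"]), int(row["scan"]))
        ms1scan = None if pd.isna(row["ms1scan"]) else int(row["ms1scan"])
        scans.append(
            _Scan(
                file_id=key[0], scan=key[1], mslevel=2,
                rt=float(row["rt"]), polarity=int(row["polarity"]),
                mobility=float(row["mobility"]), peaks=peaks2[key],
                precmz=float(row["precmz"]),
                charge=None if pd.isna(row["charge"]) else int(row["charge"]),
                ms1scan=ms1scan,
                ms1_peaks=peaks1.get((key[0], ms1scan)) if ms1scan is not None else None,
            )
        )
    return sorted(scans, key=lambda s: s.key)


# ---------------------------------------------------------------------------
# Peak matching

def _tolerance(q: QualifierSet, target: float, config: ExecutionConfig) -> float:
    if q.tolerance_mz is not None:
        return q.tolerance_mz
    if q.tolerance_ppm is not None:
        return q.tolerance_ppm * abs(target) * 1e-6
    return config.default_tolerance_mz


def peak_matches(
    peaks: ScanPeaks,
    target: "NumericExpr | float",
    qualifiers: QualifierSet,
    binding: Optional[Binding] = None,
    config: Optional[ExecutionConfig] = None,
) -> np.ndarray:
    """Boolean mask over a scan's peaks for one m/z condition.

    A peak matches iff |mz - target| <= tolerance AND it passes every
    intensity qualifier (absolute, % of base peak, % of TIC), the
    mass-defect window, and — for INTENSITYMATCH — lies within the
    relative band ``|i/Y - r| <= r * percent/100`` around the expected
    ratio r to the anchor-peak intensity Y.
    """
    config = config or ExecutionConfig()
    if isinstance(target, NumericExpr):
        target = target.resolve(binding.x if binding is not None else None)
    q = qualifiers
    tol = _tolerance(q, target, config)
    mask = np.abs(peaks.mz - target) <= tol
    if q.intensity_value is not None:
        mask &= peaks.i >= q.intensity_value
    if q.intensity_percent is not None:
        mask &= peaks.i_norm >= q.intensity_percent / 100.0
    if q.intensity_tic_percent is not None:
        mask &= peaks.i_tic_norm >= q.intensity_tic_percent / 100.0
    if q.mass_defect is not None:
        frac = np.mod(peaks.mz, 1.0)
        mask &= (frac >= q.mass_defect.min) & (frac <= q.mass_defect.max)
    if q.intensity_match_ratio is not None:
        if binding is None:
            raise ValueError("INTENSITYMATCH requires a variable binding")
        r = q.intensity_match_ratio
        band = r * (q.intensity_match_percent or 0.0) / 100.0
        mask &= np.abs(peaks.i / binding.y - r) <= band
    return mask


def _candidate_mask(peaks: ScanPeaks, q: QualifierSet) -> np.ndarray:
    """Anchor-candidate filter: the non-relational qualifiers only."""
    mask = np.ones(len(peaks), dtype=bool)
    if q.intensity_value is not None:
        mask &= peaks.i >= q.intensity_value
    if q.intensity_percent is not None:
        mask &= peaks.i_norm >= q.intensity_percent / 100.0
    if q.intensity_tic_percent is not None:
        mask &= peaks.i_tic_norm >= q.intensity_tic_percent / 100.0
    if q.mass_defect is not None:
        frac = np.mod(peaks.mz, 1.0)
        mask &= (frac >= q.mass_defect.min) & (frac <= q.mass_defect.max)
    return mask


# ---------------------------------------------------------------------------
# Leaf evaluation

def _peak_source(cond: Condition, scan: _Scan) -> Optional[ScanPeaks]:
    if cond.type is ConditionType.MS1MZ and scan.mslevel == 2:
        return scan.ms1_peaks
    return scan.peaks


def _eval_leaf(
    cond: Condition, scan: _Scan, config: ExecutionConfig, x: Optional[float], y: Optional[float]
) -> Tuple[bool, float]:
    """Evaluate one condition on one scan; returns (holds, matched intensity)."""
    t = cond.type
    q = cond.qualifiers

    if t is ConditionType.RTMIN:
        return scan.rt >= float(cond.value), math.nan
    if t is ConditionType.RTMAX:
        return scan.rt <= float(cond.value), math.nan
    if t is ConditionType.SCANMIN:
        return scan.scan >= float(cond.value), math.nan
    if t is ConditionType.SCANMAX:
        return scan.scan <= float(cond.value), math.nan
    if t is ConditionType.POLARITY:
        want = 1 if cond.value == "Positive" else -1
        return scan.polarity == want, math.nan
    if t is ConditionType.CHARGE:
        if scan.charge is None:
            return False, math.nan
        return abs(scan.charge) == int(float(cond.value)), math.nan
    if t is ConditionType.MOBILITY:
        if math.isnan(scan.mobility):
            return False, math.nan
        rng = cond.value
        return rng.min <= scan.mobility <= rng.max, math.nan

    binding = Binding(x, y) if x is not None else None

    if t is ConditionType.MS2PREC:
        if math.isnan(scan.precmz):
            holds = False
        else:
            target = cond.value.resolve(x)
            tol = _tolerance(q, target, config)
            holds = abs(scan.precmz - target) <= tol
            if holds and q.mass_defect is not None:
                holds = q.mass_defect.min <= scan.precmz % 1.0 <= q.mass_defect.max
        return (not holds) if q.excluded else holds, math.nan

    # peak-list conditions: MS1MZ, MS2PROD, MS2NL
    source = _peak_source(cond, scan)
    if source is None or len(source) == 0:
        matches = np.zeros(0, dtype=bool)
        intensities = np.empty(0)
    else:
        if t is ConditionType.MS2NL:
            if math.isnan(scan.precmz):
                return (True, math.nan) if q.excluded else (False, math.nan)
            target = scan.precmz - cond.value.resolve(x)
        else:
            target = cond.value.resolve(x)
        matches = peak_matches(source, target, q, binding, config)
        intensities = source.i[matches]
    if q.excluded:
        return not matches.any(), math.nan
    if matches.any():
        return True, float(intensities.max())
    return False, math.nan


def _eval_node(
    node: ConditionNode, scan: _Scan, config: ExecutionConfig, x: Optional[float], y: Optional[float]
) -> Tuple[bool, float]:
    if node.kind == "LEAF":
        return _eval_leaf(node.leaf, scan, config, x, y)
    results = [_eval_node(c, scan, config, x, y) for c in node.children]
    if node.kind == "AND":
        if all(r[0] for r in results):
            vals = [r[1] for r in results if not math.isnan(r[1])]
            return True, max(vals) if vals else math.nan
        return False, math.nan
    # OR
    true_vals = [r[1] for r in results if r[0]]
    if true_vals:
        vals = [v for v in true_vals if not math.isnan(v)]
        return True, max(vals) if vals else math.nan
    return False, math.nan


# ---------------------------------------------------------------------------
# Variable bindings

def _variable_conditions(query: ParsedQuery) -> List[Condition]:
    if query.where is None:
        return []
    return [
        c
        for c in query.where.iter_leaves()
        if isinstance(c.value, NumericExpr) and c.value.variable
    ]


def _anchor_condition(conditions: Sequence[Condition]) -> Condition:
    anchors = [c for c in conditions if isinstance(c.value, NumericExpr) and c.value.is_anchor]
    if not anchors:
        raise ValueError("variable query lacks an anchor condition (value X)")
    return anchors[0]


def enumerate_bindings(
    peaks: ScanPeaks,
    variable_conditions: Sequence[Condition],
    config: Optional[ExecutionConfig] = None,
) -> List[Binding]:
    """Enumerate assignments of X over one scan's peak list.

    Candidate X values are the m/z of peaks passing the anchor condition's
    non-relational qualifiers; a binding is emitted iff every variable
    condition has at least one matching peak under it.  Bindings come back
    sorted by X ascending.
    """
    config = config or ExecutionConfig()
    anchor = _anchor_condition(variable_conditions)
    candidates = np.flatnonzero(_candidate_mask(peaks, anchor.qualifiers))
    bindings: List[Binding] = []
    order = candidates[np.argsort(peaks.mz[candidates], kind="stable")]
    seen_x = set()
    for idx in order:
        x, y = float(peaks.mz[idx]), float(peaks.i[idx])
        if x in seen_x:
            continue
        binding = Binding(x, y)
        ok = True
        for ci, cond in enumerate(variable_conditions):
            mask = peak_matches(peaks, cond.value, cond.qualifiers, binding, config)
            if cond.qualifiers.excluded:
                if mask.any():
                    ok = False
                    break
                binding.matched[ci] = np.empty(0, dtype=int)
            elif mask.any():
                binding.matched[ci] = np.flatnonzero(mask)
            else:
                ok = False
                break
        if ok:
            seen_x.add(x)
            bindings.append(binding)
    return bindings


def _candidate_bindings(
    query: ParsedQuery, scan: _Scan, config: ExecutionConfig
) -> List[Tuple[float, float]]:
    """(X, Y) candidates for a scan: peaks passing the anchor's own filters."""
    var_conds = _variable_conditions(query)
    anchor = _anchor_condition(var_conds)
    source = _peak_source(anchor, scan)
    if source is None or len(source) == 0:
        return []
    mask = _candidate_mask(source, anchor.qualifiers)
    idx = np.flatnonzero(mask)
    idx = idx[np.argsort(source.mz[idx], kind="stable")]
    out = []
    seen = set()
    for k in idx:
        x = float(source.mz[k])
        if x in seen:
            continue
        seen.add(x)
        out.append((x, float(source.i[k])))
    return out


# ---------------------------------------------------------------------------
# Metadata-only helpers (exposed operations)

_METADATA_TYPES = frozenset(
    {
        ConditionType.RTMIN, ConditionType.RTMAX, ConditionType.SCANMIN,
        ConditionType.SCANMAX, ConditionType.POLARITY, ConditionType.CHARGE,
        ConditionType.MOBILITY,
    }
)


def filter_metadata(
    conditions: Iterable[Condition], table: PeakTable, datatype: str = "MS1DATA"
) -> set:
    """Scan keys passing a conjunction of metadata conditions.

    RT and scan bounds are inclusive; CHARGE compares the absolute charge;
    MOBILITY is an inclusive range.
    """
    config = ExecutionConfig()
    conditions = list(conditions)
    for cond in conditions:
        if cond.type not in _METADATA_TYPES:
            raise ValueError(f"{cond.type.value} is not a metadata condition")
    retained = set()
    for scan in _scan_index(table, datatype):
        if all(_eval_leaf(c, scan, config, None, None)[0] for c in conditions):
            retained.add(scan.key)
    return retained


def apply_excluded(
    condition: Condition,
    table: PeakTable,
    datatype: str = "MS2DATA",
    config: Optional[ExecutionConfig] = None,
) -> set:
    """Scan keys retained by an EXCLUDED condition: scans with zero
    matching peaks (all non-excluded qualifiers applied first)."""
    config = config or ExecutionConfig()
    if not condition.qualifiers.excluded:
        raise ValueError("condition is not flagged EXCLUDED")
    retained = set()
    for scan in _scan_index(table, datatype):
        holds, _ = _eval_leaf(condition, scan, config, None, None)
        if holds:
            retained.add(scan.key)
    return retained


# ---------------------------------------------------------------------------
# Execution

def _result_row(scan: _Scan, intensity: float) -> dict:
    return {
        "file_id": scan.file_id,
        "scan": scan.scan,
        "rt": scan.rt,
        "polarity": scan.polarity,
        "mslevel": scan.mslevel,
        "precmz": scan.precmz,
        "charge": np.nan if scan.charge is None else scan.charge,
        "ms1scan": np.nan if scan.ms1scan is None else scan.ms1scan,
        "matched_intensity": intensity,
    }


def execute(
    query: ParsedQuery,
    table: PeakTable,
    config: Optional[ExecutionConfig] = None,
) -> pd.DataFrame:
    """Run a query against a peak table.

    Returns one row per retained scan (per binding of X for variable
    queries), sorted by (file_id, scan, X); ``scannum`` reduces the
    columns to scan identifiers, ``scansum`` aggregates to a single row
    with the summed matched intensity.  A query whose data level has no
    scans returns an empty result, not an error.
    """
    config = config or ExecutionConfig()
    diags = [d for d in validate(query) if d.level == "error"]
    if diags:
        raise QueryValidationError(diags)

    scans = _scan_index(table, query.datatype)
    rows: List[dict] = []
    uses_x = query.uses_variable

    for scan in scans:
        if query.where is None:
            rows.append(_result_row(scan, math.nan))
            continue
        if not uses_x:
            holds, intensity = _eval_node(query.where, scan, config, None, None)
            if holds:
                rows.append(_result_row(scan, intensity))
            continue
        for x, y in _candidate_bindings(query, scan, config):
            holds, intensity = _eval_node(query.where, scan, config, x, y)
            if holds:
                row = _result_row(scan, intensity)
                row["X"] = x
                row["Y"] = y
                rows.append(row)

    columns = RESULT_COLUMNS + (["X", "Y"] if uses_x else [])
    result = pd.DataFrame(rows, columns=columns)
    sort_cols = ["file_id", "scan"] + (["X"] if uses_x else [])
    result = result.sort_values(sort_cols, kind="stable").drop_duplicates(
        subset=sort_cols
    )
    result = result.reset_index(drop=True)

    if query.function == "scannum":
        return result[["file_id", "scan"]].drop_duplicates().reset_index(drop=True)
    if query.function == "scansum":
        per_scan = result.groupby(["file_id", "scan"], sort=True)["matched_intensity"].max()
        total = float(np.nansum(per_scan.to_numpy())) if len(per_scan) else 0.0
        return pd.DataFrame(
            [{"matched_intensity": total, "n_scans": int(per_scan.shape[0])}]
        )
    return result
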