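"""A deliberately naive reference evaluator for the query language.

This module re-implements query semantics as plain Python loops over
scans x peaks x conditions x candidate bindings, sharing no evaluation
code with :mod:`massql.engine`.  It exists for two jobs: certifying that
synthetic decoy scans really contain no planted pattern, and serving as
the independent cross-check the engine's property tests compare against.
It is O(everything) and proud of it — do not use it on real data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

from .language import Condition, ConditionNode, ConditionType, NumericExpr, ParsedQuery
from .spectra import PeakTable

__all__ = ["SimpleScan", "scans_from_table", "naive_execute", "naive_result_keys"]

_DEFAULT_TOL = 0.1  # Da; mirrors the engine default independently


@dataclass
class SimpleScan:
    """A scan as plain Python data: metadata plus (mz, intensity) tuples."""

    file_id: str
    scan: int
    mslevel: int
    rt: float
    polarity: int
    peaks: List[Tuple[float, float]]
    mobility: Optional[float] = None
    precmz: Optional[float] = None
    charge: Optional[int] = None
    ms1_peaks: Optional[List[Tuple[float, float]]] = None


def scans_from_table(table: PeakTable) -> List[SimpleScan]:
    """Flatten a PeakTable into SimpleScan objects (both MS levels)."""
    ms1_peaks: Dict[Tuple[str, int], List[Tuple[float, float]]] = {}
    scans: List[SimpleScan] = []
    for (file_id, scan), g in table.ms1.groupby(["file_id", "scan"], sort=True):
        peaks = list(zip(g["mz"].tolist(), g["i"].tolist()))
        ms1_peaks[(str(file_id), int(scan))] = peaks
        first = g.iloc[0]
        scans.append(
            SimpleScan(
                file_id=str(file_id), scan=int(scan), mslevel=1,
                rt=float(first["rt"]), polarity=int(first["polarity"]),
                peaks=peaks,
                mobility=None if math.isnan(first["mobility"]) else float(first["mobility"]),
            )
        )
    import pandas as pd  # only for NA handling at the boundary

    for (file_id, scan), g in table.ms2.groupby(["file_id", "scan"], sort=True):
        first = g.iloc[0]
        link = None
        if not pd.isna(first["ms1scan"]):
            link = ms1_peaks.get((str(file_id), int(first["ms1scan"])))
        scans.append(
            SimpleScan(
                file_id=str(file_id), scan=int(scan), mslevel=2,
                rt=float(first["rt"]), polarity=int(first["polarity"]),
                peaks=list(zip(g["mz"].tolist(), g["i"].tolist())),
                mobility=None if math.isnan(first["mobility"]) else float(first["mobility"]),
                precmz=float(first["precmz"]),
                charge=None if pd.isna(first["charge"]) else int(first["charge"]),
                ms1_peaks=link,
            )
        )
    return scans


def _base_peak(peaks: Sequence[Tuple[float, float]]) -> float:
    return max(i for _, i in peaks) if peaks else 0.0


def _tic(peaks: Sequence[Tuple[float, float]]) -> float:
    return sum(i for _, i in peaks) if peaks else 0.0


def _tol_of(cond: Condition, target: float, default_tol: float) -> float:
    q = cond.qualifiers
    if q.tolerance_mz is not None:
        return q.tolerance_mz
    if q.tolerance_ppm is not None:
        return q.tolerance_ppm * abs(target) * 1e-6
    return default_tol


def _peak_ok(
    cond: Condition,
    mz: float,
    i: float,
    target: float,
    base: float,
    tic: float,
    y: Optional[float],
    default_tol: float,
) -> bool:
    q = cond.qualifiers
    if abs(mz - target) > _tol_of(cond, target, default_tol):
        return False
    if q.intensity_value is not None and i < q.intensity_value:
        return False
    if q.intensity_percent is not None and (base <= 0 or i / base < q.intensity_percent / 100.0):
        return False
    if q.intensity_tic_percent is not None and (
        tic <= 0 or i / tic < q.intensity_tic_percent / 100.0
    ):
        return False
    if q.mass_defect is not None and not (q.mass_defect.min <= mz % 1.0 <= q.mass_defect.max):
        return False
    if q.intensity_match_ratio is not None:
        if y is None:
            raise ValueError("INTENSITYMATCH needs a binding")
        r = q.intensity_match_ratio
        band = r * (q.intensity_match_percent or 0.0) / 100.0
        if abs(i / y - r) > band:
            return False
    return True


def _cond_peaks(
    cond: Condition, scan: SimpleScan
) -> Optional[List[Tuple[float, float]]]:
    if cond.type is ConditionType.MS1MZ and scan.mslevel == 2:
        return scan.ms1_peaks
    return scan.peaks


def _leaf_holds(
    cond: Condition, scan: SimpleScan, x: Optional[float], y: Optional[float], default_tol: float
) -> bool:
    t = cond.type
    q = cond.qualifiers
    if t is ConditionType.RTMIN:
        return scan.rt >= float(cond.value)
    if t is ConditionType.RTMAX:
        return scan.rt <= float(cond.value)
    if t is ConditionType.SCANMIN:
        return scan.scan >= float(cond.value)
    if t is ConditionType.SCANMAX:
        return scan.scan <= float(cond.value)
    if t is ConditionType.POLARITY:
        return scan.polarity == (1 if cond.value == "Positive" else -1)
    if t is ConditionType.CHARGE:
        return scan.charge is not None and abs(scan.charge) == int(float(cond.value))
    if t is ConditionType.MOBILITY:
        return scan.mobility is not None and cond.value.min <= scan.mobility <= cond.value.max
    if t is ConditionType.MS2PREC:
        if scan.precmz is None or math.isnan(scan.precmz):
            holds = False
        else:
            target = cond.value.resolve(x)
            holds = abs(scan.precmz - target) <= _tol_of(cond, target, default_tol)
            if holds and q.mass_defect is not None:
                holds = q.mass_defect.min <= scan.precmz % 1.0 <= q.mass_defect.max
        return (not holds) if q.excluded else holds

    peaks = _cond_peaks(cond, scan)
    if not peaks:
        return q.excluded
    if t is ConditionType.MS2NL:
        if scan.precmz is None or math.isnan(scan.precmz):
            return q.excluded
        target = scan.precmz - cond.value.resolve(x)
    else:
        target = cond.value.resolve(x)
    base, tic = _base_peak(peaks), _tic(peaks)
    any_match = False
    for mz, i in peaks:
        if _peak_ok(cond, mz, i, target, base, tic, y, default_tol):
            any_match = True
            break
    return (not any_match) if q.excluded else any_match


def _node_holds(
    node: ConditionNode, scan: SimpleScan, x: Optional[float], y: Optional[float], default_tol: float
) -> bool:
    if node.kind == "LEAF":
        return _leaf_holds(node.leaf, scan, x, y, default_tol)
    if node.kind == "AND":
        return all(_node_holds(c, scan, x, y, default_tol) for c in node.children)
    return any(_node_holds(c, scan, x, y, default_tol) for c in node.children)


def _anchor_candidates(
    query: ParsedQuery, scan: SimpleScan, default_tol: float
) -> List[Tuple[float, float]]:
    anchors = [
        c
        for c in query.where.iter_leaves()
        if isinstance(c.value, NumericExpr) and c.value.is_anchor
    ]
    anchor = anchors[0]
    peaks = _cond_peaks(anchor, scan)
    if not peaks:
        return []
    base, tic = _base_peak(peaks), _tic(peaks)
    q = anchor.qualifiers
    out = []
    seen = set()
    for mz, i in sorted(peaks):
        if mz in seen:
            continue
        if q.intensity_value is not None and i < q.intensity_value:
            continue
        if q.intensity_percent is not None and (base <= 0 or i / base < q.intensity_percent / 100.0):
            continue
        if q.intensity_tic_percent is not None and (
            tic <= 0 or i / tic < q.intensity_tic_percent / 100.0
        ):
            continue
        if q.mass_defect is not None and not (
            q.mass_defect.min <= mz % 1.0 <= q.mass_defect.max
        ):
            continue
        seen.add(mz)
        out.append((mz, i))
    return out


def naive_execute(
    query: ParsedQuery, table: PeakTable, default_tolerance_mz: float = _DEFAULT_TOL
) -> Set[tuple]:
    """Evaluate a query by exhaustive loops.

    Returns the retained set of (file_id, scan) keys, or — when the query
    uses the variable X — (file_id, scan, X) triples.
    """
    wanted_level = 1 if query.datatype == "MS1DATA" else 2
    scans = [s for s in scans_from_table(table) if s.mslevel == wanted_level]
    uses_x = query.uses_variable
    out: Set[tuple] = set()
    for scan in scans:
        if query.where is None:
            out.add((scan.file_id, scan.scan))
            continue
        if not uses_x:
            if _node_holds(query.where, scan, None, None, default_tolerance_mz):
                out.add((scan.file_id, scan.scan))
            continue
        for x, y in _anchor_candidates(query, scan, default_tolerance_mz):
            if _node_holds(query.where, scan, x, y, default_tolerance_mz):
                out.add((scan.file_id, scan.scan, x))
    return out


def naive_result_keys(
    query: ParsedQuery, table: PeakTable, default_tolerance_mz: float = _DEFAULT_TOL
) -> Set[Tuple[str, int]]:
    """Scan-level view of :func:`naive_execute` (bindings collapsed)."""
    return {(k[0], k[1]) for k in naive_execute(query, table, default_tolerance_mz)}
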