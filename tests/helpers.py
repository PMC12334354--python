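"""Shared test utilities: compact builders for in-memory peak tables and
randomized (query, dataset) pairs for cross-checking the engine against
the naive evaluator."""

from __future__ import annotations

from typing import List, Optional, Sequence, Tuple

import numpy as np

from massql.language import (
    Condition,
    ConditionNode,
    ConditionType,
    NumericExpr,
    ParsedQuery,
    QualifierSet,
    Range,
    validate,
)
from massql.spectra import PeakTable, ScanRecord, table_from_records


def make_scan(
    scan: int,
    mslevel: int = 1,
    peaks: Sequence[Tuple[float, float]] = ((100.0, 1e3),),
    rt: float = 1.0,
    polarity: int = 1,
    mobility: Optional[float] = None,
    precmz: Optional[float] = None,
    charge: Optional[int] = None,
    ms1scan: Optional[int] = None,
) -> ScanRecord:
    mz = np.array([p[0] for p in peaks], dtype=float)
    i = np.array([p[1] for p in peaks], dtype=float)
    return ScanRecord(
        scan=scan, mslevel=mslevel, rt=rt, polarity=polarity, mz=mz, i=i,
        mobility=mobility, precmz=precmz, charge=charge, ms1scan=ms1scan,
    )


def make_table(records: Sequence[ScanRecord], file_id: str = "mem") -> PeakTable:
    return table_from_records(records, file_id=file_id)


# ---------------------------------------------------------------------------
# Randomized (dataset, query) pairs

def random_dataset(rng: np.random.Generator, file_id: str = "rand") -> PeakTable:
    records: List[ScanRecord] = []
    scan = 1
    last_ms1 = None
    for _ in range(int(rng.integers(3, 7))):
        n = int(rng.integers(2, 8))
        records.append(
            make_scan(
                scan, 1,
                peaks=list(zip(rng.uniform(100, 500, n).round(3), rng.uniform(1e3, 1e6, n))),
                rt=round(float(rng.uniform(0, 20)), 2),
                polarity=int(rng.choice([1, -1], p=[0.8, 0.2])),
                mobility=round(float(rng.uniform(0.5, 2.5)), 3) if rng.random() < 0.5 else None,
            )
        )
        last_ms1 = scan
        scan += 1
    for _ in range(int(rng.integers(3, 7))):
        n = int(rng.integers(2, 8))
        polarity = int(rng.choice([1, -1], p=[0.8, 0.2]))
        records.append(
            make_scan(
                scan, 2,
                peaks=list(zip(rng.uniform(50, 450, n).round(3), rng.uniform(1e3, 1e6, n))),
                rt=round(float(rng.uniform(0, 20)), 2),
                polarity=polarity,
                precmz=round(float(rng.uniform(150, 600)), 3),
                charge=int(rng.choice([1, 2, 3])) * polarity,
                ms1scan=last_ms1 if rng.random() < 0.8 else None,
            )
        )
        scan += 1
    return make_table(records, file_id=file_id)


def _peak_pool(table: PeakTable, datatype: str, cond_type: ConditionType) -> np.ndarray:
    if cond_type is ConditionType.MS1MZ:
        return table.ms1["mz"].to_numpy()
    if cond_type is ConditionType.MS2PROD:
        return table.ms2["mz"].to_numpy()
    if cond_type is ConditionType.MS2PREC:
        return table.ms2["precmz"].to_numpy()
    return np.array([])


def _random_mz_qualifiers(rng: np.random.Generator, cond_type: ConditionType) -> QualifierSet:
    kw = {}
    roll = rng.random()
    if roll < 0.4:
        kw["tolerance_mz"] = float(rng.choice([0.01, 0.05, 0.2, 0.5]))
    elif roll < 0.8:
        kw["tolerance_ppm"] = float(rng.choice([5.0, 50.0, 200.0, 1000.0]))
    if cond_type in (ConditionType.MS1MZ, ConditionType.MS2PROD):
        if rng.random() < 0.3:
            kw["intensity_percent"] = float(rng.choice([5.0, 10.0, 50.0, 80.0]))
        if rng.random() < 0.2:
            kw["intensity_value"] = float(rng.choice([1e3, 1e5, 5e5]))
        if rng.random() < 0.2:
            kw["intensity_tic_percent"] = float(rng.choice([1.0, 5.0, 20.0]))
    if cond_type is not ConditionType.MS2NL and rng.random() < 0.15:
        lo = round(float(rng.uniform(0, 0.8)), 2)
        kw["mass_defect"] = Range(lo, min(1.0, lo + float(rng.uniform(0.05, 0.4))))
    if rng.random() < 0.2:
        kw["excluded"] = True
    return QualifierSet(**kw)


def _random_leaf(rng: np.random.Generator, table: PeakTable, datatype: str) -> Condition:
    if datatype == "MS2DATA":
        pool = [
            ConditionType.MS2PROD, ConditionType.MS2PROD, ConditionType.MS2PREC,
            ConditionType.MS2NL, ConditionType.MS1MZ, ConditionType.CHARGE,
            ConditionType.RTMIN, ConditionType.RTMAX, ConditionType.POLARITY,
            ConditionType.SCANMIN, ConditionType.SCANMAX,
        ]
    else:
        pool = [
            ConditionType.MS1MZ, ConditionType.MS1MZ, ConditionType.RTMIN,
            ConditionType.RTMAX, ConditionType.POLARITY, ConditionType.SCANMIN,
            ConditionType.SCANMAX, ConditionType.MOBILITY,
        ]
    ctype = pool[int(rng.integers(len(pool)))]
    if ctype in (ConditionType.MS1MZ, ConditionType.MS2PROD, ConditionType.MS2PREC):
        peaks = _peak_pool(table, datatype, ctype)
        if len(peaks) and rng.random() < 0.65:
            target = float(peaks[int(rng.integers(len(peaks)))]) + float(
                rng.normal(0, 0.01)
            )
        else:
            target = round(float(rng.uniform(50, 600)), 3)
        return Condition(ctype, NumericExpr(False, round(target, 4)),
                         _random_mz_qualifiers(rng, ctype))
    if ctype is ConditionType.MS2NL:
        ms2 = table.ms2
        if len(ms2) and rng.random() < 0.65:
            k = int(rng.integers(len(ms2)))
            loss = float(ms2["precmz"].iloc[k] - ms2["mz"].iloc[k]) + float(rng.normal(0, 0.01))
        else:
            loss = round(float(rng.uniform(1, 200)), 3)
        return Condition(ctype, NumericExpr(False, round(loss, 4)),
                         _random_mz_qualifiers(rng, ctype))
    if ctype is ConditionType.CHARGE:
        return Condition(ctype, float(rng.integers(1, 4)))
    if ctype is ConditionType.POLARITY:
        return Condition(ctype, str(rng.choice(["Positive", "Negative"])))
    if ctype in (ConditionType.RTMIN, ConditionType.RTMAX):
        return Condition(ctype, round(float(rng.uniform(0, 20)), 2))
    if ctype in (ConditionType.SCANMIN, ConditionType.SCANMAX):
        return Condition(ctype, float(rng.integers(1, 14)))
    lo = round(float(rng.uniform(0.3, 2.0)), 2)
    return Condition(ctype, Range(lo, lo + round(float(rng.uniform(0.1, 1.0)), 2)))


def _random_variable_tree(rng: np.random.Generator, table: PeakTable) -> Optional[ConditionNode]:
    """An anchored multi-peak MS1 pattern, offsets drawn from real peak
    spacings so that hits actually occur."""
    ms1 = table.ms1
    if not len(ms1):
        return None
    leaves = [
        ConditionNode("LEAF", leaf=Condition(
            ConditionType.MS1MZ, NumericExpr(True, 0.0),
            QualifierSet(intensity_percent=float(rng.choice([0.0, 10.0, 50.0])) or None),
        ))
    ]
    scans = ms1.groupby("scan")["mz"].apply(list)
    donor = scans.iloc[int(rng.integers(len(scans)))]
    for _ in range(int(rng.integers(1, 3))):
        if len(donor) >= 2 and rng.random() < 0.7:
            a, b = rng.choice(len(donor), 2, replace=False)
            offset = float(donor[int(b)] - donor[int(a)]) + float(rng.normal(0, 0.005))
        else:
            offset = round(float(rng.uniform(-30, 30)), 3)
        kw = {}
        if rng.random() < 0.5:
            kw["tolerance_mz"] = float(rng.choice([0.01, 0.1, 0.5]))
        if rng.random() < 0.3:
            kw["intensity_match_ratio"] = round(float(rng.uniform(0.05, 1.5)), 3)
            kw["intensity_match_percent"] = float(rng.choice([25.0, 50.0, 200.0]))
        leaves.append(
            ConditionNode("LEAF", leaf=Condition(
                ConditionType.MS1MZ, NumericExpr(True, round(offset, 4)), QualifierSet(**kw)
            ))
        )
    return ConditionNode("AND", tuple(leaves)) if len(leaves) > 1 else leaves[0]


def random_query(rng: np.random.Generator, table: PeakTable) -> ParsedQuery:
    """A random valid query against the given table."""
    for _ in range(50):
        datatype = str(rng.choice(["MS1DATA", "MS2DATA"]))
        variable = False
        if datatype == "MS1DATA" and rng.random() < 0.3:
            where = _random_variable_tree(rng, table)
            variable = where is not None
        if not variable:
            n = int(rng.integers(1, 4))
            leaves = [
                ConditionNode("LEAF", leaf=_random_leaf(rng, table, datatype))
                for _ in range(n)
            ]
            if n == 1:
                where = leaves[0]
            elif rng.random() < 0.3 and n >= 3:
                inner = ConditionNode(str(rng.choice(["AND", "OR"])), tuple(leaves[:2]))
                outer_kind = "OR" if inner.kind == "AND" else "AND"
                where = ConditionNode(outer_kind, (inner,) + tuple(leaves[2:]))
            else:
                where = ConditionNode(str(rng.choice(["AND", "OR"])), tuple(leaves))
        function = "scaninfo" if variable else str(rng.choice(["scaninfo", "scannum"]))
        query = ParsedQuery(function, datatype, where)
        if not [d for d in validate(query) if d.level == "error"]:
            return query
    raise AssertionError("could not build a valid random query")
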