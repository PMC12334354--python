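"""Multi-file batch querying with deterministic result merging.

Each input file is parsed (through the cache when one is configured) and
queried independently — file tasks share no mutable state, so they can run
in a process pool.  Per-file results are merged and sorted by
(file_id, scan, X), which makes the merged output invariant to worker
count and scheduling order.
"""

from __future__ import annotations

from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import pandas as pd

from .engine import ExecutionConfig, execute
from .language import parse, validate
from .spectra import (
    PeakTable,
    SpectraCache,
    export_spectra,
    load_spectra_cached,
    records_from_table,
    write_mzml,
    write_result_table,
)
from .spectra import _write_mgf, _write_json_spectra  # reuse exporter internals

__all__ = ["BatchJob", "BatchError", "run_batch"]


class BatchError(RuntimeError):
    pass


@dataclass
class BatchJob:
    """A batch run: one query over many files, with optional extraction."""

    query: str
    inputs: List[str]
    output: Optional[str] = None
    output_format: str = "tsv"
    extract: Optional[str] = None  # path for retrieved spectra
    extract_format: str = "mgf"
    cache_dir: Optional[str] = None
    workers: int = 1
    keep_going: bool = False  # skip-and-report instead of fail-fast
    default_tolerance_mz: float = 0.1


def _query_one_file(args: Tuple[str, str, Optional[str], float]) -> pd.DataFrame:
    query_text, path, cache_dir, default_tol = args
    cache = SpectraCache(cache_dir) if cache_dir else None
    table = load_spectra_cached(path, cache)
    query = parse(query_text)
    return execute(query, table, ExecutionConfig(default_tolerance_mz=default_tol))


def run_batch(job: BatchJob) -> pd.DataFrame:
    """Execute a batch job and return the merged result table.

    The query is parsed and validated up front; syntax or validation
    errors raise before any file work starts.  Per-file failures abort
    the run unless ``keep_going`` is set, in which case the offending
    file is skipped and reported via a warning-level message in the
    raised-at-end summary.
    """
    query = parse(job.query)  # raises QuerySyntaxError with offset
    diags = [d for d in validate(query) if d.level == "error"]
    if diags:
        raise BatchError("; ".join(d.message for d in diags))
    if job.workers < 1:
        raise BatchError("worker count must be >= 1")
    missing = [p for p in job.inputs if not Path(p).exists()]
    if missing:
        raise FileNotFoundError(f"input file not found: {missing[0]}")

    tasks = [
        (job.query, str(p), job.cache_dir, job.default_tolerance_mz) for p in job.inputs
    ]
    results: List[pd.DataFrame] = []
    failures: List[str] = []

    if job.workers == 1 or len(tasks) == 1:
        iterator = ((t, None) for t in tasks)
        for task, _ in iterator:
            try:
                results.append(_query_one_file(task))
            except Exception as exc:  # noqa: BLE001 - policy decision point
                if not job.keep_going:
                    raise
                failures.append(f"{task[1]}: {exc}")
    else:
        with ProcessPoolExecutor(max_workers=job.workers) as pool:
            futures = [pool.submit(_query_one_file, t) for t in tasks]
            for task, fut in zip(tasks, futures):
                try:
                    results.append(fut.result())
                except Exception as exc:  # noqa: BLE001
                    if not job.keep_going:
                        raise
                    failures.append(f"{task[1]}: {exc}")

    non_empty = [r for r in results if len(r)]
    if non_empty:
        merged = pd.concat(non_empty, ignore_index=True)
    elif results:
        merged = results[0].iloc[0:0]
    else:
        merged = pd.DataFrame()
    if len(merged):
        sort_cols = [c for c in ("file_id", "scan", "X") if c in merged.columns]
        if sort_cols:
            merged = merged.sort_values(sort_cols, kind="stable").reset_index(drop=True)

    if job.output:
        write_result_table(merged, job.output, format=job.output_format)
    if job.extract:
        _extract_spectra(job, query, merged)
    if failures:
        raise BatchError("some files failed: " + "; ".join(failures))
    return merged


def _extract_spectra(job: BatchJob, query, merged: pd.DataFrame) -> None:
    """Export the retrieved scans of every input file into one output."""
    cache = SpectraCache(job.cache_dir) if job.cache_dir else None
    pairs = []
    if len(merged) and {"file_id", "scan"} <= set(merged.columns):
        by_file = merged.drop_duplicates(subset=["file_id", "scan"]).groupby(
            "file_id", sort=True
        )
        for file_id, g in by_file:
            table = load_spectra_cached(file_id, cache)
            selection = [(file_id, int(s)) for s in g["scan"]]
            pairs.extend(records_from_table(table, selection))
    path = Path(job.extract)
    if job.extract_format == "mgf":
        _write_mgf(pairs, path)
    elif job.extract_format == "mzml":
        write_mzml([rec for _, rec in pairs], path)
    elif job.extract_format == "json":
        _write_json_spectra(pairs, path)
    else:
        raise BatchError(f"unsupported extract format {job.extract_format!r}")
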