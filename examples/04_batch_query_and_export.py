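"""Query several files at once, merge the results deterministically, and
export the retrieved spectra as MGF.

Equivalent shell command:

    massql "QUERY scaninfo(MS2DATA) WHERE MS2PROD=98.9847:TOLERANCEPPM=50:INTENSITYPERCENT=50" \
        fixture_*.mzML --output hits.tsv --extract hits.mgf --workers 2
"""

import tempfile
from pathlib import Path

from massql import BatchJob, PHOSPHATE_FRAGMENT_QUERY, run_batch
from massql.synthetic import generate_dataset

with tempfile.TemporaryDirectory() as tmp:
    files, _ = generate_dataset(
        tmp, n_files=3, k_iron=0, k_phosphate=6, n_decoy_ms1=0,
        n_decoy_ms2=45, seed=13,
    )
    job = BatchJob(
        query=PHOSPHATE_FRAGMENT_QUERY,
        inputs=[f["mzml"] for f in files],
        output=str(Path(tmp) / "hits.tsv"),
        extract=str(Path(tmp) / "hits.mgf"),
        cache_dir=str(Path(tmp) / "cache"),
        workers=2,
    )
    merged = run_batch(job)
    n_blocks = Path(tmp, "hits.mgf").read_text().count("BEGIN IONS")

per_file = merged.groupby(merged["file_id"].str.split("/").str[-1]).size()
print(per_file.to_string())
print(f"\n{len(merged)} retrieved scans merged from {len(files)} files;"
      f" {n_blocks} spectra exported to MGF")
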