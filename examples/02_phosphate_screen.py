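"""Screen MS/MS spectra for the diagnostic phosphate product ion.

Generates a small ground-truth dataset (decoy MS2 scans plus a few
spectra carrying the planted H4O4P+ fragment above 50% of the base peak),
runs the screen query, and checks the hits against the generator's
manifest.  Every retrieved row is a scan whose spectrum shows the
fragment; `matched_intensity` is the fragment's raw intensity.
"""

import tempfile

from massql import PHOSPHATE_FRAGMENT_QUERY, execute, load_spectra, parse
from massql.synthetic import generate_dataset

with tempfile.TemporaryDirectory() as tmp:
    files, manifest = generate_dataset(
        tmp, n_files=1, k_iron=0, k_phosphate=4, n_decoy_ms1=0,
        n_decoy_ms2=30, seed=5,
    )
    table = load_spectra(files[0]["mzml"])
    hits = execute(parse(PHOSPHATE_FRAGMENT_QUERY), table)

print(hits[["scan", "rt", "precmz", "charge", "matched_intensity"]].to_string(index=False))
planted = {scan for _, scan in manifest.planted_keys("phosphate_ms2")}
print(f"\nretrieved {len(hits)} of {len(planted)} planted scans;"
      f" exact match: {set(hits['scan']) == planted}")
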