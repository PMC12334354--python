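# Methods

## The query model

A query is `QUERY <function>(<level>) [WHERE <tree>]`.  The output
function is `scaninfo` (metadata rows), `scannum` (scan identifiers) or
`scansum` (a single row with the summed matched intensity over retained
scans — defined here as the sum over scans of the most intense matching
peak, since the function family's arithmetic is not otherwise pinned
down).  The level selects which scans are candidates: `MS1DATA` survey
scans or `MS2DATA` fragmentation scans.  The WHERE tree combines leaf
conditions with n-ary AND/OR; AND binds tighter than OR, parentheses
regroup, and negation exists only as the per-condition `EXCLUDED`
qualifier (no NOT keyword — exclusion is a property of one condition,
which keeps the semantics of "the scan lacks this peak" unambiguous).

A scan is retained when the tree evaluates true with **one consistent
binding of the variable X across the whole query**.  AND over peak
conditions therefore means "the same scan contains a peak for each
condition (possibly different peaks)" — the only reading under which a
four-peak isotope/adduct pattern is expressible as a conjunction.
Candidate values of X are the m/z of peaks passing the anchor
condition's own intensity/mass-defect filters (the anchor is the
condition whose value is exactly `X`; validation requires one); each
candidate is then tested against the full tree, and every surviving
binding yields one result row with X (anchor m/z) and Y (anchor raw
intensity).

### Matching rules

* A peak matches a target m/z iff |mz − target| ≤ tol, with tol =
  `TOLERANCEMZ`, or `TOLERANCEPPM · target · 1e−6` (computed on the
  *target*, not the observed peak, so the window is fixed per condition
  and order-independent), or the configured default of 0.1 Da — the
  conventional default of reference engines for this language, wide
  enough for unit-resolution instruments; tighten it per condition for
  high-resolution data.
* Intensity gates: `INTENSITYVALUE` on raw intensity;
  `INTENSITYPERCENT` on the base-peak-normalized intensity;
  `INTENSITYTICPERCENT` on the TIC-normalized intensity.
  `INTENSITYMATCH=Y*r` with `INTENSITYMATCHPERCENT=p` accepts a peak iff
  |i/Y − r| ≤ r·p/100 — a relative band around the expected ratio to the
  anchor intensity, which is how isotope abundance ratios are specified.
  `INTENSITYMATCHPERCENT` is required alongside `INTENSITYMATCH` (the
  band width has no natural default).
* `MASSDEFECT` bounds the fractional part of the peak m/z, inclusive.
* `EXCLUDED` retains a scan iff *zero* peaks match, all other qualifiers
  applied first — so a sub-threshold occurrence of the ion does not
  count as presence.  `cond` and `cond:EXCLUDED` partition the scan set.
* `MS2NL=L` matches iff a product ion lies within tolerance of
  (precursor m/z − L), a singly-charged reading; multiply-charged
  neutral-loss arithmetic is out of scope.
* Metadata: RT bounds in minutes and scan-number bounds are inclusive;
  `CHARGE` compares |z|; `POLARITY` is exact; `MOBILITY` is an inclusive
  range over values compared as stored (units are instrument-specific
  and are not converted).
* `MS1MZ` inside an `MS2DATA` query is evaluated against the linked
  survey scan (each MS2 scan links to the most recent preceding MS1 scan
  in acquisition order); MS2-level conditions inside an `MS1DATA` query
  are rejected at validation.
* Ties: when several peaks match one condition, `matched_intensity`
  reports the most intense; all matches count for EXCLUDED logic.
  Result rows are sorted by (file, scan, X) and de-duplicated, making
  repeated runs byte-identical.

### Grammar notes

Keywords are case-insensitive; numeric literals are plain decimals
(scientific notation is rejected — screen queries are written with
printed constants, and a stray `e` is more likely a typo than an
exponent).  Variable arithmetic is limited to `X ± constant`;
multiplication of X is rejected at parse time.  Every malformed input
raises a single syntax error carrying the earliest failing character
offset; a fuzz property test asserts this totality.  `serialize` emits a
canonical form (fixed keyword case, fixed qualifier order, minimal
parentheses) whose re-parse is structurally identical, and `describe`
renders a deterministic English sentence.

## File handling

mzML and mzXML are parsed with a cvParam-accession-driven lxml reader
(base64 arrays, 32/64-bit floats, optional zlib; mzXML big-endian
interleaved pairs); MGF goes through pyteomics.  Retention times are
normalized to minutes regardless of the source unit.  Scans missing
polarity metadata default to positive mode with a warning (silent
failure would be worse, and positive mode dominates the target
applications); MS2 scans missing a precursor charge default to ±1 per
polarity, which `MS2NL` needs.  MGF carries MS2 spectra only and numbers
them by 1-based block order unless a `SCANS` header is present.
Profile-mode data are accepted as-is (each raw point is a peak); no
centroiding is performed.

Peak lists live in two pandas DataFrames (MS1/MS2), one row per peak,
with per-scan base-peak- and TIC-normalized intensities precomputed at
load: per scan max(i_norm) = 1 (ties all at 1) and Σ i_tic_norm = 1
within 1e−9 relative.  Parsed tables cache as versioned parquet blobs
keyed by the source file's content hash, with per-blob SHA-256
checksums: a version mismatch signals regeneration, a checksum mismatch
raises rather than returning wrong data, and the round trip is bit-exact.

Exports: result tables as TSV/JSON at full float precision; retrieved
spectra as MGF, JSON, or a minimal uncompressed PSI-mzML (64-bit arrays,
retention time in minutes, precursor and polarity cvParams).  Exported
mzML is verified in the test suite by an independent implementation
(Bioconductor's mzR) reading it back peak-for-peak, and by the package's
own reader within 1e−6 relative.

## The synthetic ground truth

The generator emulates the two screening studies at desk scale.  Decoy
peaks are uniform in m/z over [100, 1000] Da with log-uniform intensities
over [1e3, 1e6] (log-uniform spreads decoys across the intensity decades
a real spectrum spans), 30 per scan; retention times are uniform over
[0, 20] min; everything is positive mode; one RNG stream per file keyed
by (seed, file index).

Iron patterns are planted at theoretical spacings (1.995327, 1.003355,
52.911462 Da) with apex intensity 2e6 (so the apex is the scan's base
peak above the 1e6 decoy ceiling), the 54Fe peak at the natural 6.3%
abundance ratio, the 13C satellite at 30% (a mid-sized organic of ~25–30
carbons), and the apo species at 50%.  Anchors are sampled from
[300, 880] Da: below ≈235 Da a 10 ppm window around the printed constant
x − 1.993 no longer covers the theoretical 54Fe spacing, so the printed
query would start missing genuine patterns — the screen's own working
range.  Phosphate MS2 scans plant the H4O4P+ fragment at 80% of the base
peak with decoys kept out of its 50 ppm window.

Every scan — decoy and planted alike — is certified by the naive
evaluator: decoys must match neither screen query, planted scans must
yield exactly their planted binding.  Offending scans are resampled up
to 100 times, then generation fails loudly.  The manifest therefore
*predicts* the exact result sets, and the recovery tests assert
precision = recall = 1 rather than approximate overlap.  What passing
shows: the engine implements the pattern semantics exactly on data whose
truth is known.  What it does not show: robustness to real-data features
the generator omits — chromatographic peak shapes, isotope fine
structure beyond the planted peaks, centroiding artifacts, intensity
drift — so real-world recall depends on tolerance choices in ways these
tests cannot certify.

## Verification strategy

Two independent routes compute every retrieval: the vectorized engine
and a pure-Python loop evaluator (`massql.naive`) that shares no
evaluation code.  Property tests compare them on 110+ randomized
(query, dataset) pairs, alongside law-based tests: tolerance and
intensity monotonicity, EXCLUDED complementarity, MS2NL/MS2PROD
equivalence, parse/serialize round trips, and keyword-case invariance.
Mass arithmetic is checked by dual routes as well (bare-proton addition
vs formula-ion-minus-electron, to 1e−6 Da) and against the three
printed screen constants at printed precision.

## Batch execution

Files are independent tasks (no shared mutable state), run serially or
in a process pool; per-file results are concatenated and sorted by
(file, scan, X), so output is invariant to worker count and scheduling.
The `file_id` column is the input path as given, preventing basename
collisions across directories.  Failure policy is fail-fast by default;
`--keep-going` switches to skip-and-report.

## Known limitations

No chromatographic feature grouping across scans; no spectral
similarity/library scoring; no vendor raw formats or centroiding; no
scientific notation in query literals; one variable symbol per query;
neutral losses assume singly-charged precursors; ion-mobility values are
dimensionless pass-through.  The acceptance dataset (3 files, ~730
scans) is deliberately small enough to regenerate and query in seconds;
all counts scale linearly if larger studies are wanted.
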