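"""Canonical screening queries, written with the printed constants used in
the siderophore and organophosphate-ester (OPE) screens.

``IRON_BINDING_QUERY`` searches MS1 spectra for the iron-bound isotope /
adduct pattern anchored at an unknown m/z x: the 54Fe isotope at x - 1.993
with 6.3% of the anchor intensity (within a 25% relative band), the 13C
satellite at x + 1.0034, and the apo (iron-free) species at x - 52.91, all
within 10 ppm.  The anchor itself must rise above 10% of the scan's base
peak, which keeps candidate enumeration to real signals.

``PHOSPHATE_FRAGMENT_QUERY`` retrieves MS/MS scans showing the diagnostic
phosphate product ion at m/z 98.9847 (H4O4P+) within 50 ppm and above 50%
of the base peak.
"""

IRON_BINDING_QUERY = (
    "QUERY scaninfo(MS1DATA) WHERE "
    "MS1MZ=X:INTENSITYPERCENT=10 "
    "AND MS1MZ=X-1.993:TOLERANCEPPM=10:INTENSITYMATCH=Y*0.063:INTENSITYMATCHPERCENT=25 "
    "AND MS1MZ=X+1.0034:TOLERANCEPPM=10 "
    "AND MS1MZ=X-52.91:TOLERANCEPPM=10"
)

PHOSPHATE_FRAGMENT_QUERY = (
    "QUERY scaninfo(MS2DATA) WHERE "
    "MS2PROD=98.9847:TOLERANCEPPM=50:INTENSITYPERCENT=50"
)
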