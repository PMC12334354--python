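"""Parse a pattern query, inspect its AST, and render it back as text
and as an English sentence.

The query below is the organophosphate-ester screen: retrieve MS/MS scans
showing the diagnostic phosphate fragment (H4O4P+, m/z 98.9847) within
50 ppm and above half the base-peak intensity.
"""

from massql import describe, parse, serialize, validate

QUERY = (
    "QUERY scaninfo(MS2DATA) WHERE "
    "MS2PROD=98.9847:TOLERANCEPPM=50:INTENSITYPERCENT=50"
)

query = parse(QUERY)
print("function :", query.function)
print("datatype :", query.datatype)
print("condition:", query.where.leaf.type.value, query.where.leaf.value)
print("diagnostics:", validate(query) or "none")
print("canonical:", serialize(query))
print("english  :", describe(query))
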