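# Representative queries, one per line.  Used for parse/serialize
# round-trip and fuzzing seeds.
QUERY scaninfo(MS1DATA)
QUERY scannum(MS1DATA)
QUERY scansum(MS2DATA)
QUERY scaninfo(MS2DATA) WHERE MS2PROD=98.9847:TOLERANCEPPM=50:INTENSITYPERCENT=50
QUERY scaninfo(MS2DATA) WHERE MS2PREC=488.1
QUERY scaninfo(MS2DATA) WHERE MS2PREC=488.1:TOLERANCEMZ=0.1
QUERY scaninfo(MS1DATA) WHERE MS1MZ=163.1
QUERY scaninfo(MS1DATA) WHERE MS1MZ=163.1:TOLERANCEMZ=0.1:INTENSITYVALUE=1000
QUERY scaninfo(MS1DATA) WHERE MS1MZ=163.1:INTENSITYPERCENT=10
QUERY scaninfo(MS1DATA) WHERE MS1MZ=163.1:INTENSITYTICPERCENT=10
QUERY scaninfo(MS2DATA) WHERE MS2PROD=163.1:EXCLUDED
QUERY scaninfo(MS2DATA) WHERE MS2PROD=163.1:MASSDEFECT=massdefect(min=0.1, max=0.2)
QUERY scaninfo(MS2DATA) WHERE MS2NL=176.0321:TOLERANCEPPM=20
QUERY scaninfo(MS2DATA) WHERE CHARGE=2
QUERY scaninfo(MS1DATA) WHERE POLARITY=Positive
QUERY scaninfo(MS1DATA) WHERE POLARITY=Negative AND RTMIN=5 AND RTMAX=10
QUERY scaninfo(MS1DATA) WHERE SCANMIN=5 AND SCANMAX=5
QUERY scaninfo(MS1DATA) WHERE MOBILITY=range(min=1, max=2)
QUERY scaninfo(MS2DATA) WHERE MS2PROD=85.0284 OR MS2PROD=127.0390
QUERY scaninfo(MS2DATA) WHERE (MS2PROD=85.0284 OR MS2PROD=127.0390) AND MS2PREC=300.2
QUERY scaninfo(MS2DATA) WHERE MS2PROD=85.0284 AND MS2PROD=127.039 OR MS2NL=18.0106
QUERY scaninfo(MS1DATA) WHERE MS1MZ=X:INTENSITYPERCENT=10 AND MS1MZ=X-1.993:TOLERANCEPPM=10:INTENSITYMATCH=Y*0.063:INTENSITYMATCHPERCENT=25 AND MS1MZ=X+1.0034:TOLERANCEPPM=10 AND MS1MZ=X-52.91:TOLERANCEPPM=10
QUERY scaninfo(MS1DATA) WHERE MS1MZ=X AND MS1MZ=X+1.003355:TOLERANCEMZ=0.01
QUERY scansum(MS2DATA) WHERE MS2PROD=98.9847:TOLERANCEPPM=50
QUERY scannum(MS2DATA) WHERE MS2PREC=488.1:EXCLUDED
QUERY scaninfo(MS2DATA) WHERE RTMIN=2.5 AND MS2PROD=204.0867:TOLERANCEMZ=0.05 AND CHARGE=2
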