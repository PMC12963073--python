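# Corrected published phenotype-code -> group fixture (81 core codes).
# corrected=yes rows are the three typographical fixes where the printed
# code contradicts its own group definition; printed_code preserves the
# original entry:
#   group 7a printed "am" (duplicating 7b) -> "m" per "without acute inflammation"
#   group 4b printed "Acf" (belongs to 7c) -> "ACf" per "high-grade chronic inflammation"
#   group 4d printed "Acfm" (belongs to 7c) -> "ACfm" per "high-grade chronic inflammation"
code,group_id,corrected,printed_code
CFM,1a,no,
aCFM,1a,no,
ACFM,1a,no,
FM,1b,no,
cFM,1b,no,
aFM,1b,no,
acFM,1b,no,
AFM,1b,no,
AcFM,1b,no,
CM,1c,no,
CfM,1c,no,
aCM,1c,no,
aCfM,1c,no,
ACM,1c,no,
ACfM,1c,no,
CF,1d,no,
CFm,1d,no,
aCF,1d,no,
aCFm,1d,no,
AF,2,no,
AFm,2,no,
AcF,2,no,
AcFm,2,no,
ACF,2,no,
ACFm,2,no,
F,3a,no,
aF,3a,no,
cF,3b,no,
Fm,3b,no,
cFm,3b,no,
acF,3b,no,
aFm,3b,no,
acFm,3b,no,
C,4a,no,
Cf,4a,no,
aC,4b,no,
aCf,4b,no,
AC,4b,no,
ACf,4b,yes,Acf
Cm,4c,no,
Cfm,4c,no,
aCm,4d,no,
aCfm,4d,no,
ACm,4d,no,
ACfm,4d,yes,Acfm
M,5,no,
cM,5,no,
fM,5,no,
cfM,5,no,
aM,5,no,
acM,5,no,
afM,5,no,
acfM,5,no,
AM,5,no,
AcM,5,no,
AfM,5,no,
AcfM,5,no,
c,6a,no,
f,6a,no,
ac,6a,no,
af,6a,no,
Ac,6b,no,
Af,6b,no,
m,7a,yes,am
cm,7a,no,
cf,7a,no,
fm,7a,no,
cfm,7a,no,
am,7b,no,
acm,7b,no,
acf,7b,no,
afm,7b,no,
acfm,7b,no,
Am,7c,no,
Acm,7c,no,
Acf,7c,no,
Afm,7c,no,
Acfm,7c,no,
A,9a,no,
a,9b,no,
,10,no,
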