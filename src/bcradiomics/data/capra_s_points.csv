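# CAPRA-S post-surgical risk score point table (Cooperberg et al., Cancer 2011).
# component,category,points
component,category,points
psa,<=6,0
psa,6.01-10,1
psa,10.01-20,2
psa,>20,3
gleason,no_pattern_4_or_5,0
gleason,secondary_4_or_5,1
gleason,primary_4_or_5,2
gleason,8-10,3
margins,negative,0
margins,positive,2
ece,absent,0
ece,present,1
svi,absent,0
svi,present,2
lni,absent,0
lni,present,1
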