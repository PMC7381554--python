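study_id,length_years
S01,1
S02,2
S03,3
S04,4
S05,5
S06,6
S07,7
S08,8
S09,9
S10,10
S11,10
S12,11
S13,11
S14,11
S15,12
S16,13
S17,14
S18,15
S19,16
S20,16
S21,16
S22,16
S23,16
S24,37
S25,41
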