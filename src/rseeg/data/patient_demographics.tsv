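participant	sex	age
P01	F	50
P02	F	32
P03	F	15
P04	F	22
P05	F	25
P06	F	20
P07	F	24
P08	M	46
P09	M	28
P10	M	58
P11	F	22
P12	F	15
P13	F	17
P14	F	29
P15	F	19
P16	F	21
P17	F	29
P18	F	18
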