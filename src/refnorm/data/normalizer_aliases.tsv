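# Alias -> canonical symbol map for normalizer matching (case-insensitive).
alias	canonical
beta-Actin	Actb
beta-actin	Actb
b-Actin	Actb
ACTB	Actb
Actb	Actb
beta-tubulin	Tubb
b-tubulin	Tubb
TUBB	Tubb
Tubb	Tubb
Tubb2a	Tubb
Tubb2c	Tubb
Tubb3	Tubb
Tubb4	Tubb
Tubb5	Tubb
alpha-tubulin	Tuba
TUBA	Tuba
Tuba	Tuba
Tuba1a	Tuba
Tuba1b	Tuba
Tuba4	Tuba
Tuba4a	Tuba
Tuba8	Tuba
GAPDH	Gapdh
Gapdh	Gapdh
18s rRNA	Rn18s
Rpl24	Rpl24
PPIA	Ppia
Mapk6	Mapk6
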