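icd10,category
C34,green
I63,green
S06,green
C71,green
C18,green
C61,green
I60,green
C50,green
C25,green
C16,green
I71,green
C64,green
S32,green
C78,green
C22,green
K35,green
J44,yellow
R51,yellow
R10,yellow
R07,yellow
R06,yellow
R55,yellow
J18,yellow
G40,yellow
K80,red
M54,red
N20,red
H66,red
K57,red
M51,red
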