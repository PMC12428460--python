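# Demo gene signature: the 11 circRNA host genes of the high-risk
# meningioma transcript set used throughout the worked examples.
CCND2
CDK6
CHEK1
CKS2
COL1A1
EZH2
FBLIM1
FGFR4
MDM4
MYBL1
PIM1
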