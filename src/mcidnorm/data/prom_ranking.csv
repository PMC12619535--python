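prom,count
mHHS,71
iHOT-12,35
HOS-SSS,33
NAHS,27
HOS-ADL,27
HOOS,8
iHOT-33,7
WOMAC,4
HAGOS,4
HHS,2
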