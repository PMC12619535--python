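name,scale_min,scale_max,orientation,mcid,mcid_source,synonyms
mHHS,0,100,higher_better,9.5,"Nwachukwu 2018, doi:10.1016/j.arthro.2018.01.050",
iHOT-12,0,100,higher_better,13.0,"Nwachukwu 2018, doi:10.1016/j.arthro.2018.01.050; Martin 2019, doi:10.1016/j.arthro.2018.09.028",
HOS-SSS,0,100,higher_better,12.1,"Nwachukwu 2018, doi:10.1016/j.arthro.2018.01.050",HOS-Sport;HOS-Sports
NAHS,0,100,higher_better,8.5,"Bloom 2022, doi:10.1007/s00167-021-06756-9",
HOS-ADL,0,100,higher_better,9.8,"Nwachukwu 2018, doi:10.1016/j.arthro.2018.01.050",
iHOT-33,0,100,higher_better,10.7,"Nwachukwu 2018, doi:10.1016/j.arthro.2018.01.050",
HOOS,0,100,higher_better,,,
WOMAC,0,96,higher_worse,,,
HAGOS,0,100,higher_better,,,
HHS,0,100,higher_better,,,
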