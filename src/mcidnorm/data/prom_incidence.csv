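study_id,prom
s001,mHHS
s002,iHOT-12
s003,iHOT-33
s003,HOS-SSS
s003,HOS-ADL
s004,mHHS
s005,iHOT-12
s005,mHHS
s005,HOS-SSS
s005,NAHS
s006,mHHS
s007,mHHS
s008,mHHS
s009,iHOT-12
s009,mHHS
s010,iHOT-12
s010,mHHS
s010,NAHS
s011,iHOT-12
s011,mHHS
s011,HOOS
s012,mHHS
s012,HOS-SSS
s012,HOS-ADL
s012,NAHS
s013,mHHS
s013,HOS-SSS
s013,NAHS
s014,mHHS
s015,mHHS
s016,mHHS
s016,HOS-SSS
s016,HOS-ADL
s016,WOMAC
s017,iHOT-12
s017,mHHS
s018,iHOT-12
s018,mHHS
s019,mHHS
s019,NAHS
s020,iHOT-12
s020,mHHS
s021,iHOT-12
s021,mHHS
s021,HOS-SSS
s021,HOS-ADL
s022,iHOT-12
s022,mHHS
s023,iHOT-12
s023,mHHS
s024,mHHS
s024,HOS-SSS
s024,NAHS
s025,iHOT-12
s025,mHHS
s025,HOS-SSS
s025,HOS-ADL
s026,mHHS
s027,iHOT-12
s027,mHHS
s027,HOS-SSS
s027,NAHS
s028,mHHS
s028,NAHS
s029,iHOT-12
s030,HAGOS
s031,iHOT-12
s031,mHHS
s031,HOS-SSS
s031,NAHS
s032,mHHS
s032,HOS-SSS
s032,NAHS
s033,mHHS
s034,HOOS
s035,mHHS
s035,iHOT-33
s035,HOS-SSS
s035,HOS-ADL
s036,mHHS
s036,HAGOS
s037,iHOT-12
s037,mHHS
s037,HOS-SSS
s037,HOS-ADL
s038,mHHS
s038,HOS-SSS
s038,HOS-ADL
s039,mHHS
s040,iHOT-33
s041,iHOT-12
s041,HOS-SSS
s041,HOS-ADL
s042,mHHS
s043,iHOT-12
s043,mHHS
s043,HOS-SSS
s043,HOS-ADL
s044,mHHS
s044,iHOT-33
s044,HOS-SSS
s044,HOS-ADL
s044,NAHS
s045,mHHS
s046,iHOT-12
s046,NAHS
s046,HOOS
s047,mHHS
s048,mHHS
s048,NAHS
s049,HOS-SSS
s049,HOS-ADL
s050,mHHS
s050,WOMAC
s051,mHHS
s051,HOS-SSS
s051,NAHS
s052,mHHS
s052,iHOT-33
s052,HOS-SSS
s052,HOS-ADL
s052,NAHS
s053,HOS-ADL
s053,NAHS
s053,HHS
s054,iHOT-12
s055,mHHS
s055,NAHS
s056,mHHS
s056,HOS-SSS
s056,HOS-ADL
s057,mHHS
s058,iHOT-12
s058,mHHS
s058,HOS-SSS
s058,HOS-ADL
s059,mHHS
s059,HOS-SSS
s059,HOS-ADL
s060,HOOS
s061,HOOS
s062,iHOT-12
s062,NAHS
s063,HOOS
s064,mHHS
s064,HOS-SSS
s064,NAHS
s065,iHOT-12
s065,HOS-SSS
s065,HOS-ADL
s066,mHHS
s067,mHHS
s067,WOMAC
s068,HOOS
s069,mHHS
s070,mHHS
s071,iHOT-12
s071,mHHS
s072,mHHS
s072,NAHS
s073,iHOT-12
s073,mHHS
s073,NAHS
s074,HOS-ADL
s075,HOS-SSS
s075,HOS-ADL
s076,mHHS
s076,HOS-SSS
s077,iHOT-12
s077,NAHS
s078,mHHS
s079,iHOT-12
s079,mHHS
s080,iHOT-12
s080,HAGOS
s081,iHOT-12
s081,mHHS
s081,NAHS
s082,iHOT-12
s082,HAGOS
s083,mHHS
s084,mHHS
s084,HOS-SSS
s084,HOS-ADL
s085,HHS
s086,iHOT-12
s087,mHHS
s087,iHOT-33
s087,HOS-SSS
s087,HOS-ADL
s088,iHOT-12
s088,mHHS
s088,HOS-ADL
s089,iHOT-12
s090,HOS-SSS
s090,HOS-ADL
s090,NAHS
s091,mHHS
s092,mHHS
s092,HOS-ADL
s092,WOMAC
s093,iHOT-12
s093,mHHS
s093,HOS-SSS
s093,NAHS
s094,NAHS
s095,HOOS
s096,mHHS
s097,iHOT-12
s097,mHHS
s097,NAHS
s098,mHHS
s098,iHOT-33
s099,HOS-SSS
s099,HOS-ADL
s100,mHHS
s100,HOS-SSS
s100,HOS-ADL
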