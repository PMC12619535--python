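study_id,arm_id,prom,timepoint,n,mean,sd,range_min,range_max
study-1,1,mHHS,post,22,84.7,11.4,,
study-1,1,iHOT-12,post,22,81.2,12.6,,
study-1,2,mHHS,post,21,84.0,12.5,,
study-1,2,iHOT-12,post,21,77.6,15.7,,
study-2,1,iHOT-33,post,177,76.4,16.8,,
study-2,2,iHOT-33,post,171,70.8,18.8,,
study-3,1,HOS-ADL,post,50,91.3,9.2,,
study-3,2,HOS-ADL,post,49,88.0,10.8,,
study-4,1,NAHS,post,40,82.0,13.3,,
study-4,1,HOS-ADL,post,40,86.3,11.3,,
study-4,2,NAHS,post,40,79.8,14.3,,
study-4,2,HOS-ADL,post,40,84.8,12.9,,
study-5,1,iHOT-12,post,46,75.5,11.2,,
study-5,1,HOS-SSS,post,46,80.5,16.0,,
study-5,1,HOS-ADL,post,46,82.8,13.6,,
study-5,2,iHOT-12,post,44,69.6,13.1,,
study-5,2,HOS-SSS,post,44,73.1,18.3,,
study-5,2,HOS-ADL,post,44,80.1,14.8,,
study-6,1,iHOT-12,post,45,75.6,12.5,,
study-6,2,iHOT-12,post,46,64.4,15.4,,
study-7,1,HOS-ADL,post,110,78.8,15.4,,
study-7,2,HOS-ADL,post,112,75.9,16.5,,
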