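biomarker,condition_label,group,sex,age_min,age_max,age_unit,direction,threshold,threshold_unit,use_adjusted,source
ferritin,iron_deficiency,PSC,any,6,59,months,below,12,ug/L,true,WHO 2020 guideline on use of ferritin (children under 5 y)
ferritin,iron_deficiency,WRA,any,15,49,years,below,15,ug/L,true,WHO 2020 guideline on use of ferritin (adults)
stfr,iron_deficiency_stfr,PSC,any,6,59,months,above,8.3,mg/L,true,Roche-assay convention for soluble transferrin receptor
stfr,iron_deficiency_stfr,WRA,any,15,49,years,above,8.3,mg/L,true,Roche-assay convention for soluble transferrin receptor
retinol,vitamin_a_deficiency,PSC,any,6,59,months,below,0.7,umol/L,true,WHO 2009 serum retinol indicator
retinol,vitamin_a_deficiency,WRA,any,15,49,years,below,0.7,umol/L,false,WHO 2009 serum retinol indicator
zinc,zinc_deficiency,PSC,any,6,59,months,below,9.9,umol/L,true,IZiNCG morning non-fasting cutoff for children under 10 y (65 ug/dL)
zinc,zinc_deficiency,WRA,any,15,49,years,below,10.1,umol/L,true,IZiNCG morning non-fasting cutoff for females 10 y and older (66 ug/dL)
serum_folate,folate_deficiency,WRA,any,15,49,years,below,10,nmol/L,false,WHO 2015 serum folate deficiency (metabolic indicator)
b12,b12_deficiency,WRA,any,15,49,years,below,150,pmol/L,false,WHO vitamin B-12 deficiency convention
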