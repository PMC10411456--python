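nutrient,age_band_lo,age_band_hi,cutpoint,unit
vita_ug,12,35,286,ug RE
folate_ug,12,35,120,ug
vitd_ug,12,35,5,ug
calcium_mg,12,35,417,mg
iron_mg,12,35,5.8,mg
zinc_mg,12,35,3.4,mg
vita_ug,36,47,286,ug RE
folate_ug,36,47,120,ug
vitd_ug,36,47,5,ug
calcium_mg,36,47,417,mg
iron_mg,36,47,5.8,mg
zinc_mg,36,47,4,mg
vita_ug,48,60,321,ug RE
folate_ug,48,60,160,ug
vitd_ug,48,60,5,ug
calcium_mg,48,60,500,mg
iron_mg,48,60,6.3,mg
zinc_mg,48,60,4,mg
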