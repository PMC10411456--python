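food_id,name,basis,density_g_per_mL,milk_type,ycm_ageband,energy_kcal,protein_g,vita_ug,vitc_mg,vitd_ug,folate_ug,calcium_mg,iron_mg,zinc_mg
condensed_beverage,Sweetened condensed milk beverage (illustrative; as consumed),per_100_mL,,condensed,,80.0,2.0,18.5,0.65,0.0,2.75,71.0,0.05,0.22
ycm_1plus,Young-child milk 1+ reconstituted (illustrative),per_100_mL,,ycm,1+,70.0,2.6,60.0,12.0,2.8,30.0,180.0,1.8,1.0
ycm_3plus,Young-child milk 3+ reconstituted (illustrative),per_100_mL,,ycm,3+,66.0,2.8,62.0,12.0,2.6,32.0,190.0,2.0,1.1
cow_milk,Pasteurized cow's milk (illustrative),per_100_mL,1.03,cow,,64.0,3.3,46.0,0.9,0.1,5.0,120.0,0.05,0.4
bg_energy_kcal,Background diet energy pseudo-food,per_100_g,,none,,100.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0
bg_protein_g,Background diet protein pseudo-food,per_100_g,,none,,0.0,100.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0
bg_vita_ug,Background diet vitamin A pseudo-food,per_100_g,,none,,0.0,0.0,100.0,0.0,0.0,0.0,0.0,0.0,0.0
bg_vitc_mg,Background diet vitamin C pseudo-food,per_100_g,,none,,0.0,0.0,0.0,100.0,0.0,0.0,0.0,0.0,0.0
bg_vitd_ug,Background diet vitamin D pseudo-food,per_100_g,,none,,0.0,0.0,0.0,0.0,100.0,0.0,0.0,0.0,0.0
bg_folate_ug,Background diet folate pseudo-food,per_100_g,,none,,0.0,0.0,0.0,0.0,0.0,100.0,0.0,0.0,0.0
bg_calcium_mg,Background diet calcium pseudo-food,per_100_g,,none,,0.0,0.0,0.0,0.0,0.0,0.0,100.0,0.0,0.0
bg_iron_mg,Background diet iron pseudo-food,per_100_g,,none,,0.0,0.0,0.0,0.0,0.0,0.0,0.0,100.0,0.0
bg_zinc_mg,Background diet zinc pseudo-food,per_100_g,,none,,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,100.0
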