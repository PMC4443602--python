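program_version,species,breathing_pattern,inhalability_adjustment,substance,mmad_um,gsd,density_g_cm3,alveolar_fraction,head_tb_fraction,source_note
MPPD 2.0,rat,default,off,generic,1.8,2.0,1.0,0.075,0.3333333333333333,volumetric-model rat fraction 7.5% with inhalability adjustment off; head+TB 1/3 yields the 3/2 extrathoracic factor
MPPD 2.0,rat,default,on,generic,1.8,2.0,1.0,0.063,0.25,rat fraction 6.3% with MAK-recommended inhalability adjustment; head+TB 25% yields a 4/3 factor
MPPD 2.11,rat,default,on,generic,1.8,2.0,1.0,0.033,,rat fraction 3.3% from the newer program version with identical inputs
MPPD 2.0,human,Oronasal-Mouth Breather,n/a,generic,1.8,2.0,1.0,0.164,,human fraction 16.4% under the mouth-breather pattern (matches the original volumetric-model publication)
MPPD 2.0,human,Oronasal-Normal Augmenter,n/a,generic,1.8,2.0,1.0,0.084,,human fraction 8.4% under the MAK-recommended normal-augmenter pattern
MPPD 2.11,human,Oronasal-Normal Augmenter,n/a,generic,1.8,2.0,1.0,0.088,,human fraction 8.8% from the newer program version
MPPD 2.11,human,Oronasal-Mouth Breather,n/a,generic,1.8,2.0,1.0,0.157,,human fraction 15.7% mouth-breather with the newer program version
MPPD 2.0,human,Oronasal-Normal Augmenter,n/a,toner_Muhle,,,,0.0701,,human fraction 7.01% for toner with the chronic-study substance data
MPPD 2.0,human,Oronasal-Normal Augmenter,n/a,TiO2_Muhle,,,,0.0872,,human fraction 8.72% for pigmentary TiO2 with the chronic-study substance data
MPPD 2.0,rat,default,on,toner_Muhle,,,1.0,0.040,,density sweep at the toner size distribution; density 1 g/cm^3
MPPD 2.0,rat,default,on,toner_Muhle,,,1.2,0.040,,density sweep; toner true density 1.2 g/cm^3
MPPD 2.0,rat,default,on,toner_Muhle,,,2.0,0.041,,density sweep; density 2 g/cm^3
MPPD 2.0,rat,default,on,toner_Muhle,,,3.0,0.042,,density sweep; density 3 g/cm^3
MPPD 2.0,rat,default,on,toner_Muhle,,,4.0,0.042,,density sweep; density 4 g/cm^3
MPPD 2.0,rat,default,on,toner_Muhle,,,4.3,0.042,,density sweep; density of TiO2 4.3 g/cm^3
MPPD 2.0,rat,default,on,toner_Muhle,,,5.0,0.042,,density sweep; density 5 g/cm^3
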