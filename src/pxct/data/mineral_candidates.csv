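name,formula,reference_density_g_cm3,range_low_g_cm3,range_high_g_cm3
quartz,SiO2,2.66,,
hematite,Fe2O3,5.24,,
magnetite,Fe3O4,5.18,,
maghemite,Fe2O3,4.87,,
mature_kerogen,C175H102O9N4S2,1.325,1.25,1.40
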