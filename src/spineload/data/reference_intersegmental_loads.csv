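level,condition,Fx_prime_N,Fy_prime_N,source
T12,gravity,448,-70,reference_cohort_model
T12,gravity,336,-38,el_rich_2004
L1,gravity,557,-95,reference_cohort_model
L1,gravity,403,-51,el_rich_2004
L2,gravity,482,-83,reference_cohort_model
L2,gravity,445,-71,el_rich_2004
L3,gravity,450,-30,reference_cohort_model
L3,gravity,497,-9,el_rich_2004
L4,gravity,441,39,reference_cohort_model
L4,gravity,534,31,el_rich_2004
L5,gravity,461,233,reference_cohort_model
L5,gravity,575,218,el_rich_2004
T12,held_380N,1773,-214,reference_cohort_model
T12,held_380N,1486,-81,el_rich_2004
L1,held_380N,2001,-255,reference_cohort_model
L1,held_380N,1893,-228,el_rich_2004
L2,held_380N,1700,-223,reference_cohort_model
L2,held_380N,1931,-323,el_rich_2004
L3,held_380N,1509,-86,reference_cohort_model
L3,held_380N,1954,38,el_rich_2004
L4,held_380N,1383,88,reference_cohort_model
L4,held_380N,2010,273,el_rich_2004
L5,held_380N,1326,551,reference_cohort_model
L5,held_380N,2062,812,el_rich_2004
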