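level,pressure_MPa,pressure_sd_MPa,disc_area_cm2,disc_area_sd_cm2,n_subjects,source
L4L5,0.78,0.24,11.8,2.1,37,reference_cohort_model
L4L5,0.50,,18.0,,1,wilke_1999
L4L5,0.54,0.18,15.9,1.8,8,sato_1999
T6T7,0.57,0.02,5.3,1.0,37,reference_cohort_model
T7T8,0.56,0.01,5.8,1.1,37,reference_cohort_model
T9T10,0.83,0.03,6.9,1.3,37,reference_cohort_model
T10T11,1.03,0.05,7.6,1.6,37,reference_cohort_model
T6T7_T7T8,1.01,0.06,,,6,polga_2004
T9T10_T10T11,0.86,0.06,,,6,polga_2004
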