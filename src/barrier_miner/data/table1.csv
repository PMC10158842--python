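publication_id,year,stigma,logistical_financial,gender_specific,fear,lack_of_knowledge,targeted_population
centralized_intake_2006,2006,1,1,0,1,0,
stigma_nsduh_2011,2011,1,0,0,0,0,
women_trauma_integrated_2014,2014,1,1,1,0,0,women
women_centered_focus_groups_2018,2018,1,1,1,1,0,women
latino_specialty_treatment_2018,2018,1,1,0,1,0,racial_ethnic_minority
rural_moud_review_2019,2019,1,1,0,0,0,rural
moud_rapid_review_2020,2020,1,1,0,0,1,
women_oud_challenges_2020,2020,1,1,1,0,0,women
student_pharmacists_stigma_2020,2020,1,0,0,0,0,other
rural_new_mexico_mat_2020,2020,1,1,1,0,1,rural
racial_inequity_medicaid_2021,2021,0,1,0,0,0,racial_ethnic_minority
methadone_gender_disparities_2021,2021,1,1,1,0,0,women
pregnancy_rural_american_indian_2021,2021,0,1,0,0,1,women;racial_ethnic_minority;rural
moud_incarceration_2022,2022,1,1,0,0,1,carceral
jail_release_continuity_2022,2022,0,1,0,0,1,carceral
women_moud_engagement_2022,2022,1,0,1,1,0,women
pregnant_women_meta_synthesis_2022,2022,1,0,1,1,0,women
minoritized_oat_barriers_2022,2022,1,0,0,1,0,racial_ethnic_minority
segregation_facility_availability_2022,2022,0,1,0,0,0,racial_ethnic_minority
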