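service_code,label,population,intervention_eligible,control_eligible,printed_p_eligibility,intervention_received,control_received,printed_p_uptake
covid1,COVID-19 (1st dose),immunisations,608,1643,-,48,94,0.06
covid2,COVID-19 (2nd dose),immunisations,608,1643,-,97,205,0.03
covid_booster,COVID-19 (booster),immunisations,608,1643,-,213,376,<0.01
shingles,Shingles,immunisations,30,68,-,2,4,0.88
dtap_ipv_hib_hepb,DTaP/IPV/Hib/HepB (3rd dose),immunisations,1,7,0.41,0,0,-
dtap_ipv,DTaP/IPV,immunisations,8,23,0.35,1,4,0.75
hib_menc,Hib/MenC,immunisations,7,28,0.88,0,3,0.37
hpv,HPV,immunisations,12,20,0.35,1,0,0.19
influenza,Influenza,immunisations,173,417,0.18,49,62,<0.01
menb3,MenB (3rd dose),immunisations,7,28,0.14,0,3,0.37
mmr1,MMR (1st dose),immunisations,13,46,0.35,0,3,0.34
mmr2,MMR (2nd dose),immunisations,13,46,0.16,0,0,-
pcv1,PCV (1st dose),immunisations,1,7,0.38,1,5,0.54
pcv2,PCV (2nd dose),immunisations,1,5,0.35,0,3,0.27
ppv,PPV,immunisations,97,247,0.57,2,1,0.14
rotavirus,Rotavirus (2nd dose),immunisations,1,7,0.59,1,5,0.54
bowel,Bowel cancer screening,screening_hc,39,79,0.11,12,26,0.81
breast,Breast cancer screening,screening_hc,32,65,0.15,1,0,0.15
cervical_25_49,Cervical cancer screening (25-49),screening_hc,81,274,0.01,11,25,0.24
cervical_50_64,Cervical cancer screening (50-64),screening_hc,43,78,0.02,4,8,0.87
health_check,NHS Health Check,screening_hc,51,105,0.07,18,13,<0.01
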