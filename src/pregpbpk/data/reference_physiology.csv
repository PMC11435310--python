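# Adult reference whole-body physiology (ICRP-style reference persons).
# volume_fraction: L per kg body weight (reference body: male 73 kg, female 60 kg)
# flow_fraction: fraction of cardiac output (lung carries the full cardiac output
# in series and is listed with flow_fraction 0; rest_of_body closes both balances)
sex,tissue,volume_fraction,flow_fraction
male,lung,0.00685,0.0
male,adipose,0.24932,0.050
male,muscle,0.39726,0.170
male,liver,0.02466,0.065
male,kidney,0.00425,0.190
male,heart,0.00452,0.040
male,brain,0.01986,0.120
male,skin,0.04521,0.050
male,gut,0.01603,0.150
male,spleen,0.00205,0.030
male,reproductive,0.00068,0.002
male,rest_of_body,0.10498,0.133
male,arterial_blood,0.02301,0.0
male,venous_blood,0.05370,0.0
female,lung,0.00700,0.0
female,adipose,0.37500,0.085
female,muscle,0.29167,0.120
female,liver,0.02333,0.065
female,kidney,0.00458,0.170
female,heart,0.00417,0.050
female,brain,0.02167,0.120
female,skin,0.03833,0.050
female,gut,0.01667,0.160
female,spleen,0.00217,0.030
female,reproductive,0.00150,0.004
female,rest_of_body,0.09796,0.146
female,arterial_blood,0.02050,0.0
female,venous_blood,0.04783,0.0
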