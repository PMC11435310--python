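# Printed model-validation rows: predicted (pred) and observed (obs)
# AUC0-t (µg·h/mL), Cmax (µg/mL) and Tmax (h) with the reported %PE cells.
# fixture: ltg_adult / ltg_pregnancy / efv_adult / efv_pregnancy
fixture,dose_mg,gestational_week,source,auc0t_pred,auc0t_obs,auc0t_pe,cmax_pred,cmax_obs,cmax_pe,tmax_pred,tmax_obs,tmax_pe
ltg_adult,25,0,Ebert,8.42,7.9,6.64,0.31,0.26,18.27,1.6,2.65,-39.62
ltg_adult,75,0,Peck,25.85,23.30,10.92,1.03,0.883,17.11,1.1,2.108,-47.82
ltg_adult,100,0,van Luin,33.81,33.8,0.07,1.37,1.13,20.89,1.14,2.13,-47.8
ltg_adult,200,0,Incecayir,91.56,106.91,-14.35,2.75,2.84,-3.13,1.1,1.77,-37.99
ltg_adult,200,0,Wootton,93.001,89.027,4.470,2.74,2.36,16.01,1.1,2.538,-56.66
ltg_pregnancy,400,32,Reimers,47.67,43.4,9.84,5.05,5.3,-4.064,1.32,2.3,-42.6
efv_adult,400,0,Cerrone,45.58,52.86,-13.78,3.24,2.98,8.89,,,
efv_adult,600,0,Villani,68.99,100.61,-31.42,4.9,6.034,-18.79,1.92,3.034,-36.72
efv_pregnancy,600,33,Cressey,20.77,165.18,-87.4283,2.79,8.33,-66.39,1.36,1.94,-30.04
efv_pregnancy,600,23,Lartey,22.27,43.00,-48.22,2.99,3.09,-3.22,1.28,3.61,-64.51
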