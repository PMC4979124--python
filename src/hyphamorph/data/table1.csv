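strain,substrate,inoculation,rpm,tween,length_mean_um,length_sd_um,width_mean_um,width_sd_um,branches_per_cell,fpu_per_ml,protein_g_per_l
delta-cre1,wheat straw,agar,190,False,10.21,3.43,3.29,1.34,0.40,1.74,0.59
delta-cre1,wheat straw,agar,150,False,10.08,3.17,2.80,0.80,0.41,0.69,0.33
delta-cre1,wheat straw,spore,190,False,8.82,4.18,3.85,0.89,0.38,1.88,0.57
delta-cre1,wheat straw,spore,150,False,9.75,2.92,3.47,1.06,0.48,1.82,0.30
delta-cre1,wheat straw,agar,190,True,11.73,3.81,3.60,1.51,0.40,1.27,0.38
delta-cre1,wheat straw,spore,190,True,7.87,2.21,3.98,1.09,0.08,2.31,0.59
delta-cre1,lactose,agar,190,False,11.75,4.12,3.01,0.77,0.43,,0.27
delta-cre1,lactose,agar,150,False,11.67,4.64,3.20,0.56,0.25,,0.26
delta-cre1,lactose,spore,190,False,10.51,3.20,3.42,0.97,0.28,,0.30
delta-cre1,lactose,spore,150,False,8.55,3.32,2.91,1.01,0.50,,0.26
QM9414,wheat straw,agar,190,False,11.84,3.43,3.05,0.94,0.05,0.88,0.64
QM9414,wheat straw,agar,150,False,10.21,2.92,3.04,1.03,0.40,0.84,0.31
QM9414,wheat straw,spore,190,False,10.42,3.15,3.32,1.23,0.01,1.45,0.58
QM9414,wheat straw,spore,150,False,10.20,3.21,2.35,0.95,0.26,1.64,0.26
QM9414,wheat straw,agar,190,True,12.47,3.83,2.67,1.27,0.06,0.77,0.43
QM9414,wheat straw,spore,190,True,10.09,2.67,3.30,1.41,0.40,1.14,0.44
QM9414,lactose,agar,190,False,16.74,5.40,2.59,0.69,0.25,,0.09
QM9414,lactose,agar,150,False,14.24,4.11,3.03,1.20,0.31,,0.25
QM9414,lactose,spore,190,False,13.53,4.82,2.82,0.64,0.23,,0.09
QM9414,lactose,spore,150,False,10.59,3.47,3.32,0.53,0.49,,0.26
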