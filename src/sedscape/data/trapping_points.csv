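source,width_m,te
Liu et al. 2008,3,0.68
Liu et al. 2008,5,0.78
Liu et al. 2008,7,0.85
Liu et al. 2008,10,0.91
Liu et al. 2008,15,0.94
Park et al. 2011,5,0.72
Park et al. 2011,10,0.88
Park et al. 2011,20,0.96
Park et al. 2011,30,0.98
Yuan et al. 2009,4.6,0.70
Yuan et al. 2009,6.1,0.81
Yuan et al. 2009,9.1,0.89
Yuan et al. 2009,15.2,0.95
Yuan et al. 2009,30.5,0.99
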