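trait,canopy,treatment,mean,ci_lo,ci_hi,unit,display_scale
A_lum,shade,control,14.5,9.6,19.5,um2,1
A_lum,shade,drought,13.1,8.2,18.0,um2,1
A_lum,sun,control,20.2,15.2,25.1,um2,1
A_lum,sun,drought,16.3,11.3,21.2,um2,1
A_n,shade,control,0.35,0.29,0.42,mm2,1
A_n,shade,drought,0.34,0.28,0.40,mm2,1
A_n,sun,control,0.76,0.69,0.82,mm2,1
A_n,sun,drought,0.63,0.57,0.69,mm2,1
A_p,shade,control,1270,740,1800,um2,100
A_p,shade,drought,1310,780,1840,um2,100
A_p,sun,control,2940,2400,3450,um2,100
A_p,sun,drought,2870,2340,3410,um2,100
A_p_pct,shade,control,0.37,0.27,0.47,pct,1
A_p_pct,shade,drought,0.39,0.30,0.50,pct,1
A_p_pct,sun,control,0.39,0.29,0.49,pct,1
A_p_pct,sun,drought,0.47,0.36,0.56,pct,1
A_v,shade,control,0.019,0.014,0.024,mm2,0.001
A_v,shade,drought,0.017,0.012,0.022,mm2,0.001
A_v,sun,control,0.048,0.043,0.053,mm2,0.001
A_v,sun,drought,0.042,0.037,0.047,mm2,0.001
A_x,shade,control,930,650,1210,um2,100
A_x,shade,drought,900,620,1170,um2,100
A_x,sun,control,2060,1780,2340,um2,100
A_x,sun,drought,1700,1420,1970,um2,100
A_x_pct,shade,control,0.27,0.22,0.33,pct,1
A_x_pct,shade,drought,0.27,0.21,0.32,pct,1
A_x_pct,sun,control,0.27,0.22,0.33,pct,1
A_x_pct,sun,drought,0.27,0.21,0.32,pct,1
d_max,shade,control,5.2,4.4,6.0,um,1
d_max,shade,drought,4.9,4.1,5.7,um,1
d_max,sun,control,6.2,5.4,7.0,um,1
d_max,sun,drought,5.6,4.8,6.4,um,1
d_min,shade,control,3.4,2.9,3.9,um,1
d_min,shade,drought,3.2,2.7,3.7,um,1
d_min,sun,control,3.8,3.3,4.3,um,1
d_min,sun,drought,3.5,3.0,3.9,um,1
F_t,shade,control,1.61,1.55,1.66,ratio,1
F_t,shade,drought,1.60,1.55,1.66,ratio,1
F_t,sun,control,1.75,1.69,1.81,ratio,1
F_t,sun,drought,1.72,1.67,1.77,ratio,1
k_th,shade,control,1.8e-10,1.0e-10,3.2e-10,kg_m_s-1_MPa-1,1e-11
k_th,shade,drought,1.4e-10,8e-11,2.6e-10,kg_m_s-1_MPa-1,1e-11
k_th,sun,control,6.1e-10,3.4e-10,1.09e-09,kg_m_s-1_MPa-1,1e-11
k_th,sun,drought,3.6e-10,2.0e-10,6.4e-10,kg_m_s-1_MPa-1,1e-11
k_s,shade,control,2.2e-13,1.0e-13,3.3e-13,kg_m-1_s-1_MPa-1,1e-12
k_s,shade,drought,1.8e-13,6e-14,3.0e-13,kg_m-1_s-1_MPa-1,1e-12
k_s,sun,control,3.4e-13,2.3e-13,4.6e-13,kg_m-1_s-1_MPa-1,1e-12
k_s,sun,drought,2.3e-13,1.1e-13,3.5e-13,kg_m-1_s-1_MPa-1,1e-12
N_lum,shade,control,291,145,437,um2,1
N_lum,shade,drought,263,118,409,um2,1
N_lum,sun,control,713,567,860,um2,1
N_lum,sun,drought,519,373,665,um2,1
N_t,shade,control,20.4,18.2,22.6,count,1
N_t,shade,drought,20.0,17.9,22.1,count,1
N_t,sun,control,35.1,32.8,37.5,count,1
N_t,sun,drought,31.9,29.7,34.1,count,1
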