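alpha_x0: 0.0036
alpha_x1: 0.011
alpha_y0: 0.0054
alpha_y1: 0.017
p_x0: 0.89
p_x1: 0.445
p_y0: 0.97
p_y1: 0.485
c_xx: 5.6e-06
c_xy: 5.4e-06
c_yx: 5.2e-06
c_yy: 5.0e-06
s_x0: 0.14
s_y0: 0.0714
A_x0: 34.0
A_x1: 3200000.0
A_y0: 34.0
A_y1: 3200000.0
d_x1: 0.0037
d_x2: 0.15
d_y1: 0.0037
d_y2: 0.15
e_a: 120000000.0
r_s: 0.086
e_s: 72.0
I: 2.0
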