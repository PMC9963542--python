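# Lid-driven cavity, Re = 100: horizontal velocity u/U_lid along the vertical
# line through the geometric centre. Literature reference values of
# Ghia, Ghia & Shin (1982), 129x129 grid. y normalized by cavity height.
y,u
0.0000,0.00000
0.0547,-0.03717
0.0625,-0.04192
0.0703,-0.04775
0.1016,-0.06434
0.1719,-0.10150
0.2813,-0.15662
0.4531,-0.21090
0.5000,-0.20581
0.6172,-0.13641
0.7344,0.00332
0.8516,0.23151
0.9531,0.68717
0.9609,0.73722
0.9688,0.78871
0.9766,0.84123
1.0000,1.00000
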