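# Steady drag coefficient of a circular cylinder at low Reynolds
# number, tabulated from the Clift-Grace-Weber empirical correlation
# (branches 0.1 < Re <= 5 and 5 < Re <= 40).
re,cd
0.1,59.6810
0.2,35.3352
0.3,26.1386
0.5,18.0226
0.7,14.2009
1.0,11.1133
1.5,8.5096
2.0,7.1069
3.0,5.6009
5.0,4.2801
7.0,3.5296
10.0,2.9031
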