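# Default chemical-shift assignment windows (ppm) for the eleven signals
# of a triacylglycerol 1H spectrum.
[windows]
F = [0.80, 0.925]
E = [0.925, 1.06]
G = [1.12, 1.48]
D = [1.50, 1.74]
C = [1.90, 2.14]
B = [2.18, 2.42]
A = [2.65, 2.89]
alpha1 = [4.05, 4.22]
alpha2 = [4.22, 4.39]
beta = [5.12, 5.26]
H = [5.26, 5.52]
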