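# Distance (mm) of the first left-main bifurcation from the ostium,
# one expert-annotated training case per line.
21.00
21.96
17.94
17.64
10.86
22.38
15.69
11.19
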