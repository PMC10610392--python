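trait_set,component,eigenvalue
all,1,3.76
all,2,2.81
all,3,2.70
all,4,2.21
all,5,2.06
all,6,1.39
all,7,1.21
all,8,1.03
all,9,0.736
all,10,0.533
gy_related,1,1.78
gy_related,2,1.23
gy_related,3,0.98
gy_related,4,0.61
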