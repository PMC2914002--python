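name,value
k7,2.81
k8,-0.739
k9,0.99898
k10,-0.000026515
k11,10749
k12,-0.027061
k13,5.2826
ppm_to_ugm3,1322
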