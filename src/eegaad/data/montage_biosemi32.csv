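name,x,y,z
Fp1,0.912466,0.296478,0.281968
AF3,0.730617,0.530824,0.429446
F7,0.513061,0.830150,0.218218
F3,0.555563,0.555563,0.618628
FC1,0.307618,0.307618,0.900413
FC5,0.299791,0.784862,0.542326
T7,0.000000,0.951057,0.309017
C3,0.000000,0.587785,0.809017
CP1,-0.307618,0.307618,0.900413
CP5,-0.299791,0.784862,0.542326
P7,-0.513061,0.830150,0.218218
P3,-0.555563,0.555563,0.618628
Pz,-0.587785,0.000000,0.809017
PO3,-0.730617,0.530824,0.429446
O1,-0.912466,0.296478,0.281968
Oz,-0.951057,0.000000,0.309017
O2,-0.912466,-0.296478,0.281968
PO4,-0.730617,-0.530824,0.429446
P4,-0.555563,-0.555563,0.618628
P8,-0.513061,-0.830150,0.218218
CP6,-0.299791,-0.784862,0.542326
CP2,-0.307618,-0.307618,0.900413
C4,0.000000,-0.587785,0.809017
T8,0.000000,-0.951057,0.309017
FC6,0.299791,-0.784862,0.542326
FC2,0.307618,-0.307618,0.900413
F8,0.513061,-0.830150,0.218218
F4,0.555563,-0.555563,0.618628
AF4,0.730617,-0.530824,0.429446
Fp2,0.912466,-0.296478,0.281968
Fz,0.587785,0.000000,0.809017
Cz,0.000000,0.000000,1.000000
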