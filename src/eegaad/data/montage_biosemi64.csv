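name,x,y,z
Fp1,0.912466,0.296478,0.281968
AF7,0.641187,0.753761,0.143956
AF3,0.730617,0.530824,0.429446
F1,0.578323,0.304042,0.757034
F3,0.555563,0.555563,0.618628
F5,0.530824,0.730617,0.429446
F7,0.513061,0.830150,0.218218
FT7,0.296478,0.912466,0.281968
FC5,0.299791,0.784862,0.542326
FC3,0.304042,0.578323,0.757034
FC1,0.307618,0.307618,0.900413
C1,0.000000,0.309017,0.951057
C3,0.000000,0.587785,0.809017
C5,0.000000,0.809017,0.587785
T7,0.000000,0.951057,0.309017
TP7,-0.296478,0.912466,0.281968
CP5,-0.299791,0.784862,0.542326
CP3,-0.304042,0.578323,0.757034
CP1,-0.307618,0.307618,0.900413
P1,-0.578323,0.304042,0.757034
P3,-0.555563,0.555563,0.618628
P5,-0.530824,0.730617,0.429446
P7,-0.513061,0.830150,0.218218
P9,-0.506732,0.862104,0.000000
PO7,-0.641187,0.753761,0.143956
PO3,-0.730617,0.530824,0.429446
O1,-0.912466,0.296478,0.281968
Iz,-1.000000,0.000000,0.000000
Oz,-0.951057,0.000000,0.309017
POz,-0.809017,0.000000,0.587785
Pz,-0.587785,0.000000,0.809017
CPz,-0.309017,0.000000,0.951057
Fpz,0.951057,0.000000,0.309017
Fp2,0.912466,-0.296478,0.281968
AF8,0.641187,-0.753761,0.143956
AF4,0.730617,-0.530824,0.429446
AFz,0.809017,0.000000,0.587785
Fz,0.587785,0.000000,0.809017
F2,0.578323,-0.304042,0.757034
F4,0.555563,-0.555563,0.618628
F6,0.530824,-0.730617,0.429446
F8,0.513061,-0.830150,0.218218
FT8,0.296478,-0.912466,0.281968
FC6,0.299791,-0.784862,0.542326
FC4,0.304042,-0.578323,0.757034
FC2,0.307618,-0.307618,0.900413
FCz,0.309017,0.000000,0.951057
Cz,0.000000,0.000000,1.000000
C2,0.000000,-0.309017,0.951057
C4,0.000000,-0.587785,0.809017
C6,0.000000,-0.809017,0.587785
T8,0.000000,-0.951057,0.309017
TP8,-0.296478,-0.912466,0.281968
CP6,-0.299791,-0.784862,0.542326
CP4,-0.304042,-0.578323,0.757034
CP2,-0.307618,-0.307618,0.900413
P2,-0.578323,-0.304042,0.757034
P4,-0.555563,-0.555563,0.618628
P6,-0.530824,-0.730617,0.429446
P8,-0.513061,-0.830150,0.218218
P10,-0.506732,-0.862104,0.000000
PO8,-0.641187,-0.753761,0.143956
PO4,-0.730617,-0.530824,0.429446
O2,-0.912466,-0.296478,0.281968
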