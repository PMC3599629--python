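instrument,item,location,corrected_location,se
AS-18-D,AS-18-D1,0.902,0.766,0.354
AS-18-D,AS-18-D2,0.096,-0.039,0.164
AS-18-D,AS-18-D3,0.677,0.541,0.324
AS-18-D,AS-18-D4,0.479,0.344,0.182
AS-18-D,AS-18-D5,0.299,0.164,0.221
AS-18-D,AS-18-D6,-0.134,-0.270,0.303
AS-18-D,AS-18-D7,0.241,0.106,0.187
AS-18-D,AS-18-D8,0.635,0.499,0.276
AS-18-D,AS-18-D9,1.542,1.406,0.239
PHQ9,PHQ9:1,0.055,-0.013,0.189
PHQ9,PHQ9:2,-0.094,-0.162,0.168
PHQ9,PHQ9:3,-0.266,-0.334,0.244
PHQ9,PHQ9:4,-0.114,-0.182,0.221
PHQ9,PHQ9:5,0.551,0.483,0.284
PHQ9,PHQ9:6,0.067,-0.001,0.174
PHQ9,PHQ9:7,-0.393,-0.461,0.225
PHQ9,PHQ9:8,0.728,0.660,0.273
PHQ9,PHQ9:9,1.417,1.349,0.263
MADRS,MADRS1,0.160,0.133,0.198
MADRS,MADRS2,0.588,0.561,0.222
MADRS,MADRS3,-0.252,-0.279,0.284
MADRS,MADRS4,1.832,1.805,1.372
MADRS,MADRS5,1.161,1.134,0.361
MADRS,MADRS6,-0.582,-0.609,0.314
MADRS,MADRS7,0.641,0.614,0.439
MADRS,MADRS8,0.052,0.025,0.409
MADRS,MADRS9,-0.178,-0.205,0.247
MADRS,MADRS10,1.197,1.170,0.309
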