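instrument,item,rel_info_display,rel_info,discrimination,se
AS-18-D,AS-18-D1,<5,,0.574,0.188
AS-18-D,AS-18-D2,30,30,2.845,0.723
AS-18-D,AS-18-D3,5,5,0.923,0.220
AS-18-D,AS-18-D4,10,10,1.256,0.908
AS-18-D,AS-18-D5,15,15,1.751,0.274
AS-18-D,AS-18-D6,5,5,0.861,0.189
AS-18-D,AS-18-D7,10,10,1.313,0.331
AS-18-D,AS-18-D8,10,10,1.102,0.253
AS-18-D,AS-18-D9,15,15,1.710,0.416
PHQ9,PHQ9:1,>25,25,2.425,0.390
PHQ9,PHQ9:2,10,10,1.266,0.593
PHQ9,PHQ9:3,5,5,0.918,0.183
PHQ9,PHQ9:4,10,10,1.209,0.216
PHQ9,PHQ9:5,5,5,0.704,0.209
PHQ9,PHQ9:6,15,15,1.484,0.426
PHQ9,PHQ9:7,10,10,1.245,0.269
PHQ9,PHQ9:8,5,5,0.891,0.173
PHQ9,PHQ9:9,10,10,1.150,0.278
MADRS,MADRS1,25,25,1.927,0.719
MADRS,MADRS2,15,15,1.425,0.481
MADRS,MADRS3,15,15,1.175,0.239
MADRS,MADRS4,<<5,,0.273,0.047
MADRS,MADRS5,5,5,0.712,0.209
MADRS,MADRS6,5,5,0.659,0.180
MADRS,MADRS7,5,5,0.783,0.134
MADRS,MADRS8,10,10,1.065,0.155
MADRS,MADRS9,10,10,0.898,0.259
MADRS,MADRS10,5,5,0.683,0.233
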