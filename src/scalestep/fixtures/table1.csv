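instrument,item,c0,c1,c2,c3,c4,c5,c6,missing
AS-18-D,AS-18-D1,26,11,10,9,5,,,0
AS-18-D,AS-18-D2,11,12,11,15,11,,,1
AS-18-D,AS-18-D3,25,9,12,12,3,,,0
AS-18-D,AS-18-D4,14,8,14,17,8,,,0
AS-18-D,AS-18-D5,16,7,14,14,9,,,1
AS-18-D,AS-18-D6,14,10,13,15,9,,,0
AS-18-D,AS-18-D7,17,8,11,12,13,,,0
AS-18-D,AS-18-D8,22,11,15,7,5,,,1
AS-18-D,AS-18-D9,37,12,8,2,1,,,1
PHQ9,PHQ9:1,13,16,13,17,,,,2
PHQ9,PHQ9:2,18,12,8,23,,,,0
PHQ9,PHQ9:3,13,12,12,24,,,,0
PHQ9,PHQ9:4,11,20,10,20,,,,0
PHQ9,PHQ9:5,25,12,13,11,,,,0
PHQ9,PHQ9:6,18,10,13,20,,,,0
PHQ9,PHQ9:7,17,8,12,24,,,,0
PHQ9,PHQ9:8,26,15,10,10,,,,0
PHQ9,PHQ9:9,38,16,3,4,,,,0
MADRS,MADRS1,24,12,12,2,7,3,1,0
MADRS,MADRS2,26,8,15,6,2,0,0,4
MADRS,MADRS3,15,7,15,17,6,1,0,0
MADRS,MADRS4,26,3,10,7,13,0,2,0
MADRS,MADRS5,40,4,9,3,5,0,0,0
MADRS,MADRS6,12,6,12,9,21,0,1,0
MADRS,MADRS7,24,6,18,3,9,1,0,0
MADRS,MADRS8,29,6,15,7,3,0,1,0
MADRS,MADRS9,17,3,19,13,8,0,0,1
MADRS,MADRS10,38,6,10,3,4,0,0,0
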