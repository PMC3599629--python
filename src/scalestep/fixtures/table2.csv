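instrument,item,H
AS-18-D,AS-18-D1,0.326
AS-18-D,AS-18-D2,0.590
AS-18-D,AS-18-D3,0.460
AS-18-D,AS-18-D4,0.576
AS-18-D,AS-18-D5,0.557
AS-18-D,AS-18-D6,0.491
AS-18-D,AS-18-D7,0.543
AS-18-D,AS-18-D8,0.513
AS-18-D,AS-18-D9,0.582
AS-18-D,Total,0.513
AS-18-D,CI_low,0.41
AS-18-D,CI_high,0.63
AS-18-D,alpha,0.89
AS-18-D,n_obs,57
PHQ9,PHQ9:1,0.584
PHQ9,PHQ9:2,0.603
PHQ9,PHQ9:3,0.481
PHQ9,PHQ9:4,0.478
PHQ9,PHQ9:5,0.385
PHQ9,PHQ9:6,0.588
PHQ9,PHQ9:7,0.567
PHQ9,PHQ9:8,0.400
PHQ9,PHQ9:9,0.468
PHQ9,Total,0.510
PHQ9,CI_low,0.42
PHQ9,CI_high,0.61
PHQ9,alpha,0.88
PHQ9,n_obs,59
MADRS,MADRS1,0.469
MADRS,MADRS2,0.442
MADRS,MADRS3,0.419
MADRS,MADRS4,0.103
MADRS,MADRS5,0.338
MADRS,MADRS6,0.358
MADRS,MADRS7,0.281
MADRS,MADRS8,0.388
MADRS,MADRS9,0.371
MADRS,MADRS10,0.257
MADRS,Total,0.339
MADRS,CI_low,0.25
MADRS,CI_high,0.43
MADRS,alpha,0.81
MADRS,n_obs,56
MADRS-x4,MADRS1,0.514
MADRS-x4,MADRS2,0.476
MADRS-x4,MADRS3,0.449
MADRS-x4,MADRS5,0.359
MADRS-x4,MADRS6,0.370
MADRS-x4,MADRS7,0.349
MADRS-x4,MADRS8,0.456
MADRS-x4,MADRS9,0.410
MADRS-x4,MADRS10,0.332
MADRS-x4,Total,0.415
MADRS-x4,CI_low,0.31
MADRS-x4,CI_high,0.51
MADRS-x4,alpha,0.84
MADRS-x4,n_obs,56
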