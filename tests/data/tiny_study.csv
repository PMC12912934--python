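trait,day,condition_id,value,temp,light,nutrient
alpha,1,C1,0.3789,20.0,25.0,100.0
alpha,1,C1,0.3589,20.0,25.0,100.0
alpha,1,C1,0.3155,20.0,25.0,100.0
alpha,1,C1,0.2807,20.0,25.0,100.0
alpha,1,C1,0.2858,20.0,25.0,100.0
alpha,1,C2,0.2105,24.0,57.0,100.0
alpha,1,C2,0.3625,24.0,57.0,100.0
alpha,1,C2,0.3221,24.0,57.0,100.0
alpha,1,C2,0.37,24.0,57.0,100.0
alpha,1,C2,0.3725,24.0,57.0,100.0
alpha,1,C3,0.401,20.0,57.0,200.0
alpha,1,C3,0.3033,20.0,57.0,200.0
alpha,1,C3,0.3447,20.0,57.0,200.0
alpha,1,C3,0.4185,20.0,57.0,200.0
alpha,1,C3,0.2916,20.0,57.0,200.0
alpha,2,C1,0.3029,20.0,25.0,100.0
alpha,2,C1,0.304,20.0,25.0,100.0
alpha,2,C1,0.2247,20.0,25.0,100.0
alpha,2,C1,0.322,20.0,25.0,100.0
alpha,2,C1,0.2327,20.0,25.0,100.0
alpha,2,C2,0.4457,24.0,57.0,100.0
alpha,2,C2,0.2897,24.0,57.0,100.0
alpha,2,C2,0.3801,24.0,57.0,100.0
alpha,2,C2,0.3597,24.0,57.0,100.0
alpha,2,C2,0.3868,24.0,57.0,100.0
alpha,2,C3,0.3601,20.0,57.0,200.0
alpha,2,C3,0.2813,20.0,57.0,200.0
alpha,2,C3,0.3568,20.0,57.0,200.0
alpha,2,C3,0.2974,20.0,57.0,200.0
alpha,2,C3,0.3709,20.0,57.0,200.0
alpha,3,C1,0.2313,20.0,25.0,100.0
alpha,3,C1,0.2567,20.0,25.0,100.0
alpha,3,C1,0.2968,20.0,25.0,100.0
alpha,3,C1,0.3421,20.0,25.0,100.0
alpha,3,C1,0.2821,20.0,25.0,100.0
alpha,3,C2,0.3722,24.0,57.0,100.0
alpha,3,C2,0.4592,24.0,57.0,100.0
alpha,3,C2,0.4209,24.0,57.0,100.0
alpha,3,C2,0.379,24.0,57.0,100.0
alpha,3,C2,0.3474,24.0,57.0,100.0
alpha,3,C3,0.3042,20.0,57.0,200.0
alpha,3,C3,0.314,20.0,57.0,200.0
alpha,3,C3,0.2931,20.0,57.0,200.0
alpha,3,C3,0.3593,20.0,57.0,200.0
alpha,3,C3,0.372,20.0,57.0,200.0
ek,1,C1,90.5278,20.0,25.0,100.0
ek,1,C1,66.6522,20.0,25.0,100.0
ek,1,C1,78.803,20.0,25.0,100.0
ek,1,C1,72.4763,20.0,25.0,100.0
ek,1,C1,107.0231,20.0,25.0,100.0
ek,1,C2,106.8735,24.0,57.0,100.0
ek,1,C2,70.0793,24.0,57.0,100.0
ek,1,C2,107.6235,24.0,57.0,100.0
ek,1,C2,104.0312,24.0,57.0,100.0
ek,1,C2,95.3316,24.0,57.0,100.0
ek,1,C3,99.5425,20.0,57.0,200.0
ek,1,C3,100.2251,20.0,57.0,200.0
ek,1,C3,86.0619,20.0,57.0,200.0
ek,1,C3,94.5349,20.0,57.0,200.0
ek,1,C3,80.3305,20.0,57.0,200.0
ek,2,C1,78.7,20.0,25.0,100.0
ek,2,C1,81.0088,20.0,25.0,100.0
ek,2,C1,88.2083,20.0,25.0,100.0
ek,2,C1,79.2098,20.0,25.0,100.0
ek,2,C1,80.121,20.0,25.0,100.0
ek,2,C2,100.7331,24.0,57.0,100.0
ek,2,C2,76.309,24.0,57.0,100.0
ek,2,C2,99.7227,24.0,57.0,100.0
ek,2,C2,107.489,24.0,57.0,100.0
ek,2,C2,108.6166,24.0,57.0,100.0
ek,2,C3,96.3279,20.0,57.0,200.0
ek,2,C3,78.933,20.0,57.0,200.0
ek,2,C3,95.9198,20.0,57.0,200.0
ek,2,C3,99.8496,20.0,57.0,200.0
ek,2,C3,94.7405,20.0,57.0,200.0
ek,3,C1,73.4923,20.0,25.0,100.0
ek,3,C1,85.6857,20.0,25.0,100.0
ek,3,C1,72.5125,20.0,25.0,100.0
ek,3,C1,67.7052,20.0,25.0,100.0
ek,3,C1,90.4841,20.0,25.0,100.0
ek,3,C2,106.6596,24.0,57.0,100.0
ek,3,C2,118.6218,24.0,57.0,100.0
ek,3,C2,117.3593,24.0,57.0,100.0
ek,3,C2,92.3093,24.0,57.0,100.0
ek,3,C2,94.9233,24.0,57.0,100.0
ek,3,C3,109.0035,20.0,57.0,200.0
ek,3,C3,77.0675,20.0,57.0,200.0
ek,3,C3,94.5235,20.0,57.0,200.0
ek,3,C3,83.8036,20.0,57.0,200.0
ek,3,C3,81.314,20.0,57.0,200.0
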