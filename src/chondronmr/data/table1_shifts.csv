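ring,reporter,nucleus,anomer,ha4,cn4,abs_printed
N1,H-1,1H,alpha,5.155,5.205,0.050
N1,H-1,1H,beta,4.713,4.665,0.048
N1,H-2,1H,alpha,4.034,4.273,0.239
N1,H-2,1H,beta,3.806,3.983,0.177
N1,H-3,1H,alpha,3.890,3.986,0.096
N1,H-3,1H,beta,3.716,3.795,0.079
N1,H-4,1H,alpha,3.552,4.190,0.638
N1,H-4,1H,beta,3.514,4.118,0.604
N1,H-5,1H,alpha,3.869,4.104,0.235
N1,H-5,1H,beta,3.472,n/d,n/d
N1,H6proR,1H,alpha,3.792,3.727,0.065
N1,H6proR,1H,beta,3.750,3.652,0.098
N1,H6proS,1H,alpha,3.827,3.727,0.100
N1,H6proS,1H,beta,3.890,3.600,0.290
N1,HMe,1H,alpha,2.014,2.013,0.001
N1,HMe,1H,beta,2.015,1.995,0.020
U2,H-1,1H,alpha,4.507,4.547,0.040
U2,H-1,1H,beta,4.467,4.484,0.017
U2,H-2,1H,alpha,3.366,3.368,0.002
U2,H-2,1H,beta,3.363,3.368,0.005
U2,H-3,1H,alpha,3.585,3.582,0.003
U2,H-3,1H,beta,3.580,3.582,0.002
U2,H-4,1H,alpha,3.748,3.746,0.002
U2,H-4,1H,beta,3.744,3.746,0.002
U2,H-5,1H,alpha,3.712,3.684,0.028
U2,H-5,1H,beta,3.703,3.684,0.019
N3,H-1,1H,n/a,4.560,4.494,0.066
N3,H-2,1H,n/a,3.851,4.004,0.153
N3,H-3,1H,n/a,3.707,3.795,0.088
N3,H-4,1H,n/a,3.542,4.164,0.622
N3,H-5,1H,n/a,3.484,3.687,0.203
N3,H6proR,1H,n/a,3.780,3.755,0.025
N3,H6proS,1H,n/a,3.921,3.755,0.166
N3,HMe,1H,n/a,2.028,2.021,0.007
U4,H-1,1H,n/a,4.458,4.472,0.014
U4,H-2,1H,n/a,3.321,3.314,0.007
U4,H-3,1H,n/a,3.496,3.466,0.030
U4,H-4,1H,n/a,3.497,3.470,0.027
U4,H-5,1H,n/a,3.723,3.669,0.054
N1,C-1,13C,alpha,93.879,94.010,0.131
N1,C-1,13C,beta,97.589,98.023,0.434
N1,C-2,13C,alpha,55.817,55.121,0.696
N1,C-2,13C,beta,58.454,55.142,3.312
N1,C-3,13C,alpha,82.758,80.073,2.685
N1,C-3,13C,beta,85.151,83.066,2.085
N1,C-4,13C,alpha,71.390,71.345,0.045
N1,C-4,13C,beta,71.351,70.679,0.672
N1,C-5,13C,alpha,74.080,73.089,0.991
N1,C-5,13C,beta,78.264,n/d,n/d
N1,C-6,13C,alpha,63.398,64.103,0.705
N1,C-6,13C,beta,63.567,65.672,2.105
N1,CMe,13C,alpha,24.814,24.947,0.133
N1,CMe,13C,beta,25.065,24.095,0.970
U2,C-1,13C,alpha,105.675,106.812,1.137
U2,C-1,13C,beta,105.818,106.907,1.089
U2,C-2,13C,alpha,75.324,75.332,0.008
U2,C-2,13C,beta,75.294,75.332,0.038
U2,C-3,13C,n/a,76.506,76.641,0.135
U2,C-4,13C,n/a,82.781,82.502,0.279
U2,C-5,13C,n/a,79.098,79.006,0.092
N3,C-1,13C,n/a,103.325,103.646,0.321
N3,C-2,13C,n/a,57.049,53.794,3.255
N3,C-3,13C,n/a,85.839,83.801,2.038
N3,C-4,13C,n/a,71.357,70.494,0.863
N3,C-5,13C,n/a,78.183,77.773,0.410
N3,C-6,13C,n/a,63.390,63.925,0.535
N3,CMe,13C,n/a,25.326,25.274,0.052
U4,C-1,13C,n/a,105.715,106.882,1.167
U4,C-2,13C,n/a,75.578,75.580,0.002
U4,C-3,13C,n/a,78.213,78.201,0.012
U4,C-4,13C,n/a,74.560,74.644,0.084
U4,C-5,13C,n/a,78.477,78.957,0.480
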