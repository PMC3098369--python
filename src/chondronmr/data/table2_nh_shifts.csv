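ring,nucleus,cn4,ha4,cn6,ha6,cn8,ha8,cn10,ha10
N1alpha,1H,8.081,8.188,8.082,8.189,8.080,8.191,8.081,8.191
N1alpha,15N,123.312,122.943,123.322,122.947,122.319,122.362,123.322,122.951
N1beta,1H,8.184,8.271,8.183,8.271,8.183,8.181,8.180,8.271
N1beta,15N,122.354,122.089,122.363,122.098,122.362,122.101,122.362,122.098
N3,1H,7.974,8.055,7.976,8.052,7.975,8.052,7.975,8.053
N3,15N,122.337,122.134,122.326,121.996,122.329,121.996,122.333,121.993
N5,1H,,,7.963,8.042,7.961,8.042,7.960,8.040
N5,15N,,,122.299,122.097,122.288,121.954,122.290,121.942
N7,1H,,,,,n/d,8.042,n/d,8.043
N7,15N,,,,,n/d,121.907,n/d,121.950
N9,1H,,,,,,,n/d,8.042
N9,15N,,,,,,,n/d,122.093
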