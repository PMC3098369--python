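ring,coupling,cn4,cn6,cn8,cn10
N1alpha,1J_HN,92.74,93.13,92.74,92.71
N1alpha,3J_HNH2,9.39,8.98,9.40,9.55
N1beta,1J_HN,91.57,91.61,91.55,91.74
N1beta,3J_HNH2,9.69,9.75,9.71,9.76
N3,1J_HN,91.85,91.94,n/d,n/d
N3,3J_HNH2,9.75,n/d,n/d,n/d
N5,1J_HN,,91.89,n/d,n/d
N5,3J_HNH2,,n/d,n/d,n/d
N7,1J_HN,,,91.97,n/d
N7,3J_HNH2,,,n/d,n/d
N9,1J_HN,,,,91.89
N9,3J_HNH2,,,,n/d
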