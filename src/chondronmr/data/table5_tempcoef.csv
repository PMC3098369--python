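dp,residue,delta_5C,delta_25C,delta_35C,coef_cn,coef_ha,diff_printed
4,N1alpha,8.3,8.2,8.1,-8.4,-9.1,0.7
4,N1beta,8.4,8.3,8.2,-7.4,-7.6,0.2
4,N3,8.0,7.9,7.8,-7.2,-6.9,-0.3
6,N1alpha,8.3,8.2,8.1,-8.0,-9.1,1.1
6,N1beta,8.4,8.3,8.2,-7.0,-7.6,0.6
6,N3,8.2,8.1,8.0,-6.9,-6.9,0.0
6,N5,8.0,7.9,7.8,-6.8,-6.7,-0.1
8,N1alpha,8.3,8.2,8.1,-7.9,n/d,n/d
8,N1beta,8.4,8.3,8.2,-7.0,n/d,n/d
8,N3,n/d,n/d,n/d,n/d,n/d,n/d
8,N5,n/d,n/d,n/d,n/d,n/d,n/d
10,N7,8.1,7.9,7.8,-6.9,n/d,n/d
10,N1alpha,8.3,8.2,8.1,-8.0,-9.1,1.1
10,N1beta,8.4,8.3,8.2,-7.0,-7.6,0.6
10,N3,n/d,n/d,n/d,n/d,n/d,n/d
10,N5,n/d,n/d,n/d,n/d,n/d,n/d
10,N7,n/d,n/d,n/d,n/d,n/d,n/d
10,N9,8.1,7.9,7.8,-6.9,-6.9,0.0
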