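ring,anomer,pair,cn4,cn6_calc,ha4,diff_printed
N1,alpha,"1,2",3.72,n/c,3.60,0.12
N1,alpha,"2,3",11.20,n/c,10.56,0.64
N1,alpha,"3,4",0.62,n/c,8.79,-8.17
N1,alpha,"4,5",2.90,n/c,10.06,-7.16
N1,beta,"1,2",8.49,7.80,8.41,0.08
N1,beta,"2,3",10.83,8.80,n/d,n/d
N1,beta,"3,4",0.63,3.10,8.81,-8.18
N1,beta,"4,5",2.37,0.90,10.06,-7.69
U2,alpha,"1,2",7.94,n/c,7.91,0.03
U2,beta,"1,2",7.38,7.00,7.92,-0.54
U2,alpha,"2,3",9.54,n/c,9.46,0.08
U2,beta,"2,3",10.09,7.60,9.46,0.63
U2,n/a,"3,4",7.16,7.80,8.76,-1.60
U2,n/a,"4,5",9.09,8.20,9.67,-0.58
N3,n/a,"1,2",8.24,6.40,8.57,-0.33
N3,n/a,"2,3",n/d,8.80,10.37,2.96
N3,n/a,"3,4",n/d,2.90,n/d,n/d
N3,n/a,"4,5",4.76,0.90,10.00,-5.24
U4,n/a,"1,2",8.47,7.00,7.80,0.67
U4,n/a,"2,3",8.29,8.90,10.37,-2.08
U4,n/a,"3,4",n/d,8.00,s/c,n/d
U4,n/a,"4,5",9.09,8.40,9.78,-0.69
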