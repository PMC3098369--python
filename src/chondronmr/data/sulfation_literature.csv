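site,ring,reporter,delta_unsulfated,delta_sulfated,shift_diff_printed
6-O,N1beta,H6R,3.79,4.14,0.35
6-O,N1beta,H6S,3.83,4.19,0.36
4-O,N3,H-4,3.542,4.18,0.64
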