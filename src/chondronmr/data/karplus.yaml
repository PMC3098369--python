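# Karplus parameter registry.
#
# hcch: coefficient sets for the generalized (substituent-corrected) vicinal
# H-C-C-H equation
#     J(theta) = P1 cos^2(theta) + P2 cos(theta) + P3
#                + sum_i dchi_i * [P4 + P5 cos^2(xi_i * theta + P6 * |dchi_i|)]
# transcribed from the Haasnoot-de Leeuw-Altona parameterisation for three-
# and four-substituted ethane fragments (P6 in degrees).  Beta-substituent
# group corrections are not applied; electronegativity differences vs H are
# the Huggins values.
#
# amide: three-coefficient form A cos^2(theta) + B cos(theta) + C for the
# acetamido HN-C(N)-C2-H2 coupling.  The shipped defaults are an approximate
# parameterisation chosen to reproduce the ~10.5 Hz trans plateau observed
# for N-acetyl amino sugars; edit to taste.
hcch_sets:
  haasnoot_3sub: {P1: 13.22, P2: -0.99, P3: 0.0, P4: 0.87, P5: -2.46, P6: 19.9}
  haasnoot_4sub: {P1: 13.24, P2: -0.91, P3: 0.0, P4: 0.53, P5: -2.41, P6: 15.5}
default_hcch_set: haasnoot_4sub
electronegativities: {O: 1.3, N: 0.85, C: 0.4}
amide: {A: 9.0, B: -1.1, C: 0.4}
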