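structure,dp,angle,linkage,value_deg,abs_delta_printed
CN6 (this NMR/simulation),6,phi,beta1-4,-73,
CN6 (this NMR/simulation),6,psi,beta1-4,-117,
CN6 (this NMR/simulation),6,phi,beta1-3,-72,
CN6 (this NMR/simulation),6,psi,beta1-3,108,
NMR/simulation CS5,5,phi,beta1-4,-67,6
NMR/simulation CS5,5,psi,beta1-4,-124,7
NMR/simulation CS5,5,phi,beta1-3,-61,11
NMR/simulation CS5,5,psi,beta1-3,109,1
X-ray fibre CS,4,phi,beta1-4,-98,25
X-ray fibre CS,4,psi,beta1-4,-174,57
X-ray fibre CS,4,phi,beta1-3,-80,8
X-ray fibre CS,4,psi,beta1-3,107,1
X-ray chondroitinase B CS2,2,phi,beta1-4,-69,4
X-ray chondroitinase B CS2,2,psi,beta1-4,-180,63
X-ray chondroitinase B CS2,2,phi,beta1-3,-89,17
X-ray chondroitinase B CS2,2,psi,beta1-3,108,0
Simulation MM3 CS2,2,phi,beta1-4,-79,6
Simulation MM3 CS2,2,psi,beta1-4,-111,6
Simulation MM3 CS2,2,phi,beta1-3,-79,7
Simulation MM3 CS2,2,psi,beta1-3,90,18
Simulation CHARMM CN4,4,phi,beta1-4,-70,3
Simulation CHARMM CN4,4,psi,beta1-4,-120,3
Simulation CHARMM CN4,4,phi,beta1-3,-70,2
Simulation CHARMM CN4,4,psi,beta1-3,90,18
NMR/simulation CS8,8,phi,beta1-4,-80,7
NMR/simulation CS8,8,psi,beta1-4,-110,7
NMR/simulation CS8,8,phi,beta1-3,-80,8
NMR/simulation CS8,8,psi,beta1-3,90,18
NMR HA8,8,phi,beta1-4,-71,4
NMR HA8,8,psi,beta1-4,-116,7
NMR HA8,8,phi,beta1-3,-68,8
NMR HA8,8,psi,beta1-3,129,20
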