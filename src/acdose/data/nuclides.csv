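name,half_life_value,half_life_unit,alpha_energies,gamma_probability,photopeak_keV,reference
Ac-225,9.92,d,5.8:1.0,0.0,,NuDat 3.0 (ENSDF)
Fr-221,4.8,min,6.3:1.0,0.114,218,NuDat 3.0 (ENSDF)
At-217,32,ms,7.1:1.0,0.0,,NuDat 3.0 (ENSDF)
Bi-213,45.6,min,5.9:0.022,0.259,440,NuDat 3.0 (ENSDF)
Po-213,3.7,us,8.4:1.0,0.0,,NuDat 3.0 (ENSDF)
Tl-209,2.2,min,,0.0,,NuDat 3.0 (ENSDF)
Pb-209,3.234,h,,0.0,,NuDat 3.0 (ENSDF)
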