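# X-ray emission line library and relative detection sensitivities.
# energy_keV: line energy; rel_intensity: within-element family weight;
# sensitivity: counts per (ppm * s) per unit flux-area scale, monotone in Z
# over the Mg-Sr K-line range covered by a 17.1 keV pink beam.
element,line,energy_keV,rel_intensity,sensitivity
Mg,Ka,1.253,1.00,0.00036
Si,Ka,1.740,1.00,0.00049
Cl,Ka,2.622,0.88,0.0007225
Cl,Kb,2.816,0.12,0.0007225
Ar,Ka,2.958,0.88,0.00081
Ar,Kb,3.191,0.12,0.00081
Ca,Ka,3.691,0.88,0.001
Ca,Kb,4.013,0.12,0.001
Ti,Ka,4.511,0.88,0.00121
Ti,Kb,4.932,0.12,0.00121
V,Ka,4.952,0.88,0.0013225
V,Kb,5.427,0.12,0.0013225
Cr,Ka,5.415,0.88,0.00144
Cr,Kb,5.947,0.12,0.00144
Mn,Ka,5.899,0.88,0.0015625
Mn,Kb,6.490,0.12,0.0015625
Fe,Ka,6.404,0.88,0.00169
Fe,Kb,7.058,0.12,0.00169
Ni,Ka,7.478,0.88,0.00196
Ni,Kb,8.265,0.12,0.00196
Cu,Ka,8.048,0.88,0.0021025
Cu,Kb,8.905,0.12,0.0021025
Zn,Ka,8.639,0.88,0.00225
Zn,Kb,9.572,0.12,0.00225
As,Ka,10.543,0.88,0.0027225
As,Kb,11.726,0.12,0.0027225
Se,Ka,11.222,0.88,0.00289
Se,Kb,12.496,0.12,0.00289
Kr,Ka,12.649,1.00,0.00324
Sr,Ka,14.098,0.88,0.00361
Sr,Kb,15.836,0.12,0.00361
W,La,8.398,0.60,0.0009
W,Lb,9.672,0.40,0.0009
Pb,La,10.552,0.60,0.001
Pb,Lb,12.614,0.40,0.001
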