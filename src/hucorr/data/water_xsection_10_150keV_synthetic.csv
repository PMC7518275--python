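# Photon mass attenuation coefficients of liquid water, 10-150 keV.
# SYNTHETIC fixture: magnitudes follow standard XCOM/NIST-style tabulations of the
# coherent (Rayleigh), incoherent (Compton) and photoelectric components, lightly
# smoothed onto this grid; totals are the row sums (pair production is absent below
# 1.022 MeV). Intended for desk-scale modelling, not dosimetry.
# units_label: mass attenuation coefficient (cm^2/g), water density 1.0 g/cm^3
energy_keV,rayleigh,compton,photoelectric,total
10,0.0780,0.1340,5.1000,5.3120
15,0.0577,0.1520,1.4580,1.6677
20,0.0447,0.1630,0.5985,0.8062
25,0.0354,0.1695,0.2960,0.5009
30,0.0287,0.1738,0.1663,0.3688
35,0.0238,0.1763,0.1023,0.3024
40,0.0200,0.1778,0.0671,0.2649
45,0.0171,0.1785,0.0462,0.2418
50,0.0148,0.1783,0.0330,0.2261
55,0.0129,0.1770,0.0243,0.2142
60,0.0114,0.1755,0.0184,0.2053
64,0.0105,0.1745,0.0150,0.2000
70,0.0091,0.1725,0.0111,0.1927
80,0.0075,0.1692,0.0071,0.1838
90,0.0063,0.1658,0.0049,0.1770
100,0.0053,0.1624,0.0035,0.1712
120,0.0040,0.1561,0.0020,0.1621
150,0.0028,0.1475,0.0011,0.1514
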