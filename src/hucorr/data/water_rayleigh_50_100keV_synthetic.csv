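# Rayleigh attenuation component of water over the CT effective-energy window 50-100 keV.
# SYNTHETIC fixture: values reconstructed from the published power-law curve fit of the
# coherent-scattering component (amplitude 27.696, exponent -1.856); the underlying
# per-energy data points were published only as a figure. Units follow that fit and are
# recorded here as "fit units (relative)": the exponent of any refit is unit-independent,
# the amplitude is meaningful only in these units.
# units_label: fit units (relative)
energy_keV,rayleigh
50,0.0194594
55,0.0163044
60,0.0138729
65,0.0119578
70,0.0104211
75,0.00916861
80,0.00813359
85,0.00726801
90,0.00653647
95,0.00591238
100,0.00537548
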