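"""Fit the Rayleigh cross-section power law of water over the CT energy window.

The coherent-scattering component of water falls off almost exactly as a
power of the photon energy between 50 and 100 keV; its amplitude and
exponent anchor the whole size-correction model.
"""

from hucorr import fit_power_law, load_packaged_table
from hucorr.xsection import RAYLEIGH_FIT_TABLE

table = load_packaged_table(RAYLEIGH_FIT_TABLE)
fit = fit_power_law(table, "rayleigh", e_min=50.0, e_max=100.0)

print(f"fitted over {table.n_rows} energies in [{fit.fit_range[0]:g}, {fit.fit_range[1]:g}] keV")
print(f"amplitude A        = {fit.amplitude:.3f}  ({table.units_label})")
print(f"exponent b         = {fit.exponent:.4f}")
print(f"rms rel. residual  = {fit.rms_relative_residual:.2e}")
print()
print("sigma_R(V) ~ A * V**b: the exponent is unit-independent; the gain term")
print("f(x, V) = A V^(b+1) / (eps x + beta + b + 1) inherits these constants.")
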