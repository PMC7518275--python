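"""Predict how CT numbers shift with body size, depth and tube voltage.

A bone-like insert measured in an 18 cm head phantom reads differently when
the same insert sits inside a 33 x 27 cm abdomen phantom, and differently
again at another depth within the same body.  The correction model predicts
both changes from the Rayleigh gain term alone.
"""

from hucorr import (
    BeamModelParams,
    MaterialTable,
    ScannerCalibration,
    build_phantom_spec,
    load_packaged_table,
    predict_delta_hu_depth,
    predict_delta_hu_size,
)

calib = ScannerCalibration()        # 30 cm / 110 kVp calibration, eps = 0.045
params = BeamModelParams()          # A = 27.696, b = -1.856, beta = 2
xsec = load_packaged_table()        # water attenuation, 10-150 keV
materials = MaterialTable()         # CIRS-style nominal HU fixtures

head = build_phantom_spec("head")
abdomen = build_phantom_spec("abdomen")
d6_head = head.depth_of_hole(6)       # 3.5 cm below the head surface
d6_abd = abdomen.depth_of_hole(6)     # 11.0 cm below the abdomen surface
d14 = abdomen.depth_of_hole(14)       # 5.0 cm, 6 cm outboard of hole 6

print("size contrast: insert at hole 6, 18 cm head -> 30 cm abdomen")
print("depth contrast: hole 6 -> hole 14 within the abdomen")
print()
print(f"{'material':<10} {'kVp':>4} {'dHU size':>9} {'dHU depth':>10}")
for material in ("adipose", "muscle", "bone200", "bone1250"):
    for kvp in (80, 110, 130):
        ds = predict_delta_hu_size(material, kvp, 18.0, 30.0, calib, params, xsec, materials,
                                   depth1=d6_head, depth2=d6_abd)
        dd = predict_delta_hu_depth(material, kvp, d6_abd, d14, 30.0, calib, params, xsec, materials)
        print(f"{material:<10} {kvp:>4} {ds:>9.1f} {dd:>10.1f}")
print()
print("size changes dominate depth changes, are largest for the densest bone")
print("at 80 kVp, and fade as the tube voltage (hence effective energy) rises.")
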