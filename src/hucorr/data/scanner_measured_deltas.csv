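# Scanner-measured CT-number changes, shipped for comparison only.
# These are published measurements from a Siemens Somatom Emotion scanner with CIRS
# electron-density phantoms (18 cm circle vs 33 x 27 cm ellipse, tissue insert at the
# hole-6 / hole-14 positions). They are scanner- and reconstruction-specific and are
# NOT reproduced by this package's model; use them only to annotate comparison plots.
# Only the headline values reported numerically in the source text are included.
# contrast "size": hole 6, small -> large phantom. contrast "depth": hole 6 -> hole 14
# within the large phantom.
material,kvp,contrast,delta_hu
bone1250,80,size,174
bone1250,80,depth,31
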