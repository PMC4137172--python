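# Raw predictor vocabulary -> canonical compartment.
# Keys are matched case-insensitively; values name CanonicalCompartment members.
# "Non-cytoplasmic" is deliberately distinct from "Unknown": the predictor could
# exclude a cytoplasmic localization without determining the compartment.
Cytoplasmic: CYTOPLASM
Cytoplasm: CYTOPLASM
Intracellular: CYTOPLASM
CytoplasmicMembrane: CYTOPLASMIC_MEMBRANE
Cytoplasmic membrane: CYTOPLASMIC_MEMBRANE
Membrane: CYTOPLASMIC_MEMBRANE
Cellwall: CELL_WALL
Cell wall: CELL_WALL
Extracellular: EXTRACELLULAR
Secreted: EXTRACELLULAR
Secretory: EXTRACELLULAR
Unknown: UNKNOWN
"Unknown (may have multiple localization sites)": UNKNOWN
Non-cytoplasmic: SURFACE_UNKNOWN
Noncytoplasmic: SURFACE_UNKNOWN
Surface-unknown: SURFACE_UNKNOWN
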