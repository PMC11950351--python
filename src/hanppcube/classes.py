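"""Registry of the 32 land-use classes and the 5 aggregate land-use types."""

from __future__ import annotations

#: The 22 crop classes carried as separate cropland layers.
CROP_CLASSES = [
    "CL-WHEA", "CL-RICE", "CL-BARL", "CL-MAIZ", "CL-REST", "CL-MILL",
    "CL-SORG", "CL-POTA", "CL-SWPY", "CL-CASS", "CL-SUGC", "CL-SUGB",
    "CL-BEAN", "CL-OPUL", "CL-SOYB", "CL-GROU", "CL-OOIL", "CL-COTT",
    "CL-BANP", "CL-COFF", "CL-VEFR", "CL-OFIB",
]

CROPLAND_CLASSES = CROP_CLASSES + ["CL-FODD", "CL-FALL"]

ALL_CLASSES = CROPLAND_CLASSES + [
    "BU-builtup",
    "GL-notrees", "GL-owl",
    "FO-con", "FO-ncon",
    "WILD-core", "WILD-periphery", "WILD-nps",
]

assert len(ALL_CLASSES) == 32

#: Aggregation of classes to the five land-use types.
LU_TYPE = {name: "Cropland" for name in CROPLAND_CLASSES}
LU_TYPE.update({
    "BU-builtup": "Built-up",
    "GL-notrees": "Grazing",
    "GL-owl": "Grazing",
    "FO-con": "Forestry",
    "FO-ncon": "Forestry",
    "WILD-core": "Wilderness",
    "WILD-periphery": "Wilderness",
    "WILD-nps": "Wilderness",
})

LU_TYPES = ["Cropland", "Grazing", "Forestry", "Built-up", "Wilderness"]

#: Classes with no harvest layer in the output schema.
NO_HARVEST_CLASSES = {"CL-FALL", "WILD-core", "WILD-periphery", "WILD-nps"}

#: Classes whose land-conversion flow is zero by definition.
ZERO_LUC_CLASSES = {"FO-con", "FO-ncon", "WILD-core", "WILD-periphery", "WILD-nps"}
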