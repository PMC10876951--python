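"""The nine-class land-cover scheme shared across the pipeline."""

BARE_SOIL = 1
BUILT_UP = 2
BURNED_FOREST = 3  # burned before 2022
CROPLAND = 4
FOREST = 5
GRASSLAND = 6
WATER = 7
WETLAND = 8
WOODLAND = 9

CLASS_NAMES = {
    BARE_SOIL: "bare_soil",
    BUILT_UP: "built_up",
    BURNED_FOREST: "burned_forest",
    CROPLAND: "cropland",
    FOREST: "forest",
    GRASSLAND: "grassland",
    WATER: "water",
    WETLAND: "wetland",
    WOODLAND: "woodland",
}

ALL_CLASSES = frozenset(CLASS_NAMES)
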