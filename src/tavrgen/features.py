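"""Closed enumerations of anatomical structures and morphable features.

The structure set mirrors the materials of the labelled heart model: the
aortic root with its three valve leaflets, the left ventricle, the heart
muscle and the two coronary arteries.  The feature set is the list of
anatomical measurements a TAVR operator cares about, expanded per leaflet
where a quantity exists once per cusp.
"""

from __future__ import annotations

from enum import Enum


class StructureLabel(str, Enum):
    """The eight labelled submeshes of the heart model."""

    AORTA = "aorta"
    LEAFLET_LEFT = "leaflet_left"
    LEAFLET_RIGHT = "leaflet_right"
    LEAFLET_NON = "leaflet_non"
    LEFT_VENTRICLE = "left_ventricle"
    MYOCARDIUM = "myocardium"
    LCA = "lca"
    RCA = "rca"

    @classmethod
    def parse(cls, name: str) -> "StructureLabel":
        try:
            return cls(name)
        except ValueError:
            raise ValueError(
                f"unknown structure label {name!r}; valid labels: "
                + ", ".join(m.value for m in cls)
            ) from None


class FeatureName(str, Enum):
    """Morphable anatomical features of the aortic root model."""

    AORTA_DIAMETER = "aorta_diameter"
    RCA_DISTANCE = "rca_distance"
    LCA_DISTANCE = "lca_distance"
    ST_HEIGHT = "st_height"
    LEAFLET_CALCIFICATION_LEFT = "leaflet_calcification_left"
    LEAFLET_CALCIFICATION_RIGHT = "leaflet_calcification_right"
    LEAFLET_CALCIFICATION_NON = "leaflet_calcification_non"
    LEAFLET_OPENING_LEFT = "leaflet_opening_left"
    LEAFLET_OPENING_RIGHT = "leaflet_opening_right"
    LEAFLET_OPENING_NON = "leaflet_opening_non"
    VALVE_DIAMETER = "valve_diameter"
    BASAL_RING_DIAMETER = "basal_ring_diameter"
    LEAFLET_EFFECTIVE_HEIGHT_LEFT = "leaflet_effective_height_left"
    LEAFLET_EFFECTIVE_HEIGHT_RIGHT = "leaflet_effective_height_right"
    LEAFLET_EFFECTIVE_HEIGHT_NON = "leaflet_effective_height_non"
    VA_HEIGHT = "va_height"

    @classmethod
    def parse(cls, name: str) -> "FeatureName":
        try:
            return cls(name)
        except ValueError:
            raise ValueError(
                f"unknown feature {name!r}; valid features: "
                + ", ".join(m.value for m in cls)
            ) from None


#: leaflet short names used as suffixes and as calcification keys
LEAFLETS = ("left", "right", "non")

#: features that have a geometric realisation on the mesh (everything except
#: the calcification sliders, which act on material density, not geometry)
GEOMETRIC_FEATURES = tuple(
    f
    for f in FeatureName
    if not f.value.startswith("leaflet_calcification")
)

CALCIFICATION_FEATURES = tuple(
    f for f in FeatureName if f.value.startswith("leaflet_calcification")
)
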