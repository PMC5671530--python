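"""npwtox: multiscale simulation of negative pressure wound therapy.

Macro-scale hyperelastic mechanics of a residual limb under suction, coupled
to capillary-scale (Krogh cylinder) oxygen transport through an extended
Fick's law driven by the equivalent pressure stress.
"""

from .geometry import (
    LimbGeometryParams,
    Mesh,
    MeshOptions,
    ROILayerSpec,
    build_limb_geometry,
    define_roi_layers,
    wound_opening_area,
)
from .materials import (
    CAPILLARY_WALL,
    MUSCLE,
    PU_FOAM,
    HyperfoamParams,
    MooneyRivlinParams,
    mr_energy,
    mr_uniaxial_stress,
)
from .macro import NPWTLoadCase, max_deformation, solve_macro, wound_area_change

__version__ = "0.1.0"

__all__ = [
    "LimbGeometryParams",
    "Mesh",
    "MeshOptions",
    "ROILayerSpec",
    "build_limb_geometry",
    "define_roi_layers",
    "wound_opening_area",
    "MooneyRivlinParams",
    "HyperfoamParams",
    "MUSCLE",
    "CAPILLARY_WALL",
    "PU_FOAM",
    "mr_energy",
    "mr_uniaxial_stress",
    "NPWTLoadCase",
    "solve_macro",
    "max_deformation",
    "wound_area_change",
    "NPWTModel",
    "PipelineConfig",
    "run_pipeline",
]


def __getattr__(name):  # lazy: pipeline pulls in most of the package
    if name in ("NPWTModel", "NPWTResults", "PipelineConfig", "run_pipeline"):
        from . import model, pipeline

        return {
            "NPWTModel": model.NPWTModel,
            "NPWTResults": model.NPWTResults,
            "PipelineConfig": pipeline.PipelineConfig,
            "run_pipeline": pipeline.run_pipeline,
        }[name]
    raise AttributeError(name)
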