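"""Region label conventions for the subcortical + sensorimotor atlas used by the pipeline.

The label scheme mimics a PD-specific subcortical atlas (putamen, caudate,
pallidum, substantia nigra, thalamic subnuclei, ...) merged with a motor-area
template (M1, S1, SMA, preSMA, PMd, PMv).  Each anatomical region has a base
integer code; the left-hemisphere voxels carry the base code and the
right-hemisphere voxels carry ``base + RIGHT_OFFSET``.  CSF has a single
hemisphere-less code.
"""

from __future__ import annotations

RIGHT_OFFSET = 100

#: Subcortical nuclei (PD-specific atlas style).
SUBCORTICAL_REGIONS = (
    "Pu", "Ca", "NAC", "VeP", "GPi", "GPe", "SNr", "SNc",
    "RN", "STN", "HN", "TH-AN", "TH-MN", "TH-IML", "TH-LN", "TH-P",
)

#: Sensorimotor cortical regions (motor-area template style).
CORTICAL_REGIONS = ("preSMA", "SMA", "PMd", "PMv", "M1", "S1")

ALL_REGIONS = SUBCORTICAL_REGIONS + CORTICAL_REGIONS

#: name -> base (left hemisphere) label code
REGION_CODES = {name: i + 1 for i, name in enumerate(ALL_REGIONS)}

CSF_CODE = 99


def left_code(region: str) -> int:
    return REGION_CODES[region]


def right_code(region: str) -> int:
    return REGION_CODES[region] + RIGHT_OFFSET


def label_table() -> dict:
    """JSON-serializable label table (region -> {left, right})."""
    table = {
        name: {"left": left_code(name), "right": right_code(name)}
        for name in ALL_REGIONS
    }
    table["CSF"] = {"left": CSF_CODE, "right": CSF_CODE}
    return table


#: Composite regions analyzed as union ROIs to improve contrast-to-noise.
COMPOSITES = {
    "thalamus": ("TH-AN", "TH-MN", "TH-IML", "TH-LN", "TH-P"),
    "basal_ganglia": ("Ca", "GPe", "GPi", "Pu", "NAC", "VeP"),
    "deep_gray_matter": SUBCORTICAL_REGIONS,
}
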